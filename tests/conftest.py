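import numpy as np
import pytest

from deepgam import Dataset, TrainingConfig, init_model


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_dataset():
    """4-row, 3-feature classification table with known labels."""
    X = np.array([[1.0, 2.0, 3.0],
                  [4.0, 5.0, 6.0],
                  [7.0, 8.0, 9.0],
                  [1.5, 2.5, 3.5]])
    y = np.array([1.0, -1.0, -1.0, 1.0])
    return Dataset(X, y, ("age", "bmi", "crp"))


@pytest.fixture
def imbalanced_dataset(rng):
    """n=200 at ~25% positives, 6 features, mild signal on feature 0."""
    X = rng.standard_normal((200, 6))
    latent = 1.2 * X[:, 0] + 0.3 * rng.standard_normal(200)
    thresh = np.quantile(latent, 0.75)
    y = np.where(latent > thresh, 1.0, -1.0)
    return Dataset(X, y, tuple(f"f{i}" for i in range(6)))


@pytest.fixture
def small_model():
    return init_model(M=6, C=8, phi_init=0.05, seed=7)


@pytest.fixture
def quick_config():
    """Small-footprint training configuration for unit tests."""
    return TrainingConfig(epochs=3, channels=8, seed=7)
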