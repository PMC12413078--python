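import numpy as np
import pytest

from deepgam import (
    DeepGAMModel,
    ModelError,
    ScalerStats,
    gate_backward_surrogate,
    gate_forward,
    init_model,
    sigmoid,
)


class TestGate:
    def test_binary_semantics(self):
        assert gate_forward(0.05) == 1.0
        assert gate_forward(-3.0) == 0.0
        assert gate_forward(0.0) == 1.0  # tie at sigma=0.5 is alive
        assert gate_forward(-1e-12) == 0.0

    def test_monotone_in_phi(self, rng):
        phi = np.sort(rng.uniform(-5, 5, 100))
        g = gate_forward(phi)
        assert (np.diff(g) >= 0).all()

    def test_surrogate_values(self):
        assert gate_backward_surrogate(0.0, 1.0) == pytest.approx(0.25)
        # sigma'(0.05) = sigma(0.05) * (1 - sigma(0.05)) = 0.2498438...
        assert gate_backward_surrogate(0.05, 2.0) == pytest.approx(0.4996876, abs=1e-6)

    def test_surrogate_matches_finite_difference_of_sigmoid(self):
        eps = 1e-6
        for phi in np.linspace(-10, 10, 81):
            fd = (sigmoid(phi + eps) - sigmoid(phi - eps)) / (2 * eps)
            assert abs(gate_backward_surrogate(phi, 1.0) - fd) < 1e-6
            assert gate_backward_surrogate(phi, 1.0) > 0  # strictly positive


class TestShapeNetworks:
    def test_output_zero_at_zero_input(self, small_model, rng):
        # bias-free composition: f(0) = 0 exactly, for every feature
        for j in range(small_model.m):
            assert small_model.contribution(j, np.zeros(3)).tolist() == [0.0, 0.0, 0.0]

    def test_single_channel_closed_form(self):
        m = init_model(M=1, C=1, phi_init=0.05, seed=0)
        m.W1[:] = 1.0
        m.W2[:] = 1.0
        m.W3[:] = 1.0
        assert m.contribution(0, np.array([0.5]))[0] == pytest.approx(np.tanh(0.5))
        assert m.contribution(0, np.array([0.5]))[0] == pytest.approx(0.462117, abs=1e-6)
        # negative input dies at the first ReLU
        assert m.contribution(0, np.array([-2.0]))[0] == 0.0

    def test_tanh_bound_under_extreme_inputs(self, rng):
        # mathematically the open interval (-1, 1); under float rounding
        # saturated tanh returns exactly +-1.0, never beyond; 10^4 pairs
        for trial in range(100):
            m = init_model(M=4, C=16, phi_init=0.5, seed=trial)
            m.W3 *= 50.0  # exaggerate weights
            X = rng.standard_normal((25, 4)) * 10 ** rng.integers(0, 4)
            _, contribs = m.forward_batch(X)
            assert (np.abs(contribs) <= 1.0).all()

    def test_tanh_strictly_inside_at_moderate_magnitudes(self, rng):
        for trial in range(10):
            m = init_model(M=4, C=16, phi_init=0.5, seed=trial)
            _, contribs = m.forward_batch(rng.standard_normal((25, 4)) * 3)
            assert (np.abs(contribs) < 1.0).all()


class TestModelForward:
    def test_additivity_exact(self, small_model, rng):
        X = rng.standard_normal((10, small_model.m))
        scores, contribs = small_model.forward_batch(X)
        np.testing.assert_array_equal(scores, small_model.beta0 + contribs.sum(axis=1))
        # full forward equals beta0 + sum of single-feature forwards, exactly
        for i in range(3):
            total = small_model.beta0
            for j in range(small_model.m):
                xj = np.zeros((1, small_model.m))
                xj[0, j] = X[i, j]
                total += small_model.forward_batch(xj)[1][0, j]
            assert scores[i] == pytest.approx(total, abs=1e-12)

    def test_dead_feature_contributes_exactly_zero(self, small_model, rng):
        small_model.phi[2] = -1.0
        X = rng.standard_normal((8, small_model.m)) * 100
        _, contribs = small_model.forward_batch(X)
        assert (contribs[:, 2] == 0.0).all()

    def test_all_dead_returns_intercept(self, small_model, rng):
        small_model.phi[:] = -1.0
        small_model.beta0 = 0.37
        scores, _ = small_model.forward_batch(rng.standard_normal((5, small_model.m)))
        np.testing.assert_array_equal(scores, 0.37)

    def test_score_within_alive_count_of_intercept(self):
        rng = np.random.default_rng(0)
        for trial in range(50):
            M = int(rng.integers(1, 8))
            m = init_model(M=M, C=4, phi_init=float(rng.uniform(-1, 1)), seed=trial)
            m.W3 *= 30
            m.beta0 = float(rng.uniform(-1, 1))
            scores, _ = m.forward_batch(rng.standard_normal((10, M)) * 5)
            assert (np.abs(scores - m.beta0) <= m.alive_count() + 1e-12).all()

    def test_dimension_mismatch_raises(self, small_model):
        with pytest.raises(ModelError, match="features"):
            small_model.forward_batch(np.ones((2, small_model.m + 1)))

    def test_classify_strict_threshold(self, small_model):
        assert np.where(np.array([0.4]) > 0, 1.0, -1.0)[0] == 1.0
        # scores exactly at the threshold map to -1
        small_model.phi[:] = -1.0
        small_model.beta0 = 0.0
        assert small_model.classify(np.zeros((1, small_model.m)), t=0.0)[0] == -1.0
        small_model.beta0 = 0.4
        assert small_model.classify(np.zeros((1, small_model.m)), t=0.0)[0] == 1.0
        assert small_model.classify(np.zeros((1, small_model.m)), t=0.4)[0] == -1.0


class TestGradients:
    def test_theta_gradients_match_finite_differences(self, rng):
        from deepgam.training import interpretability_penalty, mse_loss

        model = init_model(M=5, C=6, phi_init=0.05, seed=3)
        X = rng.standard_normal((7, 5))
        y = rng.choice([-1.0, 1.0], 7)
        lam = 0.7

        def obj(m):
            s, c = m.forward_batch(X)
            return mse_loss(s, y) + lam * interpretability_penalty(c)

        s, c, cache = model.forward_batch(X, want_cache=True)
        g = model.backward_batch(cache, 2 * (s - y) / 7, (2 * lam / 7) * c)
        eps = 1e-6
        for name in ("W1", "W2", "W3"):
            W = getattr(model, name)
            for _ in range(10):
                idx = tuple(rng.integers(0, d) for d in W.shape)
                W[idx] += eps
                up = obj(model)
                W[idx] -= 2 * eps
                dn = obj(model)
                W[idx] += eps
                assert g[name][idx] == pytest.approx((up - dn) / (2 * eps), abs=1e-6)

    def test_dead_features_receive_no_weight_gradient(self, rng):
        model = init_model(M=4, C=6, phi_init=0.05, seed=1)
        model.phi[1] = -2.0
        X = rng.standard_normal((6, 4))
        s, c, cache = model.forward_batch(X, want_cache=True)
        g = model.backward_batch(cache, np.ones(6), None)
        assert np.all(g["W1"][1] == 0.0)
        assert np.all(g["W2"][1] == 0.0)
        assert np.all(g["W3"][1] == 0.0)
        assert g["phi"][1] == 0.0


class TestInitAndAlive:
    def test_phi_init_aliveness(self):
        m = init_model(M=99, C=4, phi_init=0.05, seed=0)
        assert m.alive_count() == 99
        assert m.alive_features() == list(range(99))  # all tied, index order
        m2 = init_model(M=10, C=4, phi_init=-0.1, seed=0)
        assert m2.alive_count() == 0
        assert m2.alive_features() == []

    def test_alive_ordering_by_phi_descending(self):
        m = init_model(M=3, C=2, phi_init=0.0, seed=0)
        m.phi = np.array([0.05, -1.0, 0.3])
        assert m.alive_features() == [2, 0]

    def test_seeded_init_identical(self):
        a = init_model(M=7, C=9, phi_init=0.05, seed=42)
        b = init_model(M=7, C=9, phi_init=0.05, seed=42)
        np.testing.assert_array_equal(a.W2, b.W2)
        np.testing.assert_array_equal(a.W1, b.W1)


class TestPersistence:
    def test_roundtrip_bit_faithful(self, tmp_path, small_model, rng):
        small_model.scaler = ScalerStats(mean=np.arange(6.0), sd=np.ones(6), degenerate=np.zeros(6, bool))
        small_model.feature_names = tuple("abcdef")
        p = tmp_path / "m.npz"
        small_model.save(p)
        loaded = DeepGAMModel.load(p)
        np.testing.assert_array_equal(loaded.W2, small_model.W2)
        np.testing.assert_array_equal(loaded.phi, small_model.phi)
        np.testing.assert_array_equal(loaded.scaler.mean, small_model.scaler.mean)
        assert loaded.feature_names == small_model.feature_names
        X = rng.standard_normal((100, 6))
        np.testing.assert_array_equal(loaded.predict_score(X), small_model.predict_score(X))

    def test_truncated_file_raises(self, tmp_path, small_model):
        p = tmp_path / "m.npz"
        small_model.save(p)
        p.write_bytes(p.read_bytes()[:50])
        with pytest.raises(ModelError, match="cannot load"):
            DeepGAMModel.load(p)
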