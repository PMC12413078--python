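"""Training: the regularized MSE objective, class-rebalancing sampler, SGD.

The objective, minimised jointly over shape-network weights theta and gate
logits phi, is

    E[ L(y~, y) + lambda1 * R1(y~) + lambda2 * R2(phi) ]

with L the mean squared error against +-1 labels, R1 the interpretability
penalty (batch mean of the sum of squared per-feature contributions — it
discourages large mutually-cancelling effects that would make shape curves
misleading) and R2 the resource penalty (the alive-gate count, whose STE
backward pass is the sum of sigmoids — it prunes features).  L2 weight
decay applies to the shape weights and intercept but not to phi, so decay
never drags gate logits toward the alive/dead boundary at 0.

Class imbalance is handled by a with-replacement sampler whose per-row
weight is inversely proportional to its class frequency, so each epoch's
draw is balanced in expectation.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from .data import Dataset
from .model import DeepGAMModel, gate_forward, sigmoid


class TrainingError(RuntimeError):
    pass


@dataclasses.dataclass
class TrainingConfig:
    """Hyperparameters of the joint objective and its SGD optimisation.

    Defaults are the reference settings for the ~1000-subject / ~100-feature
    clinical regime the package targets: SGD at learning rate 0.01, batch
    16, 40 epochs, C=128 channels, lambda1=1, lambda2=0.005, weight decay
    1e-3, gate logits initialised at 0.05 (all features alive).
    """

    learning_rate: float = 0.01
    batch_size: int = 16
    epochs: int = 40
    lambda1: float = 1.0
    lambda2: float = 0.005
    weight_decay: float = 0.001
    phi_init: float = 0.05
    channels: int = 128
    seed: int = 0
    use_r1: bool = True
    use_tanh: bool = True
    rebalance: bool = True
    freeze_gates: bool = False
    mode: str = "classification"

    def __post_init__(self) -> None:
        if self.learning_rate < 0 or self.lambda1 < 0 or self.lambda2 < 0 or self.weight_decay < 0:
            raise ValueError("rates and penalty weights must be >= 0")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")

    def replace(self, **kw) -> "TrainingConfig":
        return dataclasses.replace(self, **kw)


@dataclasses.dataclass
class TrainingHistory:
    """Per-epoch tracking of the objective terms, alive count, validation F1."""

    objective: list[float] = dataclasses.field(default_factory=list)
    data_loss: list[float] = dataclasses.field(default_factory=list)
    r1: list[float] = dataclasses.field(default_factory=list)
    r2: list[float] = dataclasses.field(default_factory=list)
    alive_count: list[int] = dataclasses.field(default_factory=list)
    val_f1: list[float] = dataclasses.field(default_factory=list)

    def __len__(self) -> int:
        return len(self.objective)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self) + 1),
                "objective": self.objective,
                "data_loss": self.data_loss,
                "r1": self.r1,
                "r2": self.r2,
                "alive_count": self.alive_count,
                "val_f1": self.val_f1 if self.val_f1 else [np.nan] * len(self),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ------------------------------------------------------------------- losses


def mse_loss(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mean over the batch of (score - label)^2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if scores.shape != labels.shape or scores.size == 0:
        raise TrainingError("scores and labels must be equal-length and nonempty")
    return float(np.mean((scores - labels) ** 2))


def interpretability_penalty(contributions: np.ndarray) -> float:
    """R1: batch mean of sum_j f_j(z_j)^2 (sum over features, mean over rows)."""
    c = np.atleast_2d(np.asarray(contributions, dtype=float))
    return float(np.mean(np.sum(c**2, axis=1)))


def resource_penalty(phi: np.ndarray) -> float:
    """R2 forward value: the number of alive gates, sum_j g(phi_j)."""
    return float(gate_forward(phi).sum())


def resource_penalty_grad(phi: np.ndarray) -> np.ndarray:
    """R2's STE gradient: d/dphi_j of sum_j sigma(phi_j)."""
    s = sigmoid(phi)
    return s * (1.0 - s)


def total_objective(
    scores: np.ndarray,
    labels: np.ndarray,
    contributions: np.ndarray,
    phi: np.ndarray,
    config: TrainingConfig,
) -> float:
    """L + lambda1*R1 + lambda2*R2 (R1 dropped when the ablation turns it off)."""
    obj = mse_loss(scores, labels)
    if config.use_r1:
        obj += config.lambda1 * interpretability_penalty(contributions)
    obj += config.lambda2 * resource_penalty(phi)
    return obj


# ------------------------------------------------------------------ sampler


def balanced_sampler_weights(labels: np.ndarray) -> np.ndarray:
    """Per-row sampling weight proportional to 1/(own-class frequency)."""
    labels = np.asarray(labels)
    pos = labels == 1.0
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise TrainingError("balanced sampling requires both classes present")
    w = np.where(pos, 1.0 / n_pos, 1.0 / n_neg)
    return w / w.sum()


def balanced_sampler(labels: np.ndarray, n_draws: int, rng: np.random.Generator) -> np.ndarray:
    """Draw row indices with replacement, inverse-class-frequency weighted."""
    w = balanced_sampler_weights(labels)
    return rng.choice(len(w), size=n_draws, replace=True, p=w)


# --------------------------------------------------------------------- train


def _f1_at_zero(model: DeepGAMModel, data: Dataset) -> float:
    from .evaluation import confusion, classification_metrics

    preds = model.classify(data.X, t=0.0)
    return classification_metrics(confusion(preds, data.y)).f1


def train(
    model: DeepGAMModel,
    train_data: Dataset,
    config: TrainingConfig,
    valid_data: Optional[Dataset] = None,
) -> tuple[DeepGAMModel, TrainingHistory]:
    """SGD on the joint objective; returns the trained model and history.

    Each epoch draws N row indices (from the balanced sampler when
    ``config.rebalance`` and classifying, else a plain reshuffle) and runs
    ceil(N/batch) steps.  History records the epoch-mean objective terms,
    the end-of-epoch alive count and, when ``valid_data`` is given, the
    validation F1 at threshold 0.  Deterministic for a fixed seed.
    """
    if model.m != train_data.m:
        raise TrainingError(f"model has {model.m} features, data has {train_data.m}")
    model = model.copy()
    rng = np.random.default_rng(config.seed)
    n = train_data.n
    lr, wd = config.learning_rate, config.weight_decay
    history = TrainingHistory()
    rebalance = config.rebalance and config.mode == "classification"
    if rebalance:
        weights = balanced_sampler_weights(train_data.y)
    for epoch in range(config.epochs):
        if rebalance:
            order = rng.choice(n, size=n, replace=True, p=weights)
        else:
            order = rng.permutation(n)
        ep_obj = ep_loss = ep_r1 = ep_r2 = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            X, y = train_data.X[idx], train_data.y[idx]
            b = len(idx)
            scores, contribs, cache = model.forward_batch(X, want_cache=True)
            loss = mse_loss(scores, y)
            r1 = interpretability_penalty(contribs)
            r2 = resource_penalty(model.phi)
            obj = loss + (config.lambda1 * r1 if config.use_r1 else 0.0) + config.lambda2 * r2
            if not np.isfinite(obj):
                raise TrainingError(
                    f"non-finite objective at epoch {epoch + 1}, step {n_batches + 1}"
                )
            dscore = 2.0 * (scores - y) / b
            dcontrib = (2.0 * config.lambda1 / b) * contribs if config.use_r1 else None
            grads = model.backward_batch(cache, dscore, dcontrib)
            model.W1 -= lr * (grads["W1"] + wd * model.W1)
            model.W2 -= lr * (grads["W2"] + wd * model.W2)
            model.W3 -= lr * (grads["W3"] + wd * model.W3)
            model.beta0 -= lr * (grads["beta0"] + wd * model.beta0)
            if not config.freeze_gates:
                gphi = grads["phi"] + config.lambda2 * resource_penalty_grad(model.phi)
                model.phi -= lr * gphi
            ep_obj += obj
            ep_loss += loss
            ep_r1 += r1
            ep_r2 += r2
            n_batches += 1
        history.objective.append(ep_obj / n_batches)
        history.data_loss.append(ep_loss / n_batches)
        history.r1.append(ep_r1 / n_batches)
        history.r2.append(ep_r2 / n_batches)
        history.alive_count.append(model.alive_count())
        if valid_data is not None and config.mode == "classification":
            history.val_f1.append(_f1_at_zero(model, valid_data))
    return model, history
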