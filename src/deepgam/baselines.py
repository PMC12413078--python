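"""Comparison heads and feature-ranking workflows.

The comparison models deliberately mirror the gated additive model's
training protocol (same SGD optimiser, batch scheme, balanced sampler,
weight decay) and differ only in architecture and loss:

* SVM — a single linear layer trained with the margin (hinge) loss
  mean max(0, 1 - y*score); this is the "SVM as a single-layer network"
  construction, not a kernel/QP solver.
* Logistic regression — the same linear layer with the log-loss
  mean log(1 + exp(-y*score)).
* Neural network — three fully connected layers (with biases) and ReLU,
  two-way softmax output, cross-entropy loss.

Feature ranking comes either from the trained gate logits (phi descending)
or from an L1-penalised linear model fit by coordinate descent, ranked by
|coefficient|.  ``select_and_retrain`` restricts the data to the top-k of a
ranking and refits from scratch; for the additive model the k gates are
frozen alive (phi excluded from optimisation, lambda2 = 0).
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from .data import Dataset
from .model import DeepGAMModel, init_model
from .training import TrainingConfig, TrainingError, balanced_sampler_weights, train


class RankingError(RuntimeError):
    pass


# --------------------------------------------------------------- linear heads


@dataclasses.dataclass
class LinearHead:
    """Affine scorer w.x + b trained with hinge or logistic loss."""

    weights: np.ndarray
    bias: float
    loss_kind: str  # "hinge" | "cross-entropy"

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.weights + self.bias

    def classify(self, X: np.ndarray, t: float = 0.0) -> np.ndarray:
        return np.where(self.predict_score(X) > t, 1.0, -1.0)


def hinge_loss(scores: np.ndarray, labels: np.ndarray) -> float:
    return float(np.mean(np.maximum(0.0, 1.0 - labels * scores)))


def logistic_loss(scores: np.ndarray, labels: np.ndarray) -> float:
    # log(1 + exp(-m)) computed stably via logaddexp
    return float(np.mean(np.logaddexp(0.0, -labels * scores)))


def _sgd_order(y: np.ndarray, rng: np.random.Generator, rebalance: bool) -> np.ndarray:
    n = len(y)
    if rebalance:
        return rng.choice(n, size=n, replace=True, p=balanced_sampler_weights(y))
    return rng.permutation(n)


def train_linear(data: Dataset, config: TrainingConfig, loss_kind: str) -> LinearHead:
    """SGD on hinge or logistic loss with the shared training protocol."""
    if loss_kind not in ("hinge", "cross-entropy"):
        raise ValueError(f"unknown loss_kind {loss_kind!r}")
    rng = np.random.default_rng(config.seed)
    w = np.zeros(data.m)
    b = 0.0
    lr, wd = config.learning_rate, config.weight_decay
    for _ in range(config.epochs):
        order = _sgd_order(data.y, rng, config.rebalance)
        for start in range(0, data.n, config.batch_size):
            idx = order[start : start + config.batch_size]
            X, y = data.X[idx], data.y[idx]
            s = X @ w + b
            if loss_kind == "hinge":
                active = (1.0 - y * s) > 0.0
                dscore = np.where(active, -y, 0.0) / len(idx)
            else:
                dscore = -y / (1.0 + np.exp(y * s)) / len(idx)
            gw = X.T @ dscore
            gb = float(dscore.sum())
            w -= lr * (gw + wd * w)
            b -= lr * (gb + wd * b)
    return LinearHead(weights=w, bias=b, loss_kind=loss_kind)


# ------------------------------------------------------------------- MLP head


@dataclasses.dataclass
class MLPHead:
    """Three FC layers with ReLU and biases, 2-way softmax output."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    W3: np.ndarray
    b3: np.ndarray

    def _logits(self, X: np.ndarray):
        h1 = np.maximum(X @ self.W1 + self.b1, 0.0)
        h2 = np.maximum(h1 @ self.W2 + self.b2, 0.0)
        return h1, h2, h2 @ self.W3 + self.b3

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Probability of the positive class (column 1 of the softmax)."""
        logits = self._logits(np.asarray(X, dtype=float))[2]
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e[:, 1] / e.sum(axis=1)

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        """Continuous score on the +-1 label scale: p(+1) - p(-1) = 2p - 1.

        Keeps the shared evaluation convention (threshold 0) meaningful
        across heads; the monotone map leaves ROC/AUC unchanged.
        """
        return 2.0 * self.predict_proba(X) - 1.0

    def classify(self, X: np.ndarray, t: float = 0.0) -> np.ndarray:
        return np.where(self.predict_score(X) > t, 1.0, -1.0)


def train_mlp(data: Dataset, config: TrainingConfig, hidden: Optional[int] = None) -> MLPHead:
    """Cross-entropy SGD for the 3-layer ReLU network."""
    rng = np.random.default_rng(config.seed)
    h = hidden if hidden is not None else config.channels
    def u(shape, fan_in):
        return rng.uniform(-1.0, 1.0, size=shape) / np.sqrt(fan_in)
    net = MLPHead(
        W1=u((data.m, h), data.m), b1=np.zeros(h),
        W2=u((h, h), h), b2=np.zeros(h),
        W3=u((h, 2), h), b3=np.zeros(2),
    )
    lr, wd = config.learning_rate, config.weight_decay
    cls = (data.y == 1.0).astype(int)  # 0 = control, 1 = case
    for _ in range(config.epochs):
        order = _sgd_order(data.y, rng, config.rebalance)
        for start in range(0, data.n, config.batch_size):
            idx = order[start : start + config.batch_size]
            X, c = data.X[idx], cls[idx]
            B = len(idx)
            h1, h2, logits = net._logits(X)
            z = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(z)
            p = e / e.sum(axis=1, keepdims=True)
            dlogits = p.copy()
            dlogits[np.arange(B), c] -= 1.0
            dlogits /= B
            gW3 = h2.T @ dlogits
            gb3 = dlogits.sum(0)
            dh2 = np.where(h2 > 0, dlogits @ net.W3.T, 0.0)
            gW2 = h1.T @ dh2
            gb2 = dh2.sum(0)
            dh1 = np.where(h1 > 0, dh2 @ net.W2.T, 0.0)
            gW1 = X.T @ dh1
            gb1 = dh1.sum(0)
            for p_, g_ in ((net.W1, gW1), (net.W2, gW2), (net.W3, gW3)):
                p_ -= lr * (g_ + wd * p_)
            for p_, g_ in ((net.b1, gb1), (net.b2, gb2), (net.b3, gb3)):
                p_ -= lr * g_
    return net


# ------------------------------------------------------------------- rankings


@dataclasses.dataclass(frozen=True)
class FeatureRanking:
    """Ordered feature indices with non-increasing importance scores."""

    indices: tuple[int, ...]
    scores: tuple[float, ...]
    method: str
    feature_names: Optional[tuple[str, ...]] = None

    def top(self, k: int) -> tuple[int, ...]:
        if k < 1 or k > len(self.indices):
            raise RankingError(f"k={k} out of range for a ranking of {len(self.indices)}")
        return self.indices[:k]

    def to_frame(self):
        import pandas as pd

        names = self.feature_names or tuple(str(i) for i in self.indices)
        return pd.DataFrame({
            "rank": np.arange(1, len(self.indices) + 1),
            "feature_index": self.indices,
            "feature_name": names,
            "score": self.scores,
            "method": self.method,
        })


def rank_by_gate(model: DeepGAMModel) -> FeatureRanking:
    """Rank features by gate logit phi descending (ties: lower index first)."""
    order = np.argsort(-model.phi, kind="stable")
    names = None
    if model.feature_names is not None:
        names = tuple(model.feature_names[i] for i in order)
    return FeatureRanking(
        indices=tuple(int(i) for i in order),
        scores=tuple(float(model.phi[i]) for i in order),
        method="ste_gate",
        feature_names=names,
    )


def _lasso_cd(X: np.ndarray, y: np.ndarray, alpha: float, n_sweeps: int = 200, tol: float = 1e-8):
    """Coordinate descent for 1/(2N)||y - Xw - b||^2 + alpha*||w||_1."""
    n, m = X.shape
    w = np.zeros(m)
    b = float(y.mean())
    col_sq = (X**2).sum(axis=0) / n
    r = y - b  # residual = y - Xw - b
    for _ in range(n_sweeps):
        max_delta = 0.0
        for j in range(m):
            if col_sq[j] == 0.0:
                continue
            rho = (X[:, j] @ r) / n + col_sq[j] * w[j]
            new = np.sign(rho) * max(abs(rho) - alpha, 0.0) / col_sq[j]
            if new != w[j]:
                r -= X[:, j] * (new - w[j])
                max_delta = max(max_delta, abs(new - w[j]))
                w[j] = new
        new_b = b + r.mean()
        r -= new_b - b
        b = new_b
        if max_delta < tol:
            break
    return w, b


def rank_by_l1(data: Dataset, regularization_strength: Optional[float] = None, k: Optional[int] = None) -> FeatureRanking:
    """L1-penalised linear ranking by |coefficient| (coordinate descent).

    Give either an explicit ``regularization_strength`` or a target ``k``;
    with ``k``, the strength is found by bisection so that at least k (and
    as close to k as the path allows) coefficients are nonzero.  Strength 0
    reduces to least-squares coefficient ranking.
    """
    X, y = data.X, data.y
    if regularization_strength is None and k is None:
        raise RankingError("need regularization_strength or k")
    if regularization_strength is not None:
        if regularization_strength == 0.0:
            coef = np.linalg.lstsq(np.c_[X, np.ones(data.n)], y, rcond=None)[0][:-1]
        else:
            coef, _ = _lasso_cd(X, y, regularization_strength)
            if np.all(coef == 0.0):
                raise RankingError(
                    f"all coefficients zero at strength {regularization_strength}; try a smaller value"
                )
    else:
        # alpha_max kills every coefficient; bisect down until >= k survive
        yc = y - y.mean()
        alpha_hi = float(np.max(np.abs(X.T @ yc)) / data.n) + 1e-12
        alpha_lo = 0.0
        coef = None
        for _ in range(60):
            alpha = 0.5 * (alpha_lo + alpha_hi)
            w, _ = _lasso_cd(X, y, alpha)
            nnz = int(np.sum(w != 0.0))
            if nnz >= k:
                coef = w
                if nnz == k:
                    break
                alpha_lo = alpha
            else:
                alpha_hi = alpha
        if coef is None or int(np.sum(coef != 0.0)) < k:
            raise RankingError(f"could not find a strength with >= {k} nonzero coefficients")
    order = np.argsort(-np.abs(coef), kind="stable")
    names = tuple(data.feature_names[i] for i in order)
    return FeatureRanking(
        indices=tuple(int(i) for i in order),
        scores=tuple(float(abs(coef[i])) for i in order),
        method="lasso",
        feature_names=names,
    )


# ------------------------------------------------------------ select/retrain


def select_and_retrain(
    data: Dataset,
    ranking: FeatureRanking,
    k: int,
    config: TrainingConfig,
    head: str = "deepgam",
    valid_data: Optional[Dataset] = None,
    feature_subset: Optional[tuple[int, ...]] = None,
):
    """Restrict to the top-k features and refit the chosen head from scratch.

    For the additive model the surviving gates are frozen alive: phi stays
    at its (alive) init, lambda2 is zeroed, and only the shape weights and
    intercept train.  ``feature_subset`` overrides the ranking's top-k (used
    for control experiments with hand-picked or random subsets).
    """
    cols = feature_subset if feature_subset is not None else ranking.top(k)
    sub = data.subset_columns(cols)
    sub_valid = valid_data.subset_columns(cols) if valid_data is not None else None
    if head == "deepgam":
        cfg = config.replace(freeze_gates=True, lambda2=0.0)
        model = init_model(
            sub.m, C=cfg.channels, phi_init=abs(cfg.phi_init), seed=cfg.seed,
            use_tanh=cfg.use_tanh, mode=cfg.mode, feature_names=sub.feature_names,
        )
        fitted, _ = train(model, sub, cfg, valid_data=sub_valid)
        return fitted, cols
    if head == "svm":
        return train_linear(sub, config, "hinge"), cols
    if head == "logistic":
        return train_linear(sub, config, "cross-entropy"), cols
    if head == "mlp":
        return train_mlp(sub, config), cols
    raise ValueError(f"unknown head {head!r}")
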