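"""The additive gated model: STE feature gates + per-feature shape networks.

Prediction is a generalized additive model

    y~(x) = beta0 + sum_j f_j( x_j * g(phi_j) )

where ``g`` is a hard binary gate in the forward pass, ``g(phi)=1`` iff
``sigma(phi) >= 0.5`` i.e. ``phi >= 0``, trained through a straight-through
estimator: the backward pass differentiates the smooth sigmoid instead of
the step.  Each ``f_j`` is a bias-free 3-layer network

    f(z; theta) = tanh( W3 relu( W2 relu( W1 z ) ) )

with ``C`` channels per layer.  Because no layer has a bias term,
``f(0) = 0`` exactly, so a dead gate (``g=0``) makes its feature contribute
exactly nothing, and the tanh output keeps every live contribution inside
(-1, 1) — the per-feature influence bound that makes the shape curves
honest explanations.

The heavy per-batch math is laid out feature-major, shape ``(M, B, C)``, so
the C-by-C middle layer runs as ``M`` stacked BLAS matmuls.
"""

from __future__ import annotations

import dataclasses
import io
import json
from pathlib import Path
from typing import Optional

import numpy as np

from .data import ScalerStats

MODEL_FORMAT_VERSION = 1


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def gate_forward(phi):
    """Hard binary gate: 1 iff sigma(phi) >= 0.5, i.e. phi >= 0.

    The tie sigma(phi)=0.5 resolves to alive, defined through the phi >= 0
    test rather than a rounding routine (avoids round-half-to-even
    ambiguity and makes the conventional init phi=0.05 alive).
    """
    return (np.asarray(phi, dtype=float) >= 0.0).astype(float)


def gate_backward_surrogate(phi, upstream_gradient):
    """STE surrogate: the gate differentiates as sigma(phi).

    Dead gates therefore keep receiving gradient through this path and can
    in principle revive.
    """
    s = sigmoid(phi)
    return np.asarray(upstream_gradient, dtype=float) * s * (1.0 - s)


class ModelError(RuntimeError):
    pass


@dataclasses.dataclass
class DeepGAMModel:
    """Gated additive neural model with M per-feature shape networks.

    Parameters are ``phi`` (M gate logits), ``W1 (M,C)``, ``W2 (M,C,C)``,
    ``W3 (M,C)`` (per-feature weight triples, disjoint across features) and
    the scalar intercept ``beta0``.
    """

    phi: np.ndarray
    W1: np.ndarray
    W2: np.ndarray
    W3: np.ndarray
    beta0: float
    use_tanh: bool = True
    mode: str = "classification"
    scaler: Optional[ScalerStats] = None
    feature_names: Optional[tuple[str, ...]] = None

    @property
    def m(self) -> int:
        return self.phi.shape[0]

    @property
    def channels(self) -> int:
        return self.W1.shape[1]

    # ---------------------------------------------------------------- forward

    def forward_batch(self, X: np.ndarray, want_cache: bool = False):
        """Scores and per-feature contributions for a batch.

        Returns ``(scores, contributions)`` with ``scores = beta0 +
        contributions.sum(axis=1)`` exactly; with ``want_cache`` also the
        intermediate activations needed by :meth:`backward_batch`.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.m:
            raise ModelError(f"input has {X.shape[1]} features, model expects {self.m}")
        g = gate_forward(self.phi)
        Z = X * g  # (B, M)
        Zt = Z.T[:, :, None]  # (M, B, 1)
        A1 = Zt * self.W1[:, None, :]  # (M, B, C)
        H1 = np.maximum(A1, 0.0)
        A2 = H1 @ self.W2.transpose(0, 2, 1)  # (M, B, C)
        H2 = np.maximum(A2, 0.0)
        U = np.einsum("mbc,mc->mb", H2, self.W3)  # (M, B)
        F = np.tanh(U) if self.use_tanh else U
        contributions = F.T  # (B, M)
        scores = self.beta0 + F.sum(axis=0)
        if not want_cache:
            return scores, contributions
        cache = {"X": X, "Z": Z, "Zt": Zt, "A1": A1, "H1": H1, "A2": A2, "H2": H2, "F": F}
        return scores, contributions, cache

    def backward_batch(self, cache: dict, dscore: np.ndarray, dcontrib: Optional[np.ndarray] = None) -> dict:
        """Gradients of a scalar objective w.r.t. all parameters.

        ``dscore`` is d(objective)/d(score) per row; ``dcontrib`` an optional
        extra d(objective)/d(contribution) term (the interpretability
        penalty feeds in here).  The gate logits receive the STE surrogate
        through the gated-input path; dead features pass no gradient to
        their own weights (their activations are identically zero).

        Gradient routing: the shape weights see both terms, but the gate
        logits see only the ``dscore`` (prediction-error) path.  Routing
        the magnitude penalty into the gates as well would, at the
        shape-weight equilibrium, exactly cancel the error-reduction pull
        on precisely the informative features (the penalty's gate gradient
        grows with the fitted effect size), leaving selection to drift;
        decoupled, the gate logit integrates a clean "does scaling this
        feature up reduce error" signal while the penalty still shrinks
        magnitudes through the weights.
        """
        F, H2, H1, A2, A1, Zt, X = (cache[k] for k in ("F", "H2", "H1", "A2", "A1", "Zt", "X"))
        dF = np.broadcast_to(dscore[None, :], F.shape).copy()  # (M, B)
        if dcontrib is not None:
            dF += dcontrib.T
        dU = dF * (1.0 - F**2) if self.use_tanh else dF
        gW3 = np.einsum("mb,mbc->mc", dU, H2)
        dH2 = dU[:, :, None] * self.W3[:, None, :]
        dA2 = np.where(A2 > 0, dH2, 0.0)
        gW2 = dA2.transpose(0, 2, 1) @ H1
        dH1 = dA2 @ self.W2
        dA1 = np.where(A1 > 0, dH1, 0.0)
        gW1 = np.einsum("mbc,mb->mc", dA1, Zt[:, :, 0])
        if dcontrib is None:
            dA1_err = dA1
        else:
            # error-only chain for the gates; the ReLU masks are fixed, so
            # the dU -> dZ map is linear and can be rerun on the dscore part
            dU_err = (np.broadcast_to(dscore[None, :], F.shape) * (1.0 - F**2)
                      if self.use_tanh else np.broadcast_to(dscore[None, :], F.shape))
            dA2_err = np.where(A2 > 0, dU_err[:, :, None] * self.W3[:, None, :], 0.0)
            dA1_err = np.where(A1 > 0, dA2_err @ self.W2, 0.0)
        dZ = np.einsum("mbc,mc->mb", dA1_err, self.W1)  # (M, B)
        gphi = gate_backward_surrogate(self.phi, np.einsum("mb,bm->m", dZ, X))
        gbeta0 = float(dscore.sum())
        return {"W1": gW1, "W2": gW2, "W3": gW3, "beta0": gbeta0, "phi": gphi}

    # --------------------------------------------------------------- services

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        return self.forward_batch(X)[0]

    def classify(self, X: np.ndarray, t: float = 0.0) -> np.ndarray:
        """Hard labels: +1 iff score > t (strict), else -1."""
        return np.where(self.predict_score(X) > t, 1.0, -1.0)

    def contribution(self, feature: int, z: np.ndarray) -> np.ndarray:
        """f_j evaluated on already-gated inputs z (no gate applied here)."""
        z = np.asarray(z, dtype=float)
        h1 = np.maximum(z[:, None] * self.W1[feature][None, :], 0.0)
        h2 = np.maximum(h1 @ self.W2[feature].T, 0.0)
        u = h2 @ self.W3[feature]
        return np.tanh(u) if self.use_tanh else u

    def alive_features(self) -> list[int]:
        """Indices with phi >= 0, ordered by phi descending (ties: lower index first)."""
        alive = np.flatnonzero(self.phi >= 0.0)
        order = np.argsort(-self.phi[alive], kind="stable")
        return [int(i) for i in alive[order]]

    def alive_count(self) -> int:
        return int(gate_forward(self.phi).sum())

    def copy(self) -> "DeepGAMModel":
        return DeepGAMModel(
            phi=self.phi.copy(), W1=self.W1.copy(), W2=self.W2.copy(), W3=self.W3.copy(),
            beta0=self.beta0, use_tanh=self.use_tanh, mode=self.mode,
            scaler=self.scaler, feature_names=self.feature_names,
        )

    # ------------------------------------------------------------ persistence

    def save(self, path: str | Path) -> None:
        meta = {
            "format_version": MODEL_FORMAT_VERSION,
            "use_tanh": self.use_tanh,
            "mode": self.mode,
            "beta0": self.beta0,
            "feature_names": list(self.feature_names) if self.feature_names else None,
            "scaler": self.scaler.to_dict() if self.scaler is not None else None,
        }
        buf = io.BytesIO()
        np.savez(buf, phi=self.phi, W1=self.W1, W2=self.W2, W3=self.W3,
                 meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8))
        Path(path).write_bytes(buf.getvalue())

    @classmethod
    def load(cls, path: str | Path) -> "DeepGAMModel":
        try:
            with np.load(Path(path)) as z:
                meta = json.loads(bytes(z["meta"].tobytes()).decode())
                if meta.get("format_version") != MODEL_FORMAT_VERSION:
                    raise ModelError(f"unsupported model format version {meta.get('format_version')}")
                return cls(
                    phi=z["phi"], W1=z["W1"], W2=z["W2"], W3=z["W3"],
                    beta0=float(meta["beta0"]), use_tanh=meta["use_tanh"], mode=meta["mode"],
                    scaler=ScalerStats.from_dict(meta["scaler"]) if meta["scaler"] else None,
                    feature_names=tuple(meta["feature_names"]) if meta["feature_names"] else None,
                )
        except ModelError:
            raise
        except Exception as e:  # truncated / corrupt archive
            raise ModelError(f"cannot load model from {path}: {e}") from e


def init_model(
    M: int,
    C: int = 128,
    phi_init: float = 0.05,
    seed: int = 0,
    use_tanh: bool = True,
    mode: str = "classification",
    feature_names: Optional[tuple[str, ...]] = None,
) -> DeepGAMModel:
    """Fresh model: all gate logits at ``phi_init``, scaled-uniform weights.

    Hidden weights are drawn uniform in +-1/sqrt(fan_in); the output layer
    uses the smaller +-1/fan_in so every shape function starts near zero
    and the additive ensemble starts at the intercept.  With M ~ 100
    additive terms a full-scale output init makes the initial score sum and
    the interpretability penalty so large that every gate is crushed below
    the alive threshold within the first epoch, before any shape can align
    with the outcome; the near-zero start removes that shock and lets the
    gradual gate pruning play out.  ``beta0`` starts at 0; the conventional
    ``phi_init=0.05`` starts every gate alive (sigma(0.05) ~ 0.512 >= 0.5).
    """
    if M < 1 or C < 1:
        raise ValueError("M and C must be >= 1")
    rng = np.random.default_rng(seed)
    W1 = rng.uniform(-1.0, 1.0, size=(M, C))  # fan_in = 1
    W2 = rng.uniform(-1.0, 1.0, size=(M, C, C)) / np.sqrt(C)
    W3 = rng.uniform(-1.0, 1.0, size=(M, C)) / C
    return DeepGAMModel(
        phi=np.full(M, float(phi_init)), W1=W1, W2=W2, W3=W3, beta0=0.0,
        use_tanh=use_tanh, mode=mode, feature_names=feature_names,
    )
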