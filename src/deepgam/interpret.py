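"""Shape curves, feature histograms, explanation export, ablation suite.

The model's explanation for feature j IS the curve of its additive
contribution f_j over the observed range of x_j.  Grids live in
standardized units (what the model sees) with the raw-unit axis recorded
alongside when a scaler is attached, and are clipped to the [0.5%, 99.5%]
quantiles of the observed values so right-skewed tails do not dominate the
plot range.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .data import Dataset
from .model import DeepGAMModel, gate_forward, init_model
from .training import TrainingConfig, train
from .evaluation import evaluate_classifier


@dataclasses.dataclass(frozen=True)
class ShapeCurve:
    """Per-feature additive-contribution curve on a standardized grid."""

    feature: int
    name: str
    grid: np.ndarray       # standardized units, strictly increasing
    grid_raw: np.ndarray   # original units (equals grid when no scaler)
    values: np.ndarray
    alive: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"grid_std": self.grid, "grid_raw": self.grid_raw, "value": self.values})


def shape_curve(model: DeepGAMModel, feature: int, data: Dataset, n_points: int = 101) -> ShapeCurve:
    """Evaluate f_j(grid * g(phi_j)) over the observed quantile range.

    Dead features yield the identically-zero curve; live tanh-bounded
    curves stay inside (-1, 1).
    """
    if not 0 <= feature < model.m:
        raise IndexError(f"feature {feature} out of range for M={model.m}")
    col = data.X[:, feature]
    lo, hi = np.quantile(col, (0.005, 0.995))
    if hi <= lo:
        hi = lo + 1.0
    grid = np.linspace(lo, hi, n_points)
    g = float(gate_forward(model.phi[feature]))
    values = model.contribution(feature, grid * g)
    if model.scaler is not None:
        grid_raw = grid * model.scaler.sd[feature] + model.scaler.mean[feature]
    else:
        grid_raw = grid.copy()
    name = model.feature_names[feature] if model.feature_names else f"x{feature:03d}"
    return ShapeCurve(feature=feature, name=name, grid=grid, grid_raw=grid_raw,
                      values=values, alive=bool(g))


def feature_histogram(data: Dataset, feature: int, bins: int = 30) -> tuple[np.ndarray, np.ndarray]:
    """Histogram (edges, counts) of one observed column; counts sum to N."""
    if bins < 1:
        raise ValueError("bins must be >= 1")
    counts, edges = np.histogram(data.X[:, feature], bins=bins)
    return edges, counts


def export_explanation(model: DeepGAMModel, data: Dataset, out_dir: str | Path, n_points: int = 101) -> list[Path]:
    """Write one curve CSV per alive feature, histograms, and a summary JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    alive = model.alive_features()
    hist_rows = []
    for j in alive:
        curve = shape_curve(model, j, data, n_points)
        p = out / f"shape_{curve.name}.csv"
        curve.to_frame().to_csv(p, index=False, float_format="%.10g")
        written.append(p)
        edges, counts = feature_histogram(data, j)
        for lo, hi, c in zip(edges[:-1], edges[1:], counts):
            hist_rows.append({"feature": curve.name, "bin_lo": lo, "bin_hi": hi, "count": int(c)})
    hist_path = out / "feature_histograms.csv"
    pd.DataFrame(hist_rows).to_csv(hist_path, index=False, float_format="%.10g")
    written.append(hist_path)
    names = model.feature_names or tuple(f"x{j:03d}" for j in range(model.m))
    summary = {
        "beta0": model.beta0,
        "alive_features": [names[j] for j in alive],
        "alive_indices": alive,
        "phi": model.phi.tolist(),
        "use_tanh": model.use_tanh,
    }
    spath = out / "explanation_summary.json"
    spath.write_text(json.dumps(summary, indent=2, sort_keys=True))
    written.append(spath)
    return written


def plot_shapes(model: DeepGAMModel, data: Dataset, out_path: str | Path, features: Optional[list[int]] = None) -> None:
    """Optional rendering: histogram + shape curve per feature, one column."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    feats = features if features is not None else model.alive_features()
    fig, axes = plt.subplots(len(feats), 2, figsize=(8, 2.2 * len(feats)), squeeze=False)
    for row, j in enumerate(feats):
        curve = shape_curve(model, j, data)
        edges, counts = feature_histogram(data, j)
        axes[row][0].bar(edges[:-1], counts, width=np.diff(edges), align="edge")
        axes[row][0].set_ylabel(curve.name)
        axes[row][1].plot(curve.grid, curve.values)
        axes[row][1].set_ylim(-1.05, 1.05)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


# ------------------------------------------------------------ ablation suite


def ablation_suite(
    train_data: Dataset,
    test_data: Dataset,
    base_config: TrainingConfig,
    seeds: list[int],
) -> pd.DataFrame:
    """Train the four (R1, tanh) on/off variants per seed; summarise.

    Returns one row per variant with seed-mean classification metrics and
    the mean of the per-run max / mean absolute contribution on held-out
    rows — the signatures that distinguish unconstrained (saturating
    beyond +-1), R1-shrunk (low magnitude) and tanh-bounded behaviour.
    """
    rows = []
    for use_r1, use_tanh in ((False, False), (True, False), (False, True), (True, True)):
        per_seed = []
        for seed in seeds:
            cfg = base_config.replace(use_r1=use_r1, use_tanh=use_tanh, seed=seed)
            model = init_model(train_data.m, C=cfg.channels, phi_init=cfg.phi_init,
                               seed=seed, use_tanh=use_tanh, feature_names=train_data.feature_names)
            fitted, _ = train(model, train_data, cfg)
            scores, contribs = fitted.forward_batch(test_data.X)
            rep = evaluate_classifier(scores, test_data.y)
            per_seed.append({
                "auc": rep.auc, "f1": rep.f1, "accuracy": rep.accuracy,
                "max_abs_contribution": float(np.max(np.abs(contribs))),
                "mean_abs_contribution": float(np.mean(np.abs(contribs))),
            })
        agg = {k: float(np.mean([r[k] for r in per_seed])) for k in per_seed[0]}
        rows.append({"use_r1": use_r1, "use_tanh": use_tanh, **agg,
                     "n_runs_exceeding_unit": int(sum(r["max_abs_contribution"] > 1.0 for r in per_seed))})
    return pd.DataFrame(rows)
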