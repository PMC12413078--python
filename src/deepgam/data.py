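"""Tabular data handling: loading, label encoding, standardization, folds.

The in-memory container is :class:`Dataset`, a thin frozen wrapper around a
numpy feature matrix with column names and a target vector.  For
classification the target is encoded internally as +1 (case) / -1 (control);
regression targets are kept as reals under ``mode="regression"``.

Standardization is z-scoring with population (denominator ``N``) statistics
fitted on a training split only; zero-variance columns get their standard
deviation replaced by 1 and are flagged, so applying the transform never
divides by zero.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold


class DataError(ValueError):
    """A table failed validation (non-numeric cell, non-finite value, ...)."""


class ConfigError(ValueError):
    """A requested column / parameter is inconsistent with the data."""


@dataclasses.dataclass(frozen=True)
class Dataset:
    """Feature matrix with named columns and an encoded target.

    Parameters
    ----------
    X
        ``(N, M)`` float array of feature values; must be finite.
    y
        Length-``N`` target. In classification mode every entry is exactly
        +1.0 or -1.0; in regression mode any finite real.
    feature_names
        ``M`` column identifiers.
    mode
        ``"classification"`` or ``"regression"``.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: tuple[str, ...]
    mode: str = "classification"

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        if X.ndim != 2 or X.shape[0] < 1 or X.shape[1] < 1:
            raise DataError(f"feature matrix must be 2-D and nonempty, got shape {X.shape}")
        if y.shape != (X.shape[0],):
            raise DataError(f"target length {y.shape} does not match {X.shape[0]} rows")
        if len(self.feature_names) != X.shape[1]:
            raise DataError("feature_names length does not match number of columns")
        if not np.isfinite(X).all():
            i, j = np.argwhere(~np.isfinite(X))[0]
            raise DataError(f"non-finite feature value at row {i}, column {self.feature_names[j]!r}")
        if not np.isfinite(y).all():
            raise DataError("non-finite target value")
        if self.mode == "classification":
            if not np.all(np.isin(y, (-1.0, 1.0))):
                raise DataError("classification labels must be exactly +1 or -1")
        elif self.mode != "regression":
            raise ConfigError(f"unknown mode {self.mode!r}")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def m(self) -> int:
        return self.X.shape[1]

    @property
    def n_positive(self) -> int:
        if self.mode != "classification":
            raise ConfigError("n_positive is only defined in classification mode")
        return int(np.sum(self.y == 1.0))

    def subset_rows(self, idx: Sequence[int]) -> "Dataset":
        idx = np.asarray(idx, dtype=int)
        return Dataset(self.X[idx], self.y[idx], self.feature_names, self.mode)

    def subset_columns(self, cols: Sequence[int]) -> "Dataset":
        cols = np.asarray(cols, dtype=int)
        names = tuple(self.feature_names[c] for c in cols)
        return Dataset(self.X[:, cols], self.y, names, self.mode)


@dataclasses.dataclass(frozen=True)
class ScalerStats:
    """Per-feature mean / standard deviation fitted on a training split.

    ``degenerate`` flags columns whose variance was zero; their sd is
    replaced by 1 so the transform maps them to all-zeros.
    """

    mean: np.ndarray
    sd: np.ndarray
    degenerate: np.ndarray

    def to_dict(self) -> dict:
        return {
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "degenerate": self.degenerate.astype(int).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScalerStats":
        return cls(
            mean=np.asarray(d["mean"], dtype=float),
            sd=np.asarray(d["sd"], dtype=float),
            degenerate=np.asarray(d["degenerate"], dtype=bool),
        )


def load_table(
    path: str | Path,
    target_column: str,
    positive_label: object = 1,
    impute: str | None = None,
) -> Dataset:
    """Read a CSV table and encode the target as +1 / -1.

    Rows whose target equals ``positive_label`` (compared after casting both
    sides to string, so ``1`` and ``"1"`` match) become +1, all others -1.
    Non-numeric or missing feature cells are a hard error unless
    ``impute="median"`` is given, in which case missing cells are filled with
    the column median.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"no such file: {path}")
    df = pd.read_csv(path)
    if target_column not in df.columns:
        raise ConfigError(f"target column {target_column!r} not found in {path.name}; columns are {list(df.columns)}")
    raw_target = df[target_column]
    feats = df.drop(columns=[target_column])
    feats = feats.apply(pd.to_numeric, errors="coerce")
    if feats.isna().any().any():
        if impute == "median":
            feats = feats.fillna(feats.median())
        else:
            row = int(feats.isna().any(axis=1).idxmax())
            col = feats.columns[feats.isna().any(axis=0)][0]
            raise DataError(f"non-numeric or missing value at row {row}, column {col!r} (pass impute='median' to fill)")
    y = np.where(raw_target.astype(str).values == str(positive_label), 1.0, -1.0)
    return Dataset(feats.to_numpy(dtype=float), y, tuple(feats.columns))


def save_table(data: Dataset, path: str | Path, target_column: str = "target") -> None:
    """Write a Dataset back to CSV with full float precision."""
    df = pd.DataFrame(data.X, columns=list(data.feature_names))
    if data.mode == "classification":
        df[target_column] = data.y.astype(int)
    else:
        df[target_column] = data.y
    df.to_csv(path, index=False, float_format="%.17g")


def fit_standardizer(train: Dataset) -> ScalerStats:
    """Fit per-column z-score statistics (population sd, denominator N)."""
    mean = train.X.mean(axis=0)
    sd = train.X.std(axis=0, ddof=0)
    degenerate = sd == 0.0
    sd = np.where(degenerate, 1.0, sd)
    return ScalerStats(mean=mean, sd=sd, degenerate=degenerate)


def apply_standardizer(data: Dataset, stats: ScalerStats) -> Dataset:
    if stats.mean.shape[0] != data.m:
        raise ConfigError("scaler was fitted on a different number of features")
    return Dataset((data.X - stats.mean) / stats.sd, data.y, data.feature_names, data.mode)


@dataclasses.dataclass(frozen=True)
class FoldPlan:
    """Stratified k-fold assignment; test sets partition the rows."""

    k: int
    seed: int
    train_idx: tuple[np.ndarray, ...]
    test_idx: tuple[np.ndarray, ...]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "k": self.k,
            "seed": self.seed,
            "train_idx": [t.tolist() for t in self.train_idx],
            "test_idx": [t.tolist() for t in self.test_idx],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "FoldPlan":
        d = json.loads(Path(path).read_text())
        return cls(
            k=d["k"],
            seed=d["seed"],
            train_idx=tuple(np.asarray(t, dtype=int) for t in d["train_idx"]),
            test_idx=tuple(np.asarray(t, dtype=int) for t in d["test_idx"]),
        )


def make_folds(data: Dataset, k: int, seed: int) -> FoldPlan:
    """Stratified k-fold split, deterministic for a fixed seed."""
    if k < 2:
        raise ConfigError("k must be >= 2")
    if k > data.n:
        raise ConfigError(f"k={k} exceeds the number of rows {data.n}")
    strata = (data.y == 1.0).astype(int)
    counts = np.bincount(strata, minlength=2)
    if counts.min() < k:
        raise ConfigError(f"stratification impossible: a class has only {counts.min()} members for k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    tr, te = [], []
    for train_i, test_i in skf.split(data.X, strata):
        tr.append(np.asarray(train_i, dtype=int))
        te.append(np.asarray(test_i, dtype=int))
    return FoldPlan(k=k, seed=seed, train_idx=tuple(tr), test_idx=tuple(te))
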