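"""Classification / regression metrics and the cross-validation harness.

Conventions: labels are +-1 with +1 the positive (case) class.  Metrics
with a zero denominator are reported as 0 and flagged, which keeps
cross-fold averaging well defined.  AUC follows the Mann-Whitney
convention: ties between a positive and a negative score earn half credit,
which is exactly what the trapezoidal rule over the tie-grouped ROC yields.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Callable, Optional

import numpy as np

from .data import Dataset, FoldPlan, apply_standardizer, fit_standardizer, make_folds


class MetricError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class Confusion:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclasses.dataclass
class EvalReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    specificity: float
    auc: float = float("nan")
    n: int = 0
    degenerate: tuple[str, ...] = ()
    roc_points: Optional[list[tuple[float, float]]] = None

    def to_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy, "precision": self.precision, "recall": self.recall,
            "f1": self.f1, "specificity": self.specificity, "auc": self.auc, "n": self.n,
            "degenerate": list(self.degenerate),
        }
        if self.roc_points is not None:
            d["roc_points"] = [list(p) for p in self.roc_points]
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


@dataclasses.dataclass(frozen=True)
class RegressionReport:
    mse: float
    r2: float

    def to_dict(self) -> dict:
        return {"mse": self.mse, "r2": self.r2}


def confusion(preds: np.ndarray, labels: np.ndarray) -> Confusion:
    """Count TP/FP/FN/TN for +-1 predictions against +-1 labels."""
    preds = np.asarray(preds, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if preds.shape != labels.shape or preds.size == 0:
        raise MetricError("predictions and labels must be equal-length and nonempty")
    pos_p, pos_l = preds == 1.0, labels == 1.0
    return Confusion(
        tp=int(np.sum(pos_p & pos_l)),
        fp=int(np.sum(pos_p & ~pos_l)),
        fn=int(np.sum(~pos_p & pos_l)),
        tn=int(np.sum(~pos_p & ~pos_l)),
    )


def _ratio(num: int, den: int, name: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def classification_metrics(c: Confusion) -> EvalReport:
    """Accuracy, precision, recall, F1, specificity from a confusion matrix."""
    flags: list[str] = []
    acc = _ratio(c.tp + c.tn, c.n, "accuracy", flags)
    prec = _ratio(c.tp, c.tp + c.fp, "precision", flags)
    rec = _ratio(c.tp, c.tp + c.fn, "recall", flags)
    spec = _ratio(c.tn, c.tn + c.fp, "specificity", flags)
    f1 = _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, "f1", flags)
    return EvalReport(accuracy=acc, precision=prec, recall=rec, f1=f1,
                      specificity=spec, n=c.n, degenerate=tuple(flags))


def roc_and_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[list[tuple[float, float]], float]:
    """ROC points from the sorted unique-score threshold sweep, AUC by trapezoid.

    Equal scores are grouped into a single ROC step, so the trapezoidal area
    equals the Mann-Whitney pair statistic with ties counted 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    n_pos = int(np.sum(labels == 1.0))
    n_neg = int(np.sum(labels == -1.0))
    if n_pos == 0 or n_neg == 0:
        raise MetricError("ROC requires both classes present")
    order = np.argsort(-scores, kind="stable")
    s, l = scores[order], labels[order]
    # group ties: cumulative counts only at the last row of each score group
    boundary = np.r_[s[1:] != s[:-1], True]
    cum_tp = np.cumsum(l == 1.0)[boundary]
    cum_fp = np.cumsum(l == -1.0)[boundary]
    tpr = np.r_[0.0, cum_tp / n_pos]
    fpr = np.r_[0.0, cum_fp / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def regression_metrics(pred: np.ndarray, y: np.ndarray) -> RegressionReport:
    """MSE = mean (y - yhat)^2 and R^2 = 1 - SS_res/SS_tot (may be negative)."""
    pred = np.asarray(pred, dtype=float)
    y = np.asarray(y, dtype=float)
    if pred.shape != y.shape or y.size < 2:
        raise MetricError("need equal-length vectors with n >= 2")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise MetricError("R^2 undefined for a constant target")
    mse = float(np.mean((y - pred) ** 2))
    r2 = 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot
    return RegressionReport(mse=mse, r2=r2)


def evaluate_classifier(scores: np.ndarray, labels: np.ndarray, t: float = 0.0) -> EvalReport:
    """Threshold scores at t (strict >), compute all metrics plus ROC/AUC."""
    preds = np.where(np.asarray(scores, dtype=float) > t, 1.0, -1.0)
    report = classification_metrics(confusion(preds, labels))
    roc, auc = roc_and_auc(scores, labels)
    report.auc = auc
    report.roc_points = roc
    return report


# ------------------------------------------------------------------ CV harness


def mean_report(reports: list[EvalReport]) -> EvalReport:
    """Unweighted mean of per-fold metrics (folds are near-equal size)."""
    fields = ("accuracy", "precision", "recall", "f1", "specificity", "auc")
    vals = {f: float(np.mean([getattr(r, f) for r in reports])) for f in fields}
    return EvalReport(**vals, n=sum(r.n for r in reports))


def cross_validate(
    fit_and_score: Callable[[Dataset, Dataset, int], np.ndarray],
    data: Dataset,
    k: int = 5,
    seed: int = 0,
    fold_plan: Optional[FoldPlan] = None,
) -> tuple[list[EvalReport], EvalReport]:
    """k-fold CV with leakage-free per-fold standardization.

    ``fit_and_score(train, test, fold_seed)`` receives already-standardized
    splits (scaler fitted on that fold's training rows only) and returns
    continuous scores for the test rows.  Returns per-fold reports and
    their unweighted mean.
    """
    plan = fold_plan if fold_plan is not None else make_folds(data, k, seed)
    reports = []
    for fold, (tr, te) in enumerate(zip(plan.train_idx, plan.test_idx)):
        train_split = data.subset_rows(tr)
        test_split = data.subset_rows(te)
        stats = fit_standardizer(train_split)
        scores = fit_and_score(
            apply_standardizer(train_split, stats),
            apply_standardizer(test_split, stats),
            seed + 1000 * fold,
        )
        reports.append(evaluate_classifier(scores, test_split.y))
    return reports, mean_report(reports)
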