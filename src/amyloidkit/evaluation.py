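"""Confusion-matrix metrics, stratified cross-validation and ROC curves.

Metrics follow the standard binary-classification definitions over the
confusion counts: ACC = (TP+TN)/(TP+TN+FP+FN) reported as a percentage,
SE = TP/(TP+FN), SP = TN/(TN+FP), and Matthews correlation coefficient
MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)), with MCC
defined as 0 when any denominator factor is 0.  Cross-validation pools the
confusion counts over stratified folds before computing metrics (per-fold
metrics are also reported); ROC points come from the pooled out-of-fold
positive-class scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN tallies of one evaluated sample set."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp,
            self.tn + other.tn, self.fn + other.fn,
        )


@dataclass
class MetricsReport:
    """ACC (percent), SE/SP (proportions), MCC, and optional ROC curve."""

    acc_pct: float
    se: float
    sp: float
    mcc: float
    counts: ConfusionCounts
    roc_points: np.ndarray | None = None
    auc: float | None = None


def confusion_from_predictions(y_true, y_pred) -> ConfusionCounts:
    """Tally TP/FP/TN/FN from binary label vectors (positive class = 1)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """ACC/SE/SP/MCC from confusion counts (no ROC).

    Degenerate denominators follow the usual conventions: SE/SP are 0 when
    their class is empty, MCC is 0 when any of its four denominator factors
    is 0.
    """
    if counts.total == 0:
        raise ValueError("cannot compute metrics on zero samples")
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    acc = 100.0 * (tp + tn) / counts.total
    se = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    sp = tn / (tn + fp) if (tn + fp) > 0 else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else 0.0
    return MetricsReport(acc_pct=acc, se=se, sp=sp, mcc=mcc, counts=counts)


def roc_points(y_true, scores) -> tuple[np.ndarray, float]:
    """ROC points (FPR, TPR) over all score thresholds, plus trapezoid AUC.

    Thresholds sweep the descending unique scores with ties grouped; the
    curve starts at (0, 0) and ends at (1, 1).
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if np.unique(y_true).size < 2:
        raise ValueError("both classes must be present for a ROC curve")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    fpr, tpr, _ = _sk_roc_curve(y_true, scores, drop_intermediate=False)
    points = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return points, auc


@dataclass
class CrossValResult:
    """Pooled-count metrics plus per-fold counts and secondary per-fold metrics."""

    metrics: MetricsReport
    fold_counts: list[ConfusionCounts]
    fold_metrics: list[MetricsReport] = field(default_factory=list)

    @property
    def accuracy(self) -> float:
        """Pooled accuracy as a proportion in [0, 1]."""
        return self.metrics.acc_pct / 100.0


def cross_validate(
    X, y, model, folds: int = 10, seed: int = 0
) -> CrossValResult:
    """Stratified k-fold cross-validation with pooled confusion counts.

    ``model`` is an unfitted scikit-learn-style classifier; a fresh clone is
    fitted per fold.  Metrics are computed on the counts pooled over all
    folds (matching a single reported ACC/SE/SP/MCC per experiment); the ROC
    curve uses the pooled out-of-fold positive-class scores.  Per-fold
    metrics are returned as a secondary output.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    class_sizes = np.bincount(y.astype(int))
    if class_sizes.min() < folds:
        raise ValueError(
            f"smallest class has {class_sizes.min()} members; "
            f"cannot stratify into {folds} folds"
        )
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_counts: list[ConfusionCounts] = []
    fold_metrics: list[MetricsReport] = []
    pooled_scores = np.zeros(y.shape[0])
    have_scores = True
    for train_idx, test_idx in cv.split(X, y):
        est = clone(model)
        est.fit(X[train_idx], y[train_idx])
        pred = est.predict(X[test_idx])
        counts = confusion_from_predictions(y[test_idx], pred)
        fold_counts.append(counts)
        fold_metrics.append(compute_metrics(counts))
        if hasattr(est, "predict_score"):
            pooled_scores[test_idx] = est.predict_score(X[test_idx])
        elif hasattr(est, "predict_proba"):
            pooled_scores[test_idx] = est.predict_proba(X[test_idx])[:, -1]
        else:
            have_scores = False
    pooled = fold_counts[0]
    for c in fold_counts[1:]:
        pooled = pooled + c
    report = compute_metrics(pooled)
    if have_scores:
        report.roc_points, report.auc = roc_points(y, pooled_scores)
    return CrossValResult(metrics=report, fold_counts=fold_counts, fold_metrics=fold_metrics)
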