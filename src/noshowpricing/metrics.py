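"""Binary classification metrics computed from first principles.

Everything here is derived directly from the four confusion-matrix cells
(positive class = show-up) or from raw scores: classification accuracy,
per-class and support-weighted precision / recall / F1, the Matthews
correlation coefficient, column-normalised rate matrices (the α/β rates the
pricing model consumes), ROC curves with trapezoidal AUC, and binned
calibration curves.

Single summary values follow the support-weighted convention: the per-class
metric is averaged with weights equal to the actual class sizes.  Degenerate
denominators yield 0 with a logged warning rather than an exception, so batch
evaluation never aborts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "PerClass",
    "MetricReport",
    "RatesMatrix",
    "RocCurve",
    "CalibrationCurve",
    "confusion_from_labels",
    "classification_accuracy",
    "precision",
    "recall",
    "f1",
    "mcc",
    "column_rates",
    "roc_auc",
    "calibration_curve",
    "evaluate_predictions",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/TN/FP/FN counts with show-up as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
        if self.total < 1:
            raise ValueError("confusion matrix must contain at least one sample")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def actual_positive(self) -> int:
        return self.tp + self.fn

    @property
    def actual_negative(self) -> int:
        return self.tn + self.fp

    @property
    def predicted_positive(self) -> int:
        return self.tp + self.fp

    @property
    def predicted_negative(self) -> int:
        return self.tn + self.fn


class PerClass(NamedTuple):
    """A metric for each outcome class plus its support-weighted average."""

    positive: float
    negative: float
    weighted: float


@dataclass(frozen=True)
class MetricReport:
    """One row of the performance table: AUC, CA, weighted F1/precision/recall, MCC."""

    auc: float
    ca: float
    f1: float
    precision: float
    recall: float
    mcc: float

    def __post_init__(self) -> None:
        for name in ("auc", "ca", "f1", "precision", "recall"):
            v = getattr(self, name)
            if not (math.isnan(v) or 0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not (math.isnan(self.mcc) or -1.0 <= self.mcc <= 1.0):
            raise ValueError(f"mcc must lie in [-1, 1], got {self.mcc}")


@dataclass(frozen=True)
class RatesMatrix:
    """Column-normalised confusion rates.

    ``alpha`` — P(actual no-show | predicted no-show): how often a no-show
    call is right. ``beta`` — P(actual show-up | predicted show-up): the
    positive predictive value of show-up calls, the show-up rate used by the
    penalty-fee model.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0 or not 0.0 <= self.beta <= 1.0:
            raise ValueError("alpha and beta must lie in [0, 1]")

    @property
    def miss_alpha(self) -> float:
        """P(actual show-up | predicted no-show)."""
        return 1.0 - self.alpha

    @property
    def miss_beta(self) -> float:
        """P(actual no-show | predicted show-up)."""
        return 1.0 - self.beta


@dataclass(frozen=True)
class RocCurve:
    """ROC points ordered from (0, 0) to (1, 1); thresholds decreasing."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


@dataclass(frozen=True)
class CalibrationCurve:
    """Reliability diagram points: mean score, empirical show-up fraction, bin count."""

    mean_score: np.ndarray
    frac_positive: np.ndarray
    counts: np.ndarray


def _as_binary(values: Sequence[int] | np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(values)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must be a 0/1 vector")
    return arr.astype(int)


def confusion_from_labels(actual, predicted) -> ConfusionMatrix:
    """Tally a confusion matrix from 0/1 label vectors (1 = show-up)."""
    a = _as_binary(actual, "actual")
    p = _as_binary(predicted, "predicted")
    if a.shape != p.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {p.shape}")
    return ConfusionMatrix(
        tp=int(((a == 1) & (p == 1)).sum()),
        tn=int(((a == 0) & (p == 0)).sum()),
        fp=int(((a == 0) & (p == 1)).sum()),
        fn=int(((a == 1) & (p == 0)).sum()),
    )


def _safe_ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.warning("%s undefined (zero denominator); reporting 0", what)
        return 0.0
    return num / den


def classification_accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of correctly classified appointments, (TP+TN)/total."""
    return (cm.tp + cm.tn) / cm.total


def precision(cm: ConfusionMatrix) -> PerClass:
    """Per-class precision (TP/(TP+FP) and its no-show mirror) + weighted average."""
    pos = _safe_ratio(cm.tp, cm.predicted_positive, "show-up precision")
    neg = _safe_ratio(cm.tn, cm.predicted_negative, "no-show precision")
    weighted = (cm.actual_positive * pos + cm.actual_negative * neg) / cm.total
    return PerClass(pos, neg, weighted)


def recall(cm: ConfusionMatrix) -> PerClass:
    """Per-class sensitivity (TP/(TP+FN) and its mirror) + weighted average."""
    pos = _safe_ratio(cm.tp, cm.actual_positive, "show-up recall")
    neg = _safe_ratio(cm.tn, cm.actual_negative, "no-show recall")
    weighted = (cm.actual_positive * pos + cm.actual_negative * neg) / cm.total
    return PerClass(pos, neg, weighted)


def f1(cm: ConfusionMatrix) -> PerClass:
    """Per-class harmonic mean of precision and recall + weighted average."""
    p, r = precision(cm), recall(cm)

    def hm(pp: float, rr: float, cls: str) -> float:
        return _safe_ratio(2 * pp * rr, pp + rr, f"{cls} F1")

    pos = hm(p.positive, r.positive, "show-up")
    neg = hm(p.negative, r.negative, "no-show")
    weighted = (cm.actual_positive * pos + cm.actual_negative * neg) / cm.total
    return PerClass(pos, neg, weighted)


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient; 0 with a warning if any margin is empty."""
    denom2 = (
        cm.predicted_positive * cm.actual_positive * cm.actual_negative * cm.predicted_negative
    )
    if denom2 == 0:
        logger.warning("MCC undefined (zero margin); reporting 0")
        return 0.0
    return (cm.tp * cm.tn - cm.fp * cm.fn) / math.sqrt(denom2)


def column_rates(cm: ConfusionMatrix) -> RatesMatrix:
    """Rates normalised within each predicted-class column.

    alpha = TN/(TN+FN) over the predicted-no-show column; beta = TP/(TP+FP)
    over the predicted-show-up column.  Each column of the resulting 2x2 rate
    matrix sums to 1.
    """
    if cm.predicted_negative == 0 or cm.predicted_positive == 0:
        raise ValueError("column rates need at least one prediction in each column")
    return RatesMatrix(alpha=cm.tn / cm.predicted_negative, beta=cm.tp / cm.predicted_positive)


def roc_auc(scores, labels) -> tuple[RocCurve, float]:
    """ROC curve over all score thresholds and its trapezoidal AUC.

    Tied scores are grouped into a single threshold step, so the curve is the
    exact empirical ROC and the AUC equals the normalised Mann-Whitney U
    statistic (ties counted half).
    """
    s = np.asarray(scores, dtype=float)
    y = _as_binary(labels, "labels")
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")

    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    # threshold boundaries: last index of each tied-score group
    distinct = np.flatnonzero(np.diff(s_sorted)) if len(s_sorted) > 1 else np.array([], int)
    idx = np.r_[distinct, len(s_sorted) - 1]
    tps = np.cumsum(y_sorted)[idx]
    fps = np.cumsum(1 - y_sorted)[idx]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    thresholds = np.r_[np.inf, s_sorted[idx]]
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds), auc


def calibration_curve(scores, labels, n_bins: int = 10) -> CalibrationCurve:
    """Reliability diagram on equal-width bins of [0, 1]; empty bins omitted."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    s = np.asarray(scores, dtype=float)
    y = _as_binary(labels, "labels")
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    if (s < 0).any() or (s > 1).any():
        raise ValueError("scores must lie in [0, 1]")
    bins = np.minimum((s * n_bins).astype(int), n_bins - 1)
    counts = np.bincount(bins, minlength=n_bins)
    keep = counts > 0
    sums = np.bincount(bins, weights=s, minlength=n_bins)
    pos = np.bincount(bins, weights=y, minlength=n_bins)
    return CalibrationCurve(
        mean_score=sums[keep] / counts[keep],
        frac_positive=pos[keep] / counts[keep],
        counts=counts[keep],
    )


def evaluate_predictions(actual, predicted, scores=None) -> MetricReport:
    """Full metric row for one model/phase; AUC is NaN when no scores are given."""
    cm = confusion_from_labels(actual, predicted)
    auc = float("nan")
    if scores is not None:
        _, auc = roc_auc(scores, actual)
    return MetricReport(
        auc=auc,
        ca=classification_accuracy(cm),
        f1=f1(cm).weighted,
        precision=precision(cm).weighted,
        recall=recall(cm).weighted,
        mcc=mcc(cm),
    )
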