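"""Confusion-matrix construction and binary classification performance measures.

Inhibitor is the positive class throughout. The measures are the standard
ones used to judge virtual-screening classifiers on imbalanced data:
sensitivity, specificity, accuracy, precision, the geometric mean of
sensitivity and specificity (G-mean) and the Matthews correlation
coefficient (MCC). ROC AUC is computed as the Mann-Whitney rank statistic,
which is exact under ties.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .labels import HIGHER_IS_INHIBITOR, LOWER_IS_INHIBITOR, as_binary

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionMatrix",
    "UndefinedMetricError",
    "confusion",
    "sensitivity",
    "specificity",
    "accuracy",
    "precision",
    "gmean",
    "mcc",
    "roc_auc",
    "classification_report_row",
]


class UndefinedMetricError(ValueError):
    """Raised when a metric's denominator is zero."""


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 cross-tabulation counts with inhibitor as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(predicted: Sequence, truth: Sequence) -> ConfusionMatrix:
    """Cross-tabulate predicted against true labels.

    Labels may be the string vocabulary (``"inhibitor"`` / ``"non-inhibitor"``)
    or 0/1 integers with 1 = inhibitor. Pairs where the prediction is
    ``"unpredicted"`` (or NaN) are excluded from the counts; the number of
    exclusions is logged.
    """
    pred = np.asarray(predicted, dtype=object)
    true = np.asarray(truth, dtype=object)
    if pred.shape != true.shape:
        raise ValueError(
            f"length mismatch: {pred.shape[0]} predictions vs {true.shape[0]} truths"
        )
    p = as_binary(pred, allow_unpredicted=True)
    t = as_binary(true)
    mask = ~np.isnan(p)
    n_skip = int((~mask).sum())
    if n_skip:
        logger.warning("%d unpredicted compounds excluded from confusion counts", n_skip)
    p, t = p[mask].astype(bool), t[mask].astype(bool)
    return ConfusionMatrix(
        tp=int((p & t).sum()),
        tn=int((~p & ~t).sum()),
        fp=int((p & ~t).sum()),
        fn=int((~p & t).sum()),
    )


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        raise UndefinedMetricError(f"{name} undefined: denominator is zero")
    return num / den


def sensitivity(cm: ConfusionMatrix) -> float:
    """TP / (TP + FN) — fraction of true inhibitors recovered."""
    return _ratio(cm.tp, cm.tp + cm.fn, "sensitivity")


def specificity(cm: ConfusionMatrix) -> float:
    """TN / (TN + FP)."""
    return _ratio(cm.tn, cm.tn + cm.fp, "specificity")


def accuracy(cm: ConfusionMatrix) -> float:
    """(TP + TN) / total."""
    return _ratio(cm.tp + cm.tn, cm.total, "accuracy")


def precision(cm: ConfusionMatrix) -> float:
    """TP / (TP + FP) — the quantity a screening cascade tries to raise."""
    return _ratio(cm.tp, cm.tp + cm.fp, "precision")


def gmean(cm: ConfusionMatrix) -> float:
    """sqrt(sensitivity x specificity)."""
    return math.sqrt(sensitivity(cm) * specificity(cm))


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient.

    (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); if any factor of
    the denominator is zero the standard convention of 0 is returned (logged).
    """
    factors = (cm.tp + cm.fp, cm.tp + cm.fn, cm.tn + cm.fp, cm.tn + cm.fn)
    if 0 in factors:
        logger.warning("MCC denominator has a zero factor; returning 0 by convention")
        return 0.0
    num = cm.tp * cm.tn - cm.fp * cm.fn
    return num / math.sqrt(math.prod(factors))


def roc_auc(scores: Sequence[float], truth: Sequence, orientation: str = HIGHER_IS_INHIBITOR) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic.

    Equals P(score of a random inhibitor beats a random non-inhibitor) plus
    half the tie probability, after orienting scores so that higher means
    more inhibitor-like.
    """
    s = np.asarray(scores, dtype=float)
    t = as_binary(np.asarray(truth, dtype=object)).astype(bool)
    if orientation == LOWER_IS_INHIBITOR:
        s = -s
    elif orientation != HIGHER_IS_INHIBITOR:
        raise ValueError(f"unknown orientation {orientation!r}")
    n_pos, n_neg = int(t.sum()), int((~t).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires at least one member of each class")
    ranks = rankdata(s)
    return (ranks[t].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def classification_report_row(cm: ConfusionMatrix, model: str = "", threshold: float | None = None,
                              auc: float | None = None) -> dict:
    """One report row (Table-style): counts plus the six standard measures.

    Metrics whose denominator is zero are reported as None rather than a
    silent 0 or NaN.
    """

    def safe(fn):
        try:
            return fn(cm)
        except UndefinedMetricError:
            return None

    row = {
        "model": model,
        "threshold": threshold,
        "tp": cm.tp, "tn": cm.tn, "fp": cm.fp, "fn": cm.fn,
        "sensitivity": safe(sensitivity),
        "specificity": safe(specificity),
        "accuracy": safe(accuracy),
        "precision": safe(precision),
        "gmean": None, "mcc": mcc(cm),
    }
    if row["sensitivity"] is not None and row["specificity"] is not None:
        row["gmean"] = math.sqrt(row["sensitivity"] * row["specificity"])
    if auc is not None:
        row["auc"] = auc
    return row
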