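"""Classification performance metrics.

Binary confusion counts with an optional per-histopathology-grade
breakdown (MiD / MoD / HiD / SCC pooled as the positive class against
Healthy), sensitivity TP/(TP+FN), specificity TN/(TN+FP), the
F1-score TP/(TP + (FP+FN)/2), and the empirical ROC-AUC in its
Mann–Whitney form (fraction of positive/negative score pairs ranked
concordantly, ties counted half).

Undefined metrics (empty denominators on degenerate folds) raise
:class:`UndefinedMetricError` rather than silently returning 0 or NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .core import MaflimError, ValidationError

GRADES = ("MiD", "MoD", "HiD", "SCC", "Healthy")


class UndefinedMetricError(MaflimError, ZeroDivisionError):
    """The metric's denominator is empty for these counts."""


@dataclass
class ConfusionMatrix:
    """Binary confusion counts, optionally broken down by grade.

    ``by_grade`` maps a grade name to ``(predicted_negative,
    predicted_positive)`` counts among images of that grade; grade rows
    must sum to the binary totals.
    """

    tp: int
    fn: int
    tn: int
    fp: int
    by_grade: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "tn", "fp"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValidationError(f"{name} must be a nonnegative integer, got {v}")
            setattr(self, name, int(v))
        if self.by_grade:
            pos_grades = {g: c for g, c in self.by_grade.items() if g != "Healthy"}
            neg = self.by_grade.get("Healthy", (0, 0))
            if (
                sum(c[1] for c in pos_grades.values()) != self.tp
                or sum(c[0] for c in pos_grades.values()) != self.fn
                or neg[0] != self.tn
                or neg[1] != self.fp
            ):
                raise ValidationError("grade breakdown does not sum to binary totals")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


def confusion(
    predictions: Sequence[int],
    labels: Sequence[int],
    grades: Sequence[str] | None = None,
) -> ConfusionMatrix:
    """Count TP/FN/TN/FP from binary predictions against labels.

    ``grades``, when supplied, adds the per-grade breakdown rows.
    """
    pred = np.asarray(predictions, dtype=int)
    lab = np.asarray(labels, dtype=int)
    if pred.shape != lab.shape:
        raise ValidationError(
            f"predictions ({pred.shape}) and labels ({lab.shape}) length mismatch"
        )
    tp = int(np.sum((pred == 1) & (lab == 1)))
    fn = int(np.sum((pred == 0) & (lab == 1)))
    tn = int(np.sum((pred == 0) & (lab == 0)))
    fp = int(np.sum((pred == 1) & (lab == 0)))
    by_grade: dict[str, tuple[int, int]] = {}
    if grades is not None:
        if len(grades) != pred.size:
            raise ValidationError("grades length mismatch")
        garr = np.asarray(grades)
        for g in dict.fromkeys(grades):
            sel = garr == g
            by_grade[str(g)] = (
                int(np.sum(pred[sel] == 0)),
                int(np.sum(pred[sel] == 1)),
            )
    return ConfusionMatrix(tp=tp, fn=fn, tn=tn, fp=fp, by_grade=by_grade)


def sensitivity(cm: ConfusionMatrix) -> float:
    """TP / (TP + FN)."""
    if cm.tp + cm.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no positive labels")
    return cm.tp / (cm.tp + cm.fn)


def specificity(cm: ConfusionMatrix) -> float:
    """TN / (TN + FP)."""
    if cm.tn + cm.fp == 0:
        raise UndefinedMetricError("specificity undefined: no negative labels")
    return cm.tn / (cm.tn + cm.fp)


def f1(cm: ConfusionMatrix) -> float:
    """TP / (TP + (FP + FN)/2)."""
    if cm.tp + cm.fp + cm.fn == 0:
        raise UndefinedMetricError("F1 undefined: no positives anywhere")
    return cm.tp / (cm.tp + 0.5 * (cm.fp + cm.fn))


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Empirical ROC-AUC (Mann–Whitney form).

    Fraction of (positive, negative) pairs where the positive scores
    higher, with half credit for ties; identical to the trapezoidal area
    under the empirical ROC curve.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("roc_auc needs both classes present")
    ranks = rankdata(s)  # average ranks give ties half credit
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_curve(
    scores: Sequence[float], labels: Sequence[int]
) -> list[tuple[float, float, float]]:
    """Stepwise empirical ROC curve as (FPR, TPR, threshold) points.

    Includes the (0, 0) and (1, 1) endpoints; thresholds are the unique
    score cut points (a point's threshold is the lowest score still
    classified positive there; the (0,0) endpoint carries +inf).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("roc_curve needs both classes present")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    pts: list[tuple[float, float, float]] = [(0.0, 0.0, np.inf)]
    tp = fp = 0
    i = 0
    while i < s.size:
        j = i
        while j < s.size and s_sorted[j] == s_sorted[i]:
            tp += y_sorted[j]
            fp += 1 - y_sorted[j]
            j += 1
        pts.append((fp / n_neg, tp / n_pos, float(s_sorted[i])))
        i = j
    return pts


def auc_from_curve(curve: list[tuple[float, float, float]]) -> float:
    """Trapezoidal area under an ROC curve from :func:`roc_curve`."""
    fpr = np.array([p[0] for p in curve])
    tpr = np.array([p[1] for p in curve])
    return float(np.trapezoid(tpr, fpr))


def percent(value: float) -> int:
    """Round a proportion to integer percent, half-up (printed style)."""
    import math

    return int(math.floor(value * 100 + 0.5))


def round2(value: float) -> float:
    """Round to 2 decimals, half-up (printed F1 style)."""
    import math

    return math.floor(value * 100 + 0.5) / 100
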