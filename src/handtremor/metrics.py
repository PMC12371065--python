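"""Confusion-matrix metrics and ROC analysis for the two-class detector.

The positive class is *patient* throughout.  Ratios with an empty margin
(e.g. precision with TP + FP = 0) are reported as an explicit
undefined-sentinel (NaN) and serialized as JSON ``null`` - never silently 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "RocCurve",
    "confusion",
    "metrics",
    "roc",
    "UNDEFINED",
]

LABELS = ("healthy", "patient")
POSITIVE = "patient"

#: sentinel for metrics whose denominator is empty
UNDEFINED = float("nan")


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f_measure: float
    mcc: float
    npv: float
    fpr: float
    fnr: float
    fdr: float

    def to_dict(self) -> dict[str, float | None]:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = None if (isinstance(v, float) and math.isnan(v)) else v
        return out


@dataclass(frozen=True)
class RocCurve:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def confusion(predictions, labels) -> ConfusionMatrix:
    """Count TP/FP/FN/TN with 'patient' as the positive class."""
    predictions = list(predictions)
    labels = list(labels)
    if len(predictions) != len(labels):
        raise ValueError("predictions and labels differ in length")
    for value in set(predictions) | set(labels):
        if value not in LABELS:
            raise ValueError(f"unknown label {value!r}; expected one of {LABELS}")
    tp = fp = fn = tn = 0
    for pred, true in zip(predictions, labels):
        if true == POSITIVE:
            tp += pred == POSITIVE
            fn += pred != POSITIVE
        else:
            tn += pred != POSITIVE
            fp += pred == POSITIVE
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else UNDEFINED


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Full metric set; complements satisfy their identities exactly.

    sensitivity = 1 - FNR, specificity = 1 - FPR and precision = 1 - FDR hold
    to machine precision because each pair is computed from the same ratio.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    tp, fp, fn, tn = (float(x) for x in (cm.tp, cm.fp, cm.fn, cm.tn))
    sensitivity = _ratio(tp, tp + fn)
    specificity = _ratio(tn, tn + fp)
    precision = _ratio(tp, tp + fp)
    f_measure = (
        _ratio(2 * precision * sensitivity, precision + sensitivity)
        if not (math.isnan(precision) or math.isnan(sensitivity))
        else UNDEFINED
    )
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / mcc_den if mcc_den > 0 else UNDEFINED
    return MetricsReport(
        accuracy=(tp + tn) / cm.total,
        sensitivity=sensitivity,
        specificity=specificity,
        precision=precision,
        f_measure=f_measure,
        mcc=mcc,
        npv=_ratio(tn, tn + fn),
        fpr=1.0 - specificity if not math.isnan(specificity) else UNDEFINED,
        fnr=1.0 - sensitivity if not math.isnan(sensitivity) else UNDEFINED,
        fdr=1.0 - precision if not math.isnan(precision) else UNDEFINED,
    )


def roc(scores, labels) -> RocCurve:
    """Threshold sweep over patient-class probabilities with trapezoidal AUC."""
    scores = np.asarray(scores, dtype=np.float64)
    y = np.asarray([1 if lab == POSITIVE else 0 for lab in labels])
    if len(set(y.tolist())) < 2:
        raise ValueError("ROC needs at least one sample from each class")
    fpr, tpr, thresholds = _sk_roc_curve(y, scores)
    return RocCurve(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=float(_trapezoid_auc(fpr, tpr)))
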