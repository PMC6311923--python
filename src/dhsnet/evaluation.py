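"""Evaluation statistics for binary DHS classification.

Sensitivity, specificity, accuracy and the Matthews correlation
coefficient are computed from the four confusion counts:

    Sn  = Tp / (Tp + Fn)
    Sp  = Tn / (Tn + Fp)
    ACC = (Tp + Tn) / (Tp + Fn + Tn + Fp)
    MCC = (Tp*Tn - Fp*Fn) / sqrt((Tn+Fn)(Tn+Fp)(Tp+Fn)(Tp+Fp))

plus the area under the ROC curve, the probability that a random positive
outscores a random negative with ties counting one half.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from .errors import MetricError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise MetricError("confusion counts must be non-negative")

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.n_positive + self.n_negative


@dataclass(frozen=True)
class MetricsReport:
    sn: float
    sp: float
    acc: float
    mcc: float
    auc: Optional[float] = None
    threshold: float = 0.5

    def to_dict(self) -> dict:
        return {
            "Sn": self.sn, "Sp": self.sp, "ACC": self.acc,
            "MCC": self.mcc, "AUC": self.auc, "threshold": self.threshold,
        }


def confusion(
    scores: Sequence[float],
    labels: Sequence[int],
    threshold: float = 0.5,
) -> ConfusionCounts:
    """Threshold positive-class scores: score >= threshold predicts
    positive (ties predicted positive)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.size == 0:
        raise MetricError("cannot compute a confusion matrix of nothing")
    if scores.shape != labels.shape:
        raise MetricError("scores and labels differ in shape")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int((pred & pos).sum()),
        fn=int((~pred & pos).sum()),
        tn=int((~pred & ~pos).sum()),
        fp=int((pred & ~pos).sum()),
    )


def metrics(c: ConfusionCounts, threshold: float = 0.5) -> MetricsReport:
    """Sn, Sp, ACC and MCC from confusion counts.

    MCC is defined as 0 when any factor of its denominator vanishes (the
    usual convention for degenerate margins). Requires at least one
    positive and one negative sample.
    """
    if c.n_positive == 0:
        raise MetricError("Sn undefined: no positive samples")
    if c.n_negative == 0:
        raise MetricError("Sp undefined: no negative samples")
    sn = c.tp / c.n_positive
    sp = c.tn / c.n_negative
    acc = (c.tp + c.tn) / c.total
    denom = (
        (c.tn + c.fn) * (c.tn + c.fp) * (c.tp + c.fn) * (c.tp + c.fp)
    )
    mcc = 0.0 if denom == 0 else (
        (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    )
    return MetricsReport(sn=sn, sp=sp, acc=acc, mcc=mcc, threshold=threshold)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve via trapezoidal integration over all
    distinct thresholds (equivalently the rank statistic with ties
    counting one half)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise MetricError("AUC undefined: only one class present")
    return float(roc_auc_score(labels, scores))


def roc_points(scores: Sequence[float], labels: Sequence[int]):
    """(false-positive rate, true-positive rate, thresholds) arrays for an
    ROC curve."""
    fpr, tpr, thr = roc_curve(np.asarray(labels), np.asarray(scores, dtype=float))
    return fpr, tpr, thr


def evaluate_scores(
    scores: Sequence[float],
    labels: Sequence[int],
    threshold: float = 0.5,
) -> MetricsReport:
    """Full report (Sn, Sp, ACC, MCC, AUC) for scored samples."""
    c = confusion(scores, labels, threshold)
    rep = metrics(c, threshold)
    return MetricsReport(
        sn=rep.sn, sp=rep.sp, acc=rep.acc, mcc=rep.mcc,
        auc=roc_auc(scores, labels), threshold=threshold,
    )
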