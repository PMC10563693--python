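"""Confusion-matrix metric layer: accuracy, sensitivity, specificity,
effectivity (Eff = Sen x Spe), with the wild class as positive throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ConfusionCounts", "ClassifierMetrics", "confusion_metrics", "count_confusion",
           "UndefinedMetricError"]

POSITIVE_CLASS = "wild"


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is empty."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class ClassifierMetrics:
    """Fractions in [0, 1]; eff = sen * spe exactly."""

    acc: float
    sen: float
    spe: float
    eff: float

    def as_percent(self) -> dict[str, float]:
        return {k: 100.0 * v for k, v in vars(self).items()}


def confusion_metrics(counts: ConfusionCounts) -> ClassifierMetrics:
    """Acc = (TP+TN)/total, Sen = TP/(TP+FN), Spe = TN/(TN+FP), Eff = Sen*Spe."""
    if counts.total == 0:
        raise UndefinedMetricError("acc: no evaluated records")
    if counts.tp + counts.fn == 0:
        raise UndefinedMetricError("sen: no positive-class records")
    if counts.tn + counts.fp == 0:
        raise UndefinedMetricError("spe: no negative-class records")
    acc = (counts.tp + counts.tn) / counts.total
    sen = counts.tp / (counts.tp + counts.fn)
    spe = counts.tn / (counts.tn + counts.fp)
    return ClassifierMetrics(acc, sen, spe, sen * spe)


def count_confusion(
    y_true, y_pred, positive: str = POSITIVE_CLASS
) -> ConfusionCounts:
    """Tally a confusion matrix from label sequences."""
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred lengths differ")
    pos_t = yt == positive
    pos_p = yp == positive
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
    )
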