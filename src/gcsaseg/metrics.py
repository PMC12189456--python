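"""Binary segmentation metrics from pixel confusion counts.

Foreground (tumor) is pixel value 255, background 0.  With TP/FP/FN/TN the
per-pixel tallies,

    MIoU     = ( TP/(TP+FP+FN) + TN/(TN+FN+FP) ) / 2
    MPA      = ( TP/(TP+FP)    + TN/(TN+FN)    ) / 2
    Accuracy = (TP+TN) / (TP+FP+FN+TN)

MPA is implemented exactly in this per-class *precision* form (its common
textbook namesake averages recalls TP/(TP+FN) instead; that variant is
available via ``variant="recall"``).  A class term whose denominator is zero
scores 1.0: a class that is absent and never claimed is handled perfectly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ShapeError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


def _check_mask(m: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(m)
    if not np.isin(m, (0, 255)).all():
        raise ValueError(f"{name} mask contains values outside {{0, 255}}")
    return m


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixel tallies of a predicted vs. ground-truth binary mask pair."""
    pred, truth = np.asarray(pred), np.asarray(truth)
    if pred.shape != truth.shape:
        raise ShapeError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    _check_mask(pred, "pred")
    _check_mask(truth, "truth")
    p = pred == 255
    t = truth == 255
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return ConfusionCounts(tp, fp, fn, tn)


def _term(num: int, den: int) -> float:
    return num / den if den else 1.0


def miou(c: ConfusionCounts) -> float:
    """Mean intersection-over-union of foreground and background."""
    return (_term(c.tp, c.tp + c.fp + c.fn) + _term(c.tn, c.tn + c.fn + c.fp)) / 2.0


def mpa(c: ConfusionCounts, variant: str = "printed") -> float:
    """Mean per-class pixel ratio.

    ``variant="printed"`` averages the class precisions TP/(TP+FP) and
    TN/(TN+FN); ``variant="recall"`` averages the class recalls TP/(TP+FN)
    and TN/(TN+FP).
    """
    if variant == "printed":
        return (_term(c.tp, c.tp + c.fp) + _term(c.tn, c.tn + c.fn)) / 2.0
    if variant == "recall":
        return (_term(c.tp, c.tp + c.fn) + _term(c.tn, c.tn + c.fp)) / 2.0
    raise ValueError(f"unknown MPA variant {variant!r}")


def accuracy(c: ConfusionCounts) -> float:
    """Fraction of correctly classified pixels."""
    if c.total == 0:
        raise ValueError("accuracy undefined for zero compared pixels")
    return (c.tp + c.tn) / c.total


def evaluate_set(pairs: list[tuple[np.ndarray, np.ndarray]],
                 aggregate: str = "micro",
                 mpa_variant: str = "printed") -> tuple[float, float, float]:
    """(MIoU, MPA, Accuracy) over a list of (pred, truth) mask pairs.

    ``micro`` pools confusion counts over all pairs before applying the
    formulas (consistent with stitching tiles back into one slide);
    ``macro`` averages per-pair metric values.
    """
    if not pairs:
        raise ValueError("evaluate_set requires at least one mask pair")
    counts = [confusion_counts(p, t) for p, t in pairs]
    if aggregate == "micro":
        pooled = counts[0]
        for c in counts[1:]:
            pooled = pooled + c
        return miou(pooled), mpa(pooled, mpa_variant), accuracy(pooled)
    if aggregate == "macro":
        vals = np.array([[miou(c), mpa(c, mpa_variant), accuracy(c)] for c in counts])
        return tuple(vals.mean(axis=0))
    raise ValueError(f"unknown aggregation {aggregate!r}")
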