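"""Pixel-level segmentation metrics and the COV uniformity measure.

Detection quality against a ground-truth mask is summarized by the usual
confusion-count metrics (accuracy, precision, recall, F1, Dice, Jaccard).
Restoration quality, where no highlight-free reference exists, is measured
by the coefficient of variation of the repaired region: a well-filled region
is intensity-uniform with its surroundings, so COV should drop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .imaging import as_mask, as_rgb, grayscale

__all__ = [
    "ConfusionCounts",
    "DetectionScores",
    "confusion",
    "scores",
    "evaluate",
    "mean_scores",
    "cov",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class DetectionScores:
    accuracy: float
    precision: float
    recall: float
    f1: float
    dice: float
    jaccard: float

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "dice": self.dice,
            "jaccard": self.jaccard,
        }


def confusion(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """Pixel-wise confusion counts of a predicted mask against ground truth."""
    pred = as_mask(pred)
    gt = as_mask(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    p = pred.astype(bool)
    g = gt.astype(bool)
    return ConfusionCounts(
        tp=int((p & g).sum()),
        tn=int((~p & ~g).sum()),
        fp=int((p & ~g).sum()),
        fn=int((~p & g).sum()),
    )


def _ratio(num: float, den: float, name: str) -> float:
    # 0/0 returns 0: an empty prediction never earns credit
    if den == 0:
        warnings.warn(f"{name} is 0/0 (empty masks); returning 0", stacklevel=3)
        return 0.0
    return num / den


def scores(counts: ConfusionCounts) -> DetectionScores:
    """Accuracy, precision, recall, F1, Dice and Jaccard from counts.

    Degenerate 0/0 ratios (both masks empty) return 0 with a warning;
    accuracy is always well defined for a non-empty frame.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    accuracy = _ratio(tp + tn, counts.total, "accuracy")
    precision = _ratio(tp, tp + fp, "precision")
    recall = _ratio(tp, tp + fn, "recall")
    f1 = _ratio(2.0 * precision * recall, precision + recall, "f1")
    dice = _ratio(2.0 * tp, 2.0 * tp + fp + fn, "dice")
    jaccard = _ratio(tp, tp + fp + fn, "jaccard")
    return DetectionScores(accuracy, precision, recall, f1, dice, jaccard)


def evaluate(pred: np.ndarray, gt: np.ndarray) -> DetectionScores:
    """Pooled-count scores of one predicted mask against ground truth."""
    return scores(confusion(pred, gt))


def mean_scores(pairs) -> DetectionScores:
    """Per-image averaging: score each (pred, gt) pair, then average.

    Complements :func:`evaluate` over pooled counts; the two aggregations
    differ whenever mask sizes vary between images.
    """
    all_scores = [evaluate(p, g).as_dict() for p, g in pairs]
    if not all_scores:
        raise ValueError("no mask pairs to evaluate")
    return DetectionScores(
        **{k: float(np.mean([s[k] for s in all_scores])) for k in all_scores[0]}
    )


def cov(image: np.ndarray, region: np.ndarray) -> float:
    """Coefficient of variation ``(sigma / mu) * 100`` of a region.

    Computed on grayscale intensity with the population standard deviation;
    ``region`` is a boolean/binary membership mask.  Lower is more uniform.
    """
    image = as_rgb(image)
    region = np.asarray(region).astype(bool)
    if region.shape != image.shape[:2]:
        raise ValueError("region mask shape must match the image")
    if not region.any():
        raise ValueError("region is empty")
    values = grayscale(image)[region]
    mu = float(values.mean())
    if mu == 0:
        raise ValueError("COV undefined: region mean intensity is 0")
    return float(values.std()) / mu * 100.0
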