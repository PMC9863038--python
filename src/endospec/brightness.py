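"""Global brightness classification of endoscopic frames.

Endoscopic images arrive with very different global exposure depending on the
organ and the scanner: smooth, reflective structures produce bright frames,
while deep cavities (e.g. the stomach) produce dark ones.  Downstream
threshold selection depends on which regime a frame is in, so the first stage
assigns every frame one of three classes — *high*, *medium* or *low*
brightness — from its average brightness ``la``:

    T1 = (la - La) / la

where ``La`` is the expected average brightness of a well-exposed frame.
``T1 > t1`` is high, ``T1 < -t1`` is low, the band in between is medium.
Defaults ``La = 112`` and ``t1 = 0.3``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .imaging import LUMA_WEIGHTS, as_rgb, rgb_to_hsv

__all__ = [
    "BrightnessClass",
    "ClassifierParams",
    "mean_brightness",
    "relative_deviation",
    "classify",
]


class BrightnessClass(enum.Enum):
    HIGH = "high"
    MEDIUM = "medium"
    LOW = "low"


@dataclass(frozen=True)
class ClassifierParams:
    """Knobs of the brightness classifier.

    la_expected : expected global average brightness of a normal frame,
        in 8-bit intensity units.
    t1 : relative-deviation threshold separating the three classes.
    brightness_channel : scalar brightness definition — BT.601 ``"luma"``
        (default), HSV ``"v"``, or the plain channel ``"gray-mean"``.
    """

    la_expected: float = 112.0
    t1: float = 0.3
    brightness_channel: str = "luma"

    def __post_init__(self):
        if not 0.0 < self.la_expected <= 255.0:
            raise ValueError("la_expected must be in (0, 255]")
        if not 0.0 < self.t1 < 1.0:
            raise ValueError("t1 must be in (0, 1)")
        if self.brightness_channel not in ("luma", "v", "gray-mean"):
            raise ValueError("brightness_channel must be luma, v or gray-mean")


def mean_brightness(image: np.ndarray, channel: str = "luma") -> float:
    """Average brightness ``la`` of an image, in [0, 255]."""
    image = as_rgb(image)
    if channel == "luma":
        wr, wg, wb = LUMA_WEIGHTS
        flat = image.astype(np.float64)
        return float(wr * flat[..., 0].mean() + wg * flat[..., 1].mean() + wb * flat[..., 2].mean())
    if channel == "v":
        return float(rgb_to_hsv(image)[..., 2].mean())
    if channel == "gray-mean":
        return float(image.astype(np.float64).mean())
    raise ValueError(f"unknown brightness channel {channel!r}")


def relative_deviation(la: float, la_expected: float) -> float:
    """Signed relative deviation ``T1 = (la - La) / la``.

    Positive when the image is brighter than the expected level.  The
    denominator is the observed mean, so the deviation is relative to the
    image at hand.
    """
    if la <= 0:
        raise ValueError("average brightness must be positive")
    return (la - la_expected) / la


def classify(
    image: np.ndarray, params: ClassifierParams | None = None
) -> BrightnessClass:
    """Assign one of {high, medium, low} from the mean brightness.

    A black frame (``la = 0``) is classified low without computing ``T1``.
    Boundary ties ``|T1| = t1`` go to medium, so the three classes partition
    the real line.
    """
    params = params or ClassifierParams()
    la = mean_brightness(image, params.brightness_channel)
    if la <= 0:
        return BrightnessClass.LOW
    t1 = relative_deviation(la, params.la_expected)
    if t1 > params.t1:
        return BrightnessClass.HIGH
    if t1 < -params.t1:
        return BrightnessClass.LOW
    return BrightnessClass.MEDIUM
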