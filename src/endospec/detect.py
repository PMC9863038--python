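"""Brightness-adaptive specular-highlight detection.

Endoscopic tissue is red-dominant (hemoglobin), so diffuse reflection keeps
the G and B channels well below the R channel, while specular reflection
drives all three channels up to near saturation together.  Detection
therefore runs two branches and unions them:

* **absolute highlights** — an adaptive intensity threshold on the G/B
  channels of a contrast-enhanced image,

      Th = max(g, b) - tau * (sigma_g + sigma_b) / 2

  where ``max(g, b)`` is the global maximum over both channels,
  ``sigma_g``/``sigma_b`` are the sample standard deviations, and ``tau``
  depends on the brightness class (0.3 high / 0.8 medium / 1.1 for
  brightness-enhanced low frames): bright frames get a larger threshold so
  bright diffuse tissue is not flagged, dark frames a smaller one so dim
  highlights are not missed;

* **relative highlights** — fainter spots with unstable intensity but sharp
  borders, caught by thresholding the Sobel gradient magnitude of the
  grayscale image, gating candidates on intensity, and filling enclosed
  rings.

The union is dilated with a disc structuring element to absorb the dark or
colored halo rings that surround bright spots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .brightness import BrightnessClass, ClassifierParams, classify
from .enhance import EnhancerParams, enhance
from .imaging import as_mask, as_rgb, grayscale, overlay_mask

__all__ = [
    "DetectorParams",
    "ChannelStats",
    "contrast_enhance",
    "channel_stats",
    "absolute_threshold",
    "detect_absolute",
    "detect_relative",
    "dilate",
    "detect",
]


@dataclass(frozen=True)
class ChannelStats:
    """Means and sample standard deviations of the G and B channels."""

    mu_g: float
    mu_b: float
    sigma_g: float
    sigma_b: float


@dataclass(frozen=True)
class DetectorParams:
    """Parameters of the two-branch detector.

    tau_high/tau_med/tau_low : brightness-class weights of the adaptive
        threshold; must increase (larger weight -> smaller threshold ->
        more permissive, matching dimmer frames).
    tophat_radius : disc radius of the top-/bottom-hat contrast step, in
        pixels; ``None`` scales the 5 px default with image size above
        512 px.
    sobel_threshold : gradient-magnitude cut of the relative branch;
        ``None`` adapts to 4x the mean gradient magnitude.
    min_intensity_rel : intensity floor for relative-highlight candidates;
        ``None`` adapts to mean + std of the grayscale image.
    dilate_radius : disc radius of the final mask dilation, in pixels.
    sigma_gate : if ``sigma_g + sigma_b`` falls below this, the frame is
        treated as near-constant and the absolute branch returns an empty
        mask (the threshold would degenerate to the global maximum and flag
        every pixel).
    """

    tau_high: float = 0.3
    tau_med: float = 0.8
    tau_low: float = 1.1
    tophat_radius: int | None = None
    sobel_threshold: float | None = None
    min_intensity_rel: float | None = None
    dilate_radius: int = 2
    sigma_gate: float = 1.0

    def __post_init__(self):
        if not self.tau_high < self.tau_med < self.tau_low:
            raise ValueError("need tau_high < tau_med < tau_low")
        if self.dilate_radius < 0:
            raise ValueError("dilate_radius must be >= 0")
        if self.tophat_radius is not None and self.tophat_radius < 1:
            raise ValueError("tophat_radius must be >= 1")

    def tau(self, cls: BrightnessClass) -> float:
        return {
            BrightnessClass.HIGH: self.tau_high,
            BrightnessClass.MEDIUM: self.tau_med,
            BrightnessClass.LOW: self.tau_low,
        }[cls]


def _tophat_radius(image: np.ndarray, params: DetectorParams) -> int:
    if params.tophat_radius is not None:
        return params.tophat_radius
    side = max(image.shape[:2])
    return max(5, round(5 * side / 512)) if side > 512 else 5


def contrast_enhance(image: np.ndarray, radius: int | None = None) -> np.ndarray:
    """Top-hat/bottom-hat contrast boost: ``out = in + tophat - bottomhat``.

    The white top-hat lifts small bright structures (specular spots), the
    black bottom-hat suppresses small dark ones; a constant image passes
    through unchanged.  Output is clipped to [0, 255].
    """
    image = as_rgb(image)
    if radius is None:
        radius = _tophat_radius(image, DetectorParams())
    selem = disk(radius)
    out = np.empty_like(image)
    for c in range(3):
        chan = image[..., c].astype(np.int32)
        opened = ndimage.grey_opening(chan, footprint=selem)
        closed = ndimage.grey_closing(chan, footprint=selem)
        tophat = chan - opened
        bottomhat = closed - chan
        out[..., c] = np.clip(chan + tophat - bottomhat, 0, 255).astype(np.uint8)
    return out


def channel_stats(image: np.ndarray) -> ChannelStats:
    """Sample mean/std of the G and B channels (denominator ``n - 1``)."""
    image = as_rgb(image)
    g = image[..., 1].astype(np.float64)
    b = image[..., 2].astype(np.float64)
    if g.size < 2:
        raise ValueError("need at least 2 pixels for a sample standard deviation")
    return ChannelStats(
        mu_g=float(g.mean()),
        mu_b=float(b.mean()),
        sigma_g=float(g.std(ddof=1)),
        sigma_b=float(b.std(ddof=1)),
    )


def absolute_threshold(
    stats: ChannelStats, cls: BrightnessClass, maxgb: float, params: DetectorParams | None = None
) -> float:
    """Adaptive absolute-highlight threshold ``Th``, clipped below at 0."""
    params = params or DetectorParams()
    th = maxgb - params.tau(cls) * (stats.sigma_g + stats.sigma_b) / 2.0
    return max(th, 0.0)


def detect_absolute(
    image: np.ndarray,
    cls: BrightnessClass,
    params: DetectorParams | None = None,
    *,
    enhanced: np.ndarray | None = None,
) -> np.ndarray:
    """Absolute-highlight mask: ``max(G(p), B(p)) >= Th`` on the
    contrast-enhanced image (one global scalar ``Th`` per frame).

    Pass ``enhanced`` to reuse a precomputed contrast-enhanced image.
    Near-constant frames (``sigma_g + sigma_b`` below the gate) yield an
    empty mask: with zero spread the threshold collapses to the global
    maximum and every pixel would qualify vacuously.
    """
    params = params or DetectorParams()
    image = as_rgb(image)
    # the near-constant gate reads the raw frame: contrast enhancement
    # amplifies quantization dither ~3x and would defeat the guard
    raw = channel_stats(image)
    if raw.sigma_g + raw.sigma_b < params.sigma_gate:
        return np.zeros(image.shape[:2], dtype=np.uint8)
    if enhanced is None:
        enhanced = contrast_enhance(image, _tophat_radius(image, params))
    stats = channel_stats(enhanced)
    gb = np.maximum(enhanced[..., 1], enhanced[..., 2]).astype(np.float64)
    th = absolute_threshold(stats, cls, float(gb.max()), params)
    return (gb >= th).astype(np.uint8)


def sobel_magnitude(gray: np.ndarray) -> np.ndarray:
    """Unnormalized 3x3 Sobel gradient magnitude (ideal step edge -> 1020)."""
    gray = np.asarray(gray, dtype=np.float64)
    gx = ndimage.sobel(gray, axis=1, mode="nearest")
    gy = ndimage.sobel(gray, axis=0, mode="nearest")
    return np.hypot(gx, gy)


def detect_relative(image: np.ndarray, params: DetectorParams | None = None) -> np.ndarray:
    """Relative-highlight mask from Sobel gradients.

    Candidates exceed the gradient threshold; the refinement keeps only
    candidates at least as bright as the intensity floor, then fills holes
    enclosed by candidate rings (a bright disc whose interior is flat still
    has a high-gradient rim).
    """
    params = params or DetectorParams()
    gray = grayscale(as_rgb(image))
    mag = sobel_magnitude(gray)
    thr = params.sobel_threshold
    if thr is None:
        # adaptive cut; the tiny floor keeps gradient-free frames empty
        thr = max(4.0 * float(mag.mean()), 1e-9)
    floor = params.min_intensity_rel
    if floor is None:
        floor = float(gray.mean() + gray.std())
    cand = (mag >= thr) & (gray >= floor)
    filled = ndimage.binary_fill_holes(cand)
    return filled.astype(np.uint8)


def dilate(mask: np.ndarray, radius: int) -> np.ndarray:
    """Binary dilation by a digital disc (Euclidean distance <= radius)."""
    mask = as_mask(mask)
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius == 0 or not mask.any():
        return mask.copy()
    return ndimage.binary_dilation(mask, structure=disk(radius)).astype(np.uint8)


def detect(
    image: np.ndarray,
    params: DetectorParams | None = None,
    classifier: ClassifierParams | None = None,
    enhancer: EnhancerParams | None = None,
    *,
    return_details: bool = False,
):
    """Full detection pipeline -> ``(mask, overlay)``.

    classify -> enhance if low -> contrast enhance -> union of absolute and
    relative branches -> disc dilation -> green overlay.  The absolute
    branch reads the contrast-enhanced image; the relative branch reads the
    original (possibly brightness-enhanced) grayscale.  With
    ``return_details=True`` a dict of intermediate products is appended.
    """
    params = params or DetectorParams()
    image = as_rgb(image)
    cls = classify(image, classifier)
    work = enhance(image, enhancer) if cls is BrightnessClass.LOW else image
    enhanced = contrast_enhance(work, _tophat_radius(work, params))
    absolute = detect_absolute(work, cls, params, enhanced=enhanced)
    relative = detect_relative(work, params)
    union = np.maximum(absolute, relative)
    mask = dilate(union, params.dilate_radius)
    overlay = overlay_mask(image, mask)
    if return_details:
        details = {
            "class": cls,
            "enhanced_input": work,
            "contrast_enhanced": enhanced,
            "absolute": absolute,
            "relative": relative,
            "union": union,
        }
        return mask, overlay, details
    return mask, overlay
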