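"""Seeded generator of endoscopic-like test frames with ground-truth masks.

Real endoscopic frames are dominated by hemoglobin red (R well above G and
B), crossed by darker curvilinear vessels, dotted with smooth yellowish fat,
and — on wet tissue — speckled with near-saturated specular blobs whose
three channels are almost equal.  The generator emulates exactly these
traits on low-frequency background texture, at a controllable global
brightness, so that every pipeline stage (classification, enhancement,
detection, inpainting, evaluation) can be exercised without clinical data.

Specular blobs are drawn with R, G, B in [240, 255] and a channel spread of
at most 8; an optional 1-2 px darker halo ring around each blob reproduces
the dark circles that motivate the final mask dilation.  Fat is bright but
soft-edged — glistening adipose tissue has no sharp rim — so only the
specular blobs carry both near-saturation and steep gradients.  The
ground-truth mask contains exactly the specular blobs.

Global brightness is steered to a requested class by a power-law tone curve
on the tissue (exponent bisected against the classifier); a tone curve
rather than a linear gain keeps bright-frame tissue below saturation, while
the specular blobs are composited afterwards and stay near-saturated in
every class, as they do in real frames.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .brightness import BrightnessClass, ClassifierParams, classify

__all__ = ["SyntheticSpec", "generate", "generate_dataset"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic frame.

    Counts are numbers of structures; radii in pixels.  The same spec and
    seed always produce byte-identical output.
    """

    seed: int = 0
    height: int = 128
    width: int = 128
    target_class: BrightnessClass = BrightnessClass.MEDIUM
    n_highlights: int = 3
    radius_range: tuple[int, int] = (3, 7)
    halo: bool = True
    vessel_count: int = 3
    fat_blobs: int = 2

    def __post_init__(self):
        if self.height < 16 or self.width < 16:
            raise ValueError("frame must be at least 16x16")
        if min(self.n_highlights, self.vessel_count, self.fat_blobs) < 0:
            raise ValueError("structure counts must be >= 0")
        lo, hi = self.radius_range
        if not 1 <= lo <= hi or 2 * hi >= min(self.height, self.width):
            raise ValueError("radius_range must fit inside the frame")


def _smooth_noise(rng, shape, sigma):
    noise = rng.random(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=sigma)
    lo, hi = smooth.min(), smooth.max()
    return (smooth - lo) / (hi - lo) if hi > lo else np.zeros(shape)


def _disc(shape, cy, cx, r):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


def _tissue_base(rng, spec: SyntheticSpec) -> np.ndarray:
    """Red-dominant background with vessels and fat, float RGB in [0, 255]."""
    shape = (spec.height, spec.width)
    tex = _smooth_noise(rng, shape, sigma=max(shape) / 16)
    base = np.empty((*shape, 3))
    base[..., 0] = 150 + 60 * tex  # R: dominant
    base[..., 1] = 55 + 35 * tex  # G
    base[..., 2] = 45 + 30 * tex  # B

    # darker curvilinear vessels: smoothed random walks stamped multiplicatively
    vessel = np.zeros(shape)
    for _ in range(spec.vessel_count):
        y = rng.uniform(0, spec.height)
        x = rng.uniform(0, spec.width)
        ang = rng.uniform(0, 2 * np.pi)
        for _ in range(int(2.0 * max(shape))):
            iy, ix = int(y) % spec.height, int(x) % spec.width
            vessel[iy, ix] = 1.0
            ang += rng.normal(0, 0.3)
            y += np.sin(ang)
            x += np.cos(ang)
    vessel = np.clip(ndimage.gaussian_filter(vessel, 0.8) * 2.0, 0, 1)
    base *= (1.0 - 0.35 * vessel)[..., None]

    # soft-edged yellowish fat: boost R and G, hold B; blurred so fat rims
    # stay gentle (only specular spots have steep gradients)
    boost = np.zeros(shape)
    for _ in range(spec.fat_blobs):
        r = int(rng.integers(3, max(4, min(shape) // 16)))
        cy = int(rng.integers(r, spec.height - r))
        cx = int(rng.integers(r, spec.width - r))
        boost[_disc(shape, cy, cx, r)] = 1.0
    boost = ndimage.gaussian_filter(boost, 2.5)
    boost = boost / boost.max() if boost.max() > 0 else boost
    base[..., 0] = np.minimum(base[..., 0] + 45 * boost, 210)
    base[..., 1] = np.minimum(base[..., 1] + 55 * boost, 140)
    return base


def _highlights(rng, spec: SyntheticSpec):
    """Specular blob mask, halo ring mask, and the shared blob color."""
    shape = (spec.height, spec.width)
    mask = np.zeros(shape, dtype=bool)
    halo = np.zeros(shape, dtype=bool)
    lo, hi = spec.radius_range
    margin = hi + 3
    for _ in range(spec.n_highlights):
        r = int(rng.integers(lo, hi + 1))
        cy = int(rng.integers(margin, spec.height - margin))
        cx = int(rng.integers(margin, spec.width - margin))
        blob = _disc(shape, cy, cx, r)
        if spec.halo:
            halo |= _disc(shape, cy, cx, r + 2) & ~blob
        mask |= blob
    halo &= ~mask
    base_level = int(rng.integers(244, 252))
    spread = rng.integers(0, 5, size=3)  # channel spread <= 8 by construction
    color = np.clip(base_level + spread, 240, 255).astype(np.float64)
    return mask, halo, color


def _compose(base, exponent, mask, halo, color):
    """Tone-curve the tissue, darken halos, paste the specular blobs."""
    img = 255.0 * np.power(np.clip(base, 0.0, 255.0) / 255.0, exponent)
    img[halo] *= 0.55
    img[mask] = color
    return np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)


def generate(
    spec: SyntheticSpec, classifier: ClassifierParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Generate one (image, ground-truth mask) pair.

    The tone-curve exponent is bisected until the classifier assigns the
    requested brightness class (exponent < 1 brightens).  Raises if the
    class cannot be reached in 20 iterations.
    """
    classifier = classifier or ClassifierParams()
    rng = np.random.default_rng(spec.seed)
    base = _tissue_base(rng, spec)
    mask, halo, color = _highlights(rng, spec)

    lo_exp, hi_exp = 0.10, 4.0  # brighter .. darker
    # low-class frames emulate markedly underexposed footage: dark on every
    # channel, including the V (max-channel) band the enhancer works on
    exponent = {
        BrightnessClass.HIGH: 0.45,
        BrightnessClass.MEDIUM: 1.0,
        BrightnessClass.LOW: 2.4,
    }[spec.target_class]
    order = [BrightnessClass.LOW, BrightnessClass.MEDIUM, BrightnessClass.HIGH]
    for _ in range(20):
        img = _compose(base, exponent, mask, halo, color)
        cls = classify(img, classifier)
        if cls is spec.target_class:
            return img, mask.astype(np.uint8)
        if order.index(cls) < order.index(spec.target_class):
            hi_exp = exponent  # too dark: cap the exponent
        else:
            lo_exp = exponent
        exponent = (lo_exp + hi_exp) / 2.0
    raise RuntimeError(
        f"could not reach brightness class {spec.target_class.value} in 20 iterations"
    )


def generate_dataset(
    n: int, base_seed: int, template: SyntheticSpec | None = None
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Generate ``n`` pairs with seeds ``base_seed .. base_seed+n-1``.

    Target classes cycle high / medium / low so all three regimes occur.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    template = template or SyntheticSpec()
    cycle = [BrightnessClass.HIGH, BrightnessClass.MEDIUM, BrightnessClass.LOW]
    out = []
    for i in range(n):
        spec = replace(template, seed=base_seed + i, target_class=cycle[i % 3])
        out.append(generate(spec))
    return out
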