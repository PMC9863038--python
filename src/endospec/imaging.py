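"""Core image/mask data model, file I/O, color conversions and overlays.

Images are plain ``numpy`` arrays: an RGB image is an ``(H, W, 3)`` array of
``uint8`` in R, G, B channel order; a highlight mask is an ``(H, W)`` array of
``uint8`` holding 0 (known tissue) or 1 (specular pixel).  Row-major, 0-based
``(y, x)`` indexing throughout, with y increasing downward.
"""

from __future__ import annotations

import numpy as np
from PIL import Image

__all__ = [
    "as_rgb",
    "as_mask",
    "load_image",
    "save_image",
    "load_mask",
    "save_mask",
    "overlay_mask",
    "rgb_to_hsv",
    "hsv_to_rgb",
    "grayscale",
]

#: ITU-R BT.601 luma weights for R, G, B.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

# overlay color for detected specular regions ("marked in green")
OVERLAY_GREEN = (0, 255, 0)


def as_rgb(pixels) -> np.ndarray:
    """Validate and return an ``(H, W, 3)`` uint8 RGB raster."""
    arr = np.asarray(pixels)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB raster, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError("empty image")
    if arr.dtype != np.uint8:
        if np.issubdtype(arr.dtype, np.floating) or arr.min() < 0 or arr.max() > 255:
            raise ValueError("RGB intensities must be 8-bit integers in [0, 255]")
        arr = arr.astype(np.uint8)
    return arr


def as_mask(values, image: np.ndarray | None = None) -> np.ndarray:
    """Validate a binary highlight mask, optionally against a paired image."""
    arr = np.asarray(values)
    if arr.ndim != 2:
        raise ValueError(f"expected an (H, W) mask, got shape {arr.shape}")
    uniq = np.unique(arr)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError("mask values must be 0 or 1")
    if image is not None and arr.shape != image.shape[:2]:
        raise ValueError(
            f"mask shape {arr.shape} does not match image shape {image.shape[:2]}"
        )
    return arr.astype(np.uint8)


def load_image(path) -> np.ndarray:
    """Load an 8-bit PNG/JPEG as an RGB raster.

    Grayscale files are promoted to three identical channels; any alpha
    channel is dropped.  Non-8-bit depths are rejected.
    """
    try:
        with Image.open(path) as im:
            if im.mode in ("I", "I;16", "I;16B", "I;16L", "F"):
                raise ValueError(f"{path}: not an 8-bit image (mode {im.mode})")
            im = im.convert("RGB")
            arr = np.asarray(im, dtype=np.uint8)
    except (OSError, SyntaxError) as exc:
        raise OSError(f"cannot read image {path}: {exc}") from exc
    return as_rgb(arr)


def save_image(image: np.ndarray, path) -> None:
    Image.fromarray(as_rgb(image), mode="RGB").save(path)


def load_mask(path) -> np.ndarray:
    """Load a single-channel 0/255 PNG as a binary mask.

    Values are thresholded at >= 128 so antialiased masks binarize
    deterministically.
    """
    try:
        with Image.open(path) as im:
            if im.mode in ("I", "I;16", "I;16B", "I;16L", "F"):
                raise ValueError(f"{path}: not an 8-bit mask (mode {im.mode})")
            im = im.convert("L")
            arr = np.asarray(im, dtype=np.uint8)
    except (OSError, SyntaxError) as exc:
        raise OSError(f"cannot read mask {path}: {exc}") from exc
    return (arr >= 128).astype(np.uint8)


def save_mask(mask: np.ndarray, path) -> None:
    """Write a binary mask as an 8-bit PNG with 1 -> 255 and 0 -> 0."""
    mask = as_mask(mask)
    Image.fromarray(mask * np.uint8(255), mode="L").save(path)


def overlay_mask(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Return a copy of ``image`` with masked pixels painted pure green.

    Unmasked pixels are byte-identical to the input.
    """
    image = as_rgb(image)
    mask = as_mask(mask, image)
    out = image.copy()
    out[mask == 1] = OVERLAY_GREEN
    return out


def rgb_to_hsv(image: np.ndarray) -> np.ndarray:
    """RGB -> HSV.  H, S in [0, 1]; V in [0, 255] (the max channel)."""
    rgb = as_rgb(image).astype(np.float64) / 255.0
    maxc = rgb.max(axis=2)
    minc = rgb.min(axis=2)
    v = maxc
    delta = maxc - minc
    s = np.where(maxc > 0, delta / np.where(maxc > 0, maxc, 1.0), 0.0)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    safe = np.where(delta > 0, delta, 1.0)
    h = np.zeros_like(maxc)
    idx = (maxc == r) & (delta > 0)
    h[idx] = ((g - b)[idx] / safe[idx]) % 6.0
    idx = (maxc == g) & (delta > 0) & (maxc != r)
    h[idx] = (b - r)[idx] / safe[idx] + 2.0
    idx = (maxc == b) & (delta > 0) & (maxc != r) & (maxc != g)
    h[idx] = (r - g)[idx] / safe[idx] + 4.0
    h /= 6.0
    return np.stack([h, s, v * 255.0], axis=2)


def hsv_to_rgb(hsv: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_hsv`; requantizes to uint8 (round, clip)."""
    h = hsv[..., 0] * 6.0
    s = hsv[..., 1]
    v = hsv[..., 2] / 255.0
    i = np.floor(h).astype(int) % 6
    f = h - np.floor(h)
    p = v * (1.0 - s)
    q = v * (1.0 - s * f)
    t = v * (1.0 - s * (1.0 - f))
    r = np.choose(i, [v, q, p, p, t, v])
    g = np.choose(i, [t, v, v, q, p, p])
    b = np.choose(i, [p, p, t, v, v, q])
    rgb = np.stack([r, g, b], axis=2) * 255.0
    return np.clip(np.floor(rgb + 0.5), 0, 255).astype(np.uint8)


def grayscale(image: np.ndarray) -> np.ndarray:
    """BT.601 luma of an RGB image, as float64 in [0, 255]."""
    image = as_rgb(image).astype(np.float64)
    wr, wg, wb = LUMA_WEIGHTS
    return wr * image[..., 0] + wg * image[..., 1] + wb * image[..., 2]
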