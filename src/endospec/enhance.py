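"""Brightness enhancement of low-light frames via wavelet + SVD equalization.

Low-brightness frames are brightened on the V channel of HSV space only, so
hue and saturation — and therefore tissue color — are untouched.  The chain:

1. adaptive gamma correction of V (mean mapped toward mid-gray),
2. single-level 2-D discrete wavelet transform of both the original and the
   gamma-corrected V,
3. singular-value equalization of the original low-frequency band against the
   gamma-corrected one (transfers the global intensity gain),
4. soft-threshold denoising of the original high-frequency bands,
5. inverse DWT and requantization.

Working on the approximation band concentrates the gain in global
illumination while the denoised detail bands preserve texture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .imaging import as_rgb, hsv_to_rgb, rgb_to_hsv

__all__ = [
    "EnhancerParams",
    "adaptive_gamma",
    "dwt1",
    "idwt1",
    "singular_equalize",
    "soft_threshold",
    "enhance",
]


@dataclass(frozen=True)
class EnhancerParams:
    """Options of the V-channel enhancement chain.

    wavelet : wavelet family for the single-level 2-D DWT (default Haar —
        the equalization acts on a single approximation band).
    gamma : ``None`` selects the adaptive mean-anchored exponent
        ``log(0.5) / log(mean_V / 255)``; a float forces that exponent.
    denoise : apply soft-threshold denoising to the detail bands.
    """

    wavelet: str = "haar"
    gamma: float | None = None
    denoise: bool = True


def adaptive_gamma(v: np.ndarray, gamma: float | None = None) -> np.ndarray:
    """Gamma-correct a V-channel matrix, brightening dark inputs.

    The adaptive exponent maps the mean intensity to mid-gray:
    ``gamma = log(0.5) / log(mu/255)`` with the mean clipped to [1, 254], so
    ``gamma < 1`` (brightening) whenever the mean is below 127.5.  0 and 255
    are fixed points for any exponent.
    """
    v = np.asarray(v, dtype=np.float64)
    if v.size == 0:
        raise ValueError("empty V channel")
    if gamma is None:
        mu = float(np.clip(v.mean(), 1.0, 254.0))
        gamma = np.log(0.5) / np.log(mu / 255.0)
    return 255.0 * np.power(np.clip(v, 0.0, 255.0) / 255.0, gamma)


def dwt1(v: np.ndarray, wavelet: str = "haar"):
    """Single-level 2-D DWT -> (LF, (HF_h, HF_v, HF_d)).

    Odd dimensions are handled by symmetric extension; the transform is
    perfectly reconstructed by :func:`idwt1`.
    """
    v = np.asarray(v, dtype=np.float64)
    if v.ndim != 2 or min(v.shape) < 2:
        raise ValueError(f"need a 2-D matrix of at least 2x2, got shape {v.shape}")
    lf, hf = pywt.dwt2(v, wavelet, mode="symmetric")
    return lf, hf


def idwt1(lf: np.ndarray, hf, shape=None, wavelet: str = "haar") -> np.ndarray:
    """Inverse of :func:`dwt1`; ``shape`` trims the symmetric-extension pad."""
    out = pywt.idwt2((lf, hf), wavelet, mode="symmetric")
    if shape is not None:
        out = out[: shape[0], : shape[1]]
    return out


def singular_equalize(lf: np.ndarray, lf_gamma: np.ndarray) -> np.ndarray:
    """Equalize the singular spectrum of LF against the gamma-corrected band.

    With ``LF = U diag(s) V^T``, the correction factor is

        xi = (max(s) + max(s_gamma)) / (2 max(s))

    and every singular value of LF is scaled by ``xi`` — halfway between the
    original and gamma-corrected global intensity scale.  Scaling the whole
    spectrum by one scalar leaves the singular vectors untouched, so
    ``LF_eq = xi * LF`` exactly.  An all-zero LF falls back to ``lf_gamma``.
    """
    lf = np.asarray(lf, dtype=np.float64)
    lf_gamma = np.asarray(lf_gamma, dtype=np.float64)
    if lf.shape != lf_gamma.shape:
        raise ValueError("LF and LF_gamma must have the same shape")
    s_max = float(np.linalg.svd(lf, compute_uv=False)[0]) if lf.any() else 0.0
    if s_max == 0.0:
        return lf_gamma.copy()
    s_gamma_max = float(np.linalg.svd(lf_gamma, compute_uv=False)[0])
    xi = (s_max + s_gamma_max) / (2.0 * s_max)
    return xi * lf


def soft_threshold(hf, threshold: float | None = None):
    """Soft-threshold the three detail bands.

    The universal threshold ``lambda = sigma * sqrt(2 ln N)`` is used with
    the MAD noise estimate ``sigma = median(|diagonal band|) / 0.6745`` and
    ``N`` the pixels per band.  Each coefficient maps to
    ``sign(x) * max(|x| - lambda, 0)``.
    """
    hf_h, hf_v, hf_d = (np.asarray(b, dtype=np.float64) for b in hf)
    if threshold is None:
        sigma = float(np.median(np.abs(hf_d))) / 0.6745
        threshold = sigma * np.sqrt(2.0 * np.log(hf_d.size)) if sigma > 0 else 0.0
    if threshold <= 0:
        return hf_h, hf_v, hf_d

    def shrink(x):
        return np.sign(x) * np.maximum(np.abs(x) - threshold, 0.0)

    return shrink(hf_h), shrink(hf_v), shrink(hf_d)


def enhance_v(v: np.ndarray, params: EnhancerParams | None = None) -> np.ndarray:
    """Run the enhancement chain on a float V-channel matrix (no rounding)."""
    params = params or EnhancerParams()
    v = np.asarray(v, dtype=np.float64)
    v_gamma = adaptive_gamma(v, params.gamma)
    lf, hf = dwt1(v, params.wavelet)
    lf_gamma, _ = dwt1(v_gamma, params.wavelet)
    lf_eq = singular_equalize(lf, lf_gamma)
    hf_out = soft_threshold(hf) if params.denoise else hf
    out = idwt1(lf_eq, hf_out, shape=v.shape, wavelet=params.wavelet)
    return np.clip(out, 0.0, 255.0)


def enhance(image: np.ndarray, params: EnhancerParams | None = None) -> np.ndarray:
    """Brighten a (low-class) RGB image on its V channel.

    H and S are carried through unchanged; only V is replaced by the
    enhanced band, then the image is requantized to uint8
    (round-half-away-from-zero, clip).
    """
    image = as_rgb(image)
    hsv = rgb_to_hsv(image)
    hsv[..., 2] = enhance_v(hsv[..., 2], params)
    return hsv_to_rgb(hsv)
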