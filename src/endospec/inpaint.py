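"""Exemplar-based inpainting of specular regions.

The restoration engine fills each specular region Ω patch-by-patch with
best-matching 9x9 exemplars copied from the known region ϕ, in the order
given by a boundary priority function.  Two modes are provided:

* ``criminisi`` — the classic exemplar algorithm: priority
  ``P(p) = C(p) * D(p)`` over the *global* highlight boundary and an
  exhaustive full-image search for the matching patch.  Kept as a reference
  mode.

* ``improved`` (default) — three changes aimed at endoscopic frames, where
  highlights are many, small and mutually unrelated:

  1. *per-region repair*: regions are filled one at a time, so priorities
     are only evaluated on the active region's boundary;
  2. *hybrid priority*: when confidence is low (``C(p) < 0.5``) the
     multiplicative coupling is replaced by a regularized additive form
     ``R_C(p) + beta*D(p)`` with ``R_C(p) = (1-w)*C(p) + w``, preventing the
     confidence collapse that makes late fill order arbitrary; when
     confidence is high the product form is kept but the data term is
     augmented with a curvature term, ``C(p) * (D(p) + 1/(1+|K(p)|))``, so
     straight isophotes (``K -> 0``) are favored and a vanishing data term
     can no longer zero the priority;
  3. *adaptive local search*: the exemplar search is restricted to a window
     around the region, obtained by inflating its bounding box by ``n``
     times its height/width — ``n = n1`` for short contours (``lc < a``),
     ``n = n2`` for long ones.  Tissue is locally self-similar, so nearby
     exemplars match better, and the work per region stops depending on the
     frame resolution.

All tie-breaks (equal priority, equal SSD) are lexicographic in ``(y, x)``,
making the output deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from .imaging import as_mask, as_rgb, grayscale

__all__ = [
    "InpaintParams",
    "InpaintStats",
    "HighlightRegion",
    "SearchWindow",
    "extract_regions",
    "search_window",
    "combine_priority",
    "ssd",
    "inpaint",
]


def combine_priority(
    cp: float, dp: float, kp: float, params: "InpaintParams", mode: str
) -> float:
    """Combine confidence, data and curvature terms into a fill priority.

    ``"criminisi"`` multiplies confidence and data term.  ``"improved"``
    switches on the confidence level: below 0.5 the regularized additive
    form ``R_C(p) + beta*D(p)`` with ``R_C(p) = (1-w)*C(p) + w`` keeps the
    priority informative after confidence has decayed; at or above 0.5 the
    product form is kept with the curvature-augmented data term
    ``C(p) * (D(p) + 1/(1+|K(p)|))``, which favors straight isophotes and
    never vanishes just because the data term does.
    """
    if mode == "criminisi":
        return cp * dp
    if cp < 0.5:
        return (1.0 - params.w) * cp + params.w + params.beta * dp
    return cp * (dp + 1.0 / (1.0 + abs(kp)))

_EIGHT = np.ones((3, 3), dtype=bool)  # 8-connectivity structuring element


@dataclass(frozen=True)
class InpaintParams:
    """Tunables of the inpainting engine.

    patch_side : odd side of the square exemplar patch (pixels).
    w : regularization factor of the smoothed confidence ``R_C``; in (0, 1).
    beta : data-term weight in the low-confidence additive branch.
    alpha : normalization of the data term (255 for 8-bit intensities).
    a : contour-length pivot of the window-expansion rule, in pixels;
        ``None`` selects ``0.05 * (H + W)`` from the frame resolution.
    n1, n2 : bounding-box expansion coefficients for short/long contours.
    mode : ``"improved"`` or ``"criminisi"``.
    force_full_window / force_priority : experiment overrides that let the
        improved engine run with a full-frame search window and/or the
        classic multiplicative priority.
    """

    patch_side: int = 9
    w: float = 0.7
    beta: float = 0.5
    alpha: float = 255.0
    a: float | None = None
    n1: int = 2
    n2: int = 4
    mode: str = "improved"
    force_full_window: bool = False
    force_priority: str | None = None

    def __post_init__(self):
        if self.patch_side < 1 or self.patch_side % 2 == 0:
            raise ValueError("patch_side must be odd and positive")
        if not 0.0 < self.w < 1.0:
            raise ValueError("w must be in (0, 1)")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.n1 > self.n2:
            raise ValueError("need n1 <= n2")
        if self.a is not None and self.a <= 0:
            raise ValueError("a must be positive")
        if self.mode not in ("improved", "criminisi"):
            raise ValueError("mode must be 'improved' or 'criminisi'")
        if self.force_priority not in (None, "improved", "criminisi"):
            raise ValueError("force_priority must be None, 'improved' or 'criminisi'")

    def pivot(self, shape) -> float:
        return self.a if self.a is not None else 0.05 * (shape[0] + shape[1])

    @property
    def priority_mode(self) -> str:
        return self.force_priority or self.mode


@dataclass
class InpaintStats:
    """Run counters: fill steps, candidate patches scored, windows used."""

    fill_steps: int = 0
    candidate_evaluations: int = 0
    regions: int = 0
    windows: list = field(default_factory=list)


@dataclass(frozen=True)
class SearchWindow:
    """Inclusive row/column bounds of an exemplar search area."""

    us: int
    ds: int
    ls: int
    rs: int


@dataclass(frozen=True)
class HighlightRegion:
    """One 8-connected specular component and its contour geometry."""

    label: int
    pixels: np.ndarray  # (N, 2) array of (y, x)
    contour: np.ndarray  # (M, 2) array of (y, x), 4-adjacent to known
    yup: int
    ydown: int
    xleft: int
    xright: int

    @property
    def lc(self) -> int:
        return len(self.contour)

    @property
    def h(self) -> int:
        return self.ydown - self.yup + 1

    @property
    def w(self) -> int:
        return self.xright - self.xleft + 1


def _contour_of(mask: np.ndarray) -> np.ndarray:
    """Mask pixels 4-adjacent to at least one unmasked pixel (bool out)."""
    known = ~mask
    near_known = np.zeros_like(mask)
    near_known[1:, :] |= known[:-1, :]
    near_known[:-1, :] |= known[1:, :]
    near_known[:, 1:] |= known[:, :-1]
    near_known[:, :-1] |= known[:, 1:]
    return mask & near_known


def extract_regions(mask: np.ndarray) -> list[HighlightRegion]:
    """Split a highlight mask into 8-connected regions.

    Regions are ordered by first raster-scan encounter.  An empty mask
    yields an empty list; a full-frame mask is rejected because no known
    pixels remain to copy from.
    """
    mask = as_mask(mask).astype(bool)
    if mask.all() and mask.size:
        raise ValueError("mask covers the whole frame; nothing to copy from")
    labels, n = ndimage.label(mask, structure=_EIGHT)
    regions = []
    contour_all = _contour_of(mask)
    for lab in range(1, n + 1):
        comp = labels == lab
        ys, xs = np.nonzero(comp)
        cys, cxs = np.nonzero(comp & contour_all)
        regions.append(
            HighlightRegion(
                label=lab,
                pixels=np.column_stack([ys, xs]),
                contour=np.column_stack([cys, cxs]),
                yup=int(ys.min()),
                ydown=int(ys.max()),
                xleft=int(xs.min()),
                xright=int(xs.max()),
            )
        )
    return regions


def search_window(
    region: HighlightRegion, shape, params: InpaintParams | None = None, n_extra: int = 0
) -> SearchWindow:
    """Adaptive search window around a region's bounding box.

    The expansion coefficient is ``n1`` for contours shorter than the pivot
    ``a`` and ``n2`` otherwise; the box is inflated by ``n*h`` rows and
    ``n*w`` columns and clipped to the frame.  ``n_extra`` supports the
    retry path when a window holds no viable exemplar.
    """
    params = params or InpaintParams()
    n = (params.n1 if region.lc < params.pivot(shape) else params.n2) + n_extra
    h, w = region.h, region.w
    return SearchWindow(
        us=max(region.yup - n * h, 0),
        ds=min(region.ydown + n * h, shape[0] - 1),
        ls=max(region.xleft - n * w, 0),
        rs=min(region.xright + n * w, shape[1] - 1),
    )


def ssd(patch_a: np.ndarray, patch_b: np.ndarray, valid: np.ndarray) -> int:
    """Sum of squared per-channel differences over the valid pixels."""
    patch_a = np.asarray(patch_a, dtype=np.int64)
    patch_b = np.asarray(patch_b, dtype=np.int64)
    if patch_a.shape != patch_b.shape:
        raise ValueError("patches must have the same shape")
    valid = np.asarray(valid, dtype=bool)
    if not valid.any():
        raise ValueError("no valid pixels to compare")
    diff = (patch_a - patch_b) ** 2
    return int((diff * valid[..., None]).sum())


class _State:
    """Mutable working state of one inpainting run."""

    def __init__(self, image: np.ndarray, mask: np.ndarray, params: InpaintParams):
        self.img = image.copy()
        self.known = ~mask.astype(bool)
        self.conf = self.known.astype(np.float64)  # 1 on phi, 0 on Omega
        self.gray = grayscale(self.img)
        self.params = params
        self.stats = InpaintStats()

    # -- patch geometry ----------------------------------------------------

    def patch_offsets(self, y: int, x: int):
        """Crop-aware patch extent around (y, x): (dy0, dy1, dx0, dx1)."""
        half = self.params.patch_side // 2
        H, W = self.known.shape
        return (-min(half, y), min(half, H - 1 - y), -min(half, x), min(half, W - 1 - x))

    # -- priority terms ----------------------------------------------------

    def confidence_term(self, y: int, x: int) -> float:
        """Fraction of confident knowledge in the patch at (y, x).

        Sum of confidence over the known pixels of the patch divided by the
        (crop-aware) patch area.
        """
        dy0, dy1, dx0, dx1 = self.patch_offsets(y, x)
        sl = (slice(y + dy0, y + dy1 + 1), slice(x + dx0, x + dx1 + 1))
        area = (dy1 - dy0 + 1) * (dx1 - dx0 + 1)
        return float(self.conf[sl][self.known[sl]].sum()) / area

    def data_term(self, y: int, x: int) -> float:
        """Isophote strength crossing the fill front at (y, x).

        The isophote at p is taken as the strongest central-difference
        gradient among the fully-known pixels of the patch, rotated 90
        degrees; the front normal comes from the gradient of the mask.
        ``D(p) = |isophote . normal| / alpha``, clipped to [0, 1].
        """
        dy0, dy1, dx0, dx1 = self.patch_offsets(y, x)
        H, W = self.known.shape
        # one-pixel margin so central differences at the patch rim are real
        y0, y1 = max(y + dy0 - 1, 0), min(y + dy1 + 1, H - 1)
        x0, x1 = max(x + dx0 - 1, 0), min(x + dx1 + 1, W - 1)
        crop = self.gray[y0 : y1 + 1, x0 : x1 + 1]
        kcrop = self.known[y0 : y1 + 1, x0 : x1 + 1]
        if crop.shape[0] < 2 or crop.shape[1] < 2:
            return 0.0
        gy, gx = np.gradient(crop)
        # a gradient sample is trusted only where the pixel and its 4-stencil
        # neighbors are known
        valid = kcrop & ndimage.binary_erosion(
            kcrop, structure=ndimage.generate_binary_structure(2, 1), border_value=1
        )
        # restrict to the patch proper (strip the margin)
        py0, px0 = (y + dy0) - y0, (x + dx0) - x0
        sel = np.zeros_like(valid)
        sel[py0 : py0 + (dy1 - dy0 + 1), px0 : px0 + (dx1 - dx0 + 1)] = True
        valid &= sel
        if not valid.any():
            return 0.0
        mag = np.hypot(gy, gx)
        mag_valid = np.where(valid, mag, -1.0)
        iy, ix = np.unravel_index(int(np.argmax(mag_valid)), mag.shape)
        ty, tx = -gx[iy, ix], gy[iy, ix]  # isophote: gradient rotated 90 deg
        ny, nx = self._front_normal(y, x)
        return float(np.clip(abs(ty * ny + tx * nx) / self.params.alpha, 0.0, 1.0))

    def _front_normal(self, y: int, x: int):
        """Unit normal of the fill front at (y, x), from the mask gradient."""
        H, W = self.known.shape

        def hole(yy, xx):
            return 0.0 if self.known[yy, xx] else 1.0

        gy = (hole(min(y + 1, H - 1), x) - hole(max(y - 1, 0), x)) / 2.0
        gx = (hole(y, min(x + 1, W - 1)) - hole(y, max(x - 1, 0))) / 2.0
        norm = np.hypot(gy, gx)
        if norm < 1e-12:
            return 1.0, 0.0  # isolated-pixel convention
        return gy / norm, gx / norm

    def curvature_term(self, y: int, x: int) -> float:
        """Isophote curvature ``K(p) = div(grad I / |grad I|)`` at (y, x).

        Finite differences on a small crop; returns 0 where the gradient
        magnitude is below 1e-6 (flat patch, curvature undefined).
        """
        H, W = self.known.shape
        r = 2
        y0, y1 = max(y - r, 0), min(y + r, H - 1)
        x0, x1 = max(x - r, 0), min(x + r, W - 1)
        crop = self.gray[y0 : y1 + 1, x0 : x1 + 1]
        if crop.shape[0] < 2 or crop.shape[1] < 2:
            return 0.0
        gy, gx = np.gradient(crop)
        mag = np.hypot(gy, gx)
        cy, cx = y - y0, x - x0
        if mag[cy, cx] <= 1e-6:
            return 0.0
        safe = np.where(mag > 1e-6, mag, 1.0)
        nhat_y = np.where(mag > 1e-6, gy / safe, 0.0)
        nhat_x = np.where(mag > 1e-6, gx / safe, 0.0)
        div = np.gradient(nhat_y, axis=0) + np.gradient(nhat_x, axis=1)
        return float(div[cy, cx])

    def priority(self, y: int, x: int) -> tuple[float, float]:
        """Priority of boundary pixel (y, x) -> (P(p), C(p)).

        Classic mode multiplies confidence and data term.  Improved mode
        switches on the confidence level: the additive regularized branch
        below 0.5, the curvature-augmented product branch at or above.
        """
        mode = self.params.priority_mode
        cp = self.confidence_term(y, x)
        dp = self.data_term(y, x)
        kp = 0.0
        if mode == "improved" and cp >= 0.5:
            kp = self.curvature_term(y, x)
        return combine_priority(cp, dp, kp, self.params, mode), cp

    # -- matching and filling ----------------------------------------------

    def best_match(self, y: int, x: int, window: SearchWindow):
        """Best exemplar center in ``window`` for the patch at (y, x).

        Candidates are patches with the target's (possibly cropped) extent
        that lie fully inside the window and contain only known pixels; the
        SSD over the target's known pixels is minimized, ties broken by
        smallest (y, x).  Returns ``None`` when the window has no candidate.
        """
        dy0, dy1, dx0, dx1 = self.patch_offsets(y, x)
        ph, pw = dy1 - dy0 + 1, dx1 - dx0 + 1
        us, ds, ls, rs = window.us, window.ds, window.ls, window.rs
        if ds - us + 1 < ph or rs - ls + 1 < pw:
            return None
        sub = self.img[us : ds + 1, ls : rs + 1].astype(np.int32)
        subk = self.known[us : ds + 1, ls : rs + 1]
        target = self.img[y + dy0 : y + dy1 + 1, x + dx0 : x + dx1 + 1].astype(np.int32)
        tvalid = self.known[y + dy0 : y + dy1 + 1, x + dx0 : x + dx1 + 1]
        if not tvalid.any():
            raise ValueError("target patch has no known pixels")
        kc = sliding_window_view(subk, (ph, pw)).reshape(-1, ph, pw)
        full_known = kc.all(axis=(1, 2))
        n_pos = (ds - us + 1 - ph + 1, rs - ls + 1 - pw + 1)
        self.stats.candidate_evaluations += int(full_known.sum())
        if not full_known.any():
            return None
        views = sliding_window_view(sub, (ph, pw), axis=(0, 1))  # (i, j, 3, ph, pw)
        t = target.transpose(2, 0, 1)
        diff = (views - t) ** 2
        scores = (diff * tvalid[None, None, None]).sum(axis=(2, 3, 4), dtype=np.int64)
        scores = scores.reshape(-1)
        scores[~full_known] = np.iinfo(np.int64).max
        best = int(np.argmin(scores))  # first minimum = smallest (y, x)
        bi, bj = divmod(best, n_pos[1])
        return us + bi - dy0, ls + bj - dx0

    def fill_step(self, p, q, cp: float) -> int:
        """Copy exemplar pixels into the unfilled part of the target patch.

        Newly filled pixels take the priority-time confidence ``cp`` and
        become usable sources for later steps.  Returns the number of
        pixels filled (always >= 1).
        """
        y, x = p
        qy, qx = q
        dy0, dy1, dx0, dx1 = self.patch_offsets(y, x)
        tsl = (slice(y + dy0, y + dy1 + 1), slice(x + dx0, x + dx1 + 1))
        ssl = (slice(qy + dy0, qy + dy1 + 1), slice(qx + dx0, qx + dx1 + 1))
        hole = ~self.known[tsl]
        n_fill = int(hole.sum())
        if n_fill == 0:
            raise RuntimeError("fill step would not shrink the hole")
        timg = self.img[tsl]
        timg[hole] = self.img[ssl][hole]
        self.img[tsl] = timg
        tconf = self.conf[tsl]
        tconf[hole] = cp
        self.conf[tsl] = tconf
        self.known[tsl] |= hole
        self.gray[tsl] = grayscale(self.img[tsl])
        self.stats.fill_steps += 1
        return n_fill

    # -- boundaries ---------------------------------------------------------

    def boundary_coords(self, within: np.ndarray | None = None) -> np.ndarray:
        """(y, x) coords of unfilled pixels 4-adjacent to known ones,
        optionally restricted to a region membership mask, raster-ordered."""
        hole = ~self.known
        if within is not None:
            hole = hole & within
        ys, xs = np.nonzero(_bnd(hole, self.known))
        return np.column_stack([ys, xs])


def _bnd(hole: np.ndarray, known: np.ndarray) -> np.ndarray:
    """Hole pixels 4-adjacent to a known pixel (known may exceed ~hole)."""
    near = np.zeros_like(hole)
    near[1:, :] |= known[:-1, :]
    near[:-1, :] |= known[1:, :]
    near[:, 1:] |= known[:, :-1]
    near[:, :-1] |= known[:, 1:]
    return hole & near


def _pick_max_priority(state: _State, coords: np.ndarray):
    """Highest-priority boundary pixel; ties to smallest (y, x)."""
    best_p, best_val, best_cp = None, -np.inf, 0.0
    for y, x in coords:  # raster order, strict > keeps the first of a tie
        val, cp = state.priority(int(y), int(x))
        if val > best_val:
            best_p, best_val, best_cp = (int(y), int(x)), val, cp
    return best_p, best_cp


def _full_window(shape) -> SearchWindow:
    return SearchWindow(0, shape[0] - 1, 0, shape[1] - 1)


def _inpaint_region(state: _State, region: HighlightRegion) -> dict:
    """Fill one region to completion; returns a per-region report entry."""
    params = state.params
    shape = state.known.shape
    # work on a bbox crop (+1 margin): the region's unfilled pixels never
    # leave the original bbox, so per-step cost is independent of frame size
    by0, by1 = max(region.yup - 1, 0), min(region.ydown + 1, shape[0] - 1)
    bx0, bx1 = max(region.xleft - 1, 0), min(region.xright + 1, shape[1] - 1)
    bsl = (slice(by0, by1 + 1), slice(bx0, bx1 + 1))
    member = np.zeros((by1 - by0 + 1, bx1 - bx0 + 1), dtype=bool)
    member[region.pixels[:, 0] - by0, region.pixels[:, 1] - bx0] = True
    if params.force_full_window:
        window = _full_window(shape)
    else:
        window = search_window(region, shape, params)
    steps = 0
    while True:
        known_crop = state.known[bsl]
        ys, xs = np.nonzero(_bnd(~known_crop & member, known_crop))
        if len(ys) == 0:
            break
        coords = np.column_stack([ys + by0, xs + bx0])
        p, cp = _pick_max_priority(state, coords)
        q = None
        n_extra = 0
        win = window
        while q is None:
            q = state.best_match(p[0], p[1], win)
            if q is None:
                if win == _full_window(shape):
                    raise RuntimeError(
                        "no fully-known exemplar patch exists anywhere in the frame"
                    )
                n_extra += 1
                win = (
                    _full_window(shape)
                    if params.force_full_window
                    else search_window(region, shape, params, n_extra)
                )
        state.fill_step(p, q, cp)
        steps += 1
        if steps > len(region.pixels):
            raise RuntimeError("inpainting did not terminate")
    return {
        "label": region.label,
        "size": len(region.pixels),
        "lc": region.lc,
        "window": (window.us, window.ds, window.ls, window.rs),
        "fill_steps": steps,
    }


def _inpaint_criminisi(state: _State) -> None:
    """Classic mode: global boundary priority, full-frame exemplar search."""
    shape = state.known.shape
    window = _full_window(shape)
    total = int((~state.known).sum())
    steps = 0
    while True:
        hole = ~state.known
        coords_mask = _bnd(hole, state.known)
        ys, xs = np.nonzero(coords_mask)
        if len(ys) == 0:
            break
        p, cp = _pick_max_priority(state, np.column_stack([ys, xs]))
        q = state.best_match(p[0], p[1], window)
        if q is None:
            raise RuntimeError("no fully-known exemplar patch exists anywhere in the frame")
        state.fill_step(p, q, cp)
        steps += 1
        if steps > total:
            raise RuntimeError("inpainting did not terminate")


def inpaint(
    image: np.ndarray,
    mask: np.ndarray,
    params: InpaintParams | None = None,
    *,
    return_stats: bool = False,
):
    """Restore all specular regions of ``image`` marked by ``mask``.

    Pixels outside the mask are byte-identical in the output.  In improved
    mode regions are repaired sequentially in raster-encounter order, each
    within its own adaptive window; in criminisi mode the global boundary
    is processed with full-frame search.  With ``return_stats=True`` an
    :class:`InpaintStats` with per-region window/step reports is appended.
    """
    params = params or InpaintParams()
    image = as_rgb(image)
    mask = as_mask(mask, image)
    if image.shape[0] < params.patch_side or image.shape[1] < params.patch_side:
        raise ValueError(
            f"image must be at least {params.patch_side}x{params.patch_side}"
        )
    if mask.all():
        raise ValueError("mask covers the whole frame; nothing to copy from")
    state = _State(image, mask, params)
    if mask.any():
        if params.mode == "criminisi":
            state.stats.regions = int(ndimage.label(mask, structure=_EIGHT)[1])
            _inpaint_criminisi(state)
        else:
            regions = extract_regions(mask)
            state.stats.regions = len(regions)
            for region in regions:
                state.stats.windows.append(_inpaint_region(state, region))
    if return_stats:
        return state.img, state.stats
    return state.img
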