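import numpy as np
import pytest

from endospec.inpaint import (
    HighlightRegion,
    InpaintParams,
    SearchWindow,
    _State,
    combine_priority,
    extract_regions,
    inpaint,
    search_window,
    ssd,
)


def square_mask(size, y0, y1, x0, x1):
    mask = np.zeros((size, size), dtype=np.uint8)
    mask[y0:y1, x0:x1] = 1
    return mask


class TestExtractRegions:
    def test_two_separated_squares(self):
        mask = np.zeros((16, 16), dtype=np.uint8)
        mask[2:5, 2:5] = 1
        mask[10:13, 9:12] = 1
        regions = extract_regions(mask)
        assert len(regions) == 2
        # 3x3 square: every pixel touches the outside except the center
        assert [r.lc for r in regions] == [8, 8]
        assert (regions[0].yup, regions[0].xleft) == (2, 2)

    def test_single_pixel_region(self):
        mask = np.zeros((10, 10), dtype=np.uint8)
        mask[4, 7] = 1
        (region,) = extract_regions(mask)
        assert region.lc == 1
        assert region.h == region.w == 1

    def test_raster_encounter_order(self):
        mask = np.zeros((16, 16), dtype=np.uint8)
        mask[8:10, 1:3] = 1  # encountered second
        mask[1:3, 8:10] = 1  # encountered first
        regions = extract_regions(mask)
        assert regions[0].yup == 1 and regions[1].yup == 8

    def test_full_frame_mask_rejected(self):
        with pytest.raises(ValueError):
            extract_regions(np.ones((8, 8), dtype=np.uint8))

    def test_empty_mask_gives_empty_list(self):
        assert extract_regions(np.zeros((8, 8), dtype=np.uint8)) == []


class TestSearchWindow:
    def region(self, lc=40):
        contour = np.zeros((lc, 2), dtype=int)
        return HighlightRegion(
            label=1, pixels=np.zeros((1, 2), dtype=int), contour=contour,
            yup=10, ydown=20, xleft=30, xright=40,
        )

    def test_expansion_and_clipping(self):
        # h = w = 11, n = 2: rows -12..42 clip to 0..42, cols 8..62
        win = search_window(self.region(lc=1), (100, 100), InpaintParams(a=50.0))
        assert win == SearchWindow(us=0, ds=42, ls=8, rs=62)

    def test_contour_pivot_branch_boundary(self):
        params = InpaintParams(a=40.0, n1=2, n2=4)
        short = search_window(self.region(lc=39), (500, 500), params)
        long = search_window(self.region(lc=40), (500, 500), params)
        assert short.ds - short.us < long.ds - long.us  # n1 vs n2

    def test_full_frame_region_clips_to_frame(self):
        region = HighlightRegion(
            label=1, pixels=np.zeros((1, 2), dtype=int),
            contour=np.zeros((9, 2), dtype=int),
            yup=0, ydown=31, xleft=0, xright=31,
        )
        win = search_window(region, (32, 32))
        assert win == SearchWindow(0, 31, 0, 31)


class TestSsd:
    def test_identical_patches_zero(self, rng):
        p = rng.integers(0, 256, (9, 9, 3))
        assert ssd(p, p, np.ones((9, 9), dtype=bool)) == 0

    def test_single_valid_pixel(self):
        a = np.zeros((3, 3, 3), dtype=np.uint8)
        b = np.zeros((3, 3, 3), dtype=np.uint8)
        b[1, 1] = (1, 2, 2)
        valid = np.zeros((3, 3), dtype=bool)
        valid[1, 1] = True
        assert ssd(a, b, valid) == 9  # 1 + 4 + 4

    def test_symmetry(self, rng):
        a = rng.integers(0, 256, (5, 5, 3))
        b = rng.integers(0, 256, (5, 5, 3))
        valid = rng.random((5, 5)) > 0.5
        valid[0, 0] = True
        assert ssd(a, b, valid) == ssd(b, a, valid)

    def test_no_valid_pixels_rejected(self):
        a = np.zeros((3, 3, 3))
        with pytest.raises(ValueError):
            ssd(a, a, np.zeros((3, 3), dtype=bool))


class TestPriorityTerms:
    def make_state(self, image, mask, **kwargs):
        return _State(image.astype(np.uint8), mask, InpaintParams(**kwargs))

    def test_confidence_full_knowledge(self):
        img = np.zeros((21, 21, 3), dtype=np.uint8)
        mask = square_mask(21, 14, 17, 14, 17)
        state = self.make_state(img, mask)
        assert state.confidence_term(5, 5) == 1.0

    def test_confidence_partial_patch_counts_known(self):
        img = np.zeros((21, 21, 3), dtype=np.uint8)
        mask = np.zeros((21, 21), dtype=np.uint8)
        mask[10:, :] = 1  # lower half unknown
        state = self.make_state(img, mask)
        # patch at (10, 10): rows 6..14, 4 known rows of 9 -> 36/81
        assert state.confidence_term(10, 10) == pytest.approx(36 / 81)

    def test_confidence_zero_inside_hole(self):
        img = np.zeros((31, 31, 3), dtype=np.uint8)
        mask = square_mask(31, 5, 26, 5, 26)
        state = self.make_state(img, mask)
        assert state.confidence_term(15, 15) == 0.0

    def test_data_term_zero_on_constant_image(self):
        img = np.full((21, 21, 3), 90, dtype=np.uint8)
        mask = square_mask(21, 8, 13, 8, 13)
        state = self.make_state(img, mask)
        assert state.data_term(8, 10) == 0.0

    def test_data_term_isophote_along_front(self):
        # vertical front at x=10; intensity ramps in y with slope 15:
        # gradient (15, 0), isophote (0, 15), normal (0, 1) -> D = 15/255
        ramp = np.clip(np.arange(21) * 15, 0, 255).astype(np.uint8)
        img = np.repeat(ramp[:, None, None], 21, axis=1).repeat(3, axis=2)
        mask = np.zeros((21, 21), dtype=np.uint8)
        mask[:, 10:] = 1
        state = self.make_state(img, mask)
        assert state.data_term(8, 10) == pytest.approx(15 / 255, rel=0.05)

    def test_data_term_isophote_into_front_is_zero(self):
        # intensity ramps in x: isophote vertical, normal horizontal
        ramp = np.clip(np.arange(21) * 10, 0, 255).astype(np.uint8)
        img = np.repeat(ramp[None, :, None], 21, axis=0).repeat(3, axis=2)
        mask = np.zeros((21, 21), dtype=np.uint8)
        mask[:, 14:] = 1
        state = self.make_state(img, mask)
        assert state.data_term(8, 14) == pytest.approx(0.0, abs=1e-9)

    def test_curvature_zero_on_linear_ramp(self):
        ramp = np.clip(np.arange(21) * 10, 0, 255).astype(np.uint8)
        img = np.repeat(ramp[:, None, None], 21, axis=1).repeat(3, axis=2)
        state = self.make_state(img, square_mask(21, 2, 4, 2, 4))
        assert state.curvature_term(10, 10) == pytest.approx(0.0, abs=1e-9)

    def test_curvature_of_cone_is_inverse_radius(self):
        yy, xx = np.mgrid[:64, :64].astype(float)
        r = np.hypot(yy - 32, xx - 32)
        img = np.clip(r * 3, 0, 255).astype(np.uint8)[..., None].repeat(3, axis=2)
        state = self.make_state(img, square_mask(64, 1, 3, 1, 3))
        state.gray = r * 3  # exact cone: 8-bit rounding flattens level lines
        for y, x, dist in [(32, 44, 12.0), (20, 32, 12.0), (32, 52, 20.0)]:
            kp = abs(state.curvature_term(y, x))
            assert kp == pytest.approx(1.0 / dist, rel=0.2)

    def test_curvature_flat_region_guarded_to_zero(self):
        img = np.full((21, 21, 3), 55, dtype=np.uint8)
        state = self.make_state(img, square_mask(21, 2, 4, 2, 4))
        assert state.curvature_term(10, 10) == 0.0


class TestCombinePriority:
    def test_additive_branch_worked_example(self):
        params = InpaintParams(w=0.7, beta=0.5)
        # Cp = 0.2 < 0.5: (0.3*0.2 + 0.7) + 0.5*0 = 0.76
        assert combine_priority(0.2, 0.0, 0.0, params, "improved") == pytest.approx(0.76)

    def test_multiplicative_branch_worked_example(self):
        params = InpaintParams()
        # Cp = 1 >= 0.5: 1 * (0 + 1/(1+0)) = 1
        assert combine_priority(1.0, 0.0, 0.0, params, "improved") == pytest.approx(1.0)

    def test_w_to_one_smooths_confidence_away(self):
        params = InpaintParams(w=0.999)
        lo = combine_priority(0.01, 0.3, 0.0, params, "improved")
        hi = combine_priority(0.49, 0.3, 0.0, params, "improved")
        assert hi - lo < 0.001

    def test_criminisi_mode_is_pure_product(self):
        params = InpaintParams()
        assert combine_priority(0.4, 0.5, 99.0, params, "criminisi") == pytest.approx(0.2)


class TestBestMatchAndFill:
    def test_verbatim_patch_found_with_zero_ssd(self, smooth_image):
        img = smooth_image(seed=1)
        mask = square_mask(32, 14, 17, 14, 17)
        state = _State(img, mask, InpaintParams())
        q = state.best_match(15, 15, SearchWindow(0, 31, 0, 31))
        assert q is not None

    def test_tie_breaks_to_smallest_coordinates(self):
        img = np.full((21, 21, 3), 10, dtype=np.uint8)
        mask = square_mask(21, 9, 12, 9, 12)
        state = _State(img, mask, InpaintParams())
        # uniform image: every candidate has SSD 0 -> first raster position
        q = state.best_match(10, 10, SearchWindow(0, 20, 0, 20))
        assert q == (4, 4)  # top-left feasible center for a 9x9 patch

    def test_window_equivalent_to_exhaustive_scan(self, smooth_image):
        img = smooth_image(size=21, seed=3)
        mask = square_mask(21, 9, 12, 9, 12)
        state = _State(img, mask, InpaintParams())
        p = (10, 10)
        q = state.best_match(*p, SearchWindow(0, 20, 0, 20))
        # brute-force oracle with explicit loops
        dy0, dy1, dx0, dx1 = state.patch_offsets(*p)
        target = img[p[0] + dy0 : p[0] + dy1 + 1, p[1] + dx0 : p[1] + dx1 + 1]
        tvalid = state.known[p[0] + dy0 : p[0] + dy1 + 1, p[1] + dx0 : p[1] + dx1 + 1]
        best, best_val = None, None
        for cy in range(-dy0, 21 - dy1):
            for cx in range(-dx0, 21 - dx1):
                sl = (slice(cy + dy0, cy + dy1 + 1), slice(cx + dx0, cx + dx1 + 1))
                if not state.known[sl].all():
                    continue
                val = ssd(target, img[sl], tvalid)
                if best_val is None or val < best_val:
                    best, best_val = (cy, cx), val
        assert q == best

    def test_fill_step_locality_and_confidence(self, smooth_image):
        img = smooth_image(seed=4)
        mask = square_mask(32, 14, 17, 14, 17)
        state = _State(img, mask, InpaintParams())
        coords = state.boundary_coords()
        y, x = coords[0]
        cp = state.confidence_term(y, x)
        assert cp < 1.0  # partial patch
        before = state.img.copy()
        q = state.best_match(y, x, SearchWindow(0, 31, 0, 31))
        state.fill_step((y, x), q, cp)
        changed = np.any(state.img != before, axis=2)
        assert not changed[mask == 0].any()  # only hole pixels change
        filled = state.known & (mask == 1)
        assert (state.conf[filled] == cp).all()

    def test_confidence_stays_in_unit_interval(self, smooth_image):
        img = smooth_image(seed=5)
        mask = square_mask(32, 12, 19, 12, 19)
        state = _State(img, mask, InpaintParams())
        out = inpaint(img, mask)
        assert state.conf.min() >= 0.0 and state.conf.max() <= 1.0
        assert out.shape == img.shape


class TestInpaint:
    def test_empty_mask_identity(self, smooth_image):
        img = smooth_image(seed=6)
        out = inpaint(img, np.zeros((32, 32), dtype=np.uint8))
        assert np.array_equal(out, img)

    def test_uniform_image_exact_fill(self):
        img = np.full((20, 20, 3), 77, dtype=np.uint8)
        out = inpaint(img, square_mask(20, 8, 11, 8, 11))
        assert np.array_equal(out, img)

    def test_single_pixel_region_one_step(self, smooth_image):
        img = smooth_image(seed=7)
        mask = np.zeros((32, 32), dtype=np.uint8)
        mask[16, 16] = 1
        out, stats = inpaint(img, mask, return_stats=True)
        assert stats.fill_steps == 1
        assert (out[mask == 0] == img[mask == 0]).all()

    def test_straight_edge_continues_through_hole(self):
        img = np.zeros((32, 32, 3), dtype=np.uint8)
        img[:, :16] = 40
        img[:, 16:] = 200
        out = inpaint(img, square_mask(32, 12, 17, 13, 20))
        assert (out[12:17, 13:16] == 40).all()
        assert (out[12:17, 16:20] == 200).all()

    def test_mask_exactness_and_termination_bound(self, smooth_image):
        img = smooth_image(seed=8)
        mask = square_mask(32, 10, 18, 11, 21)
        out, stats = inpaint(img, mask, return_stats=True)
        assert (out[mask == 0] == img[mask == 0]).all()
        assert stats.fill_steps <= mask.sum()

    def test_far_apart_regions_commute(self, smooth_image):
        img = smooth_image(size=64, seed=9)
        m1 = np.zeros((64, 64), dtype=np.uint8)
        m1[5:9, 5:9] = 1
        m2 = np.zeros((64, 64), dtype=np.uint8)
        m2[52:56, 52:56] = 1
        params = InpaintParams(a=1000.0, n1=1, n2=1)  # disjoint windows
        both = inpaint(img, m1 | m2, params)
        seq12 = inpaint(inpaint(img, m1, params), m2, params)
        assert np.array_equal(both, seq12)

    def test_full_frame_mask_rejected(self):
        img = np.zeros((16, 16, 3), dtype=np.uint8)
        with pytest.raises(ValueError):
            inpaint(img, np.ones((16, 16), dtype=np.uint8))

    def test_too_small_image_rejected(self):
        img = np.zeros((8, 8, 3), dtype=np.uint8)
        with pytest.raises(ValueError):
            inpaint(img, np.zeros((8, 8), dtype=np.uint8))


class TestOracleEquivalence:
    def test_improved_with_global_settings_matches_criminisi(self, smooth_image):
        for seed in range(5):
            img = smooth_image(seed=100 + seed)
            rng = np.random.default_rng(seed)
            y, x = rng.integers(8, 18, 2)
            h, w = rng.integers(3, 8, 2)
            mask = square_mask(32, y, y + h, x, x + w)
            ref = inpaint(img, mask, InpaintParams(mode="criminisi"))
            forced = inpaint(
                img,
                mask,
                InpaintParams(force_full_window=True, force_priority="criminisi"),
            )
            assert np.array_equal(ref, forced)


class TestInpaintParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"patch_side": 8},
            {"w": 0.0},
            {"w": 1.0},
            {"beta": 0.0},
            {"n1": 5, "n2": 4},
            {"mode": "magic"},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            InpaintParams(**kwargs)
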