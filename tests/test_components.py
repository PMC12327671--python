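import numpy as np
import pytest

from hu2rgb.components import (
    ExtractionConfig,
    HemorrhageSweep,
    binarize,
    boundary_point_count,
    csf_region,
    extract_components,
    gray_matter_region,
    initial_hemorrhage_masks,
    matter_mask,
    select_hemorrhage_window,
    skull_mask,
    suspect_hemorrhage,
    white_matter_region,
)
from hu2rgb.windowing import WindowSetting

from .conftest import random_hu_grid


class TestBinarize:
    def test_strictly_greater(self):
        gray = np.array([[127, 128, 129, 130]], dtype=np.uint8)
        assert binarize(gray).tolist() == [[0, 0, 1, 1]]

    def test_all_zero(self):
        assert binarize(np.zeros((3, 3), dtype=np.uint8)).sum() == 0


class TestInitialMasks:
    def test_constant_slice_drops_out_with_level(self):
        hu = np.full((4, 4), 60.0)
        masks = initial_hemorrhage_masks(hu)
        for lvl, m in zip((30, 35, 40, 45, 50, 55, 60, 65, 70, 75), masks):
            expected = 1 if lvl <= 55 else 0  # sigmoid crosses 128 just above h=l
            assert (m == expected).all(), lvl

    def test_air_slice_all_empty(self):
        masks = initial_hemorrhage_masks(np.full((4, 4), -1000.0))
        assert all(m.sum() == 0 for m in masks)

    def test_masks_nonincreasing_in_level(self, rng):
        hu = random_hu_grid(rng)
        masks = initial_hemorrhage_masks(hu)
        for a, b in zip(masks, masks[1:]):
            assert (b <= a).all()

    def test_needs_two_levels(self):
        with pytest.raises(ValueError):
            initial_hemorrhage_masks(np.zeros((2, 2)), sweep_wl=[40.0])


class TestFixedWindows:
    def test_skull_mask_values(self):
        hu = np.array([[1000.0, 30.0, -1000.0]])
        assert skull_mask(hu).tolist() == [[1, 0, 0]]

    def test_matter_mask_values(self):
        hu = np.array([[60.0, 0.0, -1000.0]])
        assert matter_mask(hu).tolist() == [[1, 0, 0]]


class TestSuspectHemorrhage:
    @pytest.mark.parametrize(
        "k,h,p,expected",
        [
            (1, 1, 70.0, 0.0),  # skull overlap excluded
            (0, 1, 70.0, 70.0),  # plain in-window blood pixel
            (0, 1, 120.0, 0.0),  # above the 110 HU cap
            (1, 0, 100.0, 100.0),  # exclusive-difference admits K-only pixels
            (0, 0, 70.0, 0.0),
        ],
    )
    def test_pixel_table(self, k, h, p, expected):
        out = suspect_hemorrhage(
            np.array([[p]]), np.array([[h]]), np.array([[k]])
        )
        assert out[0, 0] == expected

    def test_strict_containment_drops_skull_only_pixels(self):
        out = suspect_hemorrhage(
            np.array([[100.0]]),
            np.array([[0]]),
            np.array([[1]]),
            strict_containment=True,
        )
        assert out[0, 0] == 0.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            suspect_hemorrhage(np.zeros((2, 2)), np.zeros((2, 3)), np.zeros((2, 2)))


class TestBoundaryPoints:
    def test_empty_region(self):
        assert boundary_point_count(np.zeros((5, 5))) == 0

    def test_single_pixel(self):
        r = np.zeros((5, 5))
        r[2, 2] = 50.0
        assert boundary_point_count(r) == 4

    def test_square_vertex_count(self):
        # 0.5-level trace of an n x n square has 4n vertices (frozen from a
        # manual trace of the tracer's output on the 10x10 case)
        r = np.zeros((20, 20))
        r[5:15, 5:15] = 60.0
        assert boundary_point_count(r) == 40

    def test_largest_component_only(self):
        r = np.zeros((30, 30))
        r[2:12, 2:12] = 60.0  # 100 px
        r[20:23, 20:23] = 60.0  # 9 px
        assert boundary_point_count(r) == 40

    def test_touching_border_still_closed(self):
        r = np.zeros((6, 6))
        r[0:6, 0:6] = 40.0
        assert boundary_point_count(r) == 24

    def test_morph_acwe_mode_runs(self):
        r = np.zeros((20, 20))
        r[5:15, 5:15] = 60.0
        assert boundary_point_count(r, "morph_acwe") > 0

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            boundary_point_count(np.ones((3, 3)), "snakes")


def _sweep(counts, regions=None):
    n = len(counts)
    if regions is None:
        regions = [np.full((4, 4), 50.0) for _ in range(n)]
    return HemorrhageSweep(
        settings=[WindowSetting(10.0, 30.0 + 5 * i) for i in range(n)],
        regions=regions,
        boundary_counts=list(counts),
    )


class TestWindowSelection:
    def test_largest_drop_selects_following_region(self):
        out = select_hemorrhage_window(_sweep([400, 390, 380, 120, 110]))
        assert out.selected_index == 3

    def test_no_positive_drop_means_no_hemorrhage(self):
        zero_regions = [np.zeros((4, 4)) for _ in range(4)]
        out = select_hemorrhage_window(_sweep([7, 7, 7, 7], zero_regions))
        assert out.selected_index is None
        assert out.min_hu is None
        assert out.hemorrhage_mask.sum() == 0

    def test_tie_broken_by_smallest_index(self):
        out = select_hemorrhage_window(_sweep([50, 10, 50, 45]))
        assert out.selected_index == 1

    def test_min_hu_over_positive_entries(self):
        regions = [np.zeros((2, 2)) for _ in range(3)]
        regions[1] = np.array([[0.0, 60.0], [45.0, 0.0]])
        out = select_hemorrhage_window(_sweep([100, 20, 10], regions))
        assert out.selected_index == 1
        assert out.min_hu == 45.0
        assert out.hemorrhage_mask.tolist() == [[0, 1], [1, 0]]

    def test_empty_selected_region_leaves_min_hu_undefined(self):
        zero_regions = [np.zeros((4, 4)) for _ in range(3)]
        out = select_hemorrhage_window(_sweep([100, 20, 10], zero_regions))
        assert out.selected_index == 1
        assert out.min_hu is None
        assert out.hemorrhage_mask.sum() == 0

    def test_sweep_needs_two_members(self):
        with pytest.raises(ValueError):
            _sweep([5])


class TestRegionEquations:
    @pytest.mark.parametrize(
        "m,hp,p,expected",
        [(1, 1, 10.0, 0.0), (1, 0, 10.0, 10.0), (1, 0, 20.0, 0.0), (0, 0, 10.0, 0.0)],
    )
    def test_csf_pixels(self, m, hp, p, expected):
        out = csf_region(np.array([[p]]), np.array([[m]]), np.array([[hp]]))
        assert out[0, 0] == expected

    @pytest.mark.parametrize(
        "p,expected",
        [(20.0, 20.0), (25.0, 0.0), (10.0, 0.0), (15.0, 15.0)],
    )
    def test_white_matter_band(self, p, expected):
        out = white_matter_region(
            np.array([[p]]), np.array([[1]]), np.array([[0]]), a=15.0, b=40.0
        )
        assert out[0, 0] == expected

    @pytest.mark.parametrize(
        "p,expected",
        [(25.0, 25.0), (20.0, 0.0), (45.0, 0.0), (40.0, 40.0)],
    )
    def test_gray_matter_band(self, p, expected):
        out = gray_matter_region(
            np.array([[p]]), np.array([[1]]), np.array([[0]]), b=40.0
        )
        assert out[0, 0] == expected

    def test_degenerate_band_empty(self):
        out = white_matter_region(
            np.array([[20.0]]), np.array([[1]]), np.array([[0]]), a=15.0, b=10.0
        )
        assert out[0, 0] == 0.0

    def test_wm_gm_supports_disjoint(self, rng):
        hu = random_hu_grid(rng)
        m = (rng.random(hu.shape) > 0.5).astype(np.uint8)
        hp = (rng.random(hu.shape) > 0.8).astype(np.uint8)
        wm = white_matter_region(hu, m, hp, b=60.0)
        gm = gray_matter_region(hu, m, hp, b=60.0)
        assert not np.any((wm != 0) & (gm != 0))


def naive_suspect(P, A, B, keep):
    """Per-pixel reference for the |A - B| * f(P) region equations."""
    out = np.zeros_like(P, dtype=float)
    for i in range(P.shape[0]):
        for j in range(P.shape[1]):
            if abs(int(A[i, j]) - int(B[i, j])) == 1 and keep(P[i, j]):
                out[i, j] = P[i, j]
    return out


class TestVectorizedAgainstNaive:
    def test_all_four_equations_match_loops(self, rng):
        # smaller sibling of the acceptance check; full 100-grid run there
        for _ in range(10):
            hu = random_hu_grid(rng, (16, 16))
            A = (rng.random(hu.shape) > 0.5).astype(np.uint8)
            B = (rng.random(hu.shape) > 0.5).astype(np.uint8)
            b = 40.0
            np.testing.assert_array_equal(
                suspect_hemorrhage(hu, A, B), naive_suspect(hu, B, A, lambda p: p <= 110)
            )
            np.testing.assert_array_equal(
                csf_region(hu, A, B), naive_suspect(hu, A, B, lambda p: p <= 15)
            )
            np.testing.assert_array_equal(
                white_matter_region(hu, A, B, 15.0, b),
                naive_suspect(hu, A, B, lambda p: 15 <= p <= b / 2),
            )
            np.testing.assert_array_equal(
                gray_matter_region(hu, A, B, b),
                naive_suspect(hu, A, B, lambda p: b / 2 < p <= b),
            )


class TestExtractComponents:
    def test_air_slice_everything_empty(self):
        comp = extract_components(np.full((16, 16), -1000.0))
        assert comp.sweep.selected_index is None
        for region in (comp.hemorrhage_mask, comp.csf, comp.white_matter,
                       comp.gray_matter, comp.skull, comp.matter):
            assert np.count_nonzero(region) == 0
        assert comp.b == 40.0  # fallback when no hemorrhage

    def test_deterministic(self, default_phantom):
        hu, _ = default_phantom
        a = extract_components(hu)
        b = extract_components(hu.copy())
        assert a.hemorrhage_mask.tobytes() == b.hemorrhage_mask.tobytes()
        assert a.sweep.boundary_counts == b.sweep.boundary_counts
        assert a.min_hu == b.min_hu

    def test_phantom_bleed_recovered(self, default_phantom):
        from hu2rgb.phantom import dice

        hu, truth = default_phantom
        comp = extract_components(hu)
        assert comp.sweep.selected_index is not None
        assert dice(comp.hemorrhage_mask, truth.bleed) >= 0.8

    def test_exclusion_where_masks_agree(self, default_phantom):
        # suspect entries vanish wherever K and H_l agree (both 0 or both 1)
        hu, _ = default_phantom
        comp = extract_components(hu)
        h_masks = initial_hemorrhage_masks(hu)
        for h_l, region in zip(h_masks, comp.sweep.regions):
            agree = comp.skull == h_l
            assert not np.any((region != 0) & agree)

    def test_hu_caps_respected(self, default_phantom):
        hu, _ = default_phantom
        comp = extract_components(hu)
        for region in comp.sweep.regions:
            nz = region[region != 0]
            assert nz.size == 0 or nz.max() <= 110.0
        nz = comp.csf[comp.csf != 0]
        assert nz.size == 0 or nz.max() <= 15.0
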