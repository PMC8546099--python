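import numpy as np
import pytest

import grainmorph as gm
from conftest import disk_mask, mask_from_bool, single_region, square_mask
from grainmorph.errors import GrainMorphError
from grainmorph.segmentation import (
    BinaryMask,
    ThresholdMode,
    ThresholdSpec,
    default_threshold_spec,
    extract_regions,
    gaussian_smooth,
    otsu_threshold,
    threshold,
    trace_boundary,
)


# ---------------------------------------------------------------------------
# Gaussian smoothing

def brute_force_gaussian(plane, ksize):
    """Direct 2-D convolution with the separable sampled Gaussian (oracle)."""
    sigma = 0.3 * ((ksize - 1) * 0.5 - 1) + 0.8
    x = np.arange(ksize) - (ksize - 1) / 2.0
    g = np.exp(-(x**2) / (2 * sigma**2))
    g /= g.sum()
    k2d = np.outer(g, g)
    pad = ksize // 2
    padded = np.pad(plane.astype(float), pad, mode="reflect")
    out = np.empty_like(plane, dtype=float)
    for r in range(plane.shape[0]):
        for c in range(plane.shape[1]):
            out[r, c] = (padded[r : r + ksize, c : c + ksize] * k2d).sum()
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


class TestGaussianSmooth:
    def test_constant_plane_unchanged(self):
        plane = np.full((20, 20), 40, np.uint8)
        np.testing.assert_array_equal(gaussian_smooth(plane, 5), plane)

    def test_single_peak_spread(self):
        plane = np.zeros((11, 11), np.uint8)
        plane[5, 5] = 255
        out = gaussian_smooth(plane, 5)
        assert out[5, 5] < 255
        assert out[5, 6] > 0 and out[4, 5] > 0

    @pytest.mark.parametrize("ksize", [3, 5, 7])
    def test_equals_direct_convolution(self, ksize):
        rng = np.random.default_rng(12)
        plane = rng.integers(0, 256, size=(16, 14), dtype=np.uint8)
        np.testing.assert_array_equal(
            gaussian_smooth(plane, ksize), brute_force_gaussian(plane, ksize)
        )

    def test_even_kernel_rejected(self):
        with pytest.raises(GrainMorphError):
            gaussian_smooth(np.zeros((5, 5), np.uint8), 4)


# ---------------------------------------------------------------------------
# thresholding

def otsu_oracle(plane):
    """Exhaustive between-class-variance maximization, plain loops."""
    vals = plane.ravel()
    n = len(vals)
    best_t, best_var = 0, -1.0
    for t in range(256):
        lo = vals[vals <= t]
        hi = vals[vals > t]
        if len(lo) == 0 or len(hi) == 0:
            continue
        w0, w1 = len(lo) / n, len(hi) / n
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


class TestThreshold:
    def test_strict_inequality(self):
        plane = np.array([[50, 37, 36]], dtype=np.uint8)
        _, mask = threshold(plane, ThresholdSpec(ThresholdMode.FIXED, thresh=37))
        np.testing.assert_array_equal(mask.values[0], [255, 0, 0])

    def test_otsu_separates_two_level_plane(self):
        rng = np.random.default_rng(3)
        plane = np.where(rng.random((50, 50)) < 0.4, 30, 200).astype(np.uint8)
        t, mask = threshold(plane, ThresholdSpec(ThresholdMode.OTSU))
        assert 30 <= t < 200
        np.testing.assert_array_equal(mask.bool_mask, plane == 200)

    @pytest.mark.parametrize("seed", range(8))
    def test_otsu_equals_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        # bimodal-ish planes of the kind scanner scenes produce
        plane = np.concatenate(
            [
                rng.normal(30, 12, size=400),
                rng.normal(150, 30, size=rng.integers(100, 600)),
            ]
        )
        plane = np.clip(np.rint(plane), 0, 255).astype(np.uint8).reshape(-1)
        side = int(len(plane) ** 0.5)
        plane = plane[: side * side].reshape(side, side)
        assert otsu_threshold(plane) == otsu_oracle(plane)

    def test_otsu_agrees_with_skimage_mask(self):
        from skimage.filters import threshold_otsu

        rng = np.random.default_rng(5)
        plane = np.where(rng.random((40, 40)) < 0.5, 20, 180).astype(np.uint8)
        _, mask = threshold(plane, ThresholdSpec(ThresholdMode.OTSU))
        t_sk = threshold_otsu(plane)
        # both conventions must split the two populations identically
        np.testing.assert_array_equal(mask.bool_mask, plane > t_sk)

    def test_mask_idempotence(self):
        rng = np.random.default_rng(9)
        plane = rng.integers(0, 256, size=(30, 30), dtype=np.uint8)
        _, mask = threshold(plane, ThresholdSpec(ThresholdMode.FIXED, thresh=90))
        _, again = threshold(mask.values, ThresholdSpec(ThresholdMode.FIXED, thresh=90))
        np.testing.assert_array_equal(mask.values, again.values)

    def test_fixed_requires_thresh(self):
        with pytest.raises(GrainMorphError):
            ThresholdSpec(ThresholdMode.FIXED)

    def test_class_defaults(self):
        assert default_threshold_spec("sound").mode is ThresholdMode.OTSU
        assert default_threshold_spec("damaged").thresh == 37
        assert default_threshold_spec("shriveled").thresh == 74
        assert default_threshold_spec("broken").thresh == 35


# ---------------------------------------------------------------------------
# contours and regions

class TestTraceBoundary:
    @pytest.mark.parametrize("mask_fn,arg", [(disk_mask, 12), (square_mask, 9)])
    def test_closed_adjacent_distinct(self, mask_fn, arg):
        pts = trace_boundary(mask_fn(arg))
        assert len(pts) == len({tuple(p) for p in pts})  # all distinct
        closed = np.vstack([pts, pts[:1]])
        steps = np.abs(np.diff(closed, axis=0))
        assert steps.max() <= 1  # consecutive points 8-adjacent, incl. closure

    def test_isolated_pixel(self):
        m = np.zeros((5, 5), bool)
        m[2, 3] = True
        pts = trace_boundary(m)
        assert pts.tolist() == [[2, 3]]


class TestExtractRegions:
    def test_two_squares(self):
        m = np.zeros((40, 40), bool)
        m[3:13, 4:14] = True
        m[22:32, 20:30] = True
        regions = extract_regions(mask_from_bool(m), 0)
        assert len(regions) == 2
        assert [r.bounding_rect[2:] for r in regions] == [(10, 10), (10, 10)]
        assert [r.area_px for r in regions] == [100, 100]
        # ordered top-to-bottom
        assert regions[0].bounding_rect[0] < regions[1].bounding_rect[0]

    def test_empty_mask_gives_empty_list(self):
        assert extract_regions(mask_from_bool(np.zeros((10, 10), bool)), 0) == []

    def test_min_area_filters_specks(self):
        m = np.zeros((30, 30), bool)
        m[2:4, 2:4] = True  # 4 px speck
        m[10:25, 10:25] = True
        regions = extract_regions(mask_from_bool(m), min_area_px2=20)
        assert len(regions) == 1
        assert regions[0].area_px == 225

    def test_disk_ellipse_fit_and_hull(self):
        region = single_region(disk_mask(20))
        M, m, _ = region.ellipse
        assert M == pytest.approx(m, rel=0.05)
        assert region.hull_area_px2 == pytest.approx(region.area_px, rel=0.02)
        assert region.hull_area_px2 >= region.area_px

    def test_component_conservation(self):
        rng = np.random.default_rng(21)
        m = rng.random((60, 60)) < 0.35
        bm = mask_from_bool(m)
        regions = extract_regions(bm, min_area_px2=0)
        assert sum(r.area_px for r in regions) == bm.foreground_count

    def test_hull_dominates_area_for_all_regions(self):
        rng = np.random.default_rng(8)
        m = rng.random((50, 50)) < 0.3
        for r in extract_regions(mask_from_bool(m), 0):
            assert r.hull_area_px2 >= r.area_px

    def test_noise_free_scene_recovers_truth_exactly(self):
        # direct fixed threshold on the raw green channel: region count and
        # every pixel area must equal the rendered ground truth
        scene = gm.sample_class_scene(
            "sound", 9, seed=13, rgb_noise_sd=0.0, boundary_irregularity=0.0
        )
        green = scene.image[:, :, 1]
        _, mask = threshold(green, ThresholdSpec(ThresholdMode.FIXED, thresh=40))
        regions = extract_regions(mask, 20)
        assert len(regions) == len(scene.truth)
        assert sorted(r.area_px for r in regions) == sorted(
            t.area_px for t in scene.truth
        )

    def test_ellipse_axes_recovered_within_tolerance(self):
        # fitted diameters track the generating axes within max(2 px, 3%)
        scene = gm.sample_class_scene(
            "sound", 9, seed=13, rgb_noise_sd=0.0, boundary_irregularity=0.0
        )
        green = scene.image[:, :, 1]
        _, mask = threshold(green, ThresholdSpec(ThresholdMode.FIXED, thresh=40))
        regions = extract_regions(mask, 20)
        truth_centers = np.array([t.spec.center for t in scene.truth])
        for r in regions:
            top, left, h, w = r.bounding_rect
            center = np.array([top + h / 2, left + w / 2])
            t = scene.truth[np.argmin(np.abs(truth_centers - center).sum(axis=1))]
            M, m, _ = r.ellipse
            true_M, true_m = t.spec.major_axis_px, t.spec.minor_axis_px
            assert abs(M - true_M) < max(2.0, 0.03 * true_M)
            assert abs(m - true_m) < max(2.0, 0.03 * true_m)


class TestBinaryMask:
    def test_rejects_third_value(self):
        with pytest.raises(GrainMorphError):
            BinaryMask(values=np.array([[0, 128, 255]], np.uint8))

    def test_foreground_count(self):
        bm = mask_from_bool(np.eye(5, dtype=bool))
        assert bm.foreground_count == 5
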