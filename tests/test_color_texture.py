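import colorsys
import math

import numpy as np
import pytest

import grainmorph as gm
from grainmorph.color_texture import (
    glcm,
    glcm_props,
    mean_channels,
    ndi,
    nearest_chart_color,
    read_chart_csv,
    rgb_to_hsv_means,
    write_chart_csv,
)
from grainmorph.errors import GrainMorphError
from grainmorph.synthetic import make_color_chart


def image_from_rgb(rgb):
    return gm.GrainImage(pixels=np.asarray(rgb, np.uint8)[:, :, ::-1].copy(), dpi=200)


class TestMeanChannels:
    def test_uniform_kernel(self):
        rgb = np.zeros((6, 6, 3), np.uint8)
        rgb[:] = (119, 104, 69)
        mask = np.ones((6, 6), bool)
        assert mean_channels(image_from_rgb(rgb), mask) == (119.0, 104.0, 69.0)

    def test_half_and_half(self):
        rgb = np.zeros((2, 2, 3), np.uint8)
        rgb[0] = (200, 100, 50)
        mask = np.ones((2, 2), bool)
        assert mean_channels(image_from_rgb(rgb), mask) == (100.0, 50.0, 25.0)

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(2)
        rgb = rng.integers(0, 256, size=(15, 12, 3), dtype=np.uint8)
        mask = rng.random((15, 12)) < 0.4
        mask[0, 0] = True
        got = mean_channels(image_from_rgb(rgb), mask)
        sums, n = [0.0, 0.0, 0.0], 0
        for r in range(15):
            for c in range(12):
                if mask[r, c]:
                    n += 1
                    for ch in range(3):
                        sums[ch] += rgb[r, c, ch]
        assert got == pytest.approx(tuple(s / n for s in sums))

    def test_empty_mask_rejected(self):
        with pytest.raises(GrainMorphError):
            mean_channels(image_from_rgb(np.zeros((3, 3, 3), np.uint8)),
                          np.zeros((3, 3), bool))


class TestNDI:
    @pytest.mark.parametrize(
        "rgb,expected_2dp",
        [
            ((119.79, 104.98, 69.62), (0.07, 0.26, 0.20)),  # sound channel means
            ((141.15, 117.19, 90.26), (0.09, 0.22, 0.13)),  # shriveled
            ((100.0, 100.0, 100.0), (0.0, 0.0, 0.0)),
        ],
    )
    def test_worked_examples(self, rgb, expected_2dp):
        got = ndi(*rgb)
        assert tuple(round(v, 2) for v in got) == expected_2dp

    def test_exchange_symmetry(self):
        rg, rb, gb = ndi(80.0, 120.0, 60.0)
        rg2, rb2, gb2 = ndi(120.0, 80.0, 60.0)
        assert rg == rg2

    def test_bounds(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            vals = rng.uniform(1, 255, 3)
            assert all(0.0 <= v <= 1.0 for v in ndi(*vals))

    def test_zero_denominator_rejected(self):
        with pytest.raises(GrainMorphError):
            ndi(0.0, 0.0, 10.0)


class TestHSV:
    def test_pure_red_anchor(self):
        rgb = np.zeros((2, 2, 3), np.uint8)
        rgb[..., 0] = 255
        h, s, v = rgb_to_hsv_means(image_from_rgb(rgb), np.ones((2, 2), bool))
        assert (h, s, v) == (0.0, 255.0, 255.0)

    def test_gray_pixels(self):
        rgb = np.full((3, 3, 3), 137, np.uint8)
        h, s, v = rgb_to_hsv_means(image_from_rgb(rgb), np.ones((3, 3), bool))
        assert s == 0.0 and v == 137.0

    def test_matches_colorsys_reference_loop(self):
        rng = np.random.default_rng(6)
        rgb = rng.integers(0, 256, size=(10, 9, 3), dtype=np.uint8)
        mask = rng.random((10, 9)) < 0.5
        mask[3, 3] = True
        got = rgb_to_hsv_means(image_from_rgb(rgb), mask)
        hs, ss, vs = [], [], []
        for r in range(10):
            for c in range(9):
                if mask[r, c]:
                    hh, ll_s, vv = colorsys.rgb_to_hsv(*(rgb[r, c] / 255.0))
                    hs.append(hh * 360.0 / 2.0)   # halved 8-bit hue
                    ss.append(ll_s * 255.0)
                    vs.append(vv * 255.0)
        assert got == pytest.approx((np.mean(hs), np.mean(ss), np.mean(vs)), abs=1e-9)


class TestNearestChartColor:
    def test_dark_query(self):
        chart = [("A", (0, 0, 0)), ("B", (255, 255, 255))]
        code, dist = nearest_chart_color((10, 10, 10), chart)
        assert code == "A"

    def test_exact_match_distance_zero(self):
        chart = make_color_chart(20, seed=3)
        code, rgb = chart[7]
        got_code, dist = nearest_chart_color(rgb, chart)
        assert got_code == code and dist == 0.0

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(9)
        chart = make_color_chart(500, seed=1)
        for _ in range(100):
            q = rng.uniform(0, 255, 3)
            best = min(
                range(len(chart)),
                key=lambda i: sum((float(a) - b) ** 2 for a, b in zip(chart[i][1], q)),
            )
            code, dist = nearest_chart_color(q, chart)
            assert code == chart[best][0]

    def test_empty_chart_rejected(self):
        with pytest.raises(GrainMorphError):
            nearest_chart_color((1, 2, 3), [])

    def test_chart_csv_round_trip(self, tmp_path):
        chart = make_color_chart(12, seed=5)
        write_chart_csv(chart, tmp_path / "chart.csv")
        assert read_chart_csv(tmp_path / "chart.csv") == chart


def glcm_oracle(img, mask, dr, dc, levels):
    """Brute-force pair counting (double loop)."""
    h, w = img.shape
    P = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                if mask is None or (mask[r, c] and mask[r2, c2]):
                    P[img[r, c], img[r2, c2]] += 1
    s = P.sum()
    return P / s if s else P


class TestGLCM:
    def test_constant_image_single_cell(self):
        img = np.full((5, 5), 3, np.uint8)
        g = glcm(img, d=1, theta=0.0, levels=8)
        assert g.P[3, 3] == 1.0
        assert g.P.sum() == 1.0

    def test_two_column_hand_enumeration(self):
        img = np.array([[0, 1], [0, 1]], np.uint8)
        g = glcm(img, d=1, theta=0.0, levels=2)
        assert g.P[0, 1] == 1.0
        assert g.P[0, 0] == g.P[1, 0] == g.P[1, 1] == 0.0

    @pytest.mark.parametrize("theta", [0.0, math.pi / 4, math.pi / 2, 3 * math.pi / 4])
    @pytest.mark.parametrize("masked", [False, True])
    def test_matches_brute_force(self, theta, masked):
        rng = np.random.default_rng(31)
        for _ in range(5):
            img = rng.integers(0, 16, size=(12, 11), dtype=np.uint8)
            mask = (rng.random((12, 11)) < 0.6) if masked else None
            if mask is not None:
                mask[5, 5] = True
            dr = round(math.sin(theta))
            dc = round(math.cos(theta))
            got = glcm(img, mask=mask, d=1, theta=theta, levels=16).P
            np.testing.assert_allclose(got, glcm_oracle(img, mask, dr, dc, 16))

    def test_matches_skimage_unmasked(self):
        from skimage.feature import graycomatrix

        rng = np.random.default_rng(7)
        img = rng.integers(0, 32, size=(20, 18), dtype=np.uint8)
        for theta in (0.0, math.pi / 2):
            for sym in (False, True):
                ref = graycomatrix(img, [1], [theta], levels=32,
                                   symmetric=sym, normed=True)[:, :, 0, 0]
                got = glcm(img, d=1, theta=theta, levels=32, symmetric=sym).P
                np.testing.assert_allclose(got, ref)

    def test_symmetric_matrix_is_symmetric(self):
        rng = np.random.default_rng(8)
        img = rng.integers(0, 8, size=(9, 9), dtype=np.uint8)
        g = glcm(img, d=1, theta=0.0, levels=8, symmetric=True)
        np.testing.assert_allclose(g.P, g.P.T)

    def test_normalization_tight(self):
        rng = np.random.default_rng(10)
        img = rng.integers(0, 64, size=(30, 30), dtype=np.uint8)
        g = glcm(img, d=1, theta=0.0, levels=64)
        assert abs(g.P.sum() - 1.0) < 1e-12

    def test_offset_larger_than_image_rejected(self):
        with pytest.raises(GrainMorphError):
            glcm(np.zeros((2, 2), np.uint8), d=5, theta=0.0, levels=4)

    def test_values_above_levels_rejected(self):
        with pytest.raises(GrainMorphError):
            glcm(np.full((4, 4), 40, np.uint8), levels=16)


class TestGLCMProps:
    def test_constant_image_limits(self):
        g = glcm(np.full((6, 6), 9, np.uint8), d=1, theta=0.0, levels=16)
        t = glcm_props(g)
        assert t.contrast == 0.0
        assert t.dissimilarity == 0.0
        assert t.homogeneity == 1.0
        assert t.asm == 1.0 and t.energy == 1.0
        assert t.correlation == 1.0  # zero-variance convention

    def test_single_offdiagonal_cell(self):
        g = glcm(np.array([[0, 1], [0, 1]], np.uint8), d=1, theta=0.0, levels=2)
        t = glcm_props(g)
        assert t.contrast == 1.0
        assert t.dissimilarity == 1.0
        assert t.homogeneity == 0.5
        assert t.asm == 1.0 and t.energy == 1.0

    def test_stripes_anticorrelated(self):
        img = np.tile(np.array([0, 255], np.uint8), (8, 4))
        t = glcm_props(glcm(img, d=1, theta=0.0, levels=256))
        assert t.correlation == pytest.approx(-1.0, abs=1e-9)

    def test_energy_squared_is_asm(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            img = rng.integers(0, 16, size=(10, 10), dtype=np.uint8)
            t = glcm_props(glcm(img, d=1, theta=0.0, levels=16))
            assert t.energy**2 == pytest.approx(t.asm, rel=1e-12)
            assert -1.0 <= t.correlation <= 1.0

    def test_matches_skimage_props(self):
        from skimage.feature import graycomatrix, graycoprops

        rng = np.random.default_rng(13)
        img = rng.integers(0, 16, size=(14, 14), dtype=np.uint8)
        ref = graycomatrix(img, [1], [0.0], levels=16, normed=True)
        t = glcm_props(glcm(img, d=1, theta=0.0, levels=16))
        for name, val in (
            ("contrast", t.contrast), ("dissimilarity", t.dissimilarity),
            ("homogeneity", t.homogeneity), ("ASM", t.asm),
            ("energy", t.energy), ("correlation", t.correlation),
        ):
            assert val == pytest.approx(float(graycoprops(ref, name)[0, 0]), rel=1e-9)

    def test_unnormalized_rejected(self):
        g = glcm(np.array([[0, 1], [0, 1]], np.uint8), d=1, theta=0.0,
                 levels=2, normed=False)
        with pytest.raises(GrainMorphError):
            glcm_props(g)
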