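"""Metric correctness: DSC, voxel-set ASD/ASSD, contour bands, CDSC, Pearson.

Distance metrics and bands are validated against brute-force all-pairs /
per-pixel oracles on random small masks.
"""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from ctvseg.metrics import (asd, assd, cdsc, contour_band, dsc,
                            metric_time_correlation)

from conftest import random_mask


def brute_force_asd(p, g, spacing):
    fp = np.argwhere(p > 0) * np.asarray(spacing)
    fg = np.argwhere(g > 0) * np.asarray(spacing)
    return cdist(fp, fg).min(axis=1).mean()


def brute_force_band(mask2d, thickness, spacing):
    """Per-pixel check: distance to background pixels or outside the slice."""
    ny, nx = mask2d.shape
    dy, dx = spacing
    bg = [(i * dy, j * dx) for i in range(-1, ny + 1) for j in range(-1, nx + 1)
          if not (0 <= i < ny and 0 <= j < nx) or mask2d[i, j] == 0]
    bg = np.asarray(bg)
    out = np.zeros_like(mask2d, dtype=bool)
    for i in range(ny):
        for j in range(nx):
            if mask2d[i, j]:
                d = np.sqrt(((bg - (i * dy, j * dx)) ** 2).sum(axis=1)).min()
                out[i, j] = d <= thickness
    return out


class TestDsc:
    def test_identity(self):
        m = np.zeros((2, 4, 4), np.uint8)
        m[1, 1:3, 1:3] = 1
        assert dsc(m, m) == 1.0

    def test_disjoint(self):
        p = np.zeros((1, 4, 4), np.uint8)
        g = np.zeros((1, 4, 4), np.uint8)
        p[0, 0, 0] = 1
        g[0, 3, 3] = 1
        assert dsc(p, g) == 0.0

    def test_half_overlap(self):
        p = np.zeros((1, 4, 4), np.uint8)
        g = np.zeros((1, 4, 4), np.uint8)
        p[0, 0, 0:4] = 1
        g[0, 0, 2:4] = 1
        g[0, 1, 0:2] = 1
        assert dsc(p, g) == 0.5  # |P|=|G|=4, overlap 2

    def test_empty_conventions(self):
        e = np.zeros((1, 2, 2), np.uint8)
        f = np.ones((1, 2, 2), np.uint8)
        assert dsc(e, e) == 1.0
        assert dsc(e, f) == 0.0

    def test_flip_invariance(self):
        rng = np.random.default_rng(0)
        p, g = random_mask(rng, (3, 5, 5)), random_mask(rng, (3, 5, 5))
        assert dsc(p, g) == dsc(p[::-1], g[::-1])


class TestAsd:
    def test_zero_self_distance(self):
        m = random_mask(np.random.default_rng(1), (3, 4, 4))
        assert asd(m, m, (1, 1, 1)) == 0.0

    def test_single_pair(self):
        p = np.zeros((1, 1, 5), np.uint8)
        g = np.zeros((1, 1, 5), np.uint8)
        p[0, 0, 0] = 1
        g[0, 0, 3] = 1
        assert asd(p, g, (1, 1, 1)) == pytest.approx(3.0)

    def test_slice_axis_spacing(self):
        p = np.zeros((2, 1, 1), np.uint8)
        g = np.zeros((2, 1, 1), np.uint8)
        p[1] = 1
        g[0] = 1
        assert asd(p, g, (5, 1, 1)) == pytest.approx(5.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="undefined for empty"):
            asd(np.zeros((2, 2, 2)), np.ones((2, 2, 2)), (1, 1, 1))

    @pytest.mark.parametrize("spacing", [(1, 1, 1), (5, 1, 1), (2, 0.7, 1.1)])
    def test_matches_brute_force(self, spacing):
        rng = np.random.default_rng(11)
        for _ in range(25):
            shape = tuple(rng.integers(2, 9, size=3))
            p, g = random_mask(rng, shape, 0.2), random_mask(rng, shape, 0.2)
            np.testing.assert_allclose(asd(p, g, spacing),
                                       brute_force_asd(p, g, spacing),
                                       atol=1e-9)

    def test_assd_symmetry_and_value(self):
        p = np.zeros((1, 1, 4), np.uint8)
        g = np.zeros((1, 1, 4), np.uint8)
        p[0, 0, 0] = 1
        g[0, 0, 3] = 1
        assert assd(p, g, (1, 1, 1)) == pytest.approx(3.0)
        rng = np.random.default_rng(2)
        a, b = random_mask(rng, (3, 5, 5)), random_mask(rng, (3, 5, 5))
        assert assd(a, b, (2, 1, 1)) == pytest.approx(assd(b, a, (2, 1, 1)))

    def test_voxel_set_vs_surface_variant_differ_on_nested_masks(self):
        # a filled cube inside a bigger cube: voxel-set ASD(G,P) averages
        # over interior voxels too, surface ASD does not
        g = np.zeros((7, 9, 9), np.uint8)
        g[1:6, 1:8, 1:8] = 1
        p = np.zeros_like(g)
        p[2:5, 2:7, 2:7] = 1
        assert asd(g, p, (1, 1, 1)) != asd(g, p, (1, 1, 1), surface=True)
        # single-voxel masks: both variants coincide
        a = np.zeros((3, 3, 3), np.uint8)
        b = np.zeros((3, 3, 3), np.uint8)
        a[0, 0, 0] = 1
        b[2, 2, 1] = 1
        assert asd(a, b, (1, 1, 1)) == asd(a, b, (1, 1, 1), surface=True)


class TestContourBand:
    def test_filled_square_band(self):
        m = np.zeros((15, 15), np.uint8)
        m[2:13, 2:13] = 1
        band = contour_band(m, 2.0, (1, 1))
        assert band.sum() == 11 ** 2 - 7 ** 2  # 72

    def test_full_slice_large_thickness_keeps_all(self):
        m = np.ones((11, 11), np.uint8)
        band = contour_band(m, 8.0, (1, 1))  # >= half-diagonal
        assert band.sum() == m.sum()

    def test_thin_line_fully_banded(self):
        m = np.zeros((9, 9), np.uint8)
        m[4, 1:8] = 1
        band = contour_band(m, 1.0, (1, 1))
        np.testing.assert_array_equal(band, m.astype(bool))

    def test_empty_slice(self):
        assert contour_band(np.zeros((5, 5), np.uint8), 2.0).sum() == 0

    @pytest.mark.parametrize("spacing", [(1, 1), (0.7, 1.3)])
    def test_matches_per_pixel_brute_force(self, spacing):
        rng = np.random.default_rng(3)
        for _ in range(15):
            shape = tuple(rng.integers(3, 13, size=2))
            m = (rng.random(shape) < 0.5).astype(np.uint8)
            for t in (1.0, 2.0, 3.5):
                np.testing.assert_array_equal(
                    contour_band(m, t, spacing),
                    brute_force_band(m, t, spacing))


class TestCdsc:
    def test_identity_any_thickness(self):
        rng = np.random.default_rng(4)
        m = np.zeros((3, 12, 12), np.uint8)
        m[1, 3:9, 3:9] = 1
        m[2, 2:10, 4:8] = 1
        for t in (1, 2, 5, 9):
            assert cdsc(m, m, t, (5, 1, 1)) == 1.0

    def test_disjoint_single_slice(self):
        p = np.zeros((1, 8, 8), np.uint8)
        g = np.zeros((1, 8, 8), np.uint8)
        p[0, 0:2, 0:2] = 1
        g[0, 5:7, 5:7] = 1
        assert cdsc(p, g, 2.0, (1, 1, 1)) == 0.0

    def test_offset_squares_match_brute_force(self):
        p = np.zeros((1, 16, 16), np.uint8)
        g = np.zeros((1, 16, 16), np.uint8)
        p[0, 2:13, 2:13] = 1
        g[0, 2:13, 3:14] = 1  # same square shifted one pixel
        bp = brute_force_band(p[0], 2.0, (1, 1))
        bg = brute_force_band(g[0], 2.0, (1, 1))
        expected = 2 * (bp & bg).sum() / (bp.sum() + bg.sum())
        assert cdsc(p, g, 2.0, (1, 1, 1)) == pytest.approx(expected)

    def test_one_sided_empty_slice_scores_zero(self):
        p = np.zeros((2, 6, 6), np.uint8)
        g = np.zeros((2, 6, 6), np.uint8)
        p[0, 2:4, 2:4] = 1
        g[0, 2:4, 2:4] = 1
        g[1, 2:4, 2:4] = 1  # slice 1 empty in p only
        assert cdsc(p, g, 2.0, (1, 1, 1)) == pytest.approx(0.5)

    def test_large_thickness_limit_is_mean_slice_dice(self):
        rng = np.random.default_rng(5)
        p = np.zeros((4, 10, 10), np.uint8)
        g = np.zeros((4, 10, 10), np.uint8)
        for k in range(1, 4):
            p[k] = random_mask(rng, (10, 10), 0.3)
            g[k] = random_mask(rng, (10, 10), 0.3)
        t = 1000.0
        per_slice = [dsc(p[k][None], g[k][None]) for k in range(1, 4)]
        assert cdsc(p, g, t, (1, 1, 1)) == pytest.approx(np.mean(per_slice))

    def test_all_empty_rejected(self):
        with pytest.raises(ValueError, match="CDSC undefined"):
            cdsc(np.zeros((2, 4, 4)), np.zeros((2, 4, 4)), 2.0, (1, 1, 1))


class TestPearson:
    def test_perfect_linear(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert metric_time_correlation(x, [2 * v + 1 for v in x]) == pytest.approx(1.0)
        assert metric_time_correlation(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_five_point_table_closed_form(self):
        x = np.array([0.80, 0.85, 0.87, 0.90, 0.95])
        y = np.array([5.0, 4.0, 4.5, 2.0, 1.0])
        n = len(x)
        r = ((n * (x * y).sum() - x.sum() * y.sum())
             / np.sqrt(n * (x ** 2).sum() - x.sum() ** 2)
             / np.sqrt(n * (y ** 2).sum() - y.sum() ** 2))
        assert metric_time_correlation(x, y) == pytest.approx(r)

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            metric_time_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            metric_time_correlation([1.0, 2.0], [1.0, 2.0])
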