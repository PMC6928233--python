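import math

import numpy as np
import pytest

import rootpheno as rp
from rootpheno.skeleton import Skeleton
from conftest import random_blob_mask

SQRT2 = math.sqrt(2.0)


def brute_force_edt(mask):
    """O(n^2) nearest-background search, the oracle for the distance map."""
    out = np.zeros(mask.shape)
    bg = np.argwhere(~mask)
    for r, c in np.argwhere(mask):
        out[r, c] = np.sqrt(((bg - (r, c)) ** 2).sum(axis=1)).min()
    return out


def brute_force_degrees(mask):
    deg = np.zeros(mask.shape, int)
    H, W = mask.shape
    for r, c in np.argwhere(mask):
        n = 0
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < H and 0 <= cc < W and mask[rr, cc]:
                    n += 1
        deg[r, c] = n
    return deg


class TestSkeletonize:
    def test_wide_bar_thins_to_centered_line(self):
        m = np.zeros((21, 120), bool)
        m[8:13, 10:110] = True
        skel = rp.skeletonize(m)
        deg = skel.degree_image()
        # interior of the medial line is a simple path at the bar's center row
        assert skel.mask[10, 30:90].all()
        assert np.all(deg[skel.mask & (np.arange(120)[None, :] > 20)
                          & (np.arange(120)[None, :] < 100)] == 2)

    def test_small_square_collapses_to_degenerate_skeleton(self):
        # thinning tie-breaks leave 1-2 pixels for a 3x3 square; what is
        # guaranteed is a tiny skeleton fully inside the shape with no branches
        m = np.zeros((9, 9), bool)
        m[3:6, 3:6] = True
        skel = rp.skeletonize(m)
        assert 1 <= skel.n_pixels <= 2
        assert not (skel.mask & ~m).any()
        assert skel.degree_image().max() <= 1

    def test_skeleton_inside_mask_and_thin(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            m = random_blob_mask(rng, shape=(48, 48), n_blobs=4, radius_range=(3, 9))
            skel = rp.skeletonize(m)
            assert not (skel.mask & ~m).any()
            s = skel.mask
            # thinness: no 2x2 block fully on the skeleton
            assert not (s[:-1, :-1] & s[1:, :-1] & s[:-1, 1:] & s[1:, 1:]).any()

    def test_erosion_shrinks_before_thinning(self):
        m = np.zeros((30, 30), bool)
        m[5:25, 5:25] = True
        assert rp.skeletonize(m, erode_iterations=2).n_pixels <= rp.skeletonize(m).n_pixels


class TestDistanceMap:
    def test_all_background_is_zero(self):
        assert np.all(rp.distance_map(np.zeros((6, 6), bool)) == 0)

    def test_bar_centerline_distance(self):
        m = np.zeros((20, 60), bool)
        m[6:13, :] = True
        dm = rp.distance_map(m)
        assert dm[9, 30] == 4.0  # width-7 bar: 4 px to the nearest background center

    def test_single_pixel_distance_one(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        assert rp.distance_map(m)[2, 2] == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = random_blob_mask(rng, shape=(32, 32), n_blobs=3)
        if not m.any() or m.all():
            pytest.skip("degenerate random mask")
        assert np.allclose(rp.distance_map(m), brute_force_edt(m))

    def test_lipschitz(self, rng):
        m = random_blob_mask(rng, shape=(40, 40), n_blobs=4)
        dm = rp.distance_map(m)
        assert np.all(np.abs(np.diff(dm, axis=0)) <= 1.0 + 1e-9)
        assert np.all(np.abs(dm[1:, 1:] - dm[:-1, :-1]) <= SQRT2 + 1e-9)


class TestWidth:
    def test_bar_width_is_twice_distance(self):
        m = np.zeros((21, 120), bool)
        m[7:14, 10:110] = True
        skel = rp.skeletonize(m)
        widths = rp.width_along_skeleton(skel, rp.distance_map(m))
        coords = skel.coords
        mid = (coords[:, 1] > 30) & (coords[:, 1] < 90)
        assert np.allclose(widths[mid], 8.0)
        # constant along the interior of a constant-width bar
        assert widths[mid].std() == 0.0

    def test_skeleton_outside_mask_rejected(self):
        m = np.zeros((10, 10), bool)
        m[4, 4] = True
        skel = Skeleton(m)
        with pytest.raises(ValueError):
            rp.width_along_skeleton(skel, np.zeros((10, 10)))


class TestBranchEndPoints:
    def test_straight_line(self):
        m = np.zeros((5, 30), bool)
        m[2, 3:27] = True
        branch, end = rp.detect_branch_end_points(Skeleton(m))
        assert branch.shape[0] == 0
        assert end.shape[0] == 2

    def test_y_shape(self):
        m = np.zeros((30, 30), bool)
        m[15, 5:16] = True          # stem
        for i in range(1, 10):       # two diagonal arms
            m[15 - i, 15 + i] = True
            m[15 + i, 15 + i] = True
        branch, end = rp.detect_branch_end_points(Skeleton(m))
        assert branch.shape[0] == 1
        assert end.shape[0] == 3

    def test_closed_loop(self):
        from skimage.draw import circle_perimeter

        m = np.zeros((40, 40), bool)
        rr, cc = circle_perimeter(20, 20, 12)
        m[rr, cc] = True
        skel = rp.skeletonize(m)  # re-thin: perimeter rasters can be 2 px thick
        branch, end = rp.detect_branch_end_points(skel)
        assert end.shape[0] == 0
        assert branch.shape[0] == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_degrees_agree_with_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        m = random_blob_mask(rng, shape=(40, 40), n_blobs=4)
        skel = rp.skeletonize(m)
        deg = skel.degree_image()
        assert np.array_equal(deg, brute_force_degrees(skel.mask))
        _, end = rp.detect_branch_end_points(skel)
        assert end.shape[0] == int((deg == 1).sum())


class TestSkeletonLength:
    def test_horizontal_line(self):
        m = np.zeros((5, 110), bool)
        m[2, 3:104] = True  # 101 pixels
        assert rp.skeleton_length(Skeleton(m)) == pytest.approx(100.0)

    def test_diagonal_line(self):
        m = np.zeros((110, 110), bool)
        for i in range(101):
            m[i + 3, i + 3] = True
        assert rp.skeleton_length(Skeleton(m)) == pytest.approx(100 * SQRT2)

    def test_corner_not_double_counted(self):
        # L-corner: 3 pixels; path length is 2 (two unit edges), and the
        # diagonal shortcut between the arm tips must be dropped
        m = np.zeros((5, 5), bool)
        m[2, 2] = m[2, 3] = m[3, 2] = True
        assert rp.skeleton_length(Skeleton(m)) == pytest.approx(2.0)

    def test_circle_length_tracks_circumference(self):
        """Digital-circle length vs 2*pi*r: the unit/sqrt(2) edge weighting
        overestimates oblique digital curves by up to ~6%, its known bias."""
        from skimage.draw import disk

        m = np.zeros((121, 121), bool)
        rr, cc = disk((60, 60), 54)
        m[rr, cc] = True
        rr, cc = disk((60, 60), 46)
        m[rr, cc] = False
        length = rp.skeleton_length(rp.skeletonize(m))
        assert abs(length / (2 * math.pi * 50) - 1) < 0.06


class TestLocalOrientation:
    def test_horizontal_skeleton(self):
        m = np.zeros((9, 40), bool)
        m[4, 2:38] = True
        om = rp.local_orientation(Skeleton(m))
        assert om.valid[4, 20]
        assert om.angle[4, 20] == pytest.approx(0.0)
        assert om.r_squared[4, 20] == pytest.approx(1.0)

    def test_diagonal_skeleton(self):
        m = np.zeros((40, 40), bool)
        for i in range(30):
            m[i + 5, i + 5] = True
        om = rp.local_orientation(Skeleton(m))
        assert om.valid[20, 20]
        assert om.angle[20, 20] == pytest.approx(45.0, abs=0.5)

    def test_vertical_skeleton_and_axis_switch(self):
        m = np.zeros((40, 9), bool)
        m[2:38, 4] = True
        om_h = rp.local_orientation(Skeleton(m), axis="horizontal")
        om_v = rp.local_orientation(Skeleton(m), axis="vertical")
        assert om_h.angle[20, 4] == pytest.approx(90.0)
        assert om_v.angle[20, 4] == pytest.approx(0.0)

    def test_junction_fails_validity_gate(self):
        m = np.zeros((31, 31), bool)
        m[15, 3:28] = True
        m[15:28, 15] = True
        om = rp.local_orientation(Skeleton(m))
        assert not om.valid[15, 15]
        assert om.r_squared[15, 15] <= 0.5

    def test_sparse_window_invalid(self):
        m = np.zeros((31, 31), bool)
        m[15, 15] = True  # single isolated pixel: < 3 supports
        om = rp.local_orientation(Skeleton(m))
        assert not om.valid[15, 15]

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            rp.local_orientation(Skeleton(np.zeros((5, 5), bool)), window=8)
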