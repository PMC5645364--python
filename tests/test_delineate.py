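import math

import numpy as np
import pytest

from comonod.contrast import BinaryMask
from comonod.delineate import (
    DistanceMap,
    PeakSet,
    convex_hulls,
    delineate_mask,
    distance_map,
    fit_ellipse,
    fuse_small_blobs,
    local_maxima,
    split_blobs,
    suppress_peaks,
)


def mask_of(arr, res=1.0):
    return BinaryMask(np.asarray(arr, bool), res, threshold_used=0)


def disc_mask(h, w, discs, res=1.0):
    yy, xx = np.mgrid[0:h, 0:w]
    m = np.zeros((h, w), bool)
    for cy, cx, r in discs:
        m |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    return mask_of(m, res)


def brute_edt(m):
    """O(n^2) nearest-background scan."""
    h, w = m.shape
    bg = np.argwhere(~m)
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            if m[i, j]:
                d = np.sqrt(((bg - (i, j)) ** 2).sum(axis=1)).min()
                out[i, j] = d
    return out


class TestDistanceMap:
    def test_single_pixel(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        d = distance_map(mask_of(m)).values
        assert d[2, 2] == 1.0
        assert d.sum() == 1.0

    def test_stripe_centreline(self):
        m = np.zeros((9, 20), bool)
        m[:, 5:10] = True  # 5 px wide stripe, background columns 4 and 10
        d = distance_map(mask_of(m)).values
        assert np.all(d[:, 7] == 3.0)

    def test_matches_brute_force(self, rng):
        m = rng.random((12, 12)) < 0.5
        m[0, 0] = False  # guarantee some background
        d = distance_map(mask_of(m)).values
        assert np.allclose(d, brute_edt(m))

    def test_all_foreground_uses_border(self):
        m = np.ones((5, 7), bool)
        d = distance_map(mask_of(m)).values
        assert d[0, 0] == 1.0
        assert d[2, 3] == 3.0  # centre of the 5-row image

    def test_zero_on_background(self, rng):
        m = rng.random((10, 10)) < 0.4
        d = distance_map(mask_of(m)).values
        assert np.all(d[~m] == 0)
        if m.any():
            assert np.all(d[m] > 0)


class TestLocalMaxima:
    def test_single_disc_single_peak(self):
        mask = disc_mask(40, 40, [(20, 20, 10)])
        d = distance_map(mask)
        peaks = local_maxima(d)
        assert len(peaks) == 1
        r, c, h = peaks.peaks[0]
        assert abs(r - 20) <= 1 and abs(c - 20) <= 1
        assert h == pytest.approx(d.values[r, c])

    def test_dumbbell_two_peaks(self):
        # two overlapping discs: the waist is a saddle, not a maximum
        mask = disc_mask(40, 60, [(20, 20, 9), (20, 34, 9)])
        peaks = local_maxima(distance_map(mask))
        assert len(peaks) == 2

    def test_plateau_single_representative(self):
        m = np.zeros((7, 11), bool)
        m[2:5, :] = True  # flat-top ridge: constant distance along the row
        peaks = local_maxima(distance_map(mask_of(m)))
        assert len(peaks) == 1
        assert peaks.peaks[0][0] == 3  # topmost-leftmost of the plateau


def greedy_oracle(peaks, radius):
    kept = []
    for r, c, h in sorted(peaks, key=lambda p: (-p[2], p[0], p[1])):
        if all(math.hypot(r - kr, c - kc) > radius for kr, kc, _ in kept):
            kept.append((r, c, h))
    return kept


class TestSuppressPeaks:
    def test_close_pair_keeps_highest(self):
        ps = PeakSet([(10, 10, 7.0), (10, 13, 4.0)])
        out = suppress_peaks(ps, theta_r=1)
        assert out.peaks == [(10, 10, 7.0)]

    def test_boundary_is_strict(self):
        ps = PeakSet([(10, 10, 7.0), (10, 16, 4.0)])  # 6 px apart, radius 5
        out = suppress_peaks(ps, theta_r=1)
        assert len(out) == 2

    def test_matches_greedy_oracle(self, rng):
        pts = [(int(r), int(c), float(h))
               for r, c, h in zip(rng.integers(0, 60, 50),
                                  rng.integers(0, 60, 50),
                                  rng.uniform(2.0, 9.0, 50))]
        out = suppress_peaks(PeakSet(pts), theta_r=2)
        assert out.peaks == greedy_oracle(pts, 10.0)

    def test_subminimal_peaks_dropped(self):
        """A candidate whose inscribed radius is below the minimum nodule
        radius theta_r cannot be a nodule centre."""
        ps = PeakSet([(5, 5, 1.4), (30, 30, 6.0)])
        out = suppress_peaks(ps, theta_r=2)
        assert out.peaks == [(30, 30, 6.0)]


class TestSplitBlobs:
    def test_two_touching_discs_cut_at_neck(self):
        mask = disc_mask(50, 90, [(25, 30, 12), (25, 52, 12)])
        d = distance_map(mask)
        peaks = suppress_peaks(local_maxima(d), theta_r=2)
        assert len(peaks) == 2
        labels = split_blobs(mask, peaks, d)
        assert set(np.unique(labels)) == {0, 1, 2}
        # the cut should fall near the geometric neck at x ~ 41
        cut_cols = [np.abs(np.diff((labels[r] > 0) * labels[r])).argmax()
                    for r in (24, 25, 26)]
        boundary_cols = np.nonzero(
            (labels[25, :-1] != labels[25, 1:]) &
            (labels[25, :-1] > 0) & (labels[25, 1:] > 0)
        )[0]
        assert len(boundary_cols) > 0
        assert abs(boundary_cols[0] - 41) <= 2

    def test_single_peak_single_label(self):
        mask = disc_mask(30, 30, [(15, 15, 8)])
        d = distance_map(mask)
        peaks = suppress_peaks(local_maxima(d), theta_r=2)
        labels = split_blobs(mask, peaks, d)
        assert np.array_equal(labels > 0, mask.pixels)
        assert np.unique(labels[mask.pixels]).tolist() == [1]

    def test_blob_without_peak_left_unlabeled(self):
        mask = disc_mask(30, 60, [(15, 15, 8), (15, 45, 8)])
        d = distance_map(mask)
        peaks = PeakSet([(15, 15, float(d.values[15, 15]))])  # only one blob
        labels = split_blobs(mask, peaks, d)
        assert labels[15, 45] == 0

    def test_label_conservation(self, rng):
        mask = disc_mask(60, 60, [(15, 15, 8), (40, 40, 9), (15, 45, 7)])
        d = distance_map(mask)
        peaks = suppress_peaks(local_maxima(d), theta_r=2)
        labels = split_blobs(mask, peaks, d)
        assert len(np.unique(labels)) - 1 == len(peaks)


class TestFuseSmallBlobs:
    def make_labels(self, blobs, shape=(40, 60)):
        lab = np.zeros(shape, np.int32)
        for i, (r0, r1, c0, c1) in enumerate(blobs, start=1):
            lab[r0:r1, c0:c1] = i
        return lab

    def test_small_blob_fused_with_near_neighbour(self):
        # theta_r=3: cutoff pi*9 ~ 28.27 px.  20 px blob 4 px from a large one.
        lab = self.make_labels([(10, 14, 10, 15), (10, 30, 19, 40)])
        out = fuse_small_blobs(lab, theta_r=3)
        assert np.all(out[10:14, 10:15] == 2)

    def test_isolated_small_blob_discarded(self):
        lab = self.make_labels([(10, 14, 10, 15)])
        out = fuse_small_blobs(lab, theta_r=3)
        assert not out.any()

    def test_blob_at_cutoff_untouched(self):
        # 30 px >= 28.27: the rule is strict "smaller than"
        lab = self.make_labels([(10, 15, 10, 16)])
        out = fuse_small_blobs(lab, theta_r=3)
        assert (out == 1).sum() == 30

    def test_distance_rule_is_boundary_to_boundary(self):
        # gap of 7 px > 2*theta_r=6 -> no fusion, discarded instead
        lab = self.make_labels([(10, 14, 10, 15), (10, 30, 22, 40)])
        out = fuse_small_blobs(lab, theta_r=3)
        assert not (out == 1).any()
        assert (out == 2).any()


def gift_wrap(points):
    """Jarvis-march convex hull oracle (counter-clockwise)."""
    pts = sorted(map(tuple, points))
    if len(pts) < 3:
        return pts
    start = pts[0]
    hull = [start]
    cur = start
    while True:
        cand = pts[0] if pts[0] != cur else pts[1]
        for p in pts:
            if p == cur:
                continue
            cross = ((cand[0] - cur[0]) * (p[1] - cur[1]) -
                     (cand[1] - cur[1]) * (p[0] - cur[0]))
            if cross < 0 or (cross == 0 and
                             np.hypot(p[0] - cur[0], p[1] - cur[1]) >
                             np.hypot(cand[0] - cur[0], cand[1] - cur[1])):
                cand = p
        if cand == start:
            break
        hull.append(cand)
        cur = cand
    return hull


class TestConvexHulls:
    def test_square_has_four_corners(self):
        lab = np.zeros((20, 20), np.int32)
        lab[5:15, 5:15] = 1
        hulls = convex_hulls(lab)
        assert len(hulls[1]) == 4
        assert set(map(tuple, hulls[1])) == {(5, 5), (5, 14), (14, 5), (14, 14)}

    def test_c_shape_hull_closes_gap(self):
        lab = np.zeros((20, 20), np.int32)
        lab[5:15, 5:8] = 1
        lab[5:8, 5:15] = 1
        lab[12:15, 5:15] = 1
        hulls = convex_hulls(lab)
        from scipy.spatial import ConvexHull
        assert ConvexHull(hulls[1]).volume > (lab == 1).sum()

    def test_matches_gift_wrapping_oracle(self, rng):
        pts = rng.integers(0, 30, size=(40, 2))
        lab = np.zeros((32, 32), np.int32)
        lab[pts[:, 0], pts[:, 1]] = 1
        hulls = convex_hulls(lab)
        got = set(map(tuple, hulls[1].astype(int)))
        expected = set(gift_wrap(np.unique(pts, axis=0)))
        assert got == expected

    def test_degenerate_blobs_discarded(self):
        lab = np.zeros((10, 10), np.int32)
        lab[3, 2:7] = 1  # collinear
        lab[7, 7] = 2    # too small
        assert convex_hulls(lab) == {}


class TestFitEllipse:
    def disc_hull(self, r, centre=(30.0, 30.0)):
        theta = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        pts = np.column_stack([centre[0] + r * np.sin(theta),
                               centre[1] + r * np.cos(theta)])
        return np.round(pts)

    def test_disc_size_at_1_px_per_cm(self):
        nod = fit_ellipse(self.disc_hull(10), resolution_px_per_cm=1.0,
                          nodule_id=1)
        assert nod.size_cm2 == pytest.approx(math.pi * 100, rel=0.05)
        assert nod.semi_major_px == pytest.approx(10, rel=0.05)

    def test_disc_size_at_16_px_per_cm(self):
        nod = fit_ellipse(self.disc_hull(10), resolution_px_per_cm=16.0)
        assert nod.size_cm2 == pytest.approx(math.pi * (10 / 16) ** 2, rel=0.05)

    def test_axis_ratio_and_orientation_recovered(self):
        phi = math.radians(30.0)
        theta = np.linspace(0, 2 * np.pi, 128, endpoint=False)
        u, v = 20 * np.cos(theta), 10 * np.sin(theta)
        rows = 40 - (u * math.sin(phi) + v * math.cos(phi))
        cols = 40 + (u * math.cos(phi) - v * math.sin(phi))
        nod = fit_ellipse(np.column_stack([rows, cols]), 1.0)
        ratio = nod.semi_major_px / nod.semi_minor_px
        assert ratio == pytest.approx(2.0, abs=0.1)
        assert min(abs(nod.orientation_deg - 30.0),
                   abs(nod.orientation_deg - 210.0) % 180) <= 3.0

    def test_collinear_rejected(self):
        pts = np.column_stack([np.arange(5.0), np.arange(5.0)])
        assert fit_ellipse(pts, 1.0) is None

    def test_moment_fallback_for_tiny_hulls(self):
        pts = np.array([[0.0, 0.0], [0.0, 4.0], [4.0, 0.0], [4.0, 4.0]])
        nod = fit_ellipse(pts, 1.0)
        assert nod is not None
        assert nod.semi_major_px > 0


class TestDelineateMask:
    def test_planted_discs_recovered(self):
        discs = [(20, 20, 10), (20, 60, 8), (60, 30, 12), (65, 70, 9)]
        mask = disc_mask(90, 90, discs)
        nodules = delineate_mask(mask, theta_r=3, image_id="t")
        assert len(nodules) == len(discs)
        for cy, cx, r in discs:
            d = min(math.hypot(n.centroid[0] - cy, n.centroid[1] - cx)
                    for n in nodules)
            assert d <= 3.0

    def test_min_area_rule_no_tiny_final_blobs(self):
        mask = disc_mask(60, 60, [(30, 30, 8), (10, 50, 2)])
        nodules = delineate_mask(mask, theta_r=4, image_id="t")
        # the r=2 disc (area ~12 px < pi*16) is discarded
        assert len(nodules) == 1
        for nod in nodules:
            assert nod.area_px >= math.pi * 16
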