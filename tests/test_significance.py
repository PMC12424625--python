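"""Statistical testing: box geometry, enrichment ratios, one-sided KS,
overlap removal, BH correction and final thresholds."""

import numpy as np
import pytest
from scipy import stats

from chromjet import significance as sg


class TestExtractBoxes:
    def test_vertical_ridge_horizontal_boxes(self):
        # theta = 90 (vertical ridge): boxes are horizontal runs in one row
        img = np.arange(100, dtype=float).reshape(10, 10)
        t = sg.extract_boxes(img, (5.0, 5.0), width=3, angle_deg=90.0)
        assert sorted(t.center) == [54.0, 55.0, 56.0]
        assert sorted(np.concatenate([t.left, t.right])) == [51, 52, 53, 57, 58, 59]

    def test_single_pixel_boxes(self):
        img = np.arange(100, dtype=float).reshape(10, 10)
        t = sg.extract_boxes(img, (5.0, 5.0), width=1, angle_deg=90.0)
        assert list(t.center) == [55.0]
        # flanks one pixel to each side (left/right labels are orientation-
        # dependent; the pair is what matters)
        assert sorted([t.left[0], t.right[0]]) == [54.0, 56.0]

    def test_edge_clipping(self):
        img = np.ones((10, 10))
        t = sg.extract_boxes(img, (5.0, 1.0), width=3, angle_deg=90.0)
        assert min(t.left.size, t.right.size) < 3   # one flank clipped
        assert t.center.size == 3

    def test_geometry_oracle_rasterization(self):
        # brute-force rasterization oracle for an oblique ridge
        rng = np.random.default_rng(4)
        img = rng.uniform(size=(20, 20))
        y0, x0, w, theta = 10.0, 10.0, 4, 60.0
        t = sg.extract_boxes(img, (y0, x0), w, theta)
        nx, ny = -np.sin(np.radians(theta)), np.cos(np.radians(theta))
        offsets = np.arange(w) - (w - 1) / 2.0
        expect = [img[int(round(y0 + o * ny)), int(round(x0 + o * nx))] for o in offsets]
        assert sorted(t.center) == sorted(expect)


class TestEnrichmentRatio:
    def test_hand_cases(self):
        T = sg.BoxTriplet
        assert np.isclose(
            sg.enrichment_ratio(T(np.full(3, 0.8), np.full(3, 0.4), np.full(3, 0.4))), 2.0)
        assert np.isclose(
            sg.enrichment_ratio(T(np.full(3, 0.5), np.full(3, 0.5), np.full(3, 0.5))), 1.0)
        r = sg.enrichment_ratio(T(np.array([0.6, 0.9]), np.array([0.1, 0.2]),
                                  np.array([0.3, 0.4])))
        assert np.isclose(r, 3.0)

    def test_undefined_cases(self):
        T = sg.BoxTriplet
        assert sg.enrichment_ratio(T(np.array([]), np.ones(2), np.ones(2))) is None
        assert sg.enrichment_ratio(T(np.ones(2), np.zeros(2), np.zeros(2))) is None


class TestKSPvalue:
    def test_identical_samples(self):
        t = np.array([1.0, 1.2, 0.9, 1.1])
        ks, p = sg.ks_pvalue(t, t)
        assert ks == 0.0 and p == 1.0

    def test_disjoint_supports(self):
        t = np.linspace(1, 2, 20)
        ks, p = sg.ks_pvalue(t + 10, t)
        assert ks == 1.0
        assert p < 1e-6

    def test_too_few_values(self):
        with pytest.warns(UserWarning):
            ks, p = sg.ks_pvalue(np.array([1.0]), np.array([1.0, 2.0]))
        assert p == 1.0

    def test_statistic_matches_scipy(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = rng.normal(size=15)
            b = rng.normal(0.3, size=12)
            ks, _ = sg.ks_pvalue(a, b)
            ref = stats.ks_2samp(a, b, alternative="less")
            assert np.isclose(ks, ref.statistic)

    def test_null_pvalues_near_uniform(self):
        # Monte-Carlo under the null: p-values approximately uniform
        rng = np.random.default_rng(6)
        ps = []
        for _ in range(1000):
            a = rng.normal(size=25)
            b = rng.normal(size=25)
            ps.append(sg.ks_pvalue(a, b)[1])
        # one-sided asymptotic p is conservative at these n; require the
        # distribution not to be anti-conservative (too many small p)
        ps = np.asarray(ps)
        assert (ps <= 0.05).mean() <= 0.07
        assert (ps <= 0.2).mean() <= 0.25
        assert ps.min() < 0.5  # and not degenerate at 1


class _FakeRidge:
    def __init__(self, pts):
        self.points = np.atleast_2d(np.asarray(pts, float))


def bruteforce_overlap_removal(ridges, pvals, radius=7.0, iou_threshold=0.05):
    """Literal re-trace of the published greedy procedure, kept deliberately
    simple as an independent oracle."""
    J = len(ridges)
    removed, kept = set(), []
    for j in range(J):
        if j in removed:
            continue
        group = [j]
        for t in range(J):
            if t == j or t in removed:
                continue
            d = np.sqrt(((ridges[j].points[:, None] - ridges[t].points[None]) ** 2
                         ).sum(axis=2)).min()
            if d > radius:
                continue
            if sg.buffered_iou(ridges[j].points, ridges[t].points, radius) > iou_threshold:
                group.append(t)
        best = min(group, key=lambda t: (pvals[t], t))
        if best not in kept:
            kept.append(best)
        removed.update(set(group) - {best})
    return kept


class TestRemoveOverlaps:
    def test_coincident_pair_keeps_lower_p(self):
        pts = [(10, 100), (9, 100), (8, 100)]
        kept = sg.remove_overlaps([_FakeRidge(pts), _FakeRidge(pts)], [0.01, 0.02])
        assert kept == [0]

    def test_far_apart_both_kept(self):
        kept = sg.remove_overlaps([_FakeRidge([(10, 10)]), _FakeRidge([(10, 200)])],
                                  [0.5, 0.4])
        assert kept == [0, 1]

    def test_trio_greedy_group(self):
        # A ~ B ~ C pairwise overlapping, p = (0.3, 0.1, 0.2) -> exactly {B}
        a = _FakeRidge([(10, 100), (9, 100)])
        b = _FakeRidge([(10, 101), (9, 101)])
        c = _FakeRidge([(10, 102), (9, 102)])
        kept = sg.remove_overlaps([a, b, c], [0.3, 0.1, 0.2])
        assert kept == [1]

    def test_iou_decision_boundary(self):
        # two parallel 2-point ridges: IoU of radius-7 buffers decays with
        # separation; crossing 0.05 flips the decision
        def pair(sep):
            a = _FakeRidge([(10, 50), (11, 50)])
            b = _FakeRidge([(10, 50 + sep), (11, 50 + sep)])
            return sg.remove_overlaps([a, b], [0.01, 0.02])
        near = pair(4.0)
        far = pair(13.9)   # still within candidate radius? beyond radius -> kept
        assert near == [0]
        assert far == [0, 1]
        iou_near = sg.buffered_iou(np.array([[10, 50], [11, 50]]),
                                   np.array([[10, 54], [11, 54]]), 7.0)
        iou_far = sg.buffered_iou(np.array([[10, 50], [11, 50]]),
                                  np.array([[10, 63.9], [11, 63.9]]), 7.0)
        assert iou_near > 0.05 > iou_far

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_trace(self, seed):
        rng = np.random.default_rng(seed)
        ridges = []
        for _ in range(4):
            y0 = rng.uniform(5, 30)
            x0 = rng.uniform(5, 60)
            n = rng.integers(2, 6)
            ridges.append(_FakeRidge(np.column_stack([
                y0 - np.arange(n), np.full(n, x0)])))
        pvals = rng.uniform(0, 1, size=4)
        assert (sg.remove_overlaps(ridges, pvals) ==
                bruteforce_overlap_removal(ridges, pvals))

    def test_kept_set_is_independent(self):
        rng = np.random.default_rng(99)
        ridges = [_FakeRidge(np.column_stack([20 - np.arange(3),
                                              np.full(3, rng.uniform(0, 80))]))
                  for _ in range(12)]
        pvals = rng.uniform(size=12)
        kept = sg.remove_overlaps(ridges, pvals)
        for i in kept:
            for j in kept:
                if i >= j:
                    continue
                d = np.sqrt(((ridges[i].points[:, None] - ridges[j].points[None]) ** 2
                             ).sum(axis=2)).min()
                if d <= 7.0:
                    iou = sg.buffered_iou(ridges[i].points, ridges[j].points, 7.0)
                    assert iou <= 0.05


class TestBHCorrect:
    def test_single_pvalue_unchanged(self):
        assert np.allclose(sg.bh_correct([0.03]), [0.03])

    def test_hand_bh(self):
        # adjusted_i = min over tail of p_(k) * n / k
        adj = sg.bh_correct([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert np.allclose(sg.bh_correct([1.0, 1.0, 1.0]), 1.0)

    def test_monotone_and_capped(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=30)
        adj = sg.bh_correct(p)
        assert np.all(adj <= 1.0) and np.all(adj >= p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestFinalThreshold:
    def test_identity_gates(self):
        idx = sg.final_threshold([0.5, 0.9], [1.0, 2.0], alpha=1.0,
                                 saliency_thresh_percentile=0.0)
        assert list(idx) == [0, 1]

    def test_percentile_keeps_top(self):
        p = [0.01] * 10
        sal = list(range(10))
        idx = sg.final_threshold(p, sal, alpha=0.1, saliency_thresh_percentile=90.0)
        assert list(idx) == [9]

    def test_alpha_removes(self):
        idx = sg.final_threshold([0.2], [5.0], alpha=0.1,
                                 saliency_thresh_percentile=0.0)
        assert len(idx) == 0

    def test_empty(self):
        assert len(sg.final_threshold([], [], 0.1, 90.0)) == 0
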