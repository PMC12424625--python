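"""Ridge post-processing: ordering, filters, coordinate shifts, trimming.

Trim tests hand-trace the printed rules on small point sequences; positions
in comments are 1-based as in the worked examples, indices in code 0-based.
"""

import numpy as np
import pytest

from chromjet import ridge_refine as rr
from chromjet.ridge_tracing import Ridge


def make_ridge(ys, xs, angles=None, samples=None, scale_index=0):
    n = len(ys)
    pts = np.column_stack([np.asarray(ys, float), np.asarray(xs, float)])
    r = Ridge(pts, np.full(n, 3.0), np.asarray(angles if angles is not None
                                               else np.full(n, 90.0), float),
              np.ones(n), scale=2.0, scale_index=scale_index)
    if samples:
        r.samples = {k: np.asarray(v) for k, v in samples.items()}
    return r


OPEN_POLICY = rr.TrimPolicy(corner_trim=0.0, angle_trim=0.0, eig2_trim=0.0)


class TestNormalizeAndOrder:
    def test_angle_wrap(self):
        r = make_ridge([9, 8], [10, 10], angles=[270.0, 185.0])
        r = rr.normalize_and_order(r)
        assert np.allclose(r.angles, [90.0, 5.0])

    def test_tip_first_reversed(self):
        r = make_ridge([5, 6, 7], [10, 10, 10])   # y increasing = starts at tip
        r = rr.normalize_and_order(r)
        assert list(r.points[:, 0]) == [7, 6, 5]

    def test_curved_ridge_flagged(self):
        # x not monotone: ordering by distance stands, curvature flag set
        r = make_ridge([9, 8, 7], [10, 12, 11])
        r = rr.normalize_and_order(r)
        assert r.curved
        assert list(r.points[:, 0]) == [9, 8, 7]


class TestFilterPoints:
    def test_point_in_rem_k_strata_discards_two_point_ridge(self):
        # strip of 20 rows: distance = 19 - y; y=18 -> distance 1 < 2
        r = make_ridge([18, 17], [10, 10])
        assert rr.filter_points(r, rr.TrimPolicy(), (20, 40)) is None

    def test_ridge_beyond_root_within_discarded(self):
        pol = rr.TrimPolicy(root_within=5.0)
        r = make_ridge([5, 4, 3], [10, 10, 10])   # distances 14, 15, 16
        assert rr.filter_points(r, pol, (20, 40)) is None

    def test_out_of_map_point_dropped(self):
        r = make_ridge([15, 14, 13, 12, 11], [10, 10, 50, 10, 10])
        out = rr.filter_points(r, rr.TrimPolicy(), (20, 40))
        assert out.n_points == 4


class TestShiftToGenomic:
    def test_no_removals_identity(self):
        r = make_ridge([19, 18, 17], [10, 10, 10])
        r = rr.shift_to_genomic(r, np.arange(40), (20, 40))
        assert np.allclose(r.shifted_x, r.points[:, 1])
        assert np.allclose(rr.relative_shifts(r), 0.0)

    def test_global_shift_invariant(self):
        # 2 bins removed before the ridge: constant delta, d-bar all zero
        retained = np.concatenate([[0, 1], np.arange(4, 42)])  # bins 2,3 removed
        r = make_ridge([19, 18, 17], [10, 10, 10])
        r = rr.shift_to_genomic(r, retained, (20, 40))
        deltas = r.shifted_x - r.points[:, 1]
        assert np.allclose(deltas, deltas[0]) and deltas[0] == 2.0
        assert np.allclose(rr.relative_shifts(r), 0.0)

    def test_interleaved_removals_match_bruteforce(self):
        rng = np.random.default_rng(11)
        retained = np.sort(rng.choice(100, size=60, replace=False))
        m = 30
        ys = np.array([29, 28, 27, 26])
        xs = np.array([20.0, 20.0, 21.0, 21.0])
        r = make_ridge(ys, xs)
        r = rr.shift_to_genomic(r, retained, (m, 60))
        for k in range(4):
            d = (m - 1) - ys[k]
            i = int(round(xs[k] - d / 2)); j = int(round(xs[k] + d / 2))
            expect = (retained[i] + retained[j]) / 2.0
            assert r.shifted_x[k] == expect


class TestTrimCorner:
    def test_corner_at_all_scales_trims(self):
        # corner at position 4 (1-based) at all scales, N=6 -> keep 1..3
        c = np.zeros((6, 3), bool)
        c[3, :] = True
        r = make_ridge(range(19, 13, -1), [10] * 6, samples={"C": c})
        out = rr.trim_corner(r, rr.TrimPolicy())
        assert out.n_points == 3

    def test_corner_at_single_scale_no_trim(self):
        c = np.zeros((6, 3), bool)
        c[3, 1] = True          # only one scale: "for all s" fails
        r = make_ridge(range(19, 13, -1), [10] * 6, samples={"C": c})
        assert rr.trim_corner(r, rr.TrimPolicy()).n_points == 6

    def test_floor_blocks_trim(self):
        # corner at position 2 with min_bins=3: blocked, ridge unchanged
        c = np.zeros((6, 3), bool)
        c[1, :] = True
        r = make_ridge(range(19, 13, -1), [10] * 6, samples={"C": c})
        out = rr.trim_corner(r, rr.TrimPolicy(corner_trim=3.0))
        assert out.n_points == 6


class TestTrimAngle:
    def _ridge(self, thetas):
        th = np.array(thetas, float)[:, None]
        return make_ridge(range(19, 19 - len(thetas), -1), [10] * len(thetas),
                          samples={"Theta": th})

    def test_first_out_of_range_trims_tail(self):
        # angles (80, 85, 40), range [60, 120] -> keep first 2
        out = rr.trim_angle(self._ridge([80, 85, 40]), OPEN_POLICY)
        assert out.n_points == 2

    def test_all_in_range_unchanged(self):
        out = rr.trim_angle(self._ridge([80, 85, 110]), OPEN_POLICY)
        assert out.n_points == 3

    def test_first_angle_bad_discards_with_floor_off(self):
        assert rr.trim_angle(self._ridge([30, 85, 110]), OPEN_POLICY) is None


class TestTrimEigenvalue:
    def _ridge(self, psis):
        n = len(psis)
        return make_ridge(range(19, 19 - n, -1), [10] * n,
                          samples={"Psi": np.array(psis, float)[:, None],
                                   "Lambda": np.ones((n, 1))})

    def test_interior_peak_then_negative(self):
        # psi = (0.2, 0.5, 0.3, -0.1, 0.4): peak at 2 (1-based), cut at 4
        out = rr.trim_eigenvalue(self._ridge([0.2, 0.5, 0.3, -0.1, 0.4]), OPEN_POLICY)
        assert out.n_points == 3

    def test_all_positive_no_trim(self):
        out = rr.trim_eigenvalue(self._ridge([0.2, 0.5, 0.3, 0.2, 0.1]), OPEN_POLICY)
        assert out.n_points == 5

    def test_monotone_decreasing_global_max(self):
        # no interior max, global max at 1, crossing zero at 3 -> keep 1..2
        out = rr.trim_eigenvalue(self._ridge([0.5, 0.2, -0.1, -0.3]), OPEN_POLICY)
        assert out.n_points == 2

    def test_relative_tolerance_ignores_numerical_wiggle(self):
        # dips within 5% of peak strength are numerical noise, not structure
        out = rr.trim_eigenvalue(self._ridge([0.2, 0.5, 0.3, -0.02, 0.4]), OPEN_POLICY)
        assert out.n_points == 5


class TestTrimWhitespace:
    def _ridge_with_shift(self, dbar, img_vals):
        n = len(dbar)
        r = make_ridge(range(19, 19 - n, -1), range(10, 10 + n))
        r.shifted_x = r.points[:, 1] - np.asarray(dbar, float)
        img = np.zeros((20, 30))
        for k in range(n):
            img[int(r.points[k, 0]), int(r.points[k, 1])] = img_vals[k]
        img[0, :] = 0.5   # background pixels set v25 ~ 0.5
        return r, img

    def test_dim_tip_trimmed(self):
        # d-bar = (0, 0, 6, 6), tip dim -> keep positions 1..2
        r, img = self._ridge_with_shift([0, 0, 6, 6], [0.9, 0.9, 0.001, 0.001])
        out = rr.trim_whitespace(r, img, rr.TrimPolicy())
        assert out.n_points == 2
        assert list(out.points[:, 0]) == [19, 18]

    def test_small_shifts_unchanged(self):
        r, img = self._ridge_with_shift([0, 1, 2, 4], [0.9] * 4)
        assert rr.trim_whitespace(r, img, rr.TrimPolicy()).n_points == 4

    def test_single_point_head_trimmed(self):
        # i0* = 2 (1-based): head is the single position 1 -> head trimmed
        r, img = self._ridge_with_shift([0, 6, 6, 6], [0.9, 0.9, 0.9, 0.9])
        out = rr.trim_whitespace(r, img, rr.TrimPolicy())
        assert out.n_points == 3
        assert list(out.points[:, 0]) == [18, 17, 16]

    def test_threshold_is_inclusive_five(self):
        # relative shift of exactly 5 bins triggers ("5 bins or greater")
        r, img = self._ridge_with_shift([0, 0, 5, 5], [0.9, 0.9, 0.001, 0.001])
        out = rr.trim_whitespace(r, img, rr.TrimPolicy())
        assert out.n_points == 2


class TestTrimProperties:
    def _full_ridge(self, n=8, seed=0):
        rng = np.random.default_rng(seed)
        c = rng.random((n, 3)) < 0.2
        psi = rng.normal(0.1, 0.3, size=(n, 3))
        th = rng.uniform(40, 140, size=(n, 3))
        r = make_ridge(range(19, 19 - n, -1), [10] * n,
                       samples={"C": c, "Psi": psi, "Theta": th,
                                "Lambda": np.abs(rng.normal(1, 0.2, (n, 3)))})
        r.shifted_x = r.points[:, 1].copy()
        return r

    @pytest.mark.parametrize("trim", [rr.trim_corner, rr.trim_angle, rr.trim_eigenvalue])
    @pytest.mark.parametrize("seed", range(5))
    def test_idempotent_and_prefix(self, trim, seed):
        r = self._full_ridge(seed=seed)
        once = trim(r, rr.TrimPolicy())
        if once is None:
            return
        twice = trim(once, rr.TrimPolicy())
        assert twice is not None and twice.n_points == once.n_points
        # survivors are a prefix of the input ordering
        assert np.array_equal(once.points, r.points[:once.n_points])

    def test_min_fraction_floor(self):
        # with min_fraction f, no trim may cut into the first ceil(f*N) points
        c = np.ones((10, 2), bool)   # corner everywhere -> i* = 0 -> blocked
        r = make_ridge(range(19, 9, -1), [10] * 10, samples={"C": c})
        out = rr.trim_corner(r, rr.TrimPolicy(corner_trim=0.5))
        assert out.n_points == 10
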