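"""First-passage/residence times and revisit histories against independent
oracles (dense re-discretization with bisection refinement)."""

import math

import numpy as np
import pytest

import arscape as a
from arscape.residence import merged_residence_time_matrix, residence_time_matrix


# ---------------------------------------------------------------------------
# dense re-discretization oracle (independent of the production code path)
# ---------------------------------------------------------------------------

def _refine(traj, cx, cy, r, t_lo, t_hi, inward):
    """Bisection on interpolated position for the crossing between t_lo/t_hi."""

    def dist(tt):
        i = np.searchsorted(traj.t, tt, side="right") - 1
        i = min(max(i, 0), len(traj) - 2)
        s = (tt - traj.t[i]) / (traj.t[i + 1] - traj.t[i])
        x = traj.x[i] + s * (traj.x[i + 1] - traj.x[i])
        y = traj.y[i] + s * (traj.y[i + 1] - traj.y[i])
        return math.hypot(x - cx, y - cy)

    for _ in range(60):
        mid = 0.5 * (t_lo + t_hi)
        if (dist(mid) < r) == inward:
            t_hi = mid
        else:
            t_lo = mid
    return 0.5 * (t_lo + t_hi)


def oracle_inside_intervals(traj, i, r, pts_per_segment=1000):
    """Intervals the path spends inside the circle around fix i, found by
    scanning a dense time grid and refining each boundary by bisection."""
    cx, cy = traj.x[i], traj.y[i]
    ts = []
    for k in range(len(traj) - 1):
        ts.append(np.linspace(traj.t[k], traj.t[k + 1], pts_per_segment, endpoint=False))
    ts = np.concatenate(ts + [traj.t[-1:]])
    xs = np.interp(ts, traj.t, traj.x)
    ys = np.interp(ts, traj.t, traj.y)
    inside = np.hypot(xs - cx, ys - cy) < r
    intervals = []
    k = 0
    n = len(ts)
    while k < n:
        if inside[k]:
            start = k
            while k + 1 < n and inside[k + 1]:
                k += 1
            t_in = ts[start] if start == 0 else _refine(traj, cx, cy, r, ts[start - 1], ts[start], True)
            t_out = ts[k] if k == n - 1 else _refine(traj, cx, cy, r, ts[k], ts[k + 1], False)
            intervals.append((t_in, t_out))
        k += 1
    return intervals


def oracle_fpt(traj, i, r, direction):
    intervals = oracle_inside_intervals(traj, i, r)
    t0 = traj.t[i]
    focal = next((iv for iv in intervals if iv[0] <= t0 <= iv[1]), None)
    assert focal is not None
    if direction == "forward":
        cens = focal[1] >= traj.t[-1] - 1e-12
        return focal[1] - t0, cens
    cens = focal[0] <= traj.t[0] + 1e-12
    return t0 - focal[0], cens


# ---------------------------------------------------------------------------

class TestAnalyticCases:
    def test_straight_path_fpt_rt(self, straight_path):
        fwd = a.first_passage_time(straight_path, 50, 2.0, "forward")
        back = a.first_passage_time(straight_path, 50, 2.0, "backward")
        assert fwd == (pytest.approx(2.0), False)
        assert back == (pytest.approx(2.0), False)
        rt = a.residence_time(straight_path, 50, 3.0)
        assert rt.duration == pytest.approx(6.0)
        assert not rt.censored

    def test_last_fix_forward_censored(self, straight_path):
        res = a.first_passage_time(straight_path, len(straight_path) - 1, 5.0, "forward")
        assert res.censored

    def test_whole_path_circle_censored_both_ends(self, straight_path):
        rt = a.residence_time(straight_path, 50, 1e6)
        assert rt.censored
        assert rt.duration == pytest.approx(straight_path.duration)

    def test_rt_is_sum_of_directional_fpts(self, random_walk):
        for i in (0, 57, 120, 199):
            for r in (1.0, 5.0, 20.0):
                b = a.first_passage_time(random_walk, i, r, "backward")
                f = a.first_passage_time(random_walk, i, r, "forward")
                rt = a.residence_time(random_walk, i, r)
                assert rt.duration == pytest.approx(b.duration + f.duration)
                assert rt.censored == (b.censored or f.censored)


class TestOracleEquivalence:
    @pytest.mark.parametrize("i,r", [(30, 5.0), (100, 5.0), (170, 2.0), (57, 10.0)])
    def test_fpt_matches_dense_oracle(self, random_walk, i, r):
        for direction in ("backward", "forward"):
            got = a.first_passage_time(random_walk, i, r, direction)
            exp_dur, exp_cens = oracle_fpt(random_walk, i, r, direction)
            assert got.duration == pytest.approx(exp_dur, abs=1e-6)
            assert got.censored == exp_cens

    @pytest.mark.parametrize("i,r", [(30, 5.0), (100, 8.0), (170, 3.0)])
    def test_revisit_segments_match_dense_oracle(self, random_walk, i, r):
        hist = a.revisit_history(random_walk, i, r)
        expected = oracle_inside_intervals(random_walk, i, r)
        assert hist.n_visits == len(expected)
        for seg, (t_in, t_out) in zip(hist.segments, expected):
            assert seg.t_in == pytest.approx(t_in, abs=1e-6)
            assert seg.t_out == pytest.approx(t_out, abs=1e-6)


class TestMergedVisits:
    def test_no_merge_counts_each_entry(self, random_walk):
        hist = a.revisit_history(random_walk, 100, 5.0, max_time_outside=0.0)
        assert hist.n_visits == len(oracle_inside_intervals(random_walk, 100, 5.0))

    def test_full_merge_single_visit_conserves_time(self, random_walk):
        h0 = a.revisit_history(random_walk, 100, 5.0, 0.0)
        hinf = a.revisit_history(random_walk, 100, 5.0, math.inf)
        assert hinf.n_visits == 1
        assert hinf.total_time == pytest.approx(h0.total_time)

    def test_total_time_invariant_and_visits_monotone(self, random_walk):
        base = a.revisit_history(random_walk, 57, 4.0, 0.0)
        prev = base.n_visits
        for mto in (1.0, 5.0, 20.0, 100.0):
            h = a.revisit_history(random_walk, 57, 4.0, mto)
            assert h.total_time == pytest.approx(base.total_time)
            assert h.n_visits <= prev
            prev = h.n_visits

    def test_focal_always_present(self, random_walk):
        for i in (0, 99, 199):
            h = a.revisit_history(random_walk, i, 2.0)
            assert h.n_visits >= 1
            assert h.focal_segment.t_in <= random_walk.t[i] <= h.focal_segment.t_out


class TestMatrixConsistency:
    def test_matrix_matches_scalar(self, random_walk):
        radii = np.array([1.0, 3.0, 8.0, 20.0])
        mat = residence_time_matrix(random_walk, radii)
        for i in (0, 25, 101, 199):
            for j, r in enumerate(radii):
                rt = a.residence_time(random_walk, i, r)
                assert mat.durations[i, j] == pytest.approx(rt.duration, abs=1e-9)
                assert mat.censored[i, j] == rt.censored

    def test_merged_kernel_zero_threshold_equals_base(self, random_walk):
        radii = np.geomspace(0.5, 25.0, 12)
        base = residence_time_matrix(random_walk, radii)
        merged = merged_residence_time_matrix(random_walk, radii, 0.0)
        np.testing.assert_allclose(merged.durations, base.durations, atol=1e-9)
        np.testing.assert_array_equal(merged.censored, base.censored)

    def test_merged_kernel_matches_revisit_history(self, random_walk):
        radii = np.array([2.0, 6.0, 15.0])
        T = 10.0
        merged = merged_residence_time_matrix(random_walk, radii, T)
        for i in (10, 80, 150):
            for j, r in enumerate(radii):
                seg = a.revisit_history(random_walk, i, r, T).focal_segment
                assert merged.durations[i, j] == pytest.approx(seg.duration, abs=1e-9)

    def test_compiled_and_python_kernels_agree(self, random_walk):
        radii = np.array([2.0, 6.0])
        fast = merged_residence_time_matrix(random_walk, radii, 5.0, compiled=True)
        slow = merged_residence_time_matrix(random_walk, radii, 5.0, compiled=False)
        np.testing.assert_allclose(fast.durations, slow.durations, atol=1e-12)

    def test_rt_nondecreasing_in_radius(self, random_walk):
        radii = np.geomspace(0.5, 40.0, 15)
        mat = residence_time_matrix(random_walk, radii)
        diffs = np.diff(mat.durations, axis=1)
        assert (diffs >= -1e-9).all()

    def test_discrete_within_two_intervals_of_interpolated(self, random_walk):
        radii = np.array([3.0, 10.0])
        interp = residence_time_matrix(random_walk, radii, method="interpolate")
        disc = residence_time_matrix(random_walk, radii, method="discrete")
        max_dt = np.diff(random_walk.t).max()
        assert np.abs(disc.durations - interp.durations).max() <= 2 * max_dt + 1e-9


class TestRevisitStats:
    def test_matches_per_fix_histories(self, random_walk):
        r, mto = 5.0, 3.0
        stats = a.revisit_stats(random_walk, r, mto)
        for i in (0, 44, 123, 199):
            h = a.revisit_history(random_walk, i, r, mto)
            assert stats.loc[i, "n_visits"] == h.n_visits
            assert stats.loc[i, "mean_visit_duration"] == pytest.approx(h.mean_visit_duration)
            assert stats.loc[i, "total_time"] == pytest.approx(h.total_time)

    def test_infinite_radius_total_is_path_duration(self, random_walk):
        stats = a.revisit_stats(random_walk, 1e9)
        np.testing.assert_allclose(stats["total_time"], random_walk.duration)


def test_argument_validation(random_walk):
    with pytest.raises(ValueError):
        a.first_passage_time(random_walk, 0, -1.0)
    with pytest.raises(IndexError):
        a.residence_time(random_walk, 10_000, 1.0)
    with pytest.raises(ValueError):
        a.revisit_history(random_walk, 0, 1.0, max_time_outside=-1.0)
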