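"""The four-step revisited-ARS-place algorithm and its diagnostics."""

import math

import networkx as nx
import numpy as np
import pytest

import arscape as a
from arscape.places import (
    build_proximity_graph,
    choose_representative,
    connected_components,
    filter_locations,
)


# ---------------------------------------------------------------------------
# constructed fixtures: scripted visits to known places
# ---------------------------------------------------------------------------

def _dwell(cx, cy, n, rng, radius=2.0):
    ang = rng.uniform(-np.pi, np.pi, n)
    rr = rng.uniform(0, radius, n)
    return np.column_stack([cx + rr * np.cos(ang), cy + rr * np.sin(ang)])


def scripted_two_patch_path(n_visits=3, dwell=40, travel=30, seed=0):
    """Alternating slow dwells in two far-apart patches, fast travel between:
    each patch is visited ``n_visits`` times."""
    rng = np.random.default_rng(seed)
    A, B = (0.0, 0.0), (200.0, 0.0)
    pts = []
    for _ in range(n_visits):
        pts.append(_dwell(*A, dwell, rng))
        pts.append(np.column_stack([np.linspace(5, 195, travel), np.full(travel, 5.0)]))
        pts.append(_dwell(*B, dwell, rng))
        pts.append(np.column_stack([np.linspace(195, 5, travel), np.full(travel, -5.0)]))
    xy = np.vstack(pts)
    t = np.arange(len(xy), dtype=float)
    return a.Trajectory(t, xy[:, 0], xy[:, 1])


class TestFilterLocations:
    def test_threshold_is_max_of_mean_and_median(self):
        surv, thr = filter_locations([1, 1, 1, 1, 100])
        assert thr == pytest.approx(20.8)
        np.testing.assert_array_equal(surv, [4])

    def test_all_equal_yields_no_survivors(self):
        surv, thr = filter_locations([7.0] * 10)
        assert len(surv) == 0

    def test_median_dominates_when_larger(self):
        surv, thr = filter_locations([0, 10, 10, 10, 10])
        assert thr == 10.0
        assert len(surv) == 0


class TestProximityGraph:
    def test_strict_distance_convention(self):
        pos = np.array([[0.0, 0.0], [0.9, 0.0], [2.0, 0.0]])
        g = build_proximity_graph(pos, [0, 1, 2], r=1.0)
        assert g.has_edge(0, 1)
        assert not g.has_edge(1, 2)  # distance exactly r: no edge

    def test_matches_brute_force_all_pairs(self):
        rng = np.random.default_rng(3)
        pos = rng.uniform(0, 50, (50, 2))
        surv = np.arange(50)
        r = 7.0
        g = build_proximity_graph(pos, surv, r)
        expected = {
            (i, j)
            for i in range(50)
            for j in range(i + 1, 50)
            if math.hypot(*(pos[i] - pos[j])) < r
        }
        got = {tuple(sorted(e)) for e in g.edges}
        assert got == expected


class TestConnectedComponents:
    def test_edgeless_graph_singletons(self):
        g = nx.Graph()
        g.add_nodes_from(range(5))
        assert connected_components(g) == [[0], [1], [2], [3], [4]]

    def test_chain_is_one_component(self):
        g = nx.Graph([(1, 2), (2, 3)])
        assert connected_components(g) == [[1, 2, 3]]

    def test_long_path_graph_no_recursion_limit(self):
        g = nx.path_graph(10_000)
        comps = connected_components(g)
        assert len(comps) == 1 and len(comps[0]) == 10_000

    def test_matches_union_find_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = 200
            edges = [
                (int(u), int(v))
                for u, v in rng.integers(0, n, (150, 2))
                if u != v
            ]
            g = nx.Graph()
            g.add_nodes_from(range(n))
            g.add_edges_from(edges)
            parent = list(range(n))

            def find(i):
                while parent[i] != i:
                    parent[i] = parent[parent[i]]
                    i = parent[i]
                return i

            for u, v in edges:
                parent[find(u)] = find(v)
            oracle = {}
            for i in range(n):
                oracle.setdefault(find(i), set()).add(i)
            got = {frozenset(c) for c in connected_components(g)}
            assert got == {frozenset(s) for s in oracle.values()}


class TestRepresentative:
    def test_singleton_forced(self):
        assert choose_representative([5], np.arange(10.0)) == 5

    def test_max_with_earliest_tie_break(self):
        values = np.zeros(20)
        values[[3, 7, 12]] = [5.0, 9.0, 9.0]
        assert choose_representative([3, 7, 12], values) == 7


class TestIdentifyPlaces:
    def test_two_patch_path_recovers_both_with_visit_counts(self):
        traj = scripted_two_patch_path(n_visits=3)
        places = a.identify_ars_places(traj, r=8.0, criterion="mean_visit_duration")
        assert len(places) == 2
        for p in places:
            assert p.n_revisits == 3
            assert not p.flags["oversized"]
        centers = sorted(p.center[0] for p in places)
        assert abs(centers[0] - 0) < 8 and abs(centers[1] - 200) < 8

    def test_stationary_stop_is_single_visit_place(self):
        rng = np.random.default_rng(5)
        parts = [
            np.column_stack([np.linspace(0, 95, 40), np.zeros(40)]),
            np.tile([[100.0, 0.0]], (60, 1)) + rng.normal(0, 0.05, (60, 2)),
            np.column_stack([np.linspace(105, 200, 40), np.zeros(40)]),
        ]
        xy = np.vstack(parts)
        traj = a.Trajectory(np.arange(len(xy), dtype=float), xy[:, 0], xy[:, 1])
        places = a.identify_ars_places(traj, r=5.0, criterion="mean_visit_duration")
        assert len(places) == 1
        assert places[0].flags["single_visit"]
        assert a.identify_ars_places(traj, r=5.0, drop_single_visit=True) == []

    def test_total_time_overlooks_few_visit_places(self):
        """A place with one long ARS visit is kept by the mean-duration
        criterion but filtered out under total time, which is dominated by a
        heavily revisited place."""
        rng = np.random.default_rng(9)
        pts = []
        # place A: 10 revisits of 30 fixes each (total time dwarfs the rest)
        for k in range(10):
            pts.append(_dwell(0, 0, 30, rng))
            pts.append(np.column_stack([np.linspace(5, 295, 45), np.full(45, 20.0 + 4 * k)]))
            pts.append(np.column_stack([np.linspace(295, 5, 45), np.full(45, -20.0 - 4 * k)]))
        # place C: a single 45-fix ARS visit (high mean, low total)
        pts.append(np.column_stack([np.linspace(5, 145, 30), np.zeros(30)]))
        pts.append(_dwell(150, 150, 45, rng))
        pts.append(np.column_stack([np.linspace(155, 295, 30), np.zeros(30)]))
        xy = np.vstack(pts)
        traj = a.Trajectory(np.arange(len(xy), dtype=float), xy[:, 0], xy[:, 1])
        by_mean = a.identify_ars_places(traj, r=8.0, criterion="mean_visit_duration")
        by_total = a.identify_ars_places(traj, r=8.0, criterion="total_time")
        assert len(by_total) < len(by_mean)

    def test_adjacent_patches_merge_and_flag_oversized(self):
        rng = np.random.default_rng(13)
        # a chain of adjacent patches 8 apart (radius 3), analysed at r=5.5:
        # neighbouring patches' fixes sit within each other's circles, so the
        # whole chain unites into one place; the richest patch is at one end,
        # anchoring the representative there, so the united component spans
        # more than 2r from it
        centres = [(0.0, 0.0), (6.0, 0.0), (12.0, 0.0)]
        sizes = [45, 25, 25]
        pts = []
        for _ in range(3):
            for (cx, cy), n in zip(centres, sizes):
                pts.append(_dwell(cx, cy, n, rng, radius=3.0))
            pts.append(np.column_stack([np.linspace(17, 200, 25), np.full(25, 30.0)]))
            pts.append(np.column_stack([np.linspace(200, -5, 25), np.full(25, -30.0)]))
        xy = np.vstack(pts)
        traj = a.Trajectory(np.arange(len(xy), dtype=float), xy[:, 0], xy[:, 1])
        places = a.identify_ars_places(traj, r=5.0, criterion="mean_visit_duration")
        assert len(places) == 1  # erroneously united
        assert places[0].flags["oversized"]
        # at a smaller radius the same patches resolve separately
        finer = a.identify_ars_places(traj, r=4.0, criterion="mean_visit_duration")
        assert len(finer) > 1
        assert not any(p.flags["oversized"] for p in finer)

    def test_well_separated_patches_not_oversized(self):
        traj = scripted_two_patch_path()
        for p in a.identify_ars_places(traj, r=8.0):
            assert not p.flags["oversized"]

    def test_components_partition_survivors(self):
        traj = scripted_two_patch_path()
        places = a.identify_ars_places(traj, r=8.0)
        members = sorted(i for p in places for i in p.member_indices)
        assert len(members) == len(set(members))

    def test_no_survivors_returns_empty(self, straight_path):
        assert a.identify_ars_places(straight_path, r=3.0) == []


class TestBetweenVisitIntervals:
    def test_interval_arithmetic(self):
        from arscape.residence import RevisitHistory, VisitSegment

        segs = [
            VisitSegment(0, 10, 10, "focal"),
            VisitSegment(50, 70, 20, "forward"),
            VisitSegment(100, 105, 5, "forward"),
        ]
        h = RevisitHistory(focal_index=0, r=5.0, segments=segs)
        np.testing.assert_allclose(a.between_visit_intervals(h), [40.0, 30.0])

    def test_single_visit_empty(self):
        from arscape.residence import RevisitHistory, VisitSegment

        h = RevisitHistory(0, 5.0, [VisitSegment(0, 10, 10, "focal")])
        assert len(a.between_visit_intervals(h)) == 0

    def test_periodic_returns_recover_period(self):
        rng = np.random.default_rng(21)
        period_travel = 60  # fixes spent away per cycle
        dwell = 20
        pts = []
        for _ in range(5):
            pts.append(_dwell(0, 0, dwell, rng))
            ang = np.linspace(0, 2 * np.pi, period_travel, endpoint=False)
            pts.append(np.column_stack([50 + 40 * np.cos(ang), 40 * np.sin(ang)]))
        xy = np.vstack(pts)
        traj = a.Trajectory(np.arange(len(xy), dtype=float), xy[:, 0], xy[:, 1])
        places = a.identify_ars_places(traj, r=6.0, criterion="mean_visit_duration")
        home = min(places, key=lambda p: math.hypot(*p.center))
        intervals = a.between_visit_intervals(home)
        assert len(intervals) == 4
        np.testing.assert_allclose(intervals, period_travel, atol=2.0)
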