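"""Identification of spatially distinct, revisited ARS places.

Given a characteristic radius (typically from the variance-scale analysis),
the algorithm proceeds in four steps: (1) compute each fix's revisit history
at that radius; (2) filter out fixes whose criterion value (mean visit
duration or total time inside) does not exceed a data-driven threshold —
the larger of the mean and the median of the criterion distribution;
(3) link surviving fixes that lie within each other's circles and take
connected components as candidate places; (4) represent each place by its
member with the largest criterion value.

Place statistics (mean visit duration, number of revisits) come from the
representative's history only: pooling member histories would double-count
overlapping circles.  Diagnostics follow the known failure modes: places
with a single visit are flagged (long stationary stops masquerade as
places), and components stretching beyond twice the analysis radius are
flagged as probable merges of adjacent places — they are never split
automatically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .residence import RevisitHistory, revisit_history, revisit_stats
from .trajectory import Trajectory

logger = logging.getLogger(__name__)

FilterCriterion = Literal["mean_visit_duration", "total_time"]


@dataclass
class ArsPlace:
    """A spatially distinct place the animal revisited and searched.

    ``flags['single_visit']`` marks places visited exactly once (candidate
    stopping-site artifacts); ``flags['oversized']`` marks components whose
    extent exceeds twice the analysis radius (candidate merges of adjacent
    places, to be inspected and split by hand if needed).
    """

    representative_index: int
    center: tuple[float, float]
    member_indices: list[int]
    history: RevisitHistory
    r: float
    extent_radius: float
    flags: dict = field(default_factory=dict)

    @property
    def mean_visit_duration(self) -> float:
        return self.history.mean_visit_duration

    @property
    def n_revisits(self) -> int:
        return self.history.n_visits

    @property
    def total_time(self) -> float:
        return self.history.total_time


def criterion_values(stats: pd.DataFrame, criterion: FilterCriterion) -> np.ndarray:
    if criterion not in ("mean_visit_duration", "total_time"):
        raise ValueError(f"unknown criterion {criterion!r}")
    return stats[criterion].to_numpy(dtype=float)


def filter_locations(
    values: Sequence[float] | pd.DataFrame,
    criterion: FilterCriterion = "mean_visit_duration",
) -> tuple[np.ndarray, float]:
    """Step 2: keep fixes whose criterion value strictly exceeds the larger
    of the distribution's mean and median.

    Accepts either the per-fix criterion values directly or the frame from
    :func:`arscape.residence.revisit_stats`.  Returns ``(survivor_indices,
    threshold)``.  When all values are equal nothing exceeds the threshold
    and the survivor set is empty — "no ARS detected", not an error.
    """
    if isinstance(values, pd.DataFrame):
        values = criterion_values(values, criterion)
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("filter_locations needs at least one criterion value")
    threshold = float(max(values.mean(), np.median(values)))
    survivors = np.flatnonzero(values > threshold)
    return survivors, threshold


def build_proximity_graph(
    positions: np.ndarray,
    survivors: Sequence[int],
    r: float,
) -> nx.Graph:
    """Step 3a: undirected graph on surviving fixes with an edge wherever two
    fixes lie within each other's circles (Euclidean distance strictly below
    ``r``; with a single common radius mutual containment is symmetric)."""
    if not r > 0:
        raise ValueError(f"radius must be positive, got {r!r}")
    survivors = np.asarray(survivors, dtype=int)
    g = nx.Graph()
    g.add_nodes_from(int(i) for i in survivors)
    if survivors.size < 2:
        return g
    pts = np.asarray(positions, dtype=float)[survivors]
    tree = cKDTree(pts)
    for a, b in tree.query_pairs(r, output_type="ndarray"):
        i, j = int(survivors[a]), int(survivors[b])
        # query_pairs is <= r; enforce the strict open-disc convention
        if np.hypot(*(pts[a] - pts[b])) < r:
            g.add_edge(i, j)
    return g


def connected_components(graph: nx.Graph) -> list[list[int]]:
    """Step 3b: maximal connected components, as sorted index lists ordered
    by their smallest member.  The traversal is iterative (no recursion-depth
    limit), so chain-like components of arbitrary length are safe."""
    comps = [sorted(c) for c in nx.connected_components(graph)]
    comps.sort(key=lambda c: c[0])
    return comps


def choose_representative(
    component: Sequence[int],
    values: Sequence[float],
    ) -> int:
    """Step 4: the member with the largest criterion value; ties go to the
    earliest fix index, so the choice is deterministic."""
    component = sorted(int(i) for i in component)
    if not component:
        raise ValueError("empty component")
    values = np.asarray(values, dtype=float)
    best = component[0]
    for i in component[1:]:
        if values[i] > values[best]:
            best = i
    return best


def identify_ars_places(
    traj: Trajectory,
    r: float,
    criterion: FilterCriterion = "mean_visit_duration",
    max_time_outside: float = 0.0,
    drop_single_visit: bool = False,
    stats: pd.DataFrame | None = None,
) -> list[ArsPlace]:
    """Full four-step pipeline at one analysis radius.

    Parameters
    ----------
    traj : Trajectory
    r : float
        Analysis radius, typically a characteristic radius from the
        variance-scale step.
    criterion : {"mean_visit_duration", "total_time"}
        Used both for filtering fixes and for choosing representatives.
    max_time_outside : float
        Visit-merging threshold passed to the revisit histories; keep 0
        unless the relevant temporal scale is known a priori.
    drop_single_visit : bool
        Remove places with exactly one visit (stopping-site artifacts).
    stats : DataFrame, optional
        Precomputed :func:`arscape.residence.revisit_stats` for ``traj`` at
        ``(r, max_time_outside)``, to avoid recomputation.

    Returns
    -------
    list of ArsPlace, ordered by smallest member index.  Empty when no fix
    survives filtering.
    """
    if stats is None:
        stats = revisit_stats(traj, r, max_time_outside)
    values = criterion_values(stats, criterion)
    survivors, threshold = filter_locations(values)
    if survivors.size == 0:
        logger.info("no fixes above the %s threshold %.6g: no ARS places", criterion, threshold)
        return []
    graph = build_proximity_graph(traj.xy, survivors, r)
    places = []
    for comp in connected_components(graph):
        rep = choose_representative(comp, values)
        cx, cy = float(traj.x[rep]), float(traj.y[rep])
        extent = float(
            np.max(np.hypot(traj.x[comp] - cx, traj.y[comp] - cy))
        )
        history = revisit_history(traj, rep, r, max_time_outside)
        place = ArsPlace(
            representative_index=int(rep),
            center=(cx, cy),
            member_indices=[int(i) for i in comp],
            history=history,
            r=float(r),
            extent_radius=extent,
            flags={
                "single_visit": history.n_visits == 1,
                "oversized": extent > 2.0 * r,
            },
        )
        places.append(place)
    if drop_single_visit:
        places = [p for p in places if not p.flags["single_visit"]]
    return places


def between_visit_intervals(place: ArsPlace | RevisitHistory) -> np.ndarray:
    """Durations between consecutive visits (exit to next entry) of a place's
    representative history; empty for a single-visit place.  The distribution
    of these intervals is a hook for revisitation-regularity analyses such as
    trap-lining detection."""
    history = place.history if isinstance(place, ArsPlace) else place
    segs = history.segments
    if len(segs) < 2:
        return np.empty(0)
    return np.array([b.t_in - a.t_out for a, b in zip(segs[:-1], segs[1:])])


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def places_to_dataframe(places: Sequence[ArsPlace], criterion: str = "") -> pd.DataFrame:
    """One row per place: centre, radius, statistics and flags."""
    rows = []
    for pid, p in enumerate(places):
        rows.append(
            {
                "place_id": pid,
                "representative_index": p.representative_index,
                "center_x": p.center[0],
                "center_y": p.center[1],
                "r": p.r,
                "criterion": criterion,
                "mean_visit_duration": p.mean_visit_duration,
                "n_revisits": p.n_revisits,
                "total_time": p.total_time,
                "n_members": len(p.member_indices),
                "extent_radius": p.extent_radius,
                "single_visit": p.flags["single_visit"],
                "oversized": p.flags["oversized"],
            }
        )
    return pd.DataFrame(rows)


def visits_to_dataframe(places: Sequence[ArsPlace]) -> pd.DataFrame:
    """One row per visit segment per place."""
    rows = []
    for pid, p in enumerate(places):
        for s in p.history.segments:
            rows.append(
                {
                    "place_id": pid,
                    "t_in": s.t_in,
                    "t_out": s.t_out,
                    "duration": s.duration,
                    "kind": s.kind,
                    "censored_start": s.censored_start,
                    "censored_end": s.censored_end,
                }
            )
    return pd.DataFrame(rows)


def places_to_geojson(places: Sequence[ArsPlace], path: str | Path | None = None) -> dict:
    """GeoJSON-style FeatureCollection of representative points (planar
    coordinates, no CRS)."""
    features = []
    for pid, p in enumerate(places):
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": list(p.center)},
                "properties": {
                    "place_id": pid,
                    "r": p.r,
                    "mean_visit_duration": p.mean_visit_duration,
                    "n_revisits": p.n_revisits,
                    "total_time": p.total_time,
                    "single_visit": p.flags["single_visit"],
                    "oversized": p.flags["oversized"],
                },
            }
        )
    collection = {"type": "FeatureCollection", "features": features}
    if path is not None:
        Path(path).write_text(json.dumps(collection, indent=2) + "\n")
    return collection
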