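"""First-passage times, residence times, and per-location revisit histories.

Around every recorded location a virtual circle of radius ``r`` is drawn.  The
first-passage time (FPT) is the time from the focal fix to the first crossing
of that circle's perimeter, scanning forward or backward along the path; the
residence time (RT) is their sum — the total time inside the circle from first
entry to first exit.  A revisit history generalizes this to *all* intervals the
path spends inside the circle, optionally merging visits separated by brief
excursions.

All durations are computed from timestamps (never fix counts), so irregular
sampling is handled throughout.  Crossing times are located by linear
interpolation between fixes; a discrete mode that snaps to the first fix
outside the circle is available for exact replication of step-based
simulations.  The inside region is the open disc: a fix at distance exactly
``r`` is outside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd

from ._fast import merged_residence_matrix
from .trajectory import Trajectory

Direction = Literal["backward", "forward"]
Method = Literal["interpolate", "discrete"]


class FptResult(NamedTuple):
    duration: float
    censored: bool


@dataclass(frozen=True)
class VisitSegment:
    """One maximal interval the path spends inside a focal circle.

    ``duration`` is the time spent *inside*; for an unmerged segment it equals
    ``t_out - t_in``, while for a segment produced by merging visits across
    short excursions it is the sum of the merged inside durations only.
    ``kind`` locates the segment relative to the focal fix: the segment
    containing the focal time is ``focal``, earlier ones are ``backward``,
    later ones ``forward``.  ``censored_start``/``censored_end`` flag segments
    truncated by the ends of the recording.
    """

    t_in: float
    t_out: float
    duration: float
    kind: Literal["backward", "focal", "forward"]
    censored_start: bool = False
    censored_end: bool = False


@dataclass
class RevisitHistory:
    """The ordered visit segments of one (focal fix, radius) circle."""

    focal_index: int
    r: float
    segments: list[VisitSegment] = field(default_factory=list)

    @property
    def n_visits(self) -> int:
        return len(self.segments)

    @property
    def mean_visit_duration(self) -> float:
        return float(np.mean([s.duration for s in self.segments]))

    @property
    def total_time(self) -> float:
        return float(np.sum([s.duration for s in self.segments]))

    @property
    def focal_segment(self) -> VisitSegment:
        for s in self.segments:
            if s.kind == "focal":
                return s
        raise ValueError("revisit history lacks a focal segment")


def _validate(traj: Trajectory, i: int, r: float) -> None:
    n = len(traj)
    if n < 2:
        raise ValueError("residence-time computations need at least 2 fixes")
    if not 0 <= i < n:
        raise IndexError(f"fix index {i} out of range for {n} fixes")
    if not r > 0:
        raise ValueError(f"radius must be positive, got {r!r}")


def _outward_crossing(t, x, y, seg, cx, cy, r):
    """Interpolated time at which segment ``seg -> seg+1`` leaves the circle
    (distance rises through r); vectorized over ``seg``.  The caller guarantees
    d[seg] < r <= d[seg+1], so the displacement is nonzero and the larger
    quadratic root is the crossing."""
    ax, ay = x[seg] - cx, y[seg] - cy
    dx, dy = x[seg + 1] - x[seg], y[seg + 1] - y[seg]
    qa = dx * dx + dy * dy
    qb = 2.0 * (ax * dx + ay * dy)
    qc = ax * ax + ay * ay - r * r
    sq = np.sqrt(np.maximum(qb * qb - 4.0 * qa * qc, 0.0))
    s = np.clip((-qb + sq) / (2.0 * qa), 0.0, 1.0)
    return t[seg] + s * (t[seg + 1] - t[seg])


def _inward_crossing(t, x, y, seg, cx, cy, r):
    """Interpolated time at which segment ``seg -> seg+1`` enters the circle
    (distance falls through r): the smaller quadratic root."""
    ax, ay = x[seg] - cx, y[seg] - cy
    dx, dy = x[seg + 1] - x[seg], y[seg + 1] - y[seg]
    qa = dx * dx + dy * dy
    qb = 2.0 * (ax * dx + ay * dy)
    qc = ax * ax + ay * ay - r * r
    sq = np.sqrt(np.maximum(qb * qb - 4.0 * qa * qc, 0.0))
    s = np.clip((-qb - sq) / (2.0 * qa), 0.0, 1.0)
    return t[seg] + s * (t[seg + 1] - t[seg])


def first_passage_time(
    traj: Trajectory,
    i: int,
    r: float,
    direction: Direction = "forward",
    method: Method = "interpolate",
) -> FptResult:
    """Time from fix ``i`` to the first crossing of the circle of radius ``r``
    centred on fix ``i``, scanning in ``direction``.

    Returns ``(duration, censored)``; ``censored`` is true when the path ends
    (or starts) before leaving the circle, in which case the duration runs to
    the path terminus.
    """
    _validate(traj, i, r)
    t, x, y = traj.t, traj.x, traj.y
    d = np.hypot(x - x[i], y - y[i])
    if direction == "forward":
        ahead = d[i + 1 :]
        running = np.maximum.accumulate(ahead) if ahead.size else ahead
        j = int(np.searchsorted(running, r))
        if j == ahead.size:
            return FptResult(float(t[-1] - t[i]), True)
        seg = i + j  # d[seg] < r <= d[seg+1]
        if method == "discrete":
            return FptResult(float(t[seg + 1] - t[i]), False)
        tc = _outward_crossing(t, x, y, np.array([seg]), x[i], y[i], r)[0]
        return FptResult(float(tc - t[i]), False)
    elif direction == "backward":
        behind = d[i - 1 :: -1] if i > 0 else d[:0]
        running = np.maximum.accumulate(behind) if behind.size else behind
        j = int(np.searchsorted(running, r))
        if j == behind.size:
            return FptResult(float(t[i] - t[0]), True)
        seg = i - 1 - j  # d[seg] >= r > d[seg+1]
        if method == "discrete":
            return FptResult(float(t[i] - t[seg]), False)
        tc = _inward_crossing(t, x, y, np.array([seg]), x[i], y[i], r)[0]
        return FptResult(float(t[i] - tc), False)
    raise ValueError(f"direction must be 'backward' or 'forward', got {direction!r}")


def residence_time(
    traj: Trajectory, i: int, r: float, method: Method = "interpolate"
) -> FptResult:
    """Residence time at fix ``i``: backward FPT + forward FPT, i.e. the total
    time inside the circle from first entry to first exit.  Censored when
    either side runs into a path terminus."""
    back = first_passage_time(traj, i, r, "backward", method)
    fwd = first_passage_time(traj, i, r, "forward", method)
    return FptResult(back.duration + fwd.duration, back.censored or fwd.censored)


@dataclass
class ResidenceTimes:
    """Residence times of every fix at every radius of a grid.

    ``durations`` and ``censored`` have shape ``(n_fixes, n_radii)``.
    """

    radii: np.ndarray
    durations: np.ndarray
    censored: np.ndarray

    def to_long_dataframe(self, traj: Trajectory) -> pd.DataFrame:
        """Long-format table: one row per focal fix per radius."""
        n, m = self.durations.shape
        return pd.DataFrame(
            {
                "fix": np.repeat(np.arange(n), m),
                "t": np.repeat(traj.t, m),
                "x": np.repeat(traj.x, m),
                "y": np.repeat(traj.y, m),
                "r": np.tile(self.radii, n),
                "rt": self.durations.ravel(),
                "censored": self.censored.ravel(),
            }
        )


def residence_time_matrix(
    traj: Trajectory,
    radii: Sequence[float],
    method: Method = "interpolate",
) -> ResidenceTimes:
    """Residence time of every fix for every radius in one sweep.

    Equivalent to calling :func:`residence_time` for every ``(i, r)`` pair but
    organized for speed: per focal fix the running maximum of the distance
    profile is monotone, so the first-crossing segment for the whole radius
    grid is found with a single binary search per direction.
    """
    radii = np.asarray(radii, dtype=float)
    if radii.ndim != 1 or radii.size == 0:
        raise ValueError("radii must be a non-empty 1-d sequence")
    if np.any(radii <= 0) or np.any(np.diff(radii) <= 0):
        raise ValueError("radii must be positive and strictly increasing")
    n = len(traj)
    if n < 2:
        raise ValueError("residence-time computations need at least 2 fixes")
    m = radii.size
    t, x, y = traj.t, traj.x, traj.y
    durations = np.empty((n, m))
    censored = np.zeros((n, m), dtype=bool)

    for i in range(n):
        d = np.hypot(x - x[i], y - y[i])

        ahead = d[i + 1 :]
        if ahead.size:
            running = np.maximum.accumulate(ahead)
            jf = np.searchsorted(running, radii)
        else:
            jf = np.zeros(m, dtype=int)
        cens_f = jf == ahead.size
        fwd = np.full(m, t[-1] - t[i])
        live = ~cens_f
        if live.any():
            seg = i + jf[live]
            if method == "discrete":
                fwd[live] = t[seg + 1] - t[i]
            else:
                fwd[live] = _outward_crossing(t, x, y, seg, x[i], y[i], radii[live]) - t[i]

        behind = d[i - 1 :: -1] if i > 0 else d[:0]
        if behind.size:
            running = np.maximum.accumulate(behind)
            jb = np.searchsorted(running, radii)
        else:
            jb = np.zeros(m, dtype=int)
        cens_b = jb == behind.size
        back = np.full(m, t[i] - t[0])
        live = ~cens_b
        if live.any():
            seg = i - 1 - jb[live]
            if method == "discrete":
                back[live] = t[i] - t[seg]
            else:
                back[live] = t[i] - _inward_crossing(t, x, y, seg, x[i], y[i], radii[live])

        durations[i] = back + fwd
        censored[i] = cens_b | cens_f

    return ResidenceTimes(radii=radii, durations=durations, censored=censored)


def merged_residence_time_matrix(
    traj: Trajectory,
    radii: Sequence[float],
    max_time_outside: float,
    compiled: bool = True,
) -> ResidenceTimes:
    """Merged residence time of every fix at every radius.

    The focal visit is extended across excursions outside the circle shorter
    than ``max_time_outside``; the duration sums inside time only.  With a
    threshold of 0 this equals :func:`residence_time_matrix`.  A merged
    visit is censored when the path terminates inside the circle or during
    an excursion still shorter than the threshold (a further mergeable
    visit cannot be ruled out).
    """
    radii = np.asarray(radii, dtype=float)
    if radii.ndim != 1 or radii.size == 0:
        raise ValueError("radii must be a non-empty 1-d sequence")
    if np.any(radii <= 0) or np.any(np.diff(radii) <= 0):
        raise ValueError("radii must be positive and strictly increasing")
    if max_time_outside < 0:
        raise ValueError("max_time_outside must be >= 0")
    durations, censored = merged_residence_matrix(
        traj.t, traj.x, traj.y, radii, max_time_outside, compiled=compiled
    )
    return ResidenceTimes(radii=radii, durations=durations, censored=censored)


# ---------------------------------------------------------------------------
# revisit histories
# ---------------------------------------------------------------------------

def _inside_intervals(t, x, y, cx, cy, r):
    """All maximal intervals the interpolated path spends strictly inside the
    circle ``(cx, cy, r)``.

    Returns ``(t_in, t_out, cens_start, cens_end)`` arrays sorted by entry
    time.  Handles three cases: runs of inside fixes (entry/exit refined on
    the flanking segments), a path that starts or ends inside (censored), and
    segments that dip through the circle between two outside fixes.
    """
    d2 = (x - cx) ** 2 + (y - cy) ** 2
    r2 = r * r
    inside = d2 < r2
    n = t.size

    t_ins, t_outs, cs, ce = [], [], [], []

    if inside.any():
        starts = np.flatnonzero(inside & ~np.r_[False, inside[:-1]])
        ends = np.flatnonzero(inside & ~np.r_[inside[1:], False])
        for a, b in zip(starts, ends):
            if a == 0:
                t_ins.append(t[0])
                cs.append(True)
            else:
                t_ins.append(
                    float(_inward_crossing(t, x, y, np.array([a - 1]), cx, cy, r)[0])
                )
                cs.append(False)
            if b == n - 1:
                t_outs.append(t[-1])
                ce.append(True)
            else:
                t_outs.append(
                    float(_outward_crossing(t, x, y, np.array([b]), cx, cy, r)[0])
                )
                ce.append(False)

    # circle transits with both endpoints outside: the distance along a
    # segment is convex, so a dip below r shows up as two interior roots
    both_out = ~inside[:-1] & ~inside[1:]
    if both_out.any():
        seg = np.flatnonzero(both_out)
        ax, ay = x[seg] - cx, y[seg] - cy
        dx, dy = x[seg + 1] - x[seg], y[seg + 1] - y[seg]
        qa = dx * dx + dy * dy
        qb = 2.0 * (ax * dx + ay * dy)
        qc = ax * ax + ay * ay - r2
        with np.errstate(invalid="ignore", divide="ignore"):
            disc = qb * qb - 4.0 * qa * qc
            ok = (qa > 0) & (disc > 0)
            sq = np.sqrt(np.where(ok, disc, 0.0))
            s1 = np.where(ok, (-qb - sq) / (2.0 * qa), 0.0)
            s2 = np.where(ok, (-qb + sq) / (2.0 * qa), 0.0)
        ok &= (s1 > 0.0) & (s2 < 1.0) & (s2 > s1)
        for k, a1, a2 in zip(seg[ok], s1[ok], s2[ok]):
            dt = t[k + 1] - t[k]
            t_ins.append(float(t[k] + a1 * dt))
            t_outs.append(float(t[k] + a2 * dt))
            cs.append(False)
            ce.append(False)

    if not t_ins:
        return (np.empty(0), np.empty(0), np.empty(0, bool), np.empty(0, bool))
    order = np.argsort(t_ins)
    return (
        np.asarray(t_ins)[order],
        np.asarray(t_outs)[order],
        np.asarray(cs, dtype=bool)[order],
        np.asarray(ce, dtype=bool)[order],
    )


def _merge_intervals(t_in, t_out, cs, ce, max_time_outside):
    """Merge consecutive visits whose gap outside the circle is shorter than
    ``max_time_outside`` (strict).  The merged duration sums inside time only,
    so the total time inside is invariant to the threshold."""
    durs = t_out - t_in
    if t_in.size <= 1 or max_time_outside <= 0:
        return t_in, t_out, durs, cs, ce
    gaps = t_in[1:] - t_out[:-1]
    new_group = np.r_[True, gaps >= max_time_outside]
    group = np.cumsum(new_group) - 1
    k = group[-1] + 1
    first = np.r_[np.flatnonzero(new_group)]
    last = np.r_[first[1:] - 1, t_in.size - 1]
    merged_dur = np.zeros(k)
    np.add.at(merged_dur, group, durs)
    return t_in[first], t_out[last], merged_dur, cs[first], ce[last]


def revisit_history(
    traj: Trajectory,
    i: int,
    r: float,
    max_time_outside: float = 0.0,
) -> RevisitHistory:
    """Full revisit history of the circle of radius ``r`` around fix ``i``.

    Every maximal interval the interpolated path spends inside the circle
    becomes a visit segment; consecutive segments separated by less than
    ``max_time_outside`` outside the circle are merged into one visit whose
    duration sums inside time only.  ``max_time_outside=0`` keeps raw
    segments; ``inf`` collapses everything into a single visit.  The focal
    fix is always inside its own circle, so there is at least one segment.
    """
    _validate(traj, i, r)
    if max_time_outside < 0:
        raise ValueError("max_time_outside must be >= 0")
    t, x, y = traj.t, traj.x, traj.y
    t_in, t_out, cs, ce = _inside_intervals(t, x, y, x[i], y[i], r)
    t_in, t_out, durs, cs, ce = _merge_intervals(t_in, t_out, cs, ce, max_time_outside)
    t_focal = t[i]
    segments = []
    for a, b, dur, c1, c2 in zip(t_in, t_out, durs, cs, ce):
        if b < t_focal:
            kind = "backward"
        elif a > t_focal:
            kind = "forward"
        else:
            kind = "focal"
        segments.append(
            VisitSegment(
                t_in=float(a),
                t_out=float(b),
                duration=float(dur),
                kind=kind,
                censored_start=bool(c1),
                censored_end=bool(c2),
            )
        )
    return RevisitHistory(focal_index=i, r=float(r), segments=segments)


def revisit_stats(
    traj: Trajectory,
    r: float,
    max_time_outside: float = 0.0,
) -> pd.DataFrame:
    """Per-fix revisit summaries at one radius.

    Returns a frame indexed by fix with columns ``n_visits``,
    ``mean_visit_duration`` and ``total_time`` — the criterion values the
    place-identification algorithm filters on.
    """
    _validate(traj, 0, r)
    t, x, y = traj.t, traj.x, traj.y
    n = len(traj)
    n_visits = np.empty(n, dtype=int)
    mean_dur = np.empty(n)
    total = np.empty(n)
    for i in range(n):
        t_in, t_out, cs, ce = _inside_intervals(t, x, y, x[i], y[i], r)
        _, _, durs, _, _ = _merge_intervals(t_in, t_out, cs, ce, max_time_outside)
        n_visits[i] = durs.size
        mean_dur[i] = durs.mean() if durs.size else 0.0
        total[i] = durs.sum()
    return pd.DataFrame(
        {"n_visits": n_visits, "mean_visit_duration": mean_dur, "total_time": total}
    )
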