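"""Trajectory container, delimited-text I/O, resampling, and circle-crossing geometry.

A trajectory is an ordered sequence of time-stamped planar fixes ``(t, x, y)``.
All analysis modules consume this container.  Times are plain numbers (seconds,
simulation steps, ...): calendar timestamps are converted to seconds since the
first fix at the I/O boundary and never appear internally.  Coordinates are
assumed planar; no projection support is provided.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)

#: Movebank export column names, auto-detected when no explicit mapping is given.
MOVEBANK_COLUMNS = {"t": "timestamp", "x": "location-long", "y": "location-lat"}


@dataclass(frozen=True)
class Fix:
    """A single relocation: time ``t`` and planar coordinates ``(x, y)``."""

    t: float
    x: float
    y: float


class Trajectory:
    """An ordered, strictly time-increasing sequence of fixes.

    Parameters
    ----------
    t, x, y : array-like of float
        Timestamps and planar coordinates, one entry per fix.  Timestamps must
        be finite and strictly increasing.
    crs_note : str
        Free-text provenance of the coordinate unit (e.g. ``"grid cells"``,
        ``"UTM metres"``).  Informational only.
    """

    def __init__(self, t, x, y, crs_note: str = "") -> None:
        t = np.asarray(t, dtype=float)
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if not (t.shape == x.shape == y.shape) or t.ndim != 1:
            raise DataError("t, x, y must be 1-d arrays of equal length")
        if t.size == 0:
            raise DataError("a trajectory needs at least one fix")
        for name, arr in (("t", t), ("x", x), ("y", y)):
            if not np.all(np.isfinite(arr)):
                idx = int(np.flatnonzero(~np.isfinite(arr))[0])
                raise DataError(f"non-finite value in column '{name}' at row {idx}")
        dt = np.diff(t)
        if np.any(dt <= 0):
            idx = int(np.flatnonzero(dt <= 0)[0])
            raise DataError(
                f"timestamps must be strictly increasing; rows {idx} and {idx + 1} "
                f"have t={t[idx]!r} and t={t[idx + 1]!r}"
            )
        self.t = t
        self.x = x
        self.y = y
        self.crs_note = crs_note
        self.t.setflags(write=False)
        self.x.setflags(write=False)
        self.y.setflags(write=False)

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return self.t.size

    def __iter__(self) -> Iterator[Fix]:
        for ti, xi, yi in zip(self.t, self.x, self.y):
            yield Fix(float(ti), float(xi), float(yi))

    def __getitem__(self, i: int) -> Fix:
        return Fix(float(self.t[i]), float(self.x[i]), float(self.y[i]))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Trajectory):
            return NotImplemented
        return (
            np.array_equal(self.t, other.t)
            and np.array_equal(self.x, other.x)
            and np.array_equal(self.y, other.y)
        )

    def __repr__(self) -> str:
        return f"<Trajectory of {len(self)} fixes, duration {self.duration:g}>"

    # -- derived quantities ------------------------------------------------
    @property
    def duration(self) -> float:
        """Total time span of the path."""
        return float(self.t[-1] - self.t[0])

    @property
    def xy(self) -> np.ndarray:
        """``(n, 2)`` array of coordinates."""
        return np.column_stack([self.x, self.y])

    def step_lengths(self) -> np.ndarray:
        """Euclidean displacement between consecutive fixes."""
        return np.hypot(np.diff(self.x), np.diff(self.y))

    def median_step_length(self) -> float:
        return float(np.median(self.step_lengths()))

    def bounding_box(self) -> tuple[float, float, float, float]:
        """``(xmin, ymin, xmax, ymax)`` of the path."""
        return (
            float(self.x.min()),
            float(self.y.min()),
            float(self.x.max()),
            float(self.y.max()),
        )

    def bounding_box_diagonal(self) -> float:
        xmin, ymin, xmax, ymax = self.bounding_box()
        return math.hypot(xmax - xmin, ymax - ymin)

    # -- transforms --------------------------------------------------------
    def resample(self, k: int) -> "Trajectory":
        """Keep every ``k``-th fix (indices 0, k, 2k, ...), retaining timestamps.

        Thinning a 1-Hz path by ``k`` therefore yields inter-fix durations of
        ``k`` time units, mimicking a coarser GPS schedule.
        """
        if not isinstance(k, (int, np.integer)) or k < 1:
            raise ValueError(f"resample factor must be a positive integer, got {k!r}")
        return Trajectory(self.t[::k], self.x[::k], self.y[::k], self.crs_note)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "x": self.x, "y": self.y})

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, crs_note: str = "") -> "Trajectory":
        return cls(df["t"].to_numpy(), df["x"].to_numpy(), df["y"].to_numpy(), crs_note)


def resample(traj: Trajectory, k: int) -> Trajectory:
    """Functional alias for :meth:`Trajectory.resample`."""
    return traj.resample(k)


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------

def _coerce_times(values: pd.Series) -> np.ndarray:
    """Numeric timestamps pass through; anything else is parsed as ISO-8601
    and converted to seconds since the first fix."""
    numeric = pd.to_numeric(values, errors="coerce")
    if not numeric.isna().any():
        return numeric.to_numpy(dtype=float)
    try:
        stamps = pd.to_datetime(values, utc=True, format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise DataError(f"timestamps are neither numeric nor ISO-8601: {exc}") from exc
    seconds = (stamps - stamps.iloc[0]).dt.total_seconds()
    return seconds.to_numpy(dtype=float)


def read_trajectory(
    path: str | Path,
    colmap: Mapping[str, str] | None = None,
    crs_note: str = "",
) -> Trajectory:
    """Read a trajectory from a delimited text file (CSV/TSV with header).

    Parameters
    ----------
    path : path
        Input file; the delimiter is sniffed.
    colmap : mapping, optional
        Maps the logical names ``t``, ``x``, ``y`` to column names in the
        file.  When omitted, plain ``t,x,y`` headers are used if present, and
        Movebank-style headers (``timestamp``, ``location-long``,
        ``location-lat``) are auto-detected with a warning that coordinates
        are treated as planar.

    Returns
    -------
    Trajectory
        Fixes sorted by time.  Duplicate timestamps raise :class:`DataError`.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    if colmap is None:
        if {"t", "x", "y"}.issubset(df.columns):
            colmap = {"t": "t", "x": "x", "y": "y"}
        elif set(MOVEBANK_COLUMNS.values()).issubset(df.columns):
            colmap = dict(MOVEBANK_COLUMNS)
            logger.warning(
                "Movebank columns detected in %s; longitude/latitude are used as "
                "planar x/y without projection — distances will only be meaningful "
                "for small extents or pre-projected data.",
                path,
            )
        else:
            raise ConfigError(
                f"cannot infer columns from header {list(df.columns)}; "
                "pass an explicit column mapping"
            )
    for logical in ("t", "x", "y"):
        if logical not in colmap:
            raise ConfigError(f"column mapping lacks an entry for '{logical}'")
        if colmap[logical] not in df.columns:
            raise ConfigError(
                f"mapped column '{colmap[logical]}' (for '{logical}') not found in {path}"
            )
    t = _coerce_times(df[colmap["t"]])
    x = pd.to_numeric(df[colmap["x"]], errors="raise").to_numpy(dtype=float)
    y = pd.to_numeric(df[colmap["y"]], errors="raise").to_numpy(dtype=float)

    order = np.argsort(t, kind="stable")
    t, x, y = t[order], x[order], y[order]
    dup = np.flatnonzero(np.diff(t) == 0)
    if dup.size:
        row = int(order[dup[0] + 1])
        raise DataError(f"duplicate timestamp t={t[dup[0]]!r} at input row {row}")
    return Trajectory(t, x, y, crs_note or f"read from {path.name}")


def write_trajectory(
    traj: Trajectory,
    path: str | Path,
    provenance: Mapping[str, object] | None = None,
) -> None:
    """Write a trajectory as ``t,x,y`` CSV plus a JSON provenance sidecar.

    The sidecar (``<path>.provenance.json``) records the number of fixes,
    the coordinate note, and any extra mapping passed in ``provenance``
    (e.g. source file and resample factor).
    """
    path = Path(path)
    traj.to_dataframe().to_csv(path, index=False)
    meta = {"n_fixes": len(traj), "crs_note": traj.crs_note}
    if provenance:
        meta.update(provenance)
    sidecar = path.with_name(path.name + ".provenance.json")
    sidecar.write_text(json.dumps(meta, indent=2, default=str) + "\n")


# ---------------------------------------------------------------------------
# circle-crossing geometry
# ---------------------------------------------------------------------------

def _segment_circle_coefficients(ax, ay, bx, by, cx, cy, r):
    """Quadratic coefficients of ``|A + s(B-A) - C|^2 - r^2`` in the segment
    fraction ``s``; shared by the scalar and vectorized crossing solvers."""
    dx, dy = bx - ax, by - ay
    fx, fy = ax - cx, ay - cy
    qa = dx * dx + dy * dy
    qb = 2.0 * (fx * dx + fy * dy)
    qc = fx * fx + fy * fy - r * r
    return qa, qb, qc


def circle_crossing_time(
    a: Fix | Sequence[float],
    b: Fix | Sequence[float],
    center: Sequence[float],
    r: float,
) -> float | None:
    """Earliest time in ``(a.t, b.t]`` at which the straight segment from fix
    ``a`` to fix ``b`` (linear interpolation in space and time) crosses the
    circle of radius ``r`` around ``center``; ``None`` if it never does.

    The inside region is the open disc (distance strictly below ``r``); a fix
    sitting exactly on the boundary counts as outside.
    """
    if r <= 0:
        raise ValueError(f"radius must be positive, got {r!r}")
    at, ax, ay = (a.t, a.x, a.y) if isinstance(a, Fix) else (a[0], a[1], a[2])
    bt, bx, by = (b.t, b.x, b.y) if isinstance(b, Fix) else (b[0], b[1], b[2])
    if not at < bt:
        raise ValueError(f"fix times must satisfy a.t < b.t, got {at!r} >= {bt!r}")
    qa, qb, qc = _segment_circle_coefficients(ax, ay, bx, by, center[0], center[1], r)
    if qa == 0.0:  # zero displacement: distance is constant, never crosses
        return None
    disc = qb * qb - 4.0 * qa * qc
    if disc < 0:
        return None
    sq = math.sqrt(disc)
    for s in sorted(((-qb - sq) / (2 * qa), (-qb + sq) / (2 * qa))):
        if 0.0 < s <= 1.0:
            return at + s * (bt - at)
    return None
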