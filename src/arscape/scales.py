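"""Variance-scale curves and detection of distinct area-restricted-search scales.

When the radius of the virtual circle matches the spatial scale of an ARS
bout, residence times contrast maximally between searching and transiting
parts of the path, so the spread of RT across fixes — plotted against radius
— peaks at the characteristic ARS scale.  Two spread statistics are
supported: the variance of log(RT) (classical; assumes roughly log-normal
RT) and the coefficient of variation of RT (better behaved at small radii).
A path shaped by nested search behaviour produces several peaks, one per
scale domain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks as _scipy_find_peaks

from .residence import (
    Method,
    merged_residence_time_matrix,
    residence_time_matrix,
)
from .trajectory import Trajectory

logger = logging.getLogger(__name__)

CurveMode = Literal["var_log_rt", "cv_rt"]

#: defaults for the radius grid and peak detection, also used by the CLI
DEFAULT_N_RADII = 30
DEFAULT_MIN_PROMINENCE_FRAC = 0.05
DEFAULT_SMOOTH_WINDOW = 3


@dataclass
class VarianceScaleCurve:
    """Spread-of-RT statistic per radius.

    ``statistic`` carries NaN where fewer than 2 valid residence times were
    available; ``n_valid`` counts the RTs actually used per radius.
    """

    radii: np.ndarray
    statistic: np.ndarray
    mode: CurveMode
    n_valid: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "r": self.radii,
                "statistic": self.statistic,
                "n_valid": self.n_valid,
                "mode": self.mode,
            }
        )


@dataclass(frozen=True)
class Peak:
    """A local maximum of the (smoothed) variance-scale curve.

    ``prominence`` is the height above the higher of the two flanking minima
    (the stretches down to the neighbouring peaks or curve ends).
    ``is_r0`` marks a maximum sitting at the smallest grid radius — the
    signature of resting stops, reported separately and not counted as an
    ARS scale.
    """

    r_peak: float
    height: float
    prominence: float
    is_r0: bool = False


@dataclass
class PeakResult:
    """Interior ARS-scale peaks (ordered by radius) plus the optional
    smallest-radius endpoint maximum."""

    peaks: list[Peak]
    r0_peak: Peak | None = None

    @property
    def n_scales(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)


def default_radius_grid(
    traj: Trajectory,
    n_radii: int = DEFAULT_N_RADII,
    r_min: float | None = None,
    r_max: float | None = None,
) -> np.ndarray:
    """Logarithmically spaced radius grid adapted to the path.

    Spans half the median step length to a quarter of the bounding-box
    diagonal (above which circles approach the whole range and censoring
    dominates).  The lower bound deliberately sits below the typical
    displacement: intensive-search bouts move more slowly than travel, so
    their spatial scale can be smaller than the median step, and crossing
    times are interpolated rather than snapped to fixes.  Log spacing
    resolves nested scales evenly in ratio.
    """
    if r_min is None:
        r_min = 0.5 * traj.median_step_length()
    if r_max is None:
        r_max = traj.bounding_box_diagonal() / 4.0
    if not (r_min > 0 and r_max > r_min):
        raise ValueError(
            f"degenerate radius range [{r_min}, {r_max}]; "
            "pass r_min/r_max explicitly for stationary or tiny paths"
        )
    return np.geomspace(r_min, r_max, n_radii)


def variance_scale_curve(
    traj: Trajectory,
    radii: Sequence[float] | None = None,
    mode: CurveMode = "cv_rt",
    include_censored: bool = False,
    max_time_outside: float = 0.0,
    method: Method = "interpolate",
) -> VarianceScaleCurve:
    """Spread of residence time across all fixes, per radius.

    Parameters
    ----------
    traj : Trajectory
    radii : sequence of float, optional
        Strictly increasing radius grid; defaults to
        :func:`default_radius_grid`.
    mode : {"cv_rt", "var_log_rt"}
        ``cv_rt``: sample SD of RT divided by mean RT.  ``var_log_rt``:
        unbiased sample variance of natural-log RT (zero RTs are excluded
        with a logged count).
    include_censored : bool
        RTs truncated by the ends of the recording bias spread downward at
        large radii and are excluded by default.
    max_time_outside : float
        When positive, the RT of each fix is the duration of its merged
        focal visit — excursions outside the circle shorter than this
        threshold do not terminate the visit — rather than the plain
        first-entry-to-first-exit time.  Essential when the movement
        includes out-and-back excursions (forays) at scales between the
        circle radius and the bout of interest.
    """
    if radii is None:
        radii = default_radius_grid(traj)
    radii = np.asarray(radii, dtype=float)

    if max_time_outside > 0:
        rt = merged_residence_time_matrix(traj, radii, max_time_outside)
        durations, censored = rt.durations, rt.censored
    else:
        rt = residence_time_matrix(traj, radii, method=method)
        durations, censored = rt.durations, rt.censored

    valid = np.ones_like(censored, dtype=bool) if include_censored else ~censored
    if mode == "var_log_rt":
        zero = valid & (durations <= 0)
        n_zero = int(zero.sum())
        if n_zero:
            logger.info(
                "var_log_rt: excluded %d zero residence times "
                "(duplicate-position fixes)", n_zero
            )
        valid &= durations > 0
    elif mode != "cv_rt":
        raise ValueError(f"unknown curve mode {mode!r}")

    n_valid = valid.sum(axis=0)
    stat = np.full(radii.size, np.nan)
    for j in range(radii.size):
        if n_valid[j] < 2:
            continue
        vals = durations[valid[:, j], j]
        if mode == "var_log_rt":
            stat[j] = np.var(np.log(vals), ddof=1)
        else:
            mean = vals.mean()
            stat[j] = np.nan if mean == 0 else vals.std(ddof=1) / mean
    return VarianceScaleCurve(radii=radii, statistic=stat, mode=mode, n_valid=n_valid)


# ---------------------------------------------------------------------------
# peak detection
# ---------------------------------------------------------------------------

def _moving_average(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values.copy()
    kernel = np.ones(window)
    num = np.convolve(values, kernel, mode="same")
    den = np.convolve(np.ones_like(values), kernel, mode="same")
    return num / den


def _flank_minima(s: np.ndarray, peaks: list[int]) -> list[tuple[float, float]]:
    """Minimum of ``s`` between each peak and its neighbouring peak (or the
    series end) on either side."""
    out = []
    for k, p in enumerate(peaks):
        lo = peaks[k - 1] if k > 0 else 0
        hi = peaks[k + 1] if k < len(peaks) - 1 else s.size - 1
        left = s[lo : p + 1].min()
        right = s[p : hi + 1].min()
        out.append((left, right))
    return out


def detect_peaks(
    curve: VarianceScaleCurve,
    min_prominence_frac: float = DEFAULT_MIN_PROMINENCE_FRAC,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
) -> PeakResult:
    """Find the distinct interior maxima of a variance-scale curve.

    The statistic is smoothed by a centred moving average, then interior
    local maxima are kept while any maximum whose prominence (height above
    the higher flanking minimum) falls below ``min_prominence_frac`` times
    the smoothed curve's total range is discarded, shallowest first, with
    flanking minima recomputed after each removal.  A maximum at the
    smallest radius cannot be an ARS scale (it reflects stops at the
    sampling scale) and is returned separately as the ``r0`` peak.
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError(f"smooth_window must be a positive odd integer, got {smooth_window}")
    mask = np.isfinite(curve.statistic)
    if mask.sum() < 3:
        raise ValueError("peak detection needs at least 3 non-missing curve points")
    radii = curve.radii[mask]
    s = _moving_average(curve.statistic[mask], smooth_window)
    srange = float(s.max() - s.min())
    threshold = min_prominence_frac * srange

    candidates = list(_scipy_find_peaks(s)[0])
    while candidates:
        proms = [s[p] - max(lo, hi) for p, (lo, hi) in
                 zip(candidates, _flank_minima(s, candidates))]
        worst = int(np.argmin(proms))
        if proms[worst] >= threshold and srange > 0:
            break
        candidates.pop(worst)

    flanks = _flank_minima(s, candidates)
    peaks = [
        Peak(
            r_peak=float(radii[p]),
            height=float(s[p]),
            prominence=float(s[p] - max(lo, hi)),
        )
        for p, (lo, hi) in zip(candidates, flanks)
    ]

    r0_peak = None
    if s.size >= 2 and s[0] > s[1] and srange > 0:
        first_interior = candidates[0] if candidates else s.size - 1
        r0_peak = Peak(
            r_peak=float(radii[0]),
            height=float(s[0]),
            prominence=float(s[0] - s[: first_interior + 1].min()),
            is_r0=True,
        )
    return PeakResult(peaks=peaks, r0_peak=r0_peak)


def characteristic_radius(
    peaks: PeakResult | Sequence[Peak],
    policy: Literal["per_peak", "upper_limit"] = "upper_limit",
    domain_ratio: float = 2.0,
):
    """Characteristic ARS radius (or radii) from detected peaks.

    ``per_peak`` returns every peak radius.  ``upper_limit`` groups peaks
    into scale domains — consecutive peaks whose radii lie within a factor
    ``domain_ratio`` of each other belong to one domain, nested scales being
    separated multiplicatively — and returns the largest radius of each
    domain.  Working at the upper edge of a domain avoids under-sized
    circles, which would split one search bout into spurious revisits.

    Raises ``ValueError`` when no peak was detected (no ARS scale).
    """
    plist = list(peaks.peaks if isinstance(peaks, PeakResult) else peaks)
    plist = [p for p in plist if not p.is_r0]
    if not plist:
        raise ValueError("no ARS scale detected: peak list is empty")
    radii = sorted(p.r_peak for p in plist)
    if policy == "per_peak":
        return radii
    if policy != "upper_limit":
        raise ValueError(f"unknown policy {policy!r}")
    domains: list[list[float]] = [[radii[0]]]
    for r in radii[1:]:
        if r <= domains[-1][-1] * domain_ratio:
            domains[-1].append(r)
        else:
            domains.append([r])
    uppers = [d[-1] for d in domains]
    return uppers[0] if len(uppers) == 1 else uppers


def count_ars_scales(result: PeakResult) -> int:
    """Number of distinct ARS scales: interior peaks, excluding the
    smallest-radius (resting-stop) maximum."""
    return result.n_scales
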