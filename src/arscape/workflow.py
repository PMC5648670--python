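"""The end-to-end two-step analysis and the canonical validation protocol.

Step one detects the distinct spatial scales of area-restricted search from
the variance-scale curve; step two identifies revisited ARS places at each
characteristic radius.  :func:`two_step_analysis` bundles both with
reporting; :func:`scenario_analysis` runs the fixed validation protocol on a
simulated scenario (the settings every validation battery uses, kept in
:data:`VALIDATION` so tests, scripts and the CLI agree).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import places as places_mod
from .scales import (
    DEFAULT_MIN_PROMINENCE_FRAC,
    DEFAULT_SMOOTH_WINDOW,
    PeakResult,
    VarianceScaleCurve,
    characteristic_radius,
    detect_peaks,
    variance_scale_curve,
)
from .simulator import GroundTruthLog, ResourceMap, scenario_configs, simulate
from .trajectory import Trajectory


@dataclass(frozen=True)
class ValidationProtocol:
    """Fixed analysis settings of the simulation validation studies.

    Simulated walks are thinned 1-in-10 to mimic GPS sampling.  Curves use
    the variance of log(RT) (robust to the resting-stop signature at the
    smallest radii) with visit merging across excursions shorter than
    ``max_time_outside`` steps — above the within-clump foray gaps bounded
    by the clump giving-up time, below typical between-clump transit — so
    that multi-scale residence accrues.  Peak detection uses the package
    defaults (prominence fraction 0.05, smoothing window 3).
    """

    resample_factor: int = 10
    mode: str = "var_log_rt"
    max_time_outside: float = 2500.0
    min_prominence_frac: float = DEFAULT_MIN_PROMINENCE_FRAC
    smooth_window: int = DEFAULT_SMOOTH_WINDOW
    place_criterion: str = "mean_visit_duration"
    place_max_time_outside: float = 300.0  # the patch giving-up time


VALIDATION = ValidationProtocol()


@dataclass
class ScenarioResult:
    """One simulated run analysed under the validation protocol."""

    trajectory: Trajectory
    resampled: Trajectory
    log: GroundTruthLog
    resource_map: ResourceMap
    curve: VarianceScaleCurve
    peaks: PeakResult

    @property
    def n_scales(self) -> int:
        return len(self.peaks.peaks)


def scenario_analysis(
    name: str,
    seed: int,
    protocol: ValidationProtocol = VALIDATION,
    **overrides,
) -> ScenarioResult:
    """Simulate one scenario run and analyse it under the fixed protocol."""
    map_cfg, forager_cfg = scenario_configs(name, seed=seed, **overrides)
    traj, log, rmap = simulate(map_cfg, forager_cfg)
    rs = traj.resample(protocol.resample_factor)
    curve = variance_scale_curve(
        rs, mode=protocol.mode, max_time_outside=protocol.max_time_outside
    )
    peaks = detect_peaks(
        curve,
        min_prominence_frac=protocol.min_prominence_frac,
        smooth_window=protocol.smooth_window,
    )
    return ScenarioResult(
        trajectory=traj, resampled=rs, log=log, resource_map=rmap,
        curve=curve, peaks=peaks,
    )


def peak_count_battery(
    name: str,
    seeds: Sequence[int],
    protocol: ValidationProtocol = VALIDATION,
) -> list[int]:
    """Interior-peak count of each seed's variance-scale curve."""
    return [scenario_analysis(name, s, protocol).n_scales for s in seeds]


# ---------------------------------------------------------------------------
# two-step report
# ---------------------------------------------------------------------------

@dataclass
class TwoStepReport:
    """Variance-scale curves (both statistics), detected scales, and the
    ARS places identified at each characteristic radius."""

    curves: dict[str, VarianceScaleCurve]
    peaks: dict[str, PeakResult]
    characteristic_radii: list[float]
    places: dict[float, list] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = []
        for mode, pk in self.peaks.items():
            rs = ", ".join(f"{p.r_peak:.3g}" for p in pk.peaks) or "none"
            r0 = " (+ smallest-radius maximum)" if pk.r0_peak else ""
            lines.append(f"{mode}: {len(pk.peaks)} ARS scale(s) at r = {rs}{r0}")
        if not self.characteristic_radii:
            lines.append("no ARS scale detected; place analysis skipped")
        for r, pls in self.places.items():
            flagged = sum(p.flags["oversized"] for p in pls)
            single = sum(p.flags["single_visit"] for p in pls)
            lines.append(
                f"r = {r:.3g}: {len(pls)} ARS place(s)"
                f" [{single} single-visit, {flagged} oversized]"
            )
        lines.extend(self.warnings)
        return "\n".join(lines)


def two_step_analysis(
    traj: Trajectory,
    radii: Sequence[float] | None = None,
    curve_max_time_outside: float = 0.0,
    place_max_time_outside: float = 0.0,
    criterion: str = "mean_visit_duration",
    drop_single_visit: bool = False,
    scale_mode: str = "var_log_rt",
    min_prominence_frac: float = DEFAULT_MIN_PROMINENCE_FRAC,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
) -> TwoStepReport:
    """Scales-then-places pipeline on one trajectory.

    Both curve statistics are computed for reporting; peak detection and the
    characteristic radii (upper-limit policy per scale domain) come from
    ``scale_mode``.  Place identification runs once per characteristic
    radius.  With no detected peak the report states that place analysis
    was skipped (this is a result, not an error).
    """
    curves: dict[str, VarianceScaleCurve] = {}
    peaks: dict[str, PeakResult] = {}
    for mode in ("var_log_rt", "cv_rt"):
        curves[mode] = variance_scale_curve(
            traj, radii=radii, mode=mode, max_time_outside=curve_max_time_outside
        )
        peaks[mode] = detect_peaks(
            curves[mode],
            min_prominence_frac=min_prominence_frac,
            smooth_window=smooth_window,
        )
    report = TwoStepReport(curves=curves, peaks=peaks, characteristic_radii=[])
    main = peaks[scale_mode]
    if not main.peaks:
        report.warnings.append("warning: no ARS scale detected")
        return report
    cr = characteristic_radius(main, policy="upper_limit")
    radii_list = [cr] if np.isscalar(cr) else list(cr)
    report.characteristic_radii = [float(r) for r in radii_list]
    for r in report.characteristic_radii:
        report.places[r] = places_mod.identify_ars_places(
            traj,
            r,
            criterion=criterion,
            max_time_outside=place_max_time_outside,
            drop_single_visit=drop_single_visit,
        )
    return report


# ---------------------------------------------------------------------------
# ground-truth scoring (simulation validation)
# ---------------------------------------------------------------------------

@dataclass
class PlaceRecovery:
    """Precision/recall of detected places against the simulator's log."""

    n_true: int
    n_detected: int
    n_matched_detections: int
    n_recovered_patches: int
    center_errors: list[float]

    @property
    def precision(self) -> float:
        return self.n_matched_detections / self.n_detected if self.n_detected else 0.0

    @property
    def recall(self) -> float:
        return self.n_recovered_patches / self.n_true if self.n_true else 0.0

    def __add__(self, other: "PlaceRecovery") -> "PlaceRecovery":
        return PlaceRecovery(
            self.n_true + other.n_true,
            self.n_detected + other.n_detected,
            self.n_matched_detections + other.n_matched_detections,
            self.n_recovered_patches + other.n_recovered_patches,
            self.center_errors + other.center_errors,
        )


def revisited_patches(log: GroundTruthLog, merge_gap: float) -> set[int]:
    """Ground-truth revisited patches: patches with at least two ARS
    episodes after merging episodes separated by less than ``merge_gap``
    (brief mode flickers within one spatial visit are not revisits)."""
    spans: dict[int, list[tuple[float, float]]] = {}
    for e in log.ars_episodes():
        if e.patch_id >= 0:
            spans.setdefault(e.patch_id, []).append((e.t_start, e.t_end))
    out = set()
    for pid, sp in spans.items():
        sp.sort()
        n = 1 + sum(
            1 for (s1, e1), (s2, e2) in zip(sp[:-1], sp[1:]) if s2 - e1 >= merge_gap
        )
        if n >= 2:
            out.add(pid)
    return out


def score_place_recovery(
    places: Sequence,
    rmap: ResourceMap,
    log: GroundTruthLog,
    match_radius: float,
    merge_gap: float = 300.0,
) -> PlaceRecovery:
    """Match detected ARS places to ground-truth revisited patches.

    A detection matches a true patch when its representative lies within
    ``match_radius`` (the planted patch radius) of the patch centre; each
    detection is credited to its nearest true patch.
    """
    true_patches = revisited_patches(log, merge_gap)
    matched_detections = 0
    recovered: set[int] = set()
    errors: list[float] = []
    for place in places:
        cx, cy = place.center
        best, best_d = -1, np.inf
        for pid in true_patches:
            px, py = rmap.patch_centers[pid]
            d = float(np.hypot(cx - px, cy - py))
            if d < best_d:
                best, best_d = pid, d
        if best >= 0 and best_d <= match_radius:
            matched_detections += 1
            recovered.add(best)
            errors.append(best_d)
    return PlaceRecovery(
        n_true=len(true_patches),
        n_detected=len(places),
        n_matched_detections=matched_detections,
        n_recovered_patches=len(recovered),
        center_errors=errors,
    )


def first_domain_radius(peaks: PeakResult) -> float | None:
    """Upper-limit characteristic radius of the smallest scale domain (the
    patch scale); None when no peak was detected."""
    if not peaks.peaks:
        return None
    cr = characteristic_radius(peaks, policy="upper_limit")
    return float(cr) if np.isscalar(cr) else float(min(cr))


def place_recovery_battery(
    seeds: Sequence[int],
    scenario: str = "simple_ars_patchy",
    protocol: ValidationProtocol = VALIDATION,
) -> PlaceRecovery:
    """Pooled place-recovery score over a battery of simulated runs.

    The analysis radius is shared across runs — the upper limit of the
    per-run patch-scale characteristic radii, following the recommendation
    to use the upper edge of the radius range when several paths indicate a
    range of scales.  Places use the mean-visit-duration criterion, visit
    merging at the patch giving-up time, and drop single-visit places; a
    match requires the representative within the planted patch radius
    (mean + 2 SD of the item-offset magnitude) of the true centre.
    """
    runs = [scenario_analysis(scenario, s, protocol) for s in seeds]
    return place_recovery_from_results(runs, seeds, scenario, protocol)


def place_recovery_from_results(
    runs: Sequence[ScenarioResult],
    seeds: Sequence[int],
    scenario: str = "simple_ars_patchy",
    protocol: ValidationProtocol = VALIDATION,
) -> PlaceRecovery:
    """Pooled recovery score for already-analysed runs (see
    :func:`place_recovery_battery`)."""
    radii = [r for r in (first_domain_radius(res.peaks) for res in runs) if r is not None]
    if not radii:
        raise ValueError("no run produced an ARS scale; cannot score recovery")
    r_common = max(radii)
    total = PlaceRecovery(0, 0, 0, 0, [])
    for res, seed in zip(runs, seeds):
        map_cfg, _ = scenario_configs(scenario, seed=seed)
        match_radius = map_cfg.item_distance_mean + 2.0 * map_cfg.item_distance_sd
        pls = places_mod.identify_ars_places(
            res.resampled,
            r_common,
            criterion=protocol.place_criterion,
            max_time_outside=protocol.place_max_time_outside,
            drop_single_visit=True,
        )
        total = total + score_place_recovery(
            pls, res.resource_map, res.log, match_radius,
            merge_gap=protocol.place_max_time_outside,
        )
    return total
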