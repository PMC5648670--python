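"""Foraging-walk simulation for validating the residence-time analyses.

The world is a square grid of cells carrying food items in one of three
spatial structures: scattered (items uniform over the grid), patchy (items
clustered around random patch centres), or two-level hierarchical (patches
clustered around random clump centres).  A forager moves one cell per step
as a correlated random walk whose turning variance can be biased toward or
away from a target location:

    theta_t ~ N(theta_{t-1}, v),   v = v_b * (1 -/+ p cos(theta_{t-1} - omega))

with basic variance ``v_b``, attraction level ``p`` in [0, 1] and ``omega``
the bearing to the target; the minus sign gives attraction (variance shrinks
when heading at the target), the plus sign repulsion.  Three strategies are
built on this walk: a simple search (unbiased walk, opportunistic
consumption), a simple area-restricted search (attraction toward the last
consumed item until a giving-up time passes without food), and a
hierarchical ARS that, on leaving a patch, performs out-and-back forays of
geometrically growing length around the departed patch centre until it finds
a neighbouring patch or a clump-level giving-up time expires.

Every simulation also emits a ground-truth log (per-step behavioural mode,
consumption events, ARS episodes) so that analyses can be scored against
what the forager actually did.
"""

from __future__ import annotations

import heapq
import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.spatial import cKDTree

from .trajectory import Trajectory

logger = logging.getLogger(__name__)

MapKind = Literal["scattered", "patchy", "hierarchical"]
Strategy = Literal["simple_search", "simple_ars", "hierarchical_ars"]
BiasSign = Literal["attraction", "repulsion"]

MODE_NAMES = ("explore", "ars", "foray_out", "foray_back")
_EXPLORE, _ARS, _FORAY_OUT, _FORAY_BACK = range(4)


class MapConfig(BaseModel):
    """Resource-map parameters.

    Counts and offsets of the clustered structures are drawn from normal
    distributions (counts rounded, minimum 1; offset magnitudes at uniform
    angles), matching a world where patch richness and size vary around a
    typical value.
    """

    kind: MapKind = "patchy"
    grid_size: int = Field(default=1000, ge=1)
    n_items: int = Field(default=600, ge=1)  # scattered maps
    n_patches: int = Field(default=30, ge=1)
    items_per_patch_mean: float = 20.0
    items_per_patch_sd: float = Field(default=5.0, ge=0.0)
    item_distance_mean: float = 10.0
    item_distance_sd: float = Field(default=3.0, ge=0.0)
    n_clumps: int = Field(default=5, ge=1)
    patches_per_clump_mean: float = 8.0
    patches_per_clump_sd: float = Field(default=1.0, ge=0.0)
    patch_distance_mean: float = 60.0
    patch_distance_sd: float = Field(default=15.0, ge=0.0)
    clump_min_separation: float = Field(default=400.0, ge=0.0)
    regeneration_delay: float = Field(default=5000.0, ge=0.0)
    seed: int = 0


class ForagerConfig(BaseModel):
    """Behavioural parameters of the simulated forager.

    ``v_b`` is the basic turning variance (radians^2) of the correlated walk
    while exploring or on forays; ``v_b_ars`` the (much larger) basic
    variance during concentrated search, which keeps ARS bouts tight around
    the target; ``p`` the attraction strength toward the current target in
    ARS or foray modes (0 = none, 1 = complete).  Giving-up times count
    steps since the last food encounter.  Foray legs start at
    ``foray_initial_leg`` steps and grow by ``foray_growth`` per completed
    out-and-back cycle, radiating outward; the return leg ends on reaching
    ``foray_catch_radius`` of the departed patch centre or after twice the
    leg length.  While exploring, the forager rests in place with
    per-step probability ``p_rest`` for a normal-drawn duration — the
    stationary stops real animals intersperse with travel.
    """

    strategy: Strategy = "simple_ars"
    v_b: float = Field(default=0.01, gt=0.0)
    v_b_ars: float = Field(default=1.0, gt=0.0)
    p: float = Field(default=0.8, ge=0.0, le=1.0)
    perceptual_range: float = Field(default=3.0, ge=0.0)
    giving_up_time_patch: int = Field(default=300, ge=1)
    giving_up_time_clump: int = Field(default=2000, ge=1)
    n_steps: int = Field(default=60_000, ge=1)
    foray_initial_leg: float = Field(default=60.0, gt=0.0)
    foray_growth: float = Field(default=1.3, ge=1.0)
    foray_max_leg: float = Field(default=150.0, gt=0.0)
    foray_leg_sd_frac: float = Field(default=0.25, ge=0.0)
    foray_catch_radius: float = Field(default=5.0, ge=0.0)
    p_rest: float = Field(default=0.001, ge=0.0, le=1.0)
    rest_mean: float = Field(default=150.0, ge=0.0)
    rest_sd: float = Field(default=50.0, ge=0.0)
    rest_refractory: int = Field(default=1000, ge=0)
    seed: int = 0

    @model_validator(mode="after")
    def _clump_time_exceeds_patch_time(self):
        if self.giving_up_time_clump < self.giving_up_time_patch:
            raise ValueError("giving_up_time_clump must be >= giving_up_time_patch")
        return self


@dataclass
class ResourceMap:
    """World state: item coordinates, availability, and the ground-truth
    patch/clump structure items were generated around."""

    grid_size: int
    item_xy: np.ndarray          # (k, 2)
    item_patch: np.ndarray       # (k,) patch index, -1 on scattered maps
    patch_centers: np.ndarray    # (p, 2)
    patch_clump: np.ndarray      # (p,) clump index, -1 on non-hierarchical maps
    clump_centers: np.ndarray    # (c, 2)
    regeneration_delay: float
    available: np.ndarray = field(default=None)  # (k,) bool
    regrow_at: np.ndarray = field(default=None)  # (k,) float, nan when available
    _tree: cKDTree = field(default=None, repr=False)
    _pending: list = field(default_factory=list, repr=False)  # heap of (time, item)

    def __post_init__(self):
        k = len(self.item_xy)
        if self.available is None:
            self.available = np.ones(k, dtype=bool)
        if self.regrow_at is None:
            self.regrow_at = np.full(k, np.nan)
        if self._tree is None and k:
            self._tree = cKDTree(self.item_xy)

    @property
    def n_items(self) -> int:
        return len(self.item_xy)

    @property
    def n_available(self) -> int:
        return int(self.available.sum())

    @property
    def n_pending(self) -> int:
        return len(self._pending)

    def restore_due(self, t: float) -> None:
        """Bring back items whose regeneration delay has elapsed."""
        while self._pending and self._pending[0][0] <= t:
            _, j = heapq.heappop(self._pending)
            self.available[j] = True
            self.regrow_at[j] = np.nan

    def consume_within(self, x: float, y: float, radius: float, t: float) -> list[int]:
        """Consume every available item within ``radius`` of ``(x, y)``;
        returns their indices in increasing order."""
        if self._tree is None or radius <= 0:
            return []
        hits = sorted(self._tree.query_ball_point([x, y], radius))
        out = []
        for j in hits:
            if self.available[j]:
                self.available[j] = False
                self.regrow_at[j] = t + self.regeneration_delay
                heapq.heappush(self._pending, (t + self.regeneration_delay, j))
                out.append(j)
        return out

    def to_json_dict(self) -> dict:
        return {
            "grid_size": self.grid_size,
            "items": self.item_xy.tolist(),
            "item_patch": self.item_patch.tolist(),
            "patch_centers": self.patch_centers.tolist(),
            "patch_clump": self.patch_clump.tolist(),
            "clump_centers": self.clump_centers.tolist(),
            "regeneration_delay": self.regeneration_delay,
        }


def _normal_counts(rng, mean, sd, n) -> np.ndarray:
    counts = np.rint(rng.normal(mean, sd, n)).astype(int)
    n_clamped = int((counts < 1).sum())
    if n_clamped:
        logger.warning("%d drawn counts were < 1 and clamped to 1", n_clamped)
    return np.maximum(counts, 1)


def _radial_offsets(rng, dist_mean, dist_sd, n) -> np.ndarray:
    """Offsets with normal-magnitude distance at a uniform angle."""
    dist = np.abs(rng.normal(dist_mean, dist_sd, n))
    ang = rng.uniform(-math.pi, math.pi, n)
    return np.column_stack([dist * np.cos(ang), dist * np.sin(ang)])


def _separated_uniform(rng, g: float, n: int, min_sep: float) -> np.ndarray:
    """Uniform points with rejection-sampled minimum pairwise separation
    (keeps hierarchical clumps spatially distinct).  After 500 failed draws
    per point the constraint is relaxed with a warning."""
    pts: list[np.ndarray] = []
    for _ in range(n):
        for attempt in range(500):
            cand = rng.uniform(0.0, g, 2)
            if all(np.hypot(*(cand - p)) >= min_sep for p in pts):
                break
        else:
            logger.warning("could not honour clump_min_separation=%.1f", min_sep)
        pts.append(cand)
    return np.asarray(pts)


def generate_resource_map(cfg: MapConfig) -> ResourceMap:
    """Build a resource map of the configured kind, reproducibly from its seed.

    Scattered: ``n_items`` uniform over the grid.  Patchy: patch centres
    uniform, per-patch item counts and item offsets from normal draws.
    Hierarchical: clump centres uniform, patches placed around clumps the
    same way items are placed around patches.  Coordinates are clipped to
    the grid; all items start available.
    """
    rng = np.random.default_rng(cfg.seed)
    g = float(cfg.grid_size)

    if cfg.kind == "scattered":
        items = rng.uniform(0.0, g, (cfg.n_items, 2))
        item_patch = np.full(cfg.n_items, -1)
        patch_centers = np.empty((0, 2))
        patch_clump = np.empty(0, dtype=int)
        clump_centers = np.empty((0, 2))
    else:
        if cfg.kind == "patchy":
            patch_centers = rng.uniform(0.0, g, (cfg.n_patches, 2))
            patch_clump = np.full(len(patch_centers), -1)
            clump_centers = np.empty((0, 2))
        else:  # hierarchical
            clump_centers = _separated_uniform(
                rng, g, cfg.n_clumps, cfg.clump_min_separation
            )
            n_per_clump = _normal_counts(
                rng, cfg.patches_per_clump_mean, cfg.patches_per_clump_sd, cfg.n_clumps
            )
            centers, owners = [], []
            for c, n_p in enumerate(n_per_clump):
                offs = _radial_offsets(rng, cfg.patch_distance_mean, cfg.patch_distance_sd, n_p)
                centers.append(clump_centers[c] + offs)
                owners.extend([c] * n_p)
            patch_centers = np.clip(np.vstack(centers), 0.0, g)
            patch_clump = np.asarray(owners, dtype=int)
        n_per_patch = _normal_counts(
            rng, cfg.items_per_patch_mean, cfg.items_per_patch_sd, len(patch_centers)
        )
        pts, owners = [], []
        for pi, n_i in enumerate(n_per_patch):
            offs = _radial_offsets(rng, cfg.item_distance_mean, cfg.item_distance_sd, n_i)
            pts.append(patch_centers[pi] + offs)
            owners.extend([pi] * n_i)
        items = np.clip(np.vstack(pts), 0.0, g)
        item_patch = np.asarray(owners, dtype=int)

    return ResourceMap(
        grid_size=cfg.grid_size,
        item_xy=np.clip(items, 0.0, g),
        item_patch=item_patch,
        patch_centers=patch_centers,
        patch_clump=patch_clump,
        clump_centers=clump_centers,
        regeneration_delay=cfg.regeneration_delay,
    )


# ---------------------------------------------------------------------------
# movement model
# ---------------------------------------------------------------------------

def turning_variance(
    theta_prev: float,
    omega: float,
    v_b: float,
    p: float,
    bias_sign: BiasSign = "attraction",
) -> float:
    """Directional variance of the biased correlated walk.

    Attraction: ``v = v_b (1 - p cos(theta_prev - omega))`` — the variance
    collapses when already heading at the target, so with ``p = 1`` and a
    aligned heading the walk locks on.  Repulsion flips the sign.  The
    result is non-negative for any ``p`` in [0, 1].
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"attraction level p must be in [0, 1], got {p!r}")
    if not v_b > 0:
        raise ValueError(f"basic variance v_b must be positive, got {v_b!r}")
    c = p * math.cos(theta_prev - omega)
    if bias_sign == "attraction":
        return v_b * (1.0 - c)
    elif bias_sign == "repulsion":
        return v_b * (1.0 + c)
    raise ValueError(f"bias_sign must be 'attraction' or 'repulsion', got {bias_sign!r}")


def _wrap_angle(a: float) -> float:
    """Wrap to (-pi, pi]."""
    a = (a + math.pi) % (2.0 * math.pi) - math.pi
    return math.pi if a == -math.pi else a


@dataclass
class ForagerState:
    """Mutable walker state advanced by :func:`step`."""

    x: float
    y: float
    heading: float
    mode: int = _EXPLORE
    target: tuple[float, float] | None = None
    mode_timer: int = 0          # steps since last consumption (or mode entry)
    current_patch: int = -1
    foray_center: tuple[float, float] | None = None
    foray_leg_mean: float = 0.0
    foray_leg_len: float = 0.0
    foray_leg_step: int = 0
    rest_timer: int = 0          # remaining steps of the current rest
    rest_cooldown: int = 0       # refractory steps before the next rest

    @property
    def mode_name(self) -> str:
        return MODE_NAMES[self.mode]


def step(
    state: ForagerState,
    rmap: ResourceMap,
    cfg: ForagerConfig,
    rng: np.random.Generator,
    t: float,
) -> list[tuple[float, int, int]]:
    """Advance the forager by one step (one cell of displacement), in place.

    Restores items due to regrow, draws the new heading from the biased
    normal, reflects at the grid walls, consumes items within perceptual
    range, and applies the strategy's mode transitions.  Returns the list of
    consumption events ``(t, item_index, patch_id)``.
    """
    rmap.restore_due(t)

    # resting: stay in place, mode unchanged; a refractory period after each
    # rest keeps independent stops spatially well separated
    if state.rest_timer > 0:
        state.rest_timer -= 1
        if state.rest_timer == 0:
            state.rest_cooldown = cfg.rest_refractory
        return []
    if state.rest_cooldown > 0:
        state.rest_cooldown -= 1
    elif state.mode == _EXPLORE and cfg.p_rest > 0 and rng.random() < cfg.p_rest:
        state.rest_timer = max(1, int(round(rng.normal(cfg.rest_mean, cfg.rest_sd))))
        return []

    # heading update: unbiased in explore, biased toward/away from the target
    if state.target is None:
        v = cfg.v_b
    else:
        omega = math.atan2(state.target[1] - state.y, state.target[0] - state.x)
        sign = "repulsion" if state.mode == _FORAY_OUT else "attraction"
        # concentrated search turns sharply (v_b_ars); forays stay directed (v_b)
        v_base = cfg.v_b_ars if state.mode == _ARS else cfg.v_b
        v = turning_variance(state.heading, omega, v_base, cfg.p, sign)
    heading = state.heading if v <= 0 else rng.normal(state.heading, math.sqrt(v))
    heading = _wrap_angle(heading)

    # unit step plus reflecting walls (heading mirrored)
    x = state.x + math.cos(heading)
    y = state.y + math.sin(heading)
    g = float(rmap.grid_size)
    if x < 0.0:
        x, heading = -x, _wrap_angle(math.pi - heading)
    elif x > g:
        x, heading = 2.0 * g - x, _wrap_angle(math.pi - heading)
    if y < 0.0:
        y, heading = -y, _wrap_angle(-heading)
    elif y > g:
        y, heading = 2.0 * g - y, _wrap_angle(-heading)
    state.x, state.y, state.heading = x, y, heading

    consumed = rmap.consume_within(x, y, cfg.perceptual_range, t)
    events = [(t, j, int(rmap.item_patch[j])) for j in consumed]

    if cfg.strategy == "simple_search":
        state.mode = _EXPLORE  # opportunistic consumption, no mode changes
        return events

    if consumed:
        j = consumed[-1]
        state.mode = _ARS
        state.target = (float(rmap.item_xy[j, 0]), float(rmap.item_xy[j, 1]))
        state.current_patch = int(rmap.item_patch[j])
        state.mode_timer = 0
        return events

    state.mode_timer += 1
    if state.mode == _ARS and state.mode_timer > cfg.giving_up_time_patch:
        if cfg.strategy == "simple_ars":
            state.mode, state.target = _EXPLORE, None
        else:
            _begin_forays(state, rmap, cfg, rng)
    elif state.mode == _FORAY_OUT:
        state.foray_leg_step += 1
        if state.foray_leg_step >= state.foray_leg_len:
            state.mode = _FORAY_BACK
    elif state.mode == _FORAY_BACK:
        state.foray_leg_step += 1
        fc = state.foray_center
        catch = max(cfg.perceptual_range, cfg.foray_catch_radius)
        # next foray on reaching the patch centre, or after twice the leg
        # length (the biased walk can circle a small target indefinitely)
        if (
            math.hypot(state.x - fc[0], state.y - fc[1]) <= catch
            or state.foray_leg_step >= 2.0 * state.foray_leg_len
        ):
            state.foray_leg_mean *= cfg.foray_growth
            _draw_foray_leg(state, cfg, rng)
            state.mode = _FORAY_OUT
    if state.mode in (_FORAY_OUT, _FORAY_BACK) and state.mode_timer > cfg.giving_up_time_clump:
        state.mode, state.target, state.foray_center = _EXPLORE, None, None
    return events


def _begin_forays(state, rmap, cfg, rng) -> None:
    """Patch departure under the hierarchical strategy: radiate out-and-back
    forays around the centre of the patch just left (the last item's own
    location on scattered maps)."""
    if state.current_patch >= 0 and len(rmap.patch_centers):
        c = rmap.patch_centers[state.current_patch]
        center = (float(c[0]), float(c[1]))
    else:
        center = state.target if state.target is not None else (state.x, state.y)
    state.foray_center = center
    state.target = center
    state.foray_leg_mean = cfg.foray_initial_leg
    _draw_foray_leg(state, cfg, rng)
    state.mode = _FORAY_OUT


def _draw_foray_leg(state, cfg, rng) -> None:
    state.foray_leg_mean = min(state.foray_leg_mean, cfg.foray_max_leg)
    sd = cfg.foray_leg_sd_frac * state.foray_leg_mean
    state.foray_leg_len = min(
        max(1.0, rng.normal(state.foray_leg_mean, sd)), cfg.foray_max_leg
    )
    state.foray_leg_step = 0


# ---------------------------------------------------------------------------
# whole-run simulation and ground truth
# ---------------------------------------------------------------------------

@dataclass
class ArsEpisode:
    patch_id: int
    t_start: float
    t_end: float

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class GroundTruthLog:
    """What the forager actually did: per-step behavioural mode, food
    consumption events, and derived ARS episodes."""

    mode_codes: np.ndarray                       # (n_steps + 1,) int8
    events: list[tuple[float, int, int]]         # (t, item, patch_id)

    @property
    def modes(self) -> np.ndarray:
        return np.asarray(MODE_NAMES, dtype=object)[self.mode_codes]

    def events_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.events, columns=["t", "item", "patch_id"])

    def ars_episodes(self) -> list[ArsEpisode]:
        """Maximal runs of ARS mode, attributed to the patch of the
        consumption event that opened the run (non-overlapping by
        construction)."""
        in_ars = self.mode_codes == _ARS
        if not in_ars.any():
            return []
        starts = np.flatnonzero(in_ars & ~np.r_[False, in_ars[:-1]])
        ends = np.flatnonzero(in_ars & ~np.r_[in_ars[1:], False])
        ev_t = np.array([e[0] for e in self.events])
        ev_patch = np.array([e[2] for e in self.events])
        episodes = []
        for a, b in zip(starts, ends):
            k = np.searchsorted(ev_t, a, side="left")
            patch = int(ev_patch[k]) if k < ev_t.size and ev_t[k] <= b else -1
            episodes.append(ArsEpisode(patch_id=patch, t_start=float(a), t_end=float(b)))
        return episodes

    def visited_patches(self, min_duration: float = 0.0) -> set[int]:
        return {
            e.patch_id
            for e in self.ars_episodes()
            if e.patch_id >= 0 and e.duration >= min_duration
        }

    def to_dataframe(self) -> pd.DataFrame:
        """Long per-step table with consumption events joined on time."""
        df = pd.DataFrame({"t": np.arange(self.mode_codes.size), "mode": self.modes})
        ev = self.events_dataframe()
        if len(ev):
            consumed = ev.groupby("t").agg(item=("item", "first"), patch_id=("patch_id", "first"))
            df = df.join(consumed, on="t")
        else:
            df["item"] = np.nan
            df["patch_id"] = np.nan
        return df


def simulate(
    map_cfg: MapConfig,
    forager_cfg: ForagerConfig,
) -> tuple[Trajectory, GroundTruthLog, ResourceMap]:
    """Run a full foraging walk.

    The map is generated from ``map_cfg.seed`` and the walk driven by
    ``forager_cfg.seed``; identical seed pairs give bit-identical output.
    The trajectory records the position at every step (``n_steps + 1``
    fixes including the random uniform start).
    """
    rmap = generate_resource_map(map_cfg)
    rng = np.random.default_rng(forager_cfg.seed)
    g = float(rmap.grid_size)
    state = ForagerState(
        x=float(rng.uniform(0.0, g)),
        y=float(rng.uniform(0.0, g)),
        heading=float(rng.uniform(-math.pi, math.pi)),
    )
    n = forager_cfg.n_steps
    xs = np.empty(n + 1)
    ys = np.empty(n + 1)
    codes = np.zeros(n + 1, dtype=np.int8)
    xs[0], ys[0] = state.x, state.y
    events: list[tuple[float, int, int]] = []
    for t in range(1, n + 1):
        events.extend(step(state, rmap, forager_cfg, rng, float(t)))
        xs[t], ys[t] = state.x, state.y
        codes[t] = state.mode
    traj = Trajectory(np.arange(n + 1, dtype=float), xs, ys, crs_note="simulated grid cells")
    return traj, GroundTruthLog(mode_codes=codes, events=events), rmap


# ---------------------------------------------------------------------------
# canonical study scenarios
# ---------------------------------------------------------------------------

#: map kind and strategy of the five canonical validation scenarios
SCENARIOS: dict[str, tuple[MapKind, Strategy]] = {
    "simple_search_scattered": ("scattered", "simple_search"),
    "simple_search_patchy": ("patchy", "simple_search"),
    "simple_ars_patchy": ("patchy", "simple_ars"),
    "simple_ars_hierarchical": ("hierarchical", "simple_ars"),
    "hierarchical_ars_hierarchical": ("hierarchical", "hierarchical_ars"),
}


def scenario_configs(
    name: str,
    seed: int = 0,
    n_steps: int = 60_000,
    **overrides,
) -> tuple[MapConfig, ForagerConfig]:
    """Default configuration pair for a named validation scenario.

    The map and walk receive independent sub-seeds derived from ``seed``.
    Keyword overrides are applied to whichever config declares the field.
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    kind, strategy = SCENARIOS[name]
    sub = np.random.SeedSequence(seed).generate_state(2, dtype=np.uint32) % (2**31)
    map_kw = {"kind": kind, "seed": int(sub[0])}
    forager_kw = {"strategy": strategy, "seed": int(sub[1]), "n_steps": n_steps}
    for key, val in overrides.items():
        if key in MapConfig.model_fields:
            map_kw[key] = val
        elif key in ForagerConfig.model_fields:
            forager_kw[key] = val
        else:
            raise ValueError(f"unknown config field {key!r}")
    return MapConfig(**map_kw), ForagerConfig(**forager_kw)
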