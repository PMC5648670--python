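# Methods

## The residence-time framework

A relocation trajectory is an ordered sequence of fixes `(t, x, y)` in planar
coordinates. Around every fix a virtual circle of radius `r` is drawn. The
first-passage time (FPT) is the time from the focal fix to the first crossing
of the circle's perimeter, scanning forward or backward along the path; the
residence time is their sum,

    RT(i, r) = FPT_backward(i, r) + FPT_forward(i, r),

the total time inside the circle from first entry to first exit. Where an
animal performs area-restricted search (ARS) — slow, tortuous search inside a
confined area — residence times are much larger than along travel segments,
and the contrast is greatest when the circle matches the spatial scale of the
search bout. Plotting a spread statistic of RT across all fixes against `r`
(the variance-scale curve) therefore produces a peak at each characteristic
ARS scale; nested search behaviour produces several peaks.

Two spread statistics are implemented: the variance of `log RT` (classical;
appropriate when RT is roughly log-normal) and the coefficient of variation
`SD(RT)/mean(RT)`, which behaves better at small radii where the log
transform flattens genuine structure. Both are exposed; peak counts in the
validation studies use the log-variance, which suppresses the resting-stop
signature concentrated at the smallest radii (see below).

### Crossing geometry and censoring

Crossing times are located by linear interpolation between fixes: the
distance to a fixed centre is convex along a straight segment, so each
segment contributes at most one entry and one exit, found as roots of a
quadratic. The inside region is the open disc (`distance < r`); a fix
exactly on the boundary is outside. A discrete mode that snaps crossings to
the first fix beyond the perimeter exists for exact replication of
step-based simulations; interpolated and discrete RTs differ by at most two
inter-fix intervals. All durations come from timestamps, never fix counts,
so irregular sampling is handled throughout.

An RT is *censored* when the path starts or ends before the circle is
crossed. Censored RTs are lower bounds; they depress the spread statistics
at large radii and are excluded by default (with per-radius counts of valid
values reported); an option includes them.

### Merged residence times

A visit history generalizes RT to *all* intervals the path spends inside the
circle. Visits separated by excursions shorter than a threshold
`max_time_outside` can be merged into one visit whose duration sums inside
time only — total inside time is invariant to the threshold, and the number
of visits is non-increasing in it. Merging matters whenever the movement
contains out-and-back excursions at scales between the circle radius and the
bout of interest: without it, the first brief excursion terminates the
residence time, and multi-scale structure (e.g. residence in a cluster of
patches) never accrues. The library default is `max_time_outside = 0` (the
plain first-entry-to-first-exit definition); the threshold is an explicit
parameter because choosing it requires a priori knowledge of the relevant
temporal scales. The merged sweep over all (fix, radius) pairs is a
sequential scan compiled with numba; a pure-Python twin of the same function
is kept and cross-checked in the tests, as is the zero-threshold limit
against the independent vectorized implementation.

## Scale detection

The default radius grid has 30 logarithmically spaced radii from half the
median step length to a quarter of the path's bounding-box diagonal. The
lower bound deliberately sits *below* the typical displacement: search steps
are slower than travel steps, so the ARS scale can be smaller than the
median resampled displacement, and interpolation makes sub-step radii
meaningful. The upper bound avoids the regime where circles approach the
whole range and censoring dominates.

Peak detection smooths the curve with a centred moving average (window 3),
finds interior local maxima, and iteratively discards the shallowest maximum
whose prominence — height above the higher of its two flanking minima —
falls below 5% of the smoothed curve's total range, recomputing flanking
minima after each removal. Both knobs are exposed and archived with every
run. A maximum at the smallest grid radius is reported separately as the
"r → 0" peak: it is the signature of stationary resting stops, whose
residence time is large at every radius, and is not counted as an ARS scale.
The prominence rule is this package's operationalization of "distinct"
versus "shallow" peaks; the literature offers no quantitative rule.

Characteristic radii follow either a `per_peak` policy (every peak radius)
or the default `upper_limit` policy: peaks whose radii lie within a factor
of two of each other are grouped into one scale domain — nested scales
separate multiplicatively — and the largest radius of each domain is
returned. Working at the upper edge of a domain avoids under-sized analysis
circles, which would split one search bout into spurious revisits.

## Identifying revisited ARS places

At a chosen radius the algorithm has four steps:

1. compute every fix's revisit history (visit count, mean visit duration,
   total inside time);
2. filter: keep fixes whose criterion value — mean visit duration (default)
   or total time — strictly exceeds the larger of the distribution's mean
   and median. With the strict inequality an all-equal distribution yields
   zero survivors ("no ARS detected") rather than everything;
3. link surviving fixes that lie within each other's circles (Euclidean
   distance strictly below `r`) and take connected components of the graph
   as candidate places (iterative traversal; component size is unbounded);
4. represent each place by its member with the largest criterion value
   (ties go to the earliest fix), and report the representative's history as
   the place's statistics.

Place statistics come from the representative's history only: pooling member
histories would double-count overlapping circles (pseudoreplication).
Diagnostics target the two documented failure modes. Places whose
representative history contains a single visit are flagged `single_visit`
(long stationary stops masquerade as high-mean places; an option drops
them), and components whose spatial extent exceeds `2r` are flagged
`oversized` (adjacent patches erroneously united). Oversized components are
flagged, never split automatically — splitting is a judgement call for the
analyst. Durations between consecutive visits of a place are exposed
(`between_visit_intervals`) as the hook for revisitation-regularity
analyses such as trap-lining detection.

The mean-visit-duration criterion deserves one caveat: because it divides by
the visit count, it biases the representative toward fixes whose circle
captured only the single longest visit. A genuinely revisited place can
therefore carry a single-visit flag when the analysis radius is small
relative to the spread of its visits; analysing at the upper edge of the
indicated scale range mitigates this.

## The simulation model

The validation world is a 1,000 × 1,000-cell grid carrying food items in
three spatial structures: scattered (items uniform), patchy (items around
uniform patch centres), and two-level hierarchical (patches around clump
centres as items around patches). Counts are normal draws rounded with a
floor of one; offsets have normal-magnitude distances at uniform angles.
Hierarchical clump centres are rejection-sampled to a minimum pairwise
separation so clumps are spatially distinct. Consumed items re-emerge after
a fixed per-item delay.

The forager moves one cell per step as a correlated random walk whose
heading is drawn from a normal distribution centred on the previous heading
with variance

    v = v_b (1 ∓ p cos(theta_prev − omega)),

where `omega` is the bearing to the current target, `p` in [0, 1] the
attraction level, and the minus sign applies to attraction (variance
collapses when heading at the target, so `p = 1` aligned means locked on),
the plus sign to repulsion. The multiplicative form is the only reading
consistent with the attraction sign rule. Boundaries reflect (heading
mirrored), avoiding torus artifacts in distance-based place detection.

Three strategies build on this walk:

* **simple search** — unbiased walk (`p = 0`), opportunistic consumption of
  items within the perceptual range;
* **simple ARS** — explore until an item is found, then concentrated search
  attracted to the most recently consumed item (target updates on every
  consumption), abandoned when a giving-up time passes without food;
* **hierarchical ARS** — as simple ARS, but a departed patch triggers
  out-and-back forays around the patch centre: repulsion outward for a
  normal-drawn leg length, attraction back until within a catch radius (or a
  return timeout — a biased walk can circle a point target indefinitely),
  with leg lengths growing geometrically and capped; a clump-level giving-up
  time ends the foray cycle.

While exploring, the forager rests in place with a small per-step
probability for a normal-drawn duration, with a refractory period after
each rest. Resting stops are what produces the smallest-radius maximum of
search curves, and they exercise the stopping-site diagnostics of the place
algorithm; the refractory period keeps independent stops spatially separate
so chance rest pairs do not imitate mid-scale structure.

Giving-up timers count steps since the last consumption. Every run emits a
ground-truth log: per-step behavioural mode, consumption events with patch
identities, and derived ARS episodes, enabling parameter-recovery scoring.

### Parameter defaults and what they emulate

The movement and map defaults were chosen once to reproduce the qualitative
regimes the framework is meant to discriminate — travel as near-straight
legs between resources, concentrated tortuous search confined to the patch
scale, and hierarchical search that strings several patches of one clump
together — and then frozen:

| parameter | default | role |
|---|---|---|
| `v_b` | 0.01 rad² | basic turning variance while exploring/on forays (near-straight travel) |
| `v_b_ars` | 1.0 rad² | basic variance during concentrated search (tight, tortuous bouts) |
| `p` | 0.8 | attraction/repulsion strength toward the target |
| `perceptual_range` | 3 cells | consumption radius |
| `giving_up_time_patch` | 300 steps | foodless time ending a patch bout |
| `giving_up_time_clump` | 2000 steps | foodless time ending a foray cycle |
| `p_rest`, rest duration | 0.001, 150 ± 50 steps | resting stops while exploring (refractory 1000) |
| forays | 60 × 1.3^k, cap 150, catch 5 | out-and-back legs radiating from the departed patch |
| patchy map | 30 patches, 20 ± 5 items at 10 ± 3 cells | single-scale patchiness |
| hierarchical map | 5 clumps (min separation 400), 8 ± 1 patches at 60 ± 15 cells | two-level patchiness |
| `regeneration_delay` | 5000 steps | items re-emerge, enabling revisits |
| run length | 60,000 steps, resampled 1-in-10 | GPS-like sampling of a long foraging day |

The validation protocol (fixed in `arscape.workflow.VALIDATION`) analyses
the resampled paths with the log-variance statistic and merged residence
times at `max_time_outside = 2500` steps — above the within-clump foray
gaps, which are bounded by the clump giving-up time, and below typical
between-clump transit — and scores place recovery at the patch-scale
characteristic radius shared across a battery (the upper limit of the
per-run radii), with visit merging at the patch giving-up time.

### What the generator does not emulate

Real telemetry contains location error, irregular and missing fixes beyond
simple thinning, boundary effects of true home ranges, state-dependent
motivation, conspecifics and predators, and resources that move or deplete
gradually. Passing the validation batteries shows the analysis recovers the
structure this generator plants under GPS-like thinning; it does not certify
performance on data whose noise or behaviour departs from these
assumptions.

### Known limitations

Under these documented conditions the five scenario batteries reproduce the
expected qualitative regimes for simple search (flat curves, smallest-radius
maximum only) and simple ARS (a single patch-scale peak on patchy and
hierarchical maps alike). The hierarchical-ARS scenario produces its
patch-scale peak reliably, but the clump-scale second peak usually stays
below the 5% prominence threshold: transit residence times inflate with
radius about as fast as in-clump residence saturates, and clump-visit
durations disperse (foray failures, partial exploitation), so the
between-scale valley rarely re-deepens. The multi-peak tally for that
scenario is therefore reported as computed rather than asserted; the
mechanism — merged residence accruing at the clump scale — is present and
visible as a shoulder in most runs.

## Numerical choices

* Sample statistics use the unbiased (n−1) denominator.
* Radii grids must be strictly increasing and positive; statistics are NaN
  wherever fewer than two valid RTs remain.
* Zero RTs (possible only through duplicate-position fixes) are excluded
  from the log-variance with a logged count.
* Tie-breaks are deterministic everywhere (earliest fix index); components
  are ordered by smallest member; identical seeds give bit-identical
  simulations and byte-identical analysis outputs.
* Degenerate inputs: a stationary path has no valid radius grid (explicit
  error); an all-equal criterion distribution yields zero survivors; a
  trajectory shorter than two fixes cannot carry residence times.
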