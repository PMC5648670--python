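# arscape

Residence-time analysis of animal movement paths: detecting the spatial
scales of area-restricted search (ARS) and mapping the places an animal
revisits and searches intensively.

Movement ecologists routinely record trajectories — ordered `(t, x, y)`
fixes from GPS collars or similar — and need to know *where* and *at what
spatial scale* an animal concentrated its activity. Around each fix a
virtual circle of radius `r` is drawn; the residence time

    RT(i, r) = FPT_backward(i, r) + FPT_forward(i, r)

is the total time spent inside the circle from first entry to first exit
(the sum of the backward and forward first-passage times). Where the circle
matches the scale of a search bout, residence times contrast maximally
between searching and travelling fixes, so the spread of RT across fixes —
variance of log RT, or the coefficient of variation of RT — plotted against
`r` peaks at each characteristic ARS scale (the *variance-scale curve*,
with one peak per scale domain when search is hierarchically nested).

At a chosen scale, a four-step algorithm identifies spatially distinct
*revisited ARS places*: (1) compute every fix's revisit history; (2) keep
fixes whose mean visit duration (or total time) exceeds the larger of the
distribution's mean and median; (3) link surviving fixes lying within each
other's circles and take connected components; (4) summarize each place by
its best member's history — mean visit duration and number of revisits, the
two scale-dependent measures that characterize how a place is used.
Diagnostics flag single-visit places (stopping-site artifacts) and
components wider than `2r` (adjacent places erroneously united).

The package also contains the validation world: resource maps (scattered /
patchy / two-level hierarchical) and a biased correlated random walk
forager, `theta_t ~ N(theta_{t-1}, v)` with
`v = v_b (1 ∓ p cos(theta_{t-1} − omega))` (attraction/repulsion toward a
target), implementing three strategies (simple search, simple ARS,
hierarchical ARS with radiating forays) with full ground-truth logging.

## Worked example

Simulate a forager doing simple ARS on a patchy map, thin the path to
GPS-like sampling, and run the two-step analysis:

```bash
arscape simulate --map patchy --strategy simple_ars --steps 60000 --seed 42 \
        --out traj.csv --log truth.csv --map-out map.json
arscape run --input traj.csv --resample 10 --outdir results \
        --curve-max-time-outside 2500 --place-max-time-outside 300 \
        --drop-single-visit
```

which prints (seed 42):

```
var_log_rt: 1 ARS scale(s) at r = 16
cv_rt: 0 ARS scale(s) at r = none (+ smallest-radius maximum)
r = 16: 9 ARS place(s) [0 single-visit, 0 oversized]
```

One scale domain was detected: the log-variance curve peaks at a radius of
16 cells, the scale of the planted patches (items scattered 10 ± 3 cells
around their centres — the estimator sits at or slightly above the true
patch scale). The coefficient-of-variation curve instead is dominated by
the smallest-radius maximum produced by resting stops, which is reported
separately and never counted as an ARS scale. At `r = 16` the place
algorithm finds 9 distinct revisited places; `results/places_r15.98.csv`
lists each with its centre, mean visit duration, revisit count and flags,
and `results/curve_*.csv` / `results/peaks.json` hold the curves and peaks.
The same analysis is available as a library call
(`arscape.two_step_analysis`) returning the curves, peaks and places as
objects.

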