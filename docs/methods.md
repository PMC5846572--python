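# Methods

## The GVP model

A CGM trace is treated as a polyline in the (time, glucose) plane with
time in **minutes** and glucose in **mg/dL**. For each pair of
successive readings within a contiguous run, the segment has horizontal
component Δx (minutes) and vertical component Δy (mg/dL); the trace
length is the Pythagorean sum L = Σ√(Δx² + Δy²) and the flat-line
reference is L₀ = ΣΔx. GVP = (L/L₀ − 1) × 100.

The statistic deliberately mixes units: no rescaling of the time axis
is applied, because the published bands (minimal ≤ 20 %, low ≤ 30 %,
moderate 30–50 %, high > 50 %) and the worked example (L = 13,349,
L₀ = 9,670 → 38 %) are defined under exactly this convention. The
consequence is unit dependence: the same trace in mmol/L produces a
different number. The library therefore refuses mmol/L input to the GVP
path unless explicitly overridden (`allow_mmol=True`, logged), and the
converter uses 18.016 mg/dL per mmol/L (glucose molar mass).

Δx is the *actual* timestamp difference, not the nominal interval, so
jittered real exports are handled without resampling.

### Gap handling

CGM exports drop readings. A *gap* is any step between consecutive
samples exceeding a threshold, by default 1.5 × the nominal interval
(7.5 min for 5-min data) — wide enough to tolerate timestamp jitter,
tight enough to catch a single missed transmission. Gaps split the
trace into runs; both L and L₀ are summed over within-run segments
only. This implements "shorten the reference by the amount of missing
data" and avoids counting a long spurious chord across the hole.
Leading, trailing and interior gaps are treated identically (run-wise);
this is a design choice, as is rejecting duplicate timestamps outright
rather than averaging them (silent aggregation would change L).

### Sampling-interval sensitivity

Coarser sampling acts as a low-pass filter: replacing a path by chords
can only shorten it, so decimation (keep every k-th sample) never
increases GVP. The `resample` operation exists to study this; the
quantitative bands above are calibrated for ~5-min sampling and remain
qualitatively useful at 10–15 min, while 30–60 min sampling is too
coarse for any frequency-sensitive metric.

## Comparison metrics

* **SD/CV** — sample standard deviation (n−1 denominator) and SD/mean.
  The n−1 choice is pinned by the square-wave experiment: 2016
  equal-dwell samples of {40, 400} give 180·√(2016/2015) = 180.04, the
  conventionally reported value (population SD would give 180.00).
* **Distance traveled** — Σ|Δy| over within-run segments.
* **MAG** — distance traveled divided by within-run elapsed time in
  hours, so gap time never inflates the denominator.
* **CONGA(n)** — sample SD of *signed* differences G(t) − G(t − n h).
  A reading pairs with the closest reading n hours earlier if one lies
  within half the nominal interval (5-min data, 1-h lag → pair with the
  12th-previous sample). Published values from closed-source tools use
  unspecified internal variants and are not comparable; this package
  implements the standard definition and cross-checks it against a
  brute-force oracle in the tests.
* **MAGE** — turning points are the local extrema after collapsing
  monotone and flat stretches (endpoints included); an excursion
  between consecutive turning points qualifies when its amplitude
  exceeds one sample SD of the whole trace; MAGE is the mean qualifying
  amplitude counted in the direction (rise/fall) of the first
  qualifying excursion, 0 if none qualify. Several computerized MAGE
  variants exist and disagree; this is the classic turning-point
  reading.

## Simulators

### Square waves

`square_wave` samples an ideal square wave on the grid
t = 0, s, …, (N−1)s with N = ⌊duration·60/s⌋; the level is the start
level while t mod full_period is in the first half-period. The
four-wave experiment (`table1_experiment`) uses full periods
12/24/56/168 h, levels 40/400 mg/dL, 168 h at 5-min sampling → 2016
samples at t = 0..10,075 min, start low; rows are labelled by the
half-period (6/12/28/84 h), the dwell time at one level, which is how
such tables are conventionally indexed. Because the final boundary at
t = 10,080 is never sampled, the waves contain 27/13/5/1 transitions,
and every metric has a closed form (k transitions of amplitude A = 360
at spacing s = 5 over L₀ = 10,075):

GVP = k(√(s²+A²) − s)/L₀ × 100, MAG = kA/(L₀/60), SD = (A/2)√(N/(N−1)).

The generated waves are tested against these closed forms to 1e-9
relative. The start level is free (all metrics are symmetric under
swapping the levels).

### Synthetic cohorts

Clinical CGM study data are not redistributable, so cohort-level
behaviour is exercised with a synthetic generator: per subject,
baseline glucose + Poisson-timed meal-like excursions (triangular
rise/fall over a 2-h span, amplitude ~ truncated normal) + stationary
AR(1) noise (marginal SD `noise_sd`, one-step autocorrelation ρ at the
sampling interval), clipped to the 40–400 mg/dL sensor reporting range.
Defaults: 7-day traces at 5-min sampling, matching common study
duration. A `SeedSequence.spawn` per subject makes output byte-identical
for a given (spec, seed).

Five presets (`nondiabetic`, `t2d`, `t1d_adult`, `t1d_adolescent`,
`high_variability`) were calibrated **once** against the implemented
GVP so that 50-subject median GVPs land at ≈ 17 / 26 / 44 / 61 / 82 %,
emulating the observed ordering of clinical cohorts (nondiabetic
minimal, type 2 low, adult type 1 moderate, adolescent type 1 and
high-variability type 1 high), and then frozen. The generator emulates
the GVP *distribution* of such cohorts, not glucose physiology: there
is no circadian structure, no insulin dynamics, no sensor error model,
and excursion timing is uniform. Passing cohort tests therefore shows
that the pipeline (generation → GVP → percentiles → classification) is
correct and reproducible, not that the presets predict clinical values.

## Cohort analysis

Percentile summaries use linear interpolation between order statistics
(the default of most statistical software; the estimator choice is
pinned by tests against a hand-written sort-based oracle) at levels
0, 2.5, 25, 50, 75, 97.5, 100 — so the 0th/100th levels are exactly the
min/max. Classification bands overlap at their printed boundaries
(≤30 vs 30–50 vs >50); boundaries are assigned to the **lower** class so
every value has exactly one label, frozen by tests (classify(30) = low,
classify(50) = moderate). A subject whose trace cannot support a GVP
(all runs singleton) is flagged in the per-subject table rather than
aborting the cohort; class fractions are taken over non-flagged
subjects and sum to 1.

## Numerical notes and problem sizes

* Arc length uses `numpy.hypot` (overflow-safe) and is tested against a
  loop-wise brute-force sum to 1e-9 relative.
* MAG × elapsed hours equals distance traveled to floating-point
  round-off (a division immediately un-done by a multiplication); tests
  assert 1e-12 relative.
* The decimation-monotonicity property is exact when the decimation
  preserves the endpoints (n − 1 divisible by the factor) and the trace
  is gap-free; property tests generate such traces (n = 289, divisible
  by both tested factors) so the inequality is a theorem, not a
  tendency.
* Displayed GVP is rounded to the nearest integer percent and MAG to
  one decimal, the conventional reporting precisions; all library
  objects keep full precision.
* Test and acceptance workloads use 7-day, 5-min traces (2016 samples)
  and cohorts of ≤ 50 subjects; the whole suite runs in a few seconds.

## Known limitations

* GVP is unit- and sampling-rate-dependent by construction; values are
  comparable only at a common convention (mg/dL, minutes, ~5-min
  sampling).
* No imputation, smoothing or calibration is performed; gap interiors
  are simply excluded.
* The synthetic cohorts are distributional stand-ins (see above).
* CONGA values are comparable only across implementations of the
  standard definition.
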