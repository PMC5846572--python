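# glyvar

Glycemic variability metrics for continuous glucose monitoring (CGM) data.

Patients with diabetes can have a mean glucose in the target range and
still suffer frequent hypo- and hyperglycemic swings. Quantifying that
*glycemic variability* from CGM traces is a long-standing problem: the
most widely used summaries (standard deviation and coefficient of
variation of the glucose values) measure only the amplitude of glucose
excursions and are blind to their frequency. `glyvar` implements the
**glycemic variability percentage (GVP)** — an arc-length statistic that
captures both — together with the classic comparison metrics, simulators
for method studies, and cohort-level summaries. It is aimed at
researchers and analysts working with CGM exports (e.g. 5-minute Dexcom
records).

## The statistic

A CGM trace is a polyline in the (time, glucose) plane. With Δxᵢ the
time between successive readings (minutes) and Δyᵢ the glucose change
over that interval (mg/dL), the trace length and the flat-line
reference length are

```
L  = Σᵢ √(Δxᵢ² + Δyᵢ²)          L₀ = Σᵢ Δxᵢ
```

and the glycemic variability percentage is

```
GVP = (L / L₀ − 1) × 100 .
```

A perfectly flat trace has GVP = 0; both larger and more frequent
excursions lengthen the trace and raise GVP. Because L mixes units
(minutes and mg/dL), the value depends on the glucose unit; the library
enforces mg/dL with time in minutes, the convention under which GVP
bands are defined (minimal ≤ 20, low ≤ 30, moderate 30–50, high > 50).
Data gaps shorten L₀ (and L) by the missing time instead of adding a
spurious chord across the gap.

Also provided: SD, CV, distance traveled (Σ|Δy|), MAG (distance
traveled per hour), CONGA(n) (SD of differences between readings n
hours apart) and MAGE (mean amplitude of glycemic excursions exceeding
one SD).

## Worked example

The frequency sensitivity of the metrics is easiest to see on square
waves: four 7-day traces alternating between 40 and 400 mg/dL (mean
220), sampled every 5 minutes, with full oscillation periods of 12, 24,
56 and 168 h (i.e. half-periods — dwell times at one level — of 6, 12,
28 and 84 h):

```sh
$ gv table1
half_period_h,gvp_percent,mag,conga1,cv,sd
6.0,95,57.9,144.77,0.8184,180.04
12.0,46,27.9,100.44,0.8184,180.04
28.0,18,10.7,62.27,0.8184,180.04
84.0,4,2.1,27.78,0.8184,180.04
```

SD and CV are identical for all four waves — they see only the
amplitude. GVP and MAG fall roughly in proportion to the oscillation
frequency: the fastest wave is 95% longer than a flat line of the same
duration, the slowest only 4% longer. (CONGA1 here is the standard
definition — SD of signed 1-hour lagged differences; other tools ship
internal variants that produce different numbers on the same data.)

The same computation on one trace, from the library:

```python
>>> from glyvar import gvp
>>> from glyvar.simulation import SquareWaveSpec, square_wave
>>> r = gvp(square_wave(SquareWaveSpec(full_period_h=12.0)))
>>> round(r.length, 1), r.baseline, round(r.gvp_percent, 2)
(19660.9, 10075.0, 95.15)
```

The trace is 19,660.9 units long against a 10,075-minute flat
baseline — 95% excess, i.e. high variability (a real 7-day clinical
trace with L = 13,349 and L₀ = 9,670 gives GVP = 38%, moderate).

Other entry points: `gv compute --input trace.csv` for per-trace metric
tables from CSV exports, `gv simulate squarewave` / `gv simulate cohort`
for generated data, and `gv cohort --input-dir DIR` for the seven-level
percentile summary (0, 2.5, 25, 50, 75, 97.5, 100) with variability-band
fractions across a directory of traces.

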