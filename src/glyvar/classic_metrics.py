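"""Established glycemic variability metrics for comparison with GVP.

* SD / CV — sample standard deviation (n-1 denominator) of the glucose
  values and its ratio to the mean; amplitude-only measures, blind to
  the temporal ordering of readings.
* distance traveled — sum of absolute glucose changes between
  successive readings.
* MAG — mean absolute glucose change: distance traveled divided by the
  elapsed time in hours.
* CONGA(n) — continuous overall net glycemic action: SD of the signed
  differences between each reading and the reading n hours earlier.
* MAGE — mean amplitude of glycemic excursions: mean peak-to-nadir
  amplitude of excursions exceeding one SD of the whole trace, counted
  in the direction of the first qualifying excursion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cgm_data import GapReport, GlucoseTrace, detect_gaps
from .errors import InsufficientDataError
from .gvp_core import decompose


@dataclass(frozen=True)
class MetricsBundle:
    """All comparison metrics for one trace (glucose units of the trace)."""

    mean: float
    sd: float
    cv: float
    distance_traveled: float
    mag: float  # per hour
    conga: dict[float, float] = field(default_factory=dict)  # keyed by lag hours
    mage: float = 0.0


def mean_sd_cv(trace: GlucoseTrace) -> tuple[float, float, float]:
    """Arithmetic mean, sample SD (n-1 denominator) and CV = SD/mean."""
    if len(trace) < 2:
        raise InsufficientDataError("need at least 2 samples for SD")
    g = trace.glucose
    mean = float(np.mean(g))
    sd = float(np.std(g, ddof=1))
    return mean, sd, sd / mean


def distance_traveled(trace: GlucoseTrace, gaps: GapReport | None = None) -> float:
    """Sum of |glucose change| over successive within-run readings."""
    seg = decompose(trace, gaps, allow_mmol=True)
    return float(np.sum(np.abs(seg.dy)))


def mag(trace: GlucoseTrace, gaps: GapReport | None = None) -> float:
    """Mean absolute glucose change per hour.

    Distance traveled divided by the within-run elapsed time; gap time
    does not count toward the denominator.
    """
    seg = decompose(trace, gaps, allow_mmol=True)
    hours = float(np.sum(seg.dx)) / 60.0
    if hours <= 0:
        raise InsufficientDataError("elapsed within-run time must be > 0")
    return float(np.sum(np.abs(seg.dy))) / hours


def conga(trace: GlucoseTrace, lag_hours: float = 1.0) -> float:
    """CONGA(n): sample SD of differences G(t) - G(t - lag).

    A reading pairs with the reading closest to ``lag_hours`` earlier if
    one exists within half the nominal interval; at least two pairs are
    required.  A constant trace, or a perfect linear ramp, gives 0.
    """
    if not (lag_hours > 0):
        raise InsufficientDataError("lag_hours must be > 0")
    t = trace.timestamps
    g = trace.glucose
    lag_min = lag_hours * 60.0
    tol = trace.nominal_interval / 2.0
    target = t - lag_min
    idx = np.searchsorted(t, target)
    # candidate partners: t[idx-1] and t[idx]; pick the closer one
    lo = np.clip(idx - 1, 0, t.size - 1)
    hi = np.clip(idx, 0, t.size - 1)
    pick = np.where(np.abs(t[hi] - target) < np.abs(t[lo] - target), hi, lo)
    valid = np.abs(t[pick] - target) <= tol
    if np.count_nonzero(valid) < 2:
        raise InsufficientDataError(
            f"fewer than 2 readings have a partner {lag_hours} h earlier"
        )
    diffs = g[valid] - g[pick[valid]]
    return float(np.std(diffs, ddof=1))


def _turning_points(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices and values of local extrema after collapsing flat stretches.

    Endpoints are always included, so amplitudes between consecutive
    turning points cover the whole profile.
    """
    keep = np.concatenate(([True], np.diff(values) != 0))
    idx = np.flatnonzero(keep)
    v = values[idx]
    if v.size <= 2:
        return idx, v
    d = np.sign(np.diff(v))
    interior = np.flatnonzero(d[1:] != d[:-1]) + 1
    sel = np.concatenate(([0], interior, [v.size - 1]))
    return idx[sel], v[sel]


def mage(trace: GlucoseTrace) -> float:
    """Mean amplitude of glycemic excursions.

    Turning points are the local extrema of the trace (monotone and flat
    stretches collapsed).  An excursion between consecutive turning
    points qualifies when its amplitude exceeds one sample SD of the
    whole trace; MAGE is the mean amplitude of qualifying excursions
    measured in the direction (rise or fall) of the first one.  Returns
    0 when no excursion qualifies.
    """
    if len(trace) < 3:
        raise InsufficientDataError("need at least 3 samples for MAGE")
    _, sd, _ = mean_sd_cv(trace)
    _, tp = _turning_points(trace.glucose)
    if tp.size < 2 or sd == 0:
        return 0.0
    swings = np.diff(tp)
    qual = np.abs(swings) > sd
    if not np.any(qual):
        return 0.0
    direction = np.sign(swings[np.argmax(qual)])
    amps = np.abs(swings[qual & (np.sign(swings) == direction)])
    return float(np.mean(amps))


def metrics_bundle(
    trace: GlucoseTrace,
    gap_threshold: float | None = None,
    conga_lags: tuple[float, ...] = (1.0,),
) -> MetricsBundle:
    """Compute every comparison metric for one trace."""
    gaps = detect_gaps(trace, gap_threshold)
    mean, sd, cv = mean_sd_cv(trace)
    dist = distance_traveled(trace, gaps)
    congas = {}
    for lag in conga_lags:
        try:
            congas[lag] = conga(trace, lag)
        except InsufficientDataError:
            congas[lag] = float("nan")
    return MetricsBundle(
        mean=mean,
        sd=sd,
        cv=cv,
        distance_traveled=dist,
        mag=mag(trace, gaps),
        conga=congas,
        mage=mage(trace),
    )
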