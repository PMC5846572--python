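"""Shared fixtures and independent oracles for the glyvar test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import settings

from glyvar import GlucoseTrace
from glyvar.simulation import SquareWaveSpec, square_wave

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def flat_trace() -> GlucoseTrace:
    """Ten minutes of perfectly constant glucose."""
    return GlucoseTrace(timestamps=[0, 5, 10], glucose=[100, 100, 100])


@pytest.fixture
def wave_12h() -> GlucoseTrace:
    """The highest-frequency wave of the four-wave experiment."""
    return square_wave(SquareWaveSpec(full_period_h=12.0))


def make_random_trace(seed: int, n: int = 289, jitter: float = 0.5) -> GlucoseTrace:
    """A gap-free noisy trace on a jittered ~5-min grid.

    ``n`` defaults to 289 so that n-1 is divisible by both 2 and 3 and
    decimation preserves the endpoints.
    """
    rng = np.random.default_rng(seed)
    dt = 5.0 + rng.uniform(-jitter, jitter, size=n - 1)
    t = np.concatenate(([0.0], np.cumsum(dt)))
    g = np.clip(
        120 + np.cumsum(rng.normal(0, 4, size=n)) + rng.normal(0, 3, size=n),
        40,
        400,
    )
    return GlucoseTrace(timestamps=t, glucose=g)


# ---------------------------------------------------------------- oracles

def brute_force_length(timestamps, glucose) -> float:
    """Loop-wise Pythagorean arc length, independent of the vectorized path."""
    total = 0.0
    for i in range(1, len(timestamps)):
        total += math.sqrt(
            (timestamps[i] - timestamps[i - 1]) ** 2
            + (glucose[i] - glucose[i - 1]) ** 2
        )
    return total


def brute_force_percentile(values, level: float) -> float:
    """Linear interpolation between order statistics, written from scratch."""
    v = sorted(values)
    if len(v) == 1:
        return v[0]
    h = (len(v) - 1) * level / 100.0
    lo = math.floor(h)
    hi = math.ceil(h)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


def brute_force_conga(trace: GlucoseTrace, lag_hours: float) -> float:
    """Direct SD of lagged differences with nearest-sample pairing."""
    t = list(trace.timestamps)
    g = list(trace.glucose)
    tol = trace.nominal_interval / 2.0
    diffs = []
    for i in range(len(t)):
        target = t[i] - lag_hours * 60.0
        best, best_err = None, None
        for j in range(len(t)):
            err = abs(t[j] - target)
            if best_err is None or err < best_err:
                best, best_err = j, err
        if best_err is not None and best_err <= tol:
            diffs.append(g[i] - g[best])
    mean = sum(diffs) / len(diffs)
    return math.sqrt(sum((d - mean) ** 2 for d in diffs) / (len(diffs) - 1))


def square_wave_closed_forms(spec: SquareWaveSpec) -> dict[str, float]:
    """Closed-form metrics for a sampled square wave with equal dwell counts.

    With N samples at spacing s, amplitude A = high - low, and
    k = floor((N-1)s / half_period) sampled transitions:
    L0 = (N-1)s, L = L0 + k(sqrt(s^2+A^2) - s), distance = kA,
    MAG = kA / (L0/60); with equal dwell counts the sample SD is
    (A/2) sqrt(N/(N-1)).
    """
    n = math.floor(spec.duration_h * 60.0 / spec.sampling_min)
    s = spec.sampling_min
    amp = spec.high - spec.low
    l0 = (n - 1) * s
    half_period_min = spec.full_period_h * 60.0 / 2.0
    k = math.floor(l0 / half_period_min)
    length = l0 + k * (math.sqrt(s**2 + amp**2) - s)
    mean = (spec.low + spec.high) / 2.0
    sd = (amp / 2.0) * math.sqrt(n / (n - 1))
    return {
        "n": n,
        "k": k,
        "L0": l0,
        "L": length,
        "gvp_percent": (length / l0 - 1.0) * 100.0,
        "distance": k * amp,
        "mag": k * amp / (l0 / 60.0),
        "mean": mean,
        "sd": sd,
        "cv": sd / mean,
    }
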