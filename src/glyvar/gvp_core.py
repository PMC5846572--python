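"""The glycemic variability percentage (GVP): arc length of a CGM trace.

The trace is decomposed into line segments between consecutive readings
within each contiguous run.  With ``dx`` the time step in minutes and
``dy`` the glucose change in mg/dL, the trace length is the Pythagorean
sum

    L = sum_i sqrt(dx_i**2 + dy_i**2)

and the flat-line reference length is the total within-run time

    L0 = sum_i dx_i

so

    GVP = (L / L0 - 1) * 100

is the percentage by which the trace is longer than a perfectly flat
trace of the same duration.  A constant trace has GVP = 0; higher
amplitude *or* higher frequency of glucose oscillation both increase it.
L mixes units (minutes and mg/dL), so the value depends on the glucose
unit; the canonical convention, enforced here, is mg/dL with time in
minutes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cgm_data import MGDL, GapReport, GlucoseTrace, detect_gaps
from .errors import InsufficientDataError, UnitError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegmentDecomposition:
    """Per-segment (dx, dy) differences over within-run sample pairs."""

    dx: np.ndarray  # minutes, all > 0
    dy: np.ndarray  # mg/dL

    @property
    def n(self) -> int:
        return int(self.dx.size)


@dataclass(frozen=True)
class GVPResult:
    """GVP together with its ingredients.

    ``length`` (L) is in mixed units (minutes (+) mg/dL), ``baseline``
    (L0) in minutes, ``gvp_percent`` in percent; ``excluded_minutes`` is
    the gap time removed from both.
    """

    length: float
    baseline: float
    gvp_percent: float
    n_segments: int
    excluded_minutes: float


def decompose(
    trace: GlucoseTrace,
    gaps: GapReport | None = None,
    allow_mmol: bool = False,
) -> SegmentDecomposition:
    """Build the per-segment (dx, dy) pairs, skipping cross-gap pairs.

    The trace must be in mg/dL; because the statistic is unit dependent,
    mmol/L input raises :class:`UnitError` unless ``allow_mmol`` is set,
    in which case a warning is logged and the values are used as-is.
    """
    if trace.unit != MGDL:
        if not allow_mmol:
            raise UnitError(
                "GVP is defined on mg/dL traces; convert with "
                "convert_units() or pass allow_mmol=True"
            )
        logger.warning(
            "computing segment decomposition on a %s trace; the resulting "
            "GVP is not comparable with mg/dL-based values",
            trace.unit,
        )
    if gaps is None:
        gaps = detect_gaps(trace)
    dx_parts = []
    dy_parts = []
    for a, b in gaps.runs:
        if b - a >= 2:
            dx_parts.append(np.diff(trace.timestamps[a:b]))
            dy_parts.append(np.diff(trace.glucose[a:b]))
    if not dx_parts:
        raise InsufficientDataError(
            "no run with at least 2 samples; cannot form any segment"
        )
    return SegmentDecomposition(
        dx=np.concatenate(dx_parts), dy=np.concatenate(dy_parts)
    )


def trace_length(seg: SegmentDecomposition) -> float:
    """L: Pythagorean sum of segment lengths sqrt(dx^2 + dy^2)."""
    if seg.n < 1:
        raise InsufficientDataError("need at least one segment")
    return float(np.sum(np.hypot(seg.dx, seg.dy)))


def baseline_length(seg: SegmentDecomposition) -> float:
    """L0: total within-run time in minutes (sum of dx)."""
    if seg.n < 1:
        raise InsufficientDataError("need at least one segment")
    return float(np.sum(seg.dx))


def gvp_percent_from_lengths(length: float, baseline: float) -> float:
    """GVP = (L / L0 - 1) * 100 from already-computed line lengths."""
    if baseline <= 0:
        raise InsufficientDataError("baseline length must be > 0")
    return (length / baseline - 1.0) * 100.0


def gvp(
    trace: GlucoseTrace,
    gap_threshold: float | None = None,
    allow_mmol: bool = False,
) -> GVPResult:
    """Compute the glycemic variability percentage of a trace.

    Gaps (consecutive samples further apart than ``gap_threshold``,
    default 1.5 x the nominal interval) are excluded from both L and L0,
    so missing data shortens the reference flat line rather than
    contributing a spurious long chord.
    """
    gaps = detect_gaps(trace, gap_threshold)
    seg = decompose(trace, gaps, allow_mmol=allow_mmol)
    length = trace_length(seg)
    baseline = baseline_length(seg)
    return GVPResult(
        length=length,
        baseline=baseline,
        gvp_percent=gvp_percent_from_lengths(length, baseline),
        n_segments=seg.n,
        excluded_minutes=gaps.excluded_minutes,
    )
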