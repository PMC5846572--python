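"""Cohort-level summaries: percentile tables and variability classification.

Mirrors the interquartile analysis used to characterise GVP across
study cohorts: per-subject metric values are summarised at the 0, 2.5,
25, 50, 75, 97.5 and 100th percentiles, and individual GVP values map
to one of four variability bands (minimal / low / moderate / high).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cgm_data import GlucoseTrace
from .errors import InsufficientDataError, ValidationError
from .gvp_core import gvp

#: Percentile levels of the cohort summary table.
PERCENTILE_LEVELS = (0.0, 2.5, 25.0, 50.0, 75.0, 97.5, 100.0)

#: Upper bounds (inclusive) of the variability classes, in GVP percent.
CLASS_BOUNDS = (("minimal", 20.0), ("low", 30.0), ("moderate", 50.0))
CLASS_LABELS = ("minimal", "low", "moderate", "high")


@dataclass(frozen=True)
class CohortSummary:
    """Percentile table of one metric over the subjects of one cohort."""

    cohort_label: str
    metric_name: str
    percentiles: dict[float, float]
    n_subjects: int


@dataclass(frozen=True)
class VariabilityClass:
    """A GVP value with its variability band."""

    label: str
    gvp_percent: float


def percentile_summary(
    values,
    cohort_label: str = "",
    metric_name: str = "gvp",
    levels: tuple[float, ...] = PERCENTILE_LEVELS,
) -> CohortSummary:
    """Summarise per-subject values at the standard percentile levels.

    Percentiles use linear interpolation between order statistics, so
    the 0th and 100th levels are exactly the minimum and maximum.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise InsufficientDataError("percentile_summary needs at least one value")
    if not np.all(np.isfinite(v)):
        raise ValidationError("all values must be finite")
    pct = np.percentile(v, levels, method="linear")
    return CohortSummary(
        cohort_label=cohort_label,
        metric_name=metric_name,
        percentiles=dict(zip((float(p) for p in levels), map(float, pct))),
        n_subjects=int(v.size),
    )


def classify(gvp_percent: float) -> VariabilityClass:
    """Map a GVP value to its variability band.

    minimal: <= 20; low: 20 < x <= 30; moderate: 30 < x <= 50; high: > 50.
    Boundary values belong to the lower band.
    """
    x = float(gvp_percent)
    if not np.isfinite(x) or x < 0:
        raise ValidationError(f"GVP must be a finite non-negative percent, got {x!r}")
    for label, upper in CLASS_BOUNDS:
        if x <= upper:
            return VariabilityClass(label=label, gvp_percent=x)
    return VariabilityClass(label="high", gvp_percent=x)


def cohort_report(
    traces: list[GlucoseTrace],
    cohort_label: str = "",
    gap_threshold: float | None = None,
) -> tuple[CohortSummary, pd.DataFrame]:
    """Per-subject GVP with classification plus the cohort percentile table.

    Subjects whose trace cannot support a GVP (e.g. all runs singleton)
    are flagged in the per-subject table rather than aborting the run;
    they are excluded from the summary and the class fractions.

    Returns
    -------
    (CohortSummary, DataFrame)
        The DataFrame has one row per subject with columns ``subject``,
        ``gvp_percent``, ``variability_class``, ``flag``, and carries the
        per-class fractions over non-flagged subjects in
        ``df.attrs["class_fractions"]``.
    """
    if not traces:
        raise InsufficientDataError("cohort_report needs at least one trace")
    rows = []
    for i, trace in enumerate(traces):
        try:
            result = gvp(trace, gap_threshold)
        except InsufficientDataError as exc:
            rows.append(
                {
                    "subject": i,
                    "gvp_percent": np.nan,
                    "variability_class": None,
                    "flag": str(exc),
                }
            )
            continue
        rows.append(
            {
                "subject": i,
                "gvp_percent": result.gvp_percent,
                "variability_class": classify(result.gvp_percent).label,
                "flag": "",
            }
        )
    df = pd.DataFrame(rows)
    ok = df["flag"] == ""
    if not ok.any():
        raise InsufficientDataError("no subject produced a valid GVP")
    counts = df.loc[ok, "variability_class"].value_counts()
    df.attrs["class_fractions"] = {
        label: float(counts.get(label, 0)) / int(ok.sum()) for label in CLASS_LABELS
    }
    summary = percentile_summary(
        df.loc[ok, "gvp_percent"], cohort_label=cohort_label, metric_name="gvp"
    )
    return summary, df
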