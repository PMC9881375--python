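"""Detection-overlap and coverage arithmetic for acquisition-method
comparisons.

Given boolean detection matrices (analyte × sample) from repeated runs of
an acquisition method, these functions compute the summary statistics used
to compare methods: per-sample detection counts, the count detected in all
samples, the "sample overlap" percentage, percent increases between
methods, and coverage of a target universe.

Sample overlap is defined as 100 × (count detected in all samples) /
(maximum per-sample count) — the all/max convention; an all/mean variant
is available behind a flag.  Percentages are returned unrounded; reports
round to the nearest integer.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "OverlapReport",
    "overlap_percent",
    "percent_increase",
    "coverage_percent",
]


@dataclass
class OverlapReport:
    """Detection-overlap summary for one method's detection matrix."""

    per_sample_counts: pd.Series
    all_samples_count: int
    percent: float
    min_count: int
    max_count: int
    denominator: str = "max"

    @property
    def percent_rounded(self) -> int:
        return round(self.percent)


def overlap_percent(
    matrix: pd.DataFrame, denominator: str = "max"
) -> OverlapReport:
    """Sample-overlap statistics of a boolean analyte × sample matrix.

    ``denominator`` is ``"max"`` (default: the maximum per-sample count)
    or ``"mean"`` (the mean per-sample count).  Requires ≥2 samples.
    """
    if matrix.size == 0:
        raise ValueError("empty detection matrix")
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    m = matrix.astype(bool)
    per_sample = m.sum(axis=0)
    all_count = int(m.all(axis=1).sum())
    if denominator == "max":
        denom = float(per_sample.max())
    elif denominator == "mean":
        denom = float(per_sample.mean())
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom == 0:
        raise ValueError("no detections in any sample")
    return OverlapReport(
        per_sample_counts=per_sample,
        all_samples_count=all_count,
        percent=100.0 * all_count / denom,
        min_count=int(per_sample.min()),
        max_count=int(per_sample.max()),
        denominator=denominator,
    )


def percent_increase(reference_count: float, new_count: float) -> float:
    """Percent increase from a reference count to a new count."""
    if reference_count <= 0:
        raise ValueError("reference count must be > 0")
    return 100.0 * (new_count - reference_count) / reference_count


def coverage_percent(targeted_count: float, universe_count: float) -> float:
    """Percent of a universe covered by a targeted subset."""
    if universe_count <= 0:
        raise ValueError("universe count must be > 0")
    if targeted_count > universe_count or targeted_count < 0:
        raise ValueError("targeted count must be in [0, universe]")
    return 100.0 * targeted_count / universe_count
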