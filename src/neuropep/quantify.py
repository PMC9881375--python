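"""Label-free differential quantification of targeted-PRM transition reports.

The pipeline mirrors a scheduled-PRM label-free workflow between two
conditions (fed L3 vs dauer juveniles in the emulated study):

1. :func:`retain_transitions` — drop user-flagged interfering transitions,
   but only while at least five transitions remain per peptide;
2. :func:`aggregate_peptide_areas` — sum fragment areas over fragments,
   charge states and Met-oxidized variants into one area per peptide and
   run;
3. :func:`median_normalize` — per-run normalization by the median
   abundance of all MS1 features;
4. :func:`apply_detection_policy` — retain a peptide only when detected in
   all replicates of both conditions ("quantifiable") or in all replicates
   of exactly one condition ("on/off"); any partial pattern is dropped.
   Remaining zero areas are replaced by the minimum value of the entire
   dataset;
5. :class:`DifferentialAbundance` — two-sided Student's t test on log10
   areas, fold change ``10^(mean2 − mean1)``.

Order of operations: normalize → detection policy / imputation → log10 →
test.  The pipeline is scale-invariant: multiplying one run's raw areas by
any positive constant leaves the differential results unchanged after
normalization.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QuantMatrix",
    "CVReport",
    "retain_transitions",
    "aggregate_peptide_areas",
    "median_normalize",
    "apply_detection_policy",
    "DifferentialAbundance",
    "DifferentialAbundanceResults",
    "compute_cv",
]

REPORT_COLUMNS = (
    "run", "condition", "replicate", "peptide", "precursor_charge",
    "variant", "fragment", "area", "detected",
)


@dataclass
class QuantMatrix:
    """Peptide × run matrix of aggregated fragment areas.

    ``areas`` is indexed by peptide with one column per run;
    ``conditions`` maps run → condition label; ``detected`` flags whether
    the peptide's signal in that run was a real peak (vs integrated
    background); ``norm_factors`` records the per-run divisors applied by
    median normalization; ``classes`` (after the detection policy) maps
    every input peptide to {"quantifiable", "on_off", "dropped"}.
    """

    areas: pd.DataFrame
    conditions: pd.Series
    detected: pd.DataFrame
    norm_factors: pd.Series | None = None
    classes: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.areas.values < 0).any():
            raise ValueError("areas must be non-negative")
        if not self.areas.columns.equals(self.detected.columns) or not (
            self.areas.index.equals(self.detected.index)
        ):
            raise ValueError("areas and detected must be aligned")
        missing = set(self.areas.columns) - set(self.conditions.index)
        if missing:
            raise ValueError(f"runs without condition labels: {sorted(missing)}")

    @property
    def runs(self) -> list[str]:
        return list(self.areas.columns)

    def condition_runs(self, condition: str) -> list[str]:
        return [r for r in self.runs if self.conditions[r] == condition]

    def copy(self) -> "QuantMatrix":
        return QuantMatrix(
            self.areas.copy(), self.conditions.copy(), self.detected.copy(),
            None if self.norm_factors is None else self.norm_factors.copy(),
            None if self.classes is None else self.classes.copy(),
        )


def retain_transitions(
    report: pd.DataFrame,
    flagged: Iterable[dict] | pd.DataFrame | None = None,
    min_transitions: int = 5,
) -> tuple[pd.DataFrame, list[dict]]:
    """Remove user-flagged interfering transitions, keeping ≥5 per peptide.

    ``flagged`` rows identify transitions by ``peptide`` and ``fragment``
    (optionally also ``precursor_charge`` and ``variant``).  A removal that
    would leave the peptide with fewer than ``min_transitions`` distinct
    transitions is refused and reported in the returned list.  Peptides
    entering with fewer than ``min_transitions`` transitions trigger a
    warning but are retained as-is.
    """
    if flagged is None:
        return report.copy(), []
    if isinstance(flagged, pd.DataFrame):
        flagged = flagged.to_dict("records")

    ion_cols = ["precursor_charge", "variant", "fragment"]
    counts = report.groupby("peptide")[ion_cols].apply(
        lambda g: len(g.drop_duplicates())
    )
    low = counts[counts < min_transitions]
    if not low.empty:
        warnings.warn(
            f"peptides with fewer than {min_transitions} transitions in the "
            f"input (retained as-is): {sorted(low.index)}",
            stacklevel=2,
        )

    out = report.copy()
    refused = []
    for flag in flagged:
        pep = flag["peptide"]
        mask = out["peptide"] == pep
        for col in ("fragment", "precursor_charge", "variant"):
            if col in flag and flag[col] is not None:
                mask &= out[col] == flag[col]
        if not mask.any():
            continue
        remaining = out.loc[(out["peptide"] == pep) & ~mask, ion_cols]
        if len(remaining.drop_duplicates()) < min_transitions:
            refused.append(flag)
            continue
        out = out.loc[~mask]
    return out.reset_index(drop=True), refused


def aggregate_peptide_areas(report: pd.DataFrame) -> QuantMatrix:
    """Sum fragment areas into one total area per peptide and run.

    When multiple ions exist for a peptide (different charge state,
    Met-oxidized variant), the total fragment area of all the ions is
    summed.  A peptide-run cell with no rows gets area 0 and
    ``detected=False``; a cell is flagged detected when any of its
    contributing rows is detected.
    """
    areas = report.pivot_table(
        index="peptide", columns="run", values="area", aggfunc="sum", fill_value=0.0
    )
    if "detected" in report.columns:
        detected = report.pivot_table(
            index="peptide", columns="run", values="detected", aggfunc="any",
            fill_value=False,
        ).astype(bool)
    else:
        detected = areas > 0
    detected = detected.reindex(index=areas.index, columns=areas.columns,
                                fill_value=False)
    conditions = (
        report.drop_duplicates("run").set_index("run")["condition"]
    )
    return QuantMatrix(areas=areas, conditions=conditions, detected=detected)


def median_normalize(
    matrix: QuantMatrix, ms1_features: pd.DataFrame | None = None
) -> QuantMatrix:
    """Normalize each run by its median MS1-feature abundance.

    Each run's areas are divided by (run MS1 median / grand median of the
    run medians), so post-normalization the runs' MS1 medians are equal
    and the overall scale is preserved.  When no MS1 feature table is
    supplied, the per-run median of the peptide areas themselves is used
    as a fallback, with a warning.
    """
    if ms1_features is not None:
        med = ms1_features.groupby("run")["area"].median()
        missing = set(matrix.runs) - set(med.index)
        if missing:
            raise ValueError(f"runs without MS1 features: {sorted(missing)}")
        zero = med[med.reindex(matrix.runs) <= 0]
        if not zero.empty:
            raise ValueError(f"runs with non-positive MS1 median: {list(zero.index)}")
        med = med.reindex(matrix.runs)
    else:
        warnings.warn(
            "no MS1 feature table supplied; falling back to the per-run "
            "median of peptide areas",
            stacklevel=2,
        )
        med = matrix.areas.median(axis=0)
        if (med <= 0).any():
            raise ValueError("runs with non-positive peptide-area median")
    grand = med.median()
    factors = med / grand
    out = matrix.copy()
    out.areas = matrix.areas.div(factors, axis=1)
    out.norm_factors = factors
    return out


def apply_detection_policy(matrix: QuantMatrix) -> QuantMatrix:
    """Apply the all-replicates detection policy and minimum imputation.

    Peptides detected in all replicates of both conditions are
    "quantifiable"; peptides detected in all replicates of exactly one
    condition and none of the other are "on/off" (their areas in the
    undetected condition are the integrated background already present in
    the matrix); any other pattern is "dropped" and removed.  Remaining
    zero areas among retained peptides are replaced by the minimum
    positive value of the entire retained dataset.
    """
    conds = sorted(set(matrix.conditions[matrix.runs]))
    if len(conds) != 2:
        raise ValueError(f"detection policy requires exactly 2 conditions, got {conds}")
    runs1 = matrix.condition_runs(conds[0])
    runs2 = matrix.condition_runs(conds[1])

    det1 = matrix.detected[runs1].all(axis=1)
    det2 = matrix.detected[runs2].all(axis=1)
    none1 = ~matrix.detected[runs1].any(axis=1)
    none2 = ~matrix.detected[runs2].any(axis=1)

    classes = pd.Series("dropped", index=matrix.areas.index, dtype=object)
    classes[det1 & det2] = "quantifiable"
    classes[(det1 & none2) | (det2 & none1)] = "on_off"

    keep = classes != "dropped"
    areas = matrix.areas.loc[keep].copy()
    if (areas.values == 0).any():
        positive = areas.values[areas.values > 0]
        if positive.size == 0:
            raise ValueError("all retained areas are zero; nothing to impute from")
        floor = positive.min()
        areas = areas.mask(areas == 0, floor)
    return QuantMatrix(
        areas=areas,
        conditions=matrix.conditions,
        detected=matrix.detected.loc[keep],
        norm_factors=matrix.norm_factors,
        classes=classes,
    )


@dataclass
class DifferentialAbundanceResults:
    """Per-peptide differential statistics between two conditions.

    ``table`` columns: peptide class, per-condition log10 means, log10
    fold change and linear fold change (condition2 / condition1), t
    statistic, two-sided p, Benjamini–Hochberg q (emitted additionally;
    the headline significance uses the unadjusted p, matching the volcano
    presentation), and a ``degenerate`` flag for zero pooled variance.
    """

    table: pd.DataFrame
    condition1: str
    condition2: str
    alpha: float = 0.05

    @property
    def n_significant(self) -> int:
        return int((self.table["p"] < self.alpha).sum())

    def summary(self) -> str:
        t = self.table
        up = int(((t["p"] < self.alpha) & (t["log10_fold_change"] > 0)).sum())
        down = int(((t["p"] < self.alpha) & (t["log10_fold_change"] < 0)).sum())
        lines = [
            f"Differential abundance: {self.condition2} vs {self.condition1}",
            f"peptides tested: {len(t)} "
            f"(quantifiable: {(t['class'] == 'quantifiable').sum()}, "
            f"on/off: {(t['class'] == 'on_off').sum()})",
            f"significant at p < {self.alpha}: {self.n_significant} "
            f"({up} up in {self.condition2}, {down} down)",
            "",
            t.head(20).to_string(float_format=lambda v: f"{v:.4g}"),
        ]
        if len(t) > 20:
            lines.append(f"... ({len(t) - 20} more peptides)")
        return "\n".join(lines)

    def plot_volcano(self, ax=None, alpha: float | None = None):
        """Volcano plot: log10 fold change vs −log10 p.

        Quantifiable peptides are circles; on/off peptides (detected in
        only one condition) are triangles.
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        alpha = self.alpha if alpha is None else alpha
        t = self.table
        for cls, marker in (("quantifiable", "o"), ("on_off", "v")):
            sub = t[t["class"] == cls]
            ax.scatter(
                sub["log10_fold_change"], -np.log10(sub["p"]),
                marker=marker, s=18, alpha=0.7, label=cls,
            )
        ax.axhline(-math.log10(alpha), ls="--", lw=0.8, color="grey")
        ax.set_xlabel(
            f"log10 fold change ({self.condition2} / {self.condition1})"
        )
        ax.set_ylabel("-log10 p")
        ax.legend(frameon=False)
        return ax


class DifferentialAbundance:
    """Two-condition differential-abundance model for a quant matrix.

    The model is a per-peptide two-sample comparison of log10-transformed
    normalized areas using a two-sided Student's t test (equal-variance by
    default; Welch via ``equal_var=False``).  The fold change is
    ``10^(mean2 − mean1)`` on the linear scale.

    Construct from an already-processed :class:`QuantMatrix`, or use
    :meth:`from_report` to run the full pipeline (retain → aggregate →
    normalize → detection policy) from a transition-level report.
    """

    def __init__(
        self,
        matrix: QuantMatrix,
        reference: str | None = None,
        equal_var: bool = True,
        alpha: float = 0.05,
    ):
        conds = sorted(set(matrix.conditions[matrix.runs]))
        if len(conds) != 2:
            raise ValueError("exactly two conditions required")
        if reference is not None:
            if reference not in conds:
                raise ValueError(f"reference {reference!r} not among {conds}")
            conds = [reference] + [c for c in conds if c != reference]
        self.condition1, self.condition2 = conds
        for c in conds:
            if len(matrix.condition_runs(c)) < 2:
                raise ValueError(f"condition {c!r} has fewer than 2 replicates")
        self.matrix = matrix
        self.equal_var = equal_var
        self.alpha = alpha

    @classmethod
    def from_report(
        cls,
        report: pd.DataFrame,
        ms1_features: pd.DataFrame | None = None,
        flagged: Iterable[dict] | None = None,
        reference: str | None = None,
        equal_var: bool = True,
        alpha: float = 0.05,
    ) -> "DifferentialAbundance":
        retained, _ = retain_transitions(report, flagged)
        matrix = aggregate_peptide_areas(retained)
        matrix = median_normalize(matrix, ms1_features)
        matrix = apply_detection_policy(matrix)
        return cls(matrix, reference=reference, equal_var=equal_var, alpha=alpha)

    def fit(self) -> DifferentialAbundanceResults:
        m = self.matrix
        runs1 = m.condition_runs(self.condition1)
        runs2 = m.condition_runs(self.condition2)
        x1 = np.log10(m.areas[runs1].values)
        x2 = np.log10(m.areas[runs2].values)
        mean1 = x1.mean(axis=1)
        mean2 = x2.mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            t, p = stats.ttest_ind(x2, x1, axis=1, equal_var=self.equal_var)
        # zero pooled variance: p undefined, flagged rather than reported
        degenerate = ~np.isfinite(t)
        t = np.where(degenerate, np.nan, t)
        p = np.where(degenerate, np.nan, p)
        q = np.full(len(p), np.nan)
        ok = np.isfinite(p)
        if ok.any():
            q[ok] = stats.false_discovery_control(p[ok])
        classes = (
            m.classes.reindex(m.areas.index)
            if m.classes is not None
            else pd.Series("quantifiable", index=m.areas.index)
        )
        table = pd.DataFrame(
            {
                "class": classes.values,
                f"mean_log10_{self.condition1}": mean1,
                f"mean_log10_{self.condition2}": mean2,
                "log10_fold_change": mean2 - mean1,
                "fold_change": 10 ** (mean2 - mean1),
                "t": t,
                "p": p,
                "q": q,
                "degenerate": degenerate,
            },
            index=m.areas.index,
        )
        return DifferentialAbundanceResults(
            table=table, condition1=self.condition1, condition2=self.condition2,
            alpha=self.alpha,
        )


@dataclass
class CVReport:
    """Per-peptide coefficients of variation across technical replicates.

    ``per_peptide`` holds CV% = 100·sd/mean on linear-scale areas; the
    summary is the median across peptides ± the SEM of the per-peptide
    CVs.  Peptides with zero mean are excluded and listed.
    """

    per_peptide: pd.Series
    median_cv: float
    sem: float
    excluded: list = field(default_factory=list)


def compute_cv(matrix: QuantMatrix) -> CVReport:
    """CV% per peptide across the runs of a (technical-replicate) matrix."""
    if len(matrix.runs) < 2:
        raise ValueError("need at least 2 replicates")
    means = matrix.areas.mean(axis=1)
    sds = matrix.areas.std(axis=1, ddof=1)
    excluded = list(means.index[means == 0])
    valid = means != 0
    cv = 100.0 * sds[valid] / means[valid]
    sem = float(cv.std(ddof=1) / math.sqrt(len(cv))) if len(cv) > 1 else math.nan
    return CVReport(
        per_peptide=cv, median_cv=float(cv.median()), sem=sem, excluded=excluded
    )
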