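"""Simulation-based power analysis for two-condition peptide quantification.

Given per-peptide log10-scale means and standard deviations estimated from
a quantification experiment, :class:`PowerStudy` simulates two-sample
comparisons over a grid of effect sizes (fold changes) and sample sizes
(replicates per condition), applies the same two-sided Student's t test as
the differential pipeline, and records the percentage of simulations that
reach significance.  The defaults are the study grid: fold changes
{1.1, 1.2, 1.5, 2, 4} × replicates {4, 6, 8, 10, 15, 20}, 500 simulations
per cell at α = 0.05 — 30 cells per peptide.

Simulation is on the log10 scale (where the test is run), the fold change
entering as an additive log10 shift to condition 2's mean; each condition
keeps its own standard deviation.  The RNG is seeded with one substream
per (peptide, effect size, sample size) cell, so any grid cell is
reproducible in isolation.

:func:`analytic_power` gives the closed-form noncentral-t power of the
same test for cross-checking the simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["PowerConfig", "PowerGrid", "PowerStudy", "simulate_power", "analytic_power"]


@dataclass(frozen=True)
class PowerConfig:
    """Grid and simulation settings for the power analysis."""

    effect_sizes: tuple[float, ...] = (1.1, 1.2, 1.5, 2.0, 4.0)
    sample_sizes: tuple[int, ...] = (4, 6, 8, 10, 15, 20)
    n_sims: int = 500
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if any(fc <= 0 for fc in self.effect_sizes):
            raise ValueError("fold changes must be > 0")
        if any(n < 2 for n in self.sample_sizes):
            raise ValueError("sample sizes must be ≥ 2")
        if self.n_sims < 1:
            raise ValueError("n_sims must be ≥ 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class PowerGrid:
    """Percent of significant simulations per (peptide, effect, n) cell.

    ``grid`` is long-format with columns peptide, fold_change, n,
    power_percent (∈ [0, 100]).
    """

    grid: pd.DataFrame
    config: PowerConfig

    def pivot(self, peptide: str) -> pd.DataFrame:
        """Effect-size × sample-size table for one peptide."""
        sub = self.grid[self.grid["peptide"] == peptide]
        return sub.pivot(index="fold_change", columns="n", values="power_percent")

    def summary(self, threshold: float = 95.0) -> pd.DataFrame:
        """Per (effect size, n): fraction of peptides with power ≥ threshold."""
        out = (
            self.grid.assign(reached=self.grid["power_percent"] >= threshold)
            .groupby(["fold_change", "n"], as_index=False)["reached"]
            .mean()
            .rename(columns={"reached": "fraction_reaching"})
        )
        return out

    def mean_power(self) -> pd.DataFrame:
        """Per (effect size, n): power averaged over peptides."""
        return (
            self.grid.groupby(["fold_change", "n"], as_index=False)["power_percent"]
            .mean()
        )


class PowerStudy:
    """Power simulation over an effect-size × sample-size grid.

    Parameters
    ----------
    peptide_stats : DataFrame with columns ``peptide``, ``mean`` (log10
        mean of condition 1), ``sd`` (log10 sd of condition 1) and
        optionally ``sd_2`` (condition 2's sd; defaults to ``sd``).
    config : :class:`PowerConfig`
    """

    def __init__(self, peptide_stats: pd.DataFrame, config: PowerConfig | None = None):
        required = {"peptide", "mean", "sd"}
        missing = required - set(peptide_stats.columns)
        if missing:
            raise ValueError(f"peptide_stats missing columns {sorted(missing)}")
        if (peptide_stats["sd"] < 0).any():
            raise ValueError("sd must be ≥ 0")
        self.peptide_stats = peptide_stats.reset_index(drop=True)
        self.config = config or PowerConfig()

    def run(self) -> PowerGrid:
        cfg = self.config
        stats_df = self.peptide_stats
        n_pep = len(stats_df)
        root = np.random.SeedSequence(cfg.seed)
        children = root.spawn(n_pep * len(cfg.effect_sizes) * len(cfg.sample_sizes))

        tcrit = {
            n: stats.t.ppf(1 - cfg.alpha / 2, 2 * n - 2) for n in cfg.sample_sizes
        }
        rows = []
        idx = 0
        for _, prow in stats_df.iterrows():
            mean = float(prow["mean"])
            sd1 = float(prow["sd"])
            sd2 = float(prow.get("sd_2", prow["sd"]))
            for fc in cfg.effect_sizes:
                shift = math.log10(fc)
                for n in cfg.sample_sizes:
                    rng = np.random.default_rng(children[idx])
                    idx += 1
                    x1 = rng.normal(mean, sd1, size=(cfg.n_sims, n))
                    x2 = rng.normal(mean + shift, sd2, size=(cfg.n_sims, n))
                    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
                    v1 = x1.var(axis=1, ddof=1)
                    v2 = x2.var(axis=1, ddof=1)
                    sp2 = (v1 + v2) / 2.0  # equal n pooled variance
                    with np.errstate(divide="ignore", invalid="ignore"):
                        t = (m2 - m1) / np.sqrt(sp2 * 2.0 / n)
                    sig = np.abs(t) > tcrit[n]
                    rows.append(
                        {
                            "peptide": prow["peptide"],
                            "fold_change": fc,
                            "n": n,
                            "power_percent": 100.0 * float(np.mean(sig)),
                        }
                    )
        return PowerGrid(grid=pd.DataFrame(rows), config=cfg)


def simulate_power(
    peptide_stats: pd.DataFrame, config: PowerConfig | None = None
) -> PowerGrid:
    """Functional wrapper around :class:`PowerStudy`."""
    return PowerStudy(peptide_stats, config).run()


def analytic_power(
    fold_change: float, n: int, sd: float, alpha: float = 0.05
) -> float:
    """Closed-form power of the two-sided equal-variance two-sample t test.

    For a log10 shift δ = log10(fold_change), common sd, and n replicates
    per condition, the test statistic is noncentral t with
    df = 2n − 2 and noncentrality δ / (sd·√(2/n)).  Returns power as a
    percentage to match the simulation grid.
    """
    if sd <= 0:
        return 100.0 if fold_change != 1.0 else 100.0 * alpha
    df = 2 * n - 2
    ncp = math.log10(fold_change) / (sd * math.sqrt(2.0 / n))
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    power = stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp)
    return 100.0 * float(power)
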