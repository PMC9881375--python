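"""Nictation and locomotion statistics for dauer/infective-juvenile assays.

Nictation — a nematode standing on its tail and waving its body — is
quantified per individual over a fixed observation window (90 s in the
assay being emulated) with three indices:

* nictation ratio ``T_nict / T_total`` — fraction of time nictating;
* initiation index ``N_nict / (T_total − T_nict)`` — nictation starts per
  second of non-nictating time;
* average duration ``T_nict / N_nict`` — mean length of a nictation bout.

These satisfy the identity ``initiation_index × average_duration =
ratio / (1 − ratio)`` whenever they are all defined.

Group comparisons follow the assay's statistics: a one-way linear model
on individual worms with many-to-one (Dunnett) multiple-comparison
adjustment against the control group, optionally after median
inter-experimental (batch) normalization.  Crawling speed is computed
per track from centroid positions, excluding tracks shorter than a
minimum duration (30 s by default) and scaling pixels to micrometers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BoutTrack",
    "NictationMetrics",
    "LocomotionTrack",
    "GroupComparisonResults",
    "NictationComparison",
    "nictation_metrics",
    "metrics_frame",
    "bouts_to_frame",
    "frame_to_tracks",
    "normalize_batches",
    "dunnett_compare",
    "max_abs_dunnett_cdf",
    "track_speed",
    "speeds_frame",
]


@dataclass(frozen=True)
class BoutTrack:
    """One individual's observed nictation-bout timeline.

    ``bouts`` are (start, end) nictation intervals in seconds, ordered,
    non-overlapping, and contained in ``[0, t_total]``.
    """

    individual: str
    group: str
    batch: str
    t_total: float
    bouts: tuple[tuple[float, float], ...]

    def __init__(self, individual, group, batch, t_total, bouts):
        bouts = tuple((float(s), float(e)) for s, e in bouts)
        if t_total <= 0:
            raise ValueError("t_total must be > 0")
        prev_end = 0.0
        for s, e in bouts:
            if s < 0 or e > t_total + 1e-9 or e <= s:
                raise ValueError(f"bout ({s}, {e}) outside [0, {t_total}] or empty")
            if s < prev_end - 1e-12:
                raise ValueError("bouts overlap or are unordered")
            prev_end = e
        object.__setattr__(self, "individual", individual)
        object.__setattr__(self, "group", group)
        object.__setattr__(self, "batch", batch)
        object.__setattr__(self, "t_total", float(t_total))
        object.__setattr__(self, "bouts", bouts)


@dataclass(frozen=True)
class NictationMetrics:
    """The three nictation indices for one individual.

    Undefined quantities are NaN: the initiation index when the animal
    nictates for the whole window, the average duration when there are no
    bouts.
    """

    t_nict: float
    n_nict: int
    nictation_ratio: float
    initiation_index: float
    average_duration: float


def nictation_metrics(track: BoutTrack) -> NictationMetrics:
    """Compute nictation ratio, initiation index and average duration.

    Bouts truncated by the observation window count as one initiation
    event and contribute their observed duration.
    """
    t_nict = sum(e - s for s, e in track.bouts)
    n_nict = len(track.bouts)
    ratio = t_nict / track.t_total
    crawl = track.t_total - t_nict
    initiation = n_nict / crawl if crawl > 0 else math.nan
    avg_dur = t_nict / n_nict if n_nict > 0 else math.nan
    return NictationMetrics(t_nict, n_nict, ratio, initiation, avg_dur)


def metrics_frame(tracks: Sequence[BoutTrack]) -> pd.DataFrame:
    """Per-individual metrics table for a collection of bout tracks."""
    rows = []
    for tr in tracks:
        m = nictation_metrics(tr)
        rows.append(
            {
                "individual": tr.individual,
                "group": tr.group,
                "batch": tr.batch,
                "t_total": tr.t_total,
                "t_nict": m.t_nict,
                "n_nict": m.n_nict,
                "nictation_ratio": m.nictation_ratio,
                "initiation_index": m.initiation_index,
                "average_duration": m.average_duration,
            }
        )
    return pd.DataFrame(rows)


def bouts_to_frame(tracks: Sequence[BoutTrack]) -> pd.DataFrame:
    """Serialize bout tracks to a long table (one row per bout; individuals
    with no bouts get a single row with empty bout columns)."""
    rows = []
    for tr in tracks:
        if not tr.bouts:
            rows.append(
                {"individual": tr.individual, "group": tr.group, "batch": tr.batch,
                 "t_total": tr.t_total, "bout_start": np.nan, "bout_end": np.nan}
            )
        for s, e in tr.bouts:
            rows.append(
                {"individual": tr.individual, "group": tr.group, "batch": tr.batch,
                 "t_total": tr.t_total, "bout_start": s, "bout_end": e}
            )
    return pd.DataFrame(rows)


def frame_to_tracks(frame: pd.DataFrame) -> list[BoutTrack]:
    """Inverse of :func:`bouts_to_frame`."""
    tracks = []
    for (ind, group, batch, t_total), g in frame.groupby(
        ["individual", "group", "batch", "t_total"], sort=False
    ):
        bouts = [
            (s, e)
            for s, e in zip(g["bout_start"], g["bout_end"])
            if not (pd.isna(s) or pd.isna(e))
        ]
        tracks.append(BoutTrack(ind, group, batch, t_total, bouts))
    return tracks


def normalize_batches(
    data: pd.DataFrame,
    value: str = "nictation_ratio",
    group: str = "group",
    batch: str = "batch",
    control: str = "control",
    method: str = "multiplicative",
    clip: tuple[float, float] | None = (0.0, 1.0),
) -> pd.Series:
    """Median inter-experimental normalization of a per-individual statistic.

    Each batch is rescaled so its control-group median coincides with the
    grand median of all control observations; after normalization the
    control medians of all batches are equal (to that grand median), and
    a single batch passes through unchanged.  Rescaling a whole batch by
    a constant is undone exactly whenever the grand control median is
    insensitive to that batch (median robustness; always true for the
    non-rescaled batches).  ``method`` is ``"multiplicative"`` (default;
    ratios are then clipped to ``clip``) or ``"additive"``.  A batch
    without the control group is an error.
    """
    controls = data.loc[data[group] == control, value]
    if controls.empty:
        raise ValueError(f"no observations for control group {control!r}")
    grand = controls.median()
    out = pd.Series(index=data.index, dtype=float)
    for b, g in data.groupby(batch):
        batch_ctrl = g.loc[g[group] == control, value]
        if batch_ctrl.empty:
            raise ValueError(f"batch {b!r} has no control-group observations")
        m = batch_ctrl.median()
        if method == "multiplicative":
            if m == 0:
                raise ValueError(f"batch {b!r}: control median is 0")
            out.loc[g.index] = g[value] * (grand / m)
        elif method == "additive":
            out.loc[g.index] = g[value] + (grand - m)
        else:
            raise ValueError(f"unknown method {method!r}")
    if clip is not None and method == "multiplicative":
        out = out.clip(*clip)
    return out


# ---------------------------------------------------------------------------
# Dunnett many-to-one comparisons
# ---------------------------------------------------------------------------

def max_abs_dunnett_cdf(
    q: float,
    df: int,
    lambdas: np.ndarray,
    n_hermite: int = 96,
    n_s: int = 96,
) -> float:
    """P(max_i |T_i| ≤ q) for the Dunnett contrast statistics.

    The k statistics share the one-factor correlation structure
    ``ρ_ij = λ_i λ_j`` with ``λ_i = sqrt(n_i / (n_i + n_0))`` induced by
    the common control group, and a common pooled-variance denominator
    with ``df`` degrees of freedom.  The probability is computed by
    Gauss–Hermite quadrature over the shared factor and Gauss–Legendre
    quadrature (on the probability scale) over the chi-distributed
    denominator.
    """
    if q <= 0:
        return 0.0
    lambdas = np.asarray(lambdas, dtype=float)
    c = np.sqrt(1.0 - lambdas**2)
    # shared normal factor: probabilists' Hermite via scaling
    x, wx = np.polynomial.hermite.hermgauss(n_hermite)
    x0 = x * math.sqrt(2.0)
    wx = wx / math.sqrt(math.pi)
    # pooled-sd factor S = sqrt(chi2_df / df), integrated on the
    # probability scale: midpoint-free Gauss-Legendre on (0, 1)
    u, wu = np.polynomial.legendre.leggauss(n_s)
    p = 0.5 * (u + 1.0)
    wp = 0.5 * wu
    s = np.sqrt(stats.chi2.ppf(p, df) / df)

    qs = q * s[:, None]  # (n_s, 1)
    lx = lambdas[None, None, :] * x0[None, :, None]  # (1, n_hermite, k)
    upper = (qs[:, :, None] - lx) / c
    lower = (-qs[:, :, None] - lx) / c
    inner = np.prod(stats.norm.cdf(upper) - stats.norm.cdf(lower), axis=2)
    return float(wp @ inner @ wx)


@dataclass
class GroupComparisonResults:
    """Group means, SEMs and Dunnett-adjusted p values vs a control.

    ``table`` has one row per group: n, least-squares mean, SEM (from the
    pooled residual variance), t statistic vs control, unadjusted and
    Dunnett-adjusted two-sided p. The control's p vs itself is 1 by
    convention.
    """

    table: pd.DataFrame
    control: str
    df_resid: int
    pooled_sd: float

    def summary(self) -> str:
        lines = [
            "Many-to-one group comparison (Dunnett)",
            f"control: {self.control}   residual df: {self.df_resid}   "
            f"pooled sd: {self.pooled_sd:.4g}",
            "",
            self.table.to_string(
                index=False,
                float_format=lambda v: f"{v:.4g}",
            ),
        ]
        return "\n".join(lines)


class NictationComparison:
    """One-way linear model with Dunnett many-to-one comparisons.

    Fits group means with a pooled residual variance and adjusts the
    treatment-vs-control p values for multiplicity over the k contrasts
    using the multivariate-t distribution of the contrast statistics
    (one-factor correlation determined by group sizes).  With a single
    treatment group the adjusted p equals the two-sided pooled t-test p.

    Parameters
    ----------
    data : DataFrame with one row per individual.
    value, group : column names of the response and the group label.
    control : label of the control group.
    method : ``"quadrature"`` (default) or ``"mc"`` for a seeded
        Monte-Carlo evaluation of the max-|t| null distribution.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        value: str,
        group: str = "group",
        control: str = "control",
        method: str = "quadrature",
        mc_samples: int = 200_000,
        mc_seed: int = 0,
    ):
        if control not in set(data[group]):
            raise ValueError(f"control group {control!r} not present")
        sizes = data.groupby(group)[value].count()
        if (sizes < 2).any():
            small = sizes[sizes < 2].index.tolist()
            raise ValueError(f"groups with fewer than 2 observations: {small}")
        if sizes.size < 2:
            raise ValueError("need at least 2 groups including the control")
        self.data = data
        self.value = value
        self.group = group
        self.control = control
        self.method = method
        self.mc_samples = mc_samples
        self.mc_seed = mc_seed

    def fit(self) -> GroupComparisonResults:
        g = self.data.groupby(self.group)[self.value]
        means, ns = g.mean(), g.count()
        sse = ((self.data[self.value] - self.data[self.group].map(means)) ** 2).sum()
        df_resid = int(ns.sum() - ns.size)
        s2 = sse / df_resid
        s = math.sqrt(s2)
        n0 = ns[self.control]
        treatments = [grp for grp in means.index if grp != self.control]
        lambdas = np.array([math.sqrt(ns[t] / (ns[t] + n0)) for t in treatments])

        rows = []
        tstats = {}
        for t in treatments:
            se_diff = s * math.sqrt(1.0 / ns[t] + 1.0 / n0)
            tstats[t] = (means[t] - means[self.control]) / se_diff if se_diff > 0 else np.nan

        if self.method == "mc":
            rng = np.random.default_rng(self.mc_seed)
            z0 = rng.standard_normal(self.mc_samples)
            zi = rng.standard_normal((self.mc_samples, len(treatments)))
            chi = np.sqrt(rng.chisquare(df_resid, self.mc_samples) / df_resid)
            T = (lambdas * z0[:, None] + np.sqrt(1 - lambdas**2) * zi) / chi[:, None]
            max_abs = np.abs(T).max(axis=1)

        for grp in means.index:
            if grp == self.control:
                rows.append(
                    {"group": grp, "n": int(ns[grp]), "lsmean": means[grp],
                     "sem": s / math.sqrt(ns[grp]), "t": np.nan,
                     "p_unadjusted": np.nan, "p_adjusted": 1.0}
                )
                continue
            t_obs = tstats[grp]
            p_un = 2.0 * stats.t.sf(abs(t_obs), df_resid)
            if len(treatments) == 1:
                p_adj = p_un  # k = 1: Dunnett reduces to the pooled t test
            elif self.method == "mc":
                p_adj = float(np.mean(max_abs >= abs(t_obs)))
            else:
                p_adj = 1.0 - max_abs_dunnett_cdf(abs(t_obs), df_resid, lambdas)
            rows.append(
                {"group": grp, "n": int(ns[grp]), "lsmean": means[grp],
                 "sem": s / math.sqrt(ns[grp]), "t": t_obs,
                 "p_unadjusted": p_un, "p_adjusted": min(max(p_adj, 0.0), 1.0)}
            )
        table = pd.DataFrame(rows)
        return GroupComparisonResults(
            table=table, control=self.control, df_resid=df_resid, pooled_sd=s
        )


def dunnett_compare(
    data: pd.DataFrame,
    value: str,
    group: str = "group",
    control: str = "control",
    **kwargs,
) -> GroupComparisonResults:
    """Convenience wrapper: fit :class:`NictationComparison` and return results."""
    return NictationComparison(data, value, group, control, **kwargs).fit()


# ---------------------------------------------------------------------------
# Locomotion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocomotionTrack:
    """Sampled centroid positions (pixels) of one worm track."""

    track_id: str
    group: str
    times: tuple[float, ...]
    x: tuple[float, ...]
    y: tuple[float, ...]
    pixel_to_micrometer: float = 1.0
    experiment: str = "exp1"

    def __init__(self, track_id, group, times, x, y, pixel_to_micrometer=1.0,
                 experiment="exp1"):
        times = tuple(float(t) for t in times)
        if len(times) != len(tuple(x)) or len(times) != len(tuple(y)):
            raise ValueError("times, x, y must have equal length")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("timestamps must be strictly increasing")
        object.__setattr__(self, "track_id", track_id)
        object.__setattr__(self, "group", group)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "x", tuple(float(v) for v in x))
        object.__setattr__(self, "y", tuple(float(v) for v in y))
        object.__setattr__(self, "pixel_to_micrometer", float(pixel_to_micrometer))
        object.__setattr__(self, "experiment", experiment)

    @property
    def duration(self) -> float:
        return self.times[-1] - self.times[0]


def track_speed(track: LocomotionTrack, min_seconds: float = 30.0) -> float | None:
    """Mean crawling speed of a track in μm/s, or ``None`` if excluded.

    Tracks shorter than ``min_seconds`` are excluded (30 s minimum track
    length by default).  Speed is the mean of frame-to-frame displacement
    over Δt, scaled from pixels to micrometers.
    """
    if len(track.times) < 2:
        raise ValueError("track needs at least 2 samples")
    if track.duration < min_seconds:
        return None
    t = np.asarray(track.times)
    x = np.asarray(track.x)
    y = np.asarray(track.y)
    d = np.hypot(np.diff(x), np.diff(y))
    speeds = d / np.diff(t)
    return float(speeds.mean() * track.pixel_to_micrometer)


def speeds_frame(
    tracks: Sequence[LocomotionTrack], min_seconds: float = 30.0
) -> pd.DataFrame:
    """Per-track speed table with exclusions applied; includes a
    per-experiment average helper column via ``groupby`` downstream."""
    rows = []
    for tr in tracks:
        v = track_speed(tr, min_seconds)
        rows.append(
            {"track_id": tr.track_id, "group": tr.group,
             "experiment": tr.experiment, "duration_s": tr.duration,
             "included": v is not None, "speed_um_per_s": v}
        )
    return pd.DataFrame(rows)
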