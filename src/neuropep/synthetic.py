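"""Synthetic inputs for every stage of the targeted-peptidomics pipeline.

The study design being emulated: proteomes containing neuropeptide
precursors (signal peptide + dibasic-delimited mature peptides) among
decoy proteins; transition-level quant reports from a two-condition
(fed L3 vs dauer juvenile) scheduled-PRM experiment with 4 replicates per
condition; and per-individual nictation bout timelines from 90 s
observations.

Statistical structure the downstream analysis assumes, and which the
generators embed:

* peptide abundances log-normal on the log10 scale, with condition fold
  changes entering as additive log10 shifts;
* technical coefficients of variation near ~20% (default 21.63%, the
  replicate-prep CV the workflow is designed around);
* below-detection dropout via a hard abundance threshold, producing
  "dauer-only" on/off patterns, with undetected peptides carrying
  background-level areas;
* per-run global scale factors (to be undone by median MS1 normalization)
  and reference retention times spread uniformly over the gradient;
* alternating crawl/nictation bouts with exponential (memoryless)
  durations, truncated at the observation window.

Every generator takes an explicit seed through :class:`SimConfig`; there
is no global random state, and identical seed + config gives bit-identical
outputs.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .behavior import BoutTrack
from .discovery import ProteinRecord, SignalPrediction

__all__ = [
    "SimConfig",
    "GroundTruth",
    "generate_proteome",
    "generate_transition_report",
    "generate_bout_tracks",
]

# mature peptides avoid K/R so dibasic sites occur only where placed;
# C excluded to keep pyteomics masses free of cysteine chemistry caveats
_MATURE_ALPHABET = "ADEFGHILMNPQSTVWY"
_HYDROPHOBIC = "AILVFMW"
_DIBASIC = ("KR", "KK", "RR", "RK")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the simulated study.

    Defaults mirror the experimental design being emulated: 4 replicates
    per condition, technical CV 21.63%, a 75 min gradient, fold changes
    {1.1, 1.2, 1.5, 2, 4}, and 90 s behavioral observations.
    """

    seed: int = 0
    # proteome
    n_precursors: int = 20
    n_decoys: int = 10
    n_peptides_per_precursor: tuple[int, int] = (2, 5)
    signal_peptide_length: tuple[int, int] = (15, 30)
    mature_peptide_length: tuple[int, int] = (5, 15)
    amidation_fraction: float = 0.5
    pyroglu_fraction: float = 0.2
    # transition report
    gradient_minutes: float = 75.0
    conditions: tuple[str, str] = ("L3", "dauer")
    n_replicates_per_condition: int = 4
    base_log10_abundance: tuple[float, float] = (5.0, 0.5)
    technical_cv_percent: float = 21.63
    fold_changes: tuple[float, ...] = (1.1, 1.2, 1.5, 2.0, 4.0)
    dropout_threshold: float = 0.0
    background_fraction: float = 0.01
    n_fragments: int = 6
    met_ox_probability: float = 0.5
    second_charge_probability: float = 0.3
    run_scale_log10_sd: float = 0.15
    n_ms1_features: int = 200
    # behavior: exponential bout-duration means 1/rate; defaults give a
    # stationary nictation ratio of ~0.37 (wildtype-like) over 90 s
    bout_rate_nict: float = 1.0 / 7.4
    bout_rate_crawl: float = 1.0 / 12.6
    observation_seconds: float = 90.0

    def __post_init__(self) -> None:
        counts = {
            "n_precursors": self.n_precursors,
            "n_replicates_per_condition": self.n_replicates_per_condition,
            "n_fragments": self.n_fragments,
            "n_ms1_features": self.n_ms1_features,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be ≥ 1, got {v}")
        if self.n_decoys < 0:
            raise ValueError("n_decoys must be ≥ 0")
        if self.technical_cv_percent < 0:
            raise ValueError("technical_cv_percent must be ≥ 0")
        if any(fc <= 0 for fc in self.fold_changes):
            raise ValueError("fold changes must be > 0")
        if self.observation_seconds <= 0:
            raise ValueError("observation_seconds must be > 0")
        if self.bout_rate_nict <= 0 or self.bout_rate_crawl <= 0:
            raise ValueError("bout rates must be > 0")
        for name in ("n_peptides_per_precursor", "signal_peptide_length",
                     "mature_peptide_length"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"{name} must be a valid range ≥ 1")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("n_peptides_per_precursor", "signal_peptide_length",
                    "mature_peptide_length", "base_log10_abundance",
                    "conditions", "fold_changes"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(self).items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


@dataclass
class GroundTruth:
    """What the generators actually put into the data.

    Every emitted record traces to exactly one entry here: proteins to
    rows of ``proteins``/``signals``, transition rows to ``peptides`` and
    ``abundances``/``detection``, bout records to ``bout_means``.
    """

    proteins: pd.DataFrame = field(default_factory=pd.DataFrame)
    signals: pd.DataFrame = field(default_factory=pd.DataFrame)
    peptides: pd.DataFrame = field(default_factory=pd.DataFrame)
    abundances: pd.DataFrame = field(default_factory=pd.DataFrame)
    detection: pd.DataFrame = field(default_factory=pd.DataFrame)
    run_scales: pd.DataFrame = field(default_factory=pd.DataFrame)
    bout_means: pd.DataFrame = field(default_factory=pd.DataFrame)

    def signal_predictions(self) -> list[SignalPrediction]:
        return [
            SignalPrediction(
                r.protein_id,
                bool(r.has_signal),
                int(r.cleavage_position) if r.has_signal else None,
            )
            for r in self.signals.itertuples()
        ]


def _random_seq(rng: np.random.Generator, alphabet: str, n: int) -> str:
    return "".join(rng.choice(list(alphabet), size=n))


def _make_mature_peptide(
    rng: np.random.Generator, cfg: SimConfig
) -> tuple[str, bool, str]:
    """Return (core sequence, amidated, pyroglu flag)."""
    lo, hi = cfg.mature_peptide_length
    n = int(rng.integers(lo, hi + 1))
    core = list(_random_seq(rng, _MATURE_ALPHABET, n))
    pyroglu = "none"
    if rng.random() < cfg.pyroglu_fraction:
        core[0] = rng.choice(["Q", "E"])
        pyroglu = "fromQ" if core[0] == "Q" else "fromE"
    else:
        while core[0] in "QE":
            core[0] = rng.choice(list(_MATURE_ALPHABET.replace("Q", "").replace("E", "")))
    amidated = bool(rng.random() < cfg.amidation_fraction)
    if not amidated:
        # a non-amidated peptide must not end in G, or the cleavage rules
        # would (correctly, per the rules) call it an amidation donor
        while core[-1] == "G":
            core[-1] = rng.choice(list(_MATURE_ALPHABET.replace("G", "")))
    return "".join(core), amidated, pyroglu


def generate_proteome(config: SimConfig) -> tuple[str, GroundTruth]:
    """Generate a toy proteome in FASTA format plus its ground truth.

    Each synthetic precursor is ``signal peptide | peptide (dibasic
    peptide)*`` with dibasic sites drawn from {KR, KK, RR, RK}; a
    configurable fraction of mature peptides carry an amidation-donor G or
    start with Q/E (pyroglutamation donors).  Decoys of two kinds are
    interleaved: proteins with dibasic sites but no signal peptide, and
    signal-peptide proteins with no dibasic site.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    records: list[SeqRecord] = []
    prot_rows, sig_rows, pep_rows = [], [], []

    for i in range(config.n_precursors):
        pid = f"prec{i + 1:03d}"
        lo, hi = config.signal_peptide_length
        sig_len = int(rng.integers(lo, hi + 1))
        signal = "M" + _random_seq(rng, _HYDROPHOBIC, sig_len - 1)
        plo, phi = config.n_peptides_per_precursor
        n_pep = int(rng.integers(plo, phi + 1))
        parts = [signal]
        pos = sig_len
        for j in range(n_pep):
            core, amidated, pyroglu = _make_mature_peptide(rng, config)
            segment = core + ("G" if amidated else "")
            start = pos + 1
            end = pos + len(segment)
            pep_rows.append(
                {
                    "peptide_id": f"{pid}_p{j + 1}",
                    "precursor_id": pid,
                    "sequence": core,
                    "start": start,
                    "end": end,
                    "amidated": amidated,
                    "pyroglu": pyroglu,
                }
            )
            parts.append(segment)
            pos = end
            if j < n_pep - 1:
                site = str(rng.choice(_DIBASIC))
                parts.append(site)
                pos += 2
        seq = "".join(parts)
        records.append(SeqRecord(Seq(seq), id=pid, description="synthetic precursor"))
        prot_rows.append({"protein_id": pid, "is_precursor": True})
        sig_rows.append(
            {"protein_id": pid, "has_signal": True, "cleavage_position": sig_len}
        )

    for i in range(config.n_decoys):
        pid = f"decoy{i + 1:03d}"
        body = _random_seq(rng, _MATURE_ALPHABET, int(rng.integers(60, 160)))
        if i % 2 == 0:
            # dibasic sites but no signal peptide
            k = int(rng.integers(1, 4))
            chunks = []
            step = len(body) // (k + 1)
            for j in range(k):
                chunks.append(body[j * step : (j + 1) * step])
                chunks.append(str(rng.choice(_DIBASIC)))
            chunks.append(body[k * step :])
            seq = "".join(chunks)
            has_signal, cleave = False, None
        else:
            # signal peptide but no dibasic site
            lo, hi = config.signal_peptide_length
            sig_len = int(rng.integers(lo, hi + 1))
            seq = "M" + _random_seq(rng, _HYDROPHOBIC, sig_len - 1) + body
            has_signal, cleave = True, sig_len
        records.append(SeqRecord(Seq(seq), id=pid, description="synthetic decoy"))
        prot_rows.append({"protein_id": pid, "is_precursor": False})
        sig_rows.append(
            {"protein_id": pid, "has_signal": has_signal, "cleavage_position": cleave}
        )

    buf = io.StringIO()
    SeqIO.write(records, buf, "fasta")
    truth = GroundTruth(
        proteins=pd.DataFrame(prot_rows),
        signals=pd.DataFrame(sig_rows),
        peptides=pd.DataFrame(
            pep_rows,
            columns=["peptide_id", "precursor_id", "sequence", "start", "end",
                     "amidated", "pyroglu"],
        ),
    )
    return buf.getvalue(), truth


def _log10_sd_from_cv(cv_percent: float) -> float:
    """log10-scale sd of a log-normal variable with the given CV%."""
    cv = cv_percent / 100.0
    return math.sqrt(math.log1p(cv * cv)) / math.log(10)


def generate_transition_report(
    config: SimConfig,
    ground_truth: GroundTruth,
    fold_changes: Sequence[float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Emulate a transition-level quant export for a two-condition design.

    Returns ``(report, ms1_features, ground_truth)``; the ground truth is
    the input augmented with per-peptide condition means, fold changes,
    and true per-run detection status.

    Per replicate and peptide ion (possibly two charge states and a
    Met-oxidized variant), ``n_fragments`` fragment rows are emitted with
    areas log-normal around the condition mean (sd set by the technical
    CV); condition 2 means are shifted by log10(fold change).  Replicates
    whose sampled total abundance falls below ``dropout_threshold`` get
    background-level areas and ``detected=False``.  A per-run global scale
    factor multiplies every area (and the MS1 feature table), to be undone
    by median normalization.
    """
    if ground_truth.peptides.empty:
        raise ValueError("ground truth has no peptides; run generate_proteome first")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    peptides = ground_truth.peptides.reset_index(drop=True)
    n_pep = len(peptides)
    if fold_changes is None:
        fcs = [config.fold_changes[i % len(config.fold_changes)] for i in range(n_pep)]
    else:
        fcs = [float(fold_changes[i % len(fold_changes)]) for i in range(n_pep)]

    c1, c2 = config.conditions
    n_rep = config.n_replicates_per_condition
    runs = [f"{c}_{r + 1}" for c in (c1, c2) for r in range(n_rep)]
    run_condition = {f"{c}_{r + 1}": c for c in (c1, c2) for r in range(n_rep)}
    run_replicate = {f"{c}_{r + 1}": r + 1 for c in (c1, c2) for r in range(n_rep)}

    # per-run global scale factors (injection amount / instrument drift)
    scales = 10 ** rng.normal(0.0, config.run_scale_log10_sd, size=len(runs))
    run_scale = dict(zip(runs, scales))

    sigma = _log10_sd_from_cv(config.technical_cv_percent)
    mu0, sd0 = config.base_log10_abundance

    ab_rows, det_rows, report_rows = [], [], []
    for i, prow in enumerate(peptides.itertuples()):
        mean1 = float(rng.normal(mu0, sd0))
        fc = fcs[i]
        mean2 = mean1 + math.log10(fc)
        ab_rows.append(
            {
                "peptide_id": prow.peptide_id,
                f"mean_log10_{c1}": mean1,
                f"mean_log10_{c2}": mean2,
                "fold_change": fc,
            }
        )
        # peptide-level ion structure, fixed across runs
        has_ox = ("M" in prow.sequence) and (rng.random() < config.met_ox_probability)
        two_charges = rng.random() < config.second_charge_probability
        variants = [("", 2, 1.0)]
        if two_charges:
            variants = [("", 2, 0.7), ("", 3, 0.3)]
        if has_ox:
            variants = [(m, z, w * 0.85) for m, z, w in variants] + [
                ("Met-ox", 2, 0.15)
            ]
        frac = rng.dirichlet(np.full(config.n_fragments, 2.0))
        frag_labels = [f"y{k + 1}" for k in range(config.n_fragments)]
        rt_ref = float(rng.uniform(0.05, 0.95) * config.gradient_minutes)

        for run in runs:
            cond_mean = mean1 if run_condition[run] == c1 else mean2
            log_total = cond_mean + (rng.normal(0.0, sigma) if sigma > 0 else 0.0)
            total = 10.0 ** log_total
            detected = total >= config.dropout_threshold
            if not detected:
                # background integration near the dataset floor
                total = config.dropout_threshold * config.background_fraction * (
                    0.5 + rng.random()
                )
            det_rows.append(
                {"peptide_id": prow.peptide_id, "run": run, "detected": detected}
            )
            for mod, charge, w in variants:
                for k, label in enumerate(frag_labels):
                    report_rows.append(
                        {
                            "run": run,
                            "condition": run_condition[run],
                            "replicate": run_replicate[run],
                            "peptide": prow.peptide_id,
                            "precursor_charge": charge,
                            "variant": mod,
                            "fragment": label,
                            "area": total * w * frac[k] * run_scale[run],
                            "rt": rt_ref,
                            "detected": detected,
                        }
                    )

    report = pd.DataFrame(report_rows)

    # MS1 feature table: fixed feature population scaled per run
    feature_base = 10 ** rng.normal(mu0, sd0, size=config.n_ms1_features)
    ms1_rows = [
        {"run": run, "feature": f"f{j + 1}", "area": feature_base[j] * run_scale[run]}
        for run in runs
        for j in range(config.n_ms1_features)
    ]
    ms1 = pd.DataFrame(ms1_rows)

    truth = GroundTruth(
        proteins=ground_truth.proteins,
        signals=ground_truth.signals,
        peptides=ground_truth.peptides,
        abundances=pd.DataFrame(ab_rows),
        detection=pd.DataFrame(det_rows),
        run_scales=pd.DataFrame(
            {"run": runs, "scale": scales,
             "condition": [run_condition[r] for r in runs]}
        ),
        bout_means=ground_truth.bout_means,
    )
    return report, ms1, truth


def generate_bout_tracks(
    config: SimConfig,
    n_individuals: int,
    group: str = "control",
    batch: str = "batch1",
    rate_nict: float | None = None,
    rate_crawl: float | None = None,
    seed_offset: int = 0,
) -> tuple[list[BoutTrack], GroundTruth]:
    """Simulate alternating crawl/nictation bout timelines.

    A two-state alternating-renewal process with exponential bout
    durations (means ``1/rate``), truncated at ``observation_seconds``.
    The initial state is drawn from the stationary distribution (and the
    memoryless durations make the process stationary), so the expected
    nictation ratio equals μ_nict/(μ_nict + μ_crawl).
    """
    rn = config.bout_rate_nict if rate_nict is None else rate_nict
    rc = config.bout_rate_crawl if rate_crawl is None else rate_crawl
    if rn <= 0 or rc <= 0:
        raise ValueError("bout rates must be > 0")
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 303, seed_offset])
    )
    T = config.observation_seconds
    mu_n, mu_c = 1.0 / rn, 1.0 / rc
    p_nict = mu_n / (mu_n + mu_c)

    tracks = []
    for i in range(n_individuals):
        nictating = bool(rng.random() < p_nict)
        t = 0.0
        bouts = []
        while t < T:
            dur = float(rng.exponential(mu_n if nictating else mu_c))
            end = min(t + dur, T)
            if nictating and end > t:
                bouts.append((t, end))
            t = end
            nictating = not nictating
        tracks.append(
            BoutTrack(
                individual=f"{group}_{batch}_{i + 1}",
                group=group,
                batch=batch,
                t_total=T,
                bouts=bouts,
            )
        )
    truth = GroundTruth(
        bout_means=pd.DataFrame(
            [
                {
                    "group": group,
                    "batch": batch,
                    "mean_nict_bout": mu_n,
                    "mean_crawl_bout": mu_c,
                    "stationary_ratio": p_nict,
                }
            ]
        )
    )
    return tracks, truth
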