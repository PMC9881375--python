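"""Rule-based discovery of neuropeptide precursor genes in a proteome.

Neuropeptide precursors are secreted proteins with a stereotyped
architecture: an N-terminal signal peptide followed by one or more mature
peptide sequences delimited by dibasic cleavage sites (KK, KR, RK, RR)
recognised by prohormone convertases.  Maturation frequently adds two
post-translational modifications that are inferable from sequence alone:
C-terminal amidation (a C-terminal glycine is consumed, net −0.98 Da
relative to the free acid) and N-terminal pyroglutamation of glutamine
(−17.03 Da) or glutamate (−18.01 Da).

This module turns those rules into an annotation pipeline:

* :func:`find_cleavage_sites` — locate dibasic cleavage regions downstream
  of the signal-peptide boundary, merging runs of ≥2 basic residues into a
  single cleavage region.
* :func:`cleave_precursor` — enumerate the candidate mature peptides
  between cleavage regions, with amidation / pyroglutamation flags.
* :func:`annotate_precursor` — decide whether a protein is a candidate
  precursor (signal peptide + properly flanked peptide evidence).
* :func:`map_peptides_to_precursors` — map detected peptide sequences back
  onto precursor genes by exact substring match.
* :func:`classify_complement` — three-set (detected / predicted / homolog)
  Venn accounting of a species' neuropeptide gene complement.

Signal-peptide calls are inputs (in the study workflow they come from a
dedicated predictor); :func:`predict_signal_peptide` provides a naive
hydrophobic-window heuristic for synthetic data only.

Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from pyteomics import mass as _ptmass

__all__ = [
    "AMIDATION_DA",
    "PYROGLU_Q_DA",
    "PYROGLU_E_DA",
    "DISULFIDE_HALF_DA",
    "ProteinRecord",
    "SignalPrediction",
    "CleavageSite",
    "MaturePeptide",
    "PrecursorAnnotation",
    "ComplementPartition",
    "MappingResult",
    "find_cleavage_sites",
    "cleave_precursor",
    "annotate_precursor",
    "map_peptides_to_precursors",
    "classify_complement",
    "predict_signal_peptide",
    "strip_modifications",
]

#: Mass deltas (Da, monoisotopic) of the sequence-inferable modifications.
AMIDATION_DA = -0.98
PYROGLU_Q_DA = -17.03
PYROGLU_E_DA = -18.01
#: Half of a disulfide bridge on cysteine. Recognised as a modification
#: mass for annotation purposes but never inferred from sequence.
DISULFIDE_HALF_DA = -1.01

_VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")
_BASIC_RUN = re.compile(r"[KR]{2,}")
_DIBASIC_MOTIFS = ("KK", "KR", "RK", "RR")


@dataclass(frozen=True)
class ProteinRecord:
    """One proteome entry: an id and an uppercase amino-acid sequence.

    Unknown residues are tolerated as ``X``.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - _VALID_RESIDUES
        if bad:
            raise ValueError(
                f"protein {self.id!r}: invalid residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SignalPrediction:
    """Signal-peptide call for one protein.

    ``cleavage_position`` is the 1-based index of the *last* signal-peptide
    residue; mature sequence starts at ``cleavage_position + 1``.
    """

    protein_id: str
    has_signal: bool
    cleavage_position: int | None = None

    def __post_init__(self) -> None:
        if self.has_signal:
            if self.cleavage_position is None or self.cleavage_position < 1:
                raise ValueError(
                    f"{self.protein_id!r}: signal call requires a positive "
                    "cleavage_position"
                )


@dataclass(frozen=True)
class CleavageSite:
    """A dibasic cleavage region: a maximal run of ≥2 basic residues.

    1-based inclusive coordinates on the precursor. A run like ``KRR`` is a
    single region of length 3.
    """

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class MaturePeptide:
    """A candidate mature peptide cut out of a precursor.

    ``start``/``end`` span the full precursor segment including the
    amidation-donor glycine when present; ``sequence`` is the mature core
    (donor G removed).  ``mass_shift_da`` sums the modification deltas
    implied by the flags.
    """

    sequence: str
    precursor_id: str
    start: int
    end: int
    n_flank: str  # {"signal_boundary", "dibasic", "chain_start"}
    c_flank: str  # {"dibasic", "chain_end"}
    amidated: bool
    pyroglu: str  # {"none", "fromQ", "fromE"}
    mass_shift_da: float

    def monoisotopic_mass(self) -> float:
        """Monoisotopic mass (Da) of the modified peptide.

        Computed as the unmodified free-acid mass of the mature core plus
        the summed modification deltas, so an amidated peptide weighs
        0.98 Da less than its core free acid.
        """
        return _ptmass.calculate_mass(sequence=self.sequence) + self.mass_shift_da


@dataclass
class PrecursorAnnotation:
    """Candidate-precursor verdict for one protein, with the evidence."""

    protein_id: str
    is_candidate: bool
    evidence: dict
    mature_peptides: list[MaturePeptide] = field(default_factory=list)


def find_cleavage_sites(
    protein: ProteinRecord, signal: SignalPrediction
) -> list[CleavageSite]:
    """Locate dibasic cleavage regions downstream of the signal boundary.

    All occurrences of the dibasic motifs {KK, KR, RK, RR} are found in the
    sequence after the signal-peptide boundary; overlapping motifs (any run
    of ≥2 consecutive K/R) are merged into one maximal cleavage region.

    Returns regions ordered by position. A protein whose sequence is not
    longer than the declared signal peptide is inconsistent input and
    raises ``ValueError``.
    """
    if signal.protein_id != protein.id:
        raise ValueError(
            f"signal prediction for {signal.protein_id!r} does not belong "
            f"to protein {protein.id!r}"
        )
    boundary = signal.cleavage_position if signal.has_signal else 0
    if boundary >= len(protein.sequence):
        raise ValueError(
            f"protein {protein.id!r}: sequence (length {len(protein)}) not "
            f"longer than its signal peptide (boundary {boundary})"
        )
    downstream = protein.sequence[boundary:]
    sites = []
    for m in _BASIC_RUN.finditer(downstream):
        sites.append(CleavageSite(boundary + m.start() + 1, boundary + m.end()))
    return sites


def cleave_precursor(
    protein: ProteinRecord,
    signal: SignalPrediction,
    sites: Sequence[CleavageSite] | None = None,
    include_cterm: bool = True,
) -> list[MaturePeptide]:
    """Cut a precursor into candidate mature peptides.

    Candidate peptides are the non-empty segments between consecutive
    cleavage regions, plus the segment between the signal boundary and the
    first region, plus (when ``include_cterm``) the segment after the last
    region.  A trailing glycine is consumed as the amidation donor
    (``amidated=True``); a leading Q/E flags the peptide as a potential
    pyroglutamate (``pyroglu``).  Zero-length cores are dropped.
    """
    if sites is None:
        sites = find_cleavage_sites(protein, signal)
    boundary = signal.cleavage_position if signal.has_signal else 0
    seq = protein.sequence

    # segment boundaries in 0-based half-open coordinates
    cut_points: list[tuple[int, int, str]] = []  # (seg_start0, seg_end0, c_flank)
    prev = boundary
    for site in sites:
        cut_points.append((prev, site.start - 1, "dibasic"))
        prev = site.end
    if include_cterm or not sites:
        cut_points.append((prev, len(seq), "chain_end"))

    peptides: list[MaturePeptide] = []
    first_n_flank = "signal_boundary" if signal.has_signal else "chain_start"
    for i, (s0, e0, c_flank) in enumerate(cut_points):
        if e0 <= s0:
            continue
        segment = seq[s0:e0]
        n_flank = first_n_flank if s0 == boundary else "dibasic"
        amidated = segment.endswith("G")
        core = segment[:-1] if amidated else segment
        if not core:
            continue
        shift = AMIDATION_DA if amidated else 0.0
        if core[0] == "Q":
            pyroglu = "fromQ"
            shift += PYROGLU_Q_DA
        elif core[0] == "E":
            pyroglu = "fromE"
            shift += PYROGLU_E_DA
        else:
            pyroglu = "none"
        peptides.append(
            MaturePeptide(
                sequence=core,
                precursor_id=protein.id,
                start=s0 + 1,
                end=e0,
                n_flank=n_flank,
                c_flank=c_flank,
                amidated=amidated,
                pyroglu=pyroglu,
                mass_shift_da=round(shift, 2),
            )
        )
    return peptides


_MOD_ANNOTATION = re.compile(r"\(.*?\)|\[.*?\]|[^A-Za-z]")


def strip_modifications(peptide: str) -> str:
    """Strip modification annotations, leaving the bare uppercase sequence.

    Removes parenthesised/bracketed mass annotations (e.g. ``M(+15.99)``)
    and any non-letter characters.
    """
    return _MOD_ANNOTATION.sub("", peptide).upper()


def _properly_flanked(pep: MaturePeptide, include_cterm: bool) -> bool:
    """Flanked by two dibasic sites or by the signal peptide and a dibasic
    site (optionally also accepting the chain C-terminus)."""
    n_ok = pep.n_flank in ("signal_boundary", "dibasic")
    c_ok = pep.c_flank == "dibasic" or (include_cterm and pep.c_flank == "chain_end")
    return n_ok and c_ok


def annotate_precursor(
    protein: ProteinRecord,
    signal: SignalPrediction,
    detected_peptides: Iterable[str] | None = None,
    include_cterm: bool = True,
) -> PrecursorAnnotation:
    """Decide whether a protein is a candidate neuropeptide precursor.

    A protein is a candidate iff it has a signal peptide AND at least one
    properly flanked peptide — a detected one when a detected-peptide list
    is supplied, otherwise any predicted dibasic cleavage site suffices.
    """
    try:
        sites = find_cleavage_sites(protein, signal)
        peptides = cleave_precursor(protein, signal, sites, include_cterm)
    except ValueError:
        raise
    n_detected_flanked = 0
    if detected_peptides is not None:
        detected = {strip_modifications(p) for p in detected_peptides}
        flanked_seqs = {
            p.sequence for p in peptides if _properly_flanked(p, include_cterm)
        }
        n_detected_flanked = len(detected & flanked_seqs)
        is_candidate = signal.has_signal and n_detected_flanked >= 1
    else:
        is_candidate = signal.has_signal and len(sites) >= 1
    return PrecursorAnnotation(
        protein_id=protein.id,
        is_candidate=is_candidate,
        evidence={
            "has_signal": signal.has_signal,
            "n_cleavage_sites": len(sites),
            "n_detected_peptides_properly_flanked": n_detected_flanked,
        },
        mature_peptides=peptides,
    )


@dataclass
class MappingResult:
    """Result of mapping detected peptides back onto a proteome.

    ``table`` has one row per (peptide, matching precursor); peptides
    matching several proteins are flagged ambiguous and counted once per
    distinct precursor gene. ``unmatched`` lists peptides absent from the
    proteome.
    """

    table: pd.DataFrame
    unmatched: list[str]

    @property
    def n_precursors(self) -> int:
        """Number of distinct precursor genes with ≥1 mapped peptide."""
        if self.table.empty:
            return 0
        return self.table["precursor_id"].nunique()


def map_peptides_to_precursors(
    peptides: Sequence[str], proteome: Sequence[ProteinRecord]
) -> MappingResult:
    """Map peptide sequences to precursors by exact substring match.

    Modification annotations are stripped before matching. Empty peptides
    are rejected.
    """
    rows = []
    unmatched = []
    for raw in peptides:
        seq = strip_modifications(raw)
        if not seq:
            raise ValueError(f"empty peptide sequence: {raw!r}")
        hits = [p.id for p in proteome if seq in p.sequence]
        if not hits:
            unmatched.append(raw)
            continue
        for pid in hits:
            rows.append(
                {
                    "peptide": raw,
                    "sequence": seq,
                    "precursor_id": pid,
                    "n_matches": len(hits),
                    "ambiguous": len(hits) > 1,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=["peptide", "sequence", "precursor_id", "n_matches", "ambiguous"],
    )
    return MappingResult(table=table, unmatched=unmatched)


@dataclass
class ComplementPartition:
    """Three-set Venn accounting of a neuropeptide gene complement.

    Region counts for all 7 regions of the (detected, predicted, homolog)
    Venn diagram, plus the union. Region counts always sum to the union.
    """

    regions: dict[str, int]
    union_count: int
    set_sizes: dict[str, int]

    REGION_NAMES = (
        "detected_only",
        "predicted_only",
        "homolog_only",
        "detected_predicted",
        "detected_homolog",
        "predicted_homolog",
        "all_three",
    )


def classify_complement(
    detected: Iterable, predicted: Iterable, homolog: Iterable
) -> ComplementPartition:
    """Partition three gene-id sets into the 7 Venn regions.

    The sets must share an id space (orthology resolution is upstream).
    """
    d, p, h = set(detected), set(predicted), set(homolog)
    regions = {
        "detected_only": len(d - p - h),
        "predicted_only": len(p - d - h),
        "homolog_only": len(h - d - p),
        "detected_predicted": len((d & p) - h),
        "detected_homolog": len((d & h) - p),
        "predicted_homolog": len((p & h) - d),
        "all_three": len(d & p & h),
    }
    union = d | p | h
    return ComplementPartition(
        regions=regions,
        union_count=len(union),
        set_sizes={"detected": len(d), "predicted": len(p), "homolog": len(h)},
    )


# Kyte-Doolittle hydropathy scale
_KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2, "X": 0.0,
}


def predict_signal_peptide(
    protein: ProteinRecord,
    window: int = 8,
    threshold: float = 2.0,
    max_boundary: int = 40,
) -> SignalPrediction:
    """Naive hydrophobic-window signal-peptide heuristic.

    This is NOT a trained signal-peptide predictor: it flags a protein as
    having a signal peptide when a ``window``-residue stretch within the
    first ``max_boundary`` residues has mean Kyte-Doolittle hydropathy
    ≥ ``threshold``, and places the boundary at the end of the last such
    window.  Intended only for synthetic data; real analyses should supply
    externally predicted signal calls.
    """
    seq = protein.sequence[:max_boundary]
    if len(seq) < window:
        return SignalPrediction(protein.id, False)
    scores = [
        sum(_KD[a] for a in seq[i : i + window]) / window
        for i in range(len(seq) - window + 1)
    ]
    hits = [i for i, s in enumerate(scores) if s >= threshold]
    if not hits:
        return SignalPrediction(protein.id, False)
    boundary = min(hits[-1] + window, len(protein.sequence) - 1)
    return SignalPrediction(protein.id, True, boundary)
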