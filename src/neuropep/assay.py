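"""Scheduled parallel-reaction-monitoring (PRM) assay design.

A PRM assay monitors a predefined list of peptide precursor ions, each
within a retention-time (RT) window around its library reference RT.  The
instrument can only follow a limited number of targets simultaneously
(caps of 50, or 70–80, simultaneous targets at any RT in the emulated
workflow), so large target lists must be split over several sample
injections.

* :func:`build_assay` — from a spectral library, pick each peptide's most
  intense precursor charge state and its six most intense fragment ions.
* :func:`concurrency_profile` — the maximum number of targets whose RT
  windows overlap any single retention time.
* :func:`schedule_injections` — greedy first-fit assignment of targets to
  the fewest injections that keep peak concurrency under the cap.
* :func:`unscheduled_injections` — injections needed without RT
  scheduling (every target monitored for the whole run):
  ``ceil(n_targets / cap)``.
* :func:`calibrate_rt` — least-squares linear mapping from library
  (indexed) RTs to observed run RTs, fitted on standard peptides.

RT windows are full widths centered on the reference RT; typical values
are 5 min (technical replicates) to 10 min (biological comparisons, where
RT variability is higher).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Fragment",
    "LibrarySpectrum",
    "AssayTarget",
    "ScheduleResult",
    "build_assay",
    "concurrency_profile",
    "schedule_injections",
    "unscheduled_injections",
    "calibrate_rt",
    "library_from_frame",
    "targets_to_frame",
]


@dataclass(frozen=True)
class Fragment:
    """One fragment ion of a library spectrum."""

    label: str
    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError(f"fragment {self.label}: negative intensity")


@dataclass(frozen=True)
class LibrarySpectrum:
    """Reference spectrum of one peptide ion in a spectral library."""

    peptide: str
    charge: int
    fragments: tuple[Fragment, ...]
    rt: float
    modifications: str = ""
    is_standard: bool = False

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError(f"{self.peptide}: charge must be ≥ 1")
        if not self.fragments:
            raise ValueError(f"{self.peptide}/{self.charge}+: no fragments")

    @property
    def peptide_ion(self) -> str:
        mods = f"[{self.modifications}]" if self.modifications else ""
        return f"{self.peptide}{mods}"

    @property
    def total_intensity(self) -> float:
        return sum(f.intensity for f in self.fragments)


@dataclass(frozen=True)
class AssayTarget:
    """A peptide ion to be monitored: chosen charge, top fragments, RT window."""

    peptide_ion: str
    charge: int
    fragments: tuple[Fragment, ...]
    rt_center: float
    rt_window: float

    def __post_init__(self) -> None:
        if self.rt_window <= 0:
            raise ValueError("rt_window must be > 0")

    @property
    def rt_start(self) -> float:
        return self.rt_center - self.rt_window / 2.0

    @property
    def rt_end(self) -> float:
        return self.rt_center + self.rt_window / 2.0


def build_assay(
    library: Sequence[LibrarySpectrum],
    top_k: int = 6,
    rt_window: float = 10.0,
) -> list[AssayTarget]:
    """Build one assay target per peptide from a spectral library.

    For each peptide the most intense precursor charge state is chosen
    (ties broken by lower charge), and its ``top_k`` most intense fragment
    ions are retained, sorted by descending intensity (ties broken by
    fragment label for determinism).
    """
    if not library:
        raise ValueError("empty spectral library")
    by_peptide: dict[str, list[LibrarySpectrum]] = {}
    for spec in library:
        by_peptide.setdefault(spec.peptide_ion, []).append(spec)

    targets = []
    for ion in sorted(by_peptide):
        specs = by_peptide[ion]
        best = max(specs, key=lambda s: (s.total_intensity, -s.charge))
        frags = sorted(best.fragments, key=lambda f: (-f.intensity, f.label))[:top_k]
        targets.append(
            AssayTarget(
                peptide_ion=ion,
                charge=best.charge,
                fragments=tuple(frags),
                rt_center=best.rt,
                rt_window=rt_window,
            )
        )
    return targets


def concurrency_profile(
    targets: Sequence[AssayTarget],
) -> tuple[int, float]:
    """Maximum number of simultaneously monitored targets, and an RT where
    that maximum is reached.

    Windows are closed intervals [center − w/2, center + w/2]; the maximum
    overlap of closed intervals is attained at some window start, so a
    sweep over window endpoints suffices.
    """
    if not targets:
        return 0, 0.0
    starts = np.array([t.rt_start for t in targets])
    ends = np.array([t.rt_end for t in targets])
    best, best_rt = 0, float(starts[0])
    for s in starts:
        count = int(np.sum((starts <= s) & (ends >= s)))
        if count > best:
            best, best_rt = count, float(s)
    return best, best_rt


@dataclass
class ScheduleResult:
    """Assignment of assay targets to sample injections.

    ``assignment`` maps peptide ion → injection index (0-based); every
    target is assigned exactly once and every injection's peak concurrency
    respects the cap.
    """

    assignment: dict[str, int]
    n_injections: int
    max_concurrent: int
    peak_concurrency: list[int] = field(default_factory=list)

    def injection_targets(self, targets: Sequence[AssayTarget], i: int
                          ) -> list[AssayTarget]:
        return [t for t in targets if self.assignment[t.peptide_ion] == i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"peptide_ion": list(self.assignment),
             "injection": list(self.assignment.values())}
        )


def schedule_injections(
    targets: Sequence[AssayTarget],
    max_concurrent: int,
    rt_window: float | None = None,
) -> ScheduleResult:
    """Greedy first-fit scheduling of targets into injections.

    Targets are taken in ascending RT-center order (ties by peptide ion
    for determinism) and placed into the first injection where adding them
    keeps peak concurrency ≤ ``max_concurrent``; a new injection is opened
    when none fits.  ``rt_window``, if given, overrides each target's own
    window.
    """
    if max_concurrent < 1:
        raise ValueError("max_concurrent must be ≥ 1")
    if rt_window is not None:
        targets = [
            AssayTarget(t.peptide_ion, t.charge, t.fragments, t.rt_center, rt_window)
            for t in targets
        ]
    order = sorted(targets, key=lambda t: (t.rt_center, t.peptide_ion))
    injections: list[list[AssayTarget]] = []
    assignment: dict[str, int] = {}
    for t in order:
        placed = False
        for i, inj in enumerate(injections):
            peak, _ = concurrency_profile(inj + [t])
            if peak <= max_concurrent:
                inj.append(t)
                assignment[t.peptide_ion] = i
                placed = True
                break
        if not placed:
            injections.append([t])
            assignment[t.peptide_ion] = len(injections) - 1
    peaks = [concurrency_profile(inj)[0] for inj in injections]
    return ScheduleResult(
        assignment=assignment,
        n_injections=len(injections),
        max_concurrent=max_concurrent,
        peak_concurrency=peaks,
    )


def unscheduled_injections(n_targets: int, max_concurrent: int) -> int:
    """Injections needed without RT scheduling: every target is monitored
    for the whole run, so ``ceil(n_targets / max_concurrent)``.

    This is a simple model of an unscheduled workflow (real instruments
    add cycle-time constraints on top).
    """
    if n_targets < 1 or max_concurrent < 1:
        raise ValueError("n_targets and max_concurrent must be ≥ 1")
    return math.ceil(n_targets / max_concurrent)


def calibrate_rt(
    library: Sequence[LibrarySpectrum],
    observed: dict[str, float] | pd.Series,
) -> tuple[float, float]:
    """Least-squares linear mapping from library RT to run RT.

    Fitted on the library's standard peptides (``is_standard`` rows) that
    appear in ``observed`` (peptide ion → run RT).  Returns (slope,
    intercept).
    """
    pairs = [
        (s.rt, observed[s.peptide_ion])
        for s in library
        if s.is_standard and s.peptide_ion in observed
    ]
    if len(pairs) < 2:
        raise ValueError("need at least 2 observed standards for RT calibration")
    x, y = np.array(pairs).T
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def library_from_frame(frame: pd.DataFrame) -> list[LibrarySpectrum]:
    """Read a spectral library from a long table (one row per fragment).

    Expected columns: peptide, charge, fragment, mz, intensity, rt;
    optional: modifications, is_standard.
    """
    specs = []
    keys = ["peptide", "charge"]
    if "modifications" in frame.columns:
        keys.append("modifications")
    for key, g in frame.groupby(keys, sort=False):
        vals = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        frags = tuple(
            Fragment(str(r.fragment), float(r.mz), float(r.intensity))
            for r in g.itertuples()
        )
        specs.append(
            LibrarySpectrum(
                peptide=str(vals["peptide"]),
                charge=int(vals["charge"]),
                fragments=frags,
                rt=float(g["rt"].iloc[0]),
                modifications=str(vals.get("modifications", "") or ""),
                is_standard=bool(g["is_standard"].iloc[0])
                if "is_standard" in g.columns
                else False,
            )
        )
    return specs


def targets_to_frame(targets: Sequence[AssayTarget]) -> pd.DataFrame:
    """Serialize assay targets to a long table (one row per fragment)."""
    rows = []
    for t in targets:
        for f in t.fragments:
            rows.append(
                {"peptide_ion": t.peptide_ion, "charge": t.charge,
                 "fragment": f.label, "mz": f.mz, "intensity": f.intensity,
                 "rt_center": t.rt_center, "rt_window": t.rt_window}
            )
    return pd.DataFrame(rows)
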