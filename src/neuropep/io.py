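"""File I/O helpers: FASTA proteomes, delimited tables, signal-call tables.

FASTA is read and written through Biopython; delimited tables (comma or
tab, header row, UTF-8) through pandas with separator sniffing on read.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO

from .discovery import ProteinRecord, SignalPrediction

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_table",
    "write_table",
    "read_signal_predictions",
    "write_signal_predictions",
]


def read_fasta(source) -> list[ProteinRecord]:
    """Read a proteome FASTA (path or file-like) into protein records."""
    if isinstance(source, (str, Path)):
        handle = open(source)
        close = True
    else:
        handle = source
        close = False
    try:
        return [
            ProteinRecord(id=rec.id, sequence=str(rec.seq).upper())
            for rec in SeqIO.parse(handle, "fasta")
        ]
    finally:
        if close:
            handle.close()


def write_fasta(proteins: Sequence[ProteinRecord] | str, path) -> None:
    """Write protein records (or pre-formatted FASTA text) to a file."""
    if isinstance(proteins, str):
        Path(path).write_text(proteins)
        return
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(p.sequence), id=p.id, description="") for p in proteins]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_table(path) -> pd.DataFrame:
    """Read a delimited table, sniffing tab vs comma from the header row."""
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if "\t" in first else ","
    return pd.read_csv(path, sep=sep)


def write_table(frame: pd.DataFrame, path, sep: str = "\t") -> None:
    frame.to_csv(path, sep=sep, index=False)


def read_signal_predictions(path) -> list[SignalPrediction]:
    """Read signal-peptide calls from a table with columns protein_id,
    has_signal, cleavage_position (1-based index of the last signal
    residue)."""
    df = read_table(path)
    preds = []
    for r in df.itertuples():
        has = bool(r.has_signal)
        preds.append(
            SignalPrediction(
                protein_id=str(r.protein_id),
                has_signal=has,
                cleavage_position=int(r.cleavage_position) if has else None,
            )
        )
    return preds


def write_signal_predictions(preds: Sequence[SignalPrediction], path) -> None:
    rows = [
        {
            "protein_id": p.protein_id,
            "has_signal": p.has_signal,
            "cleavage_position": p.cleavage_position if p.has_signal else "",
        }
        for p in preds
    ]
    write_table(pd.DataFrame(rows), path)
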