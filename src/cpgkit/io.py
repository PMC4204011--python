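"""FASTA / TSV / BED plumbing shared by the library and the CLI."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from cpgkit.composition import NucleotideSequence

__all__ = ["read_fasta", "write_fasta", "write_tsv", "write_bed"]


def read_fasta(path: str | Path) -> dict[str, NucleotideSequence]:
    """Read a (multi-record, wrapped or unwrapped) FASTA into sequences.

    Record order is preserved; duplicate ids raise ``ValueError``.
    """
    out: dict[str, NucleotideSequence] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in out:
            raise ValueError(f"duplicate FASTA id {record.id!r} in {path}")
        out[record.id] = NucleotideSequence(record.id, str(record.seq))
    return out


def write_fasta(
    sequences: Mapping[str, NucleotideSequence] | Iterable[NucleotideSequence],
    path: str | Path,
    line_width: int = 60,
) -> None:
    seqs = sequences.values() if isinstance(sequences, Mapping) else sequences
    records = [SeqRecord(Seq(s.bases), id=s.id, description="") for s in seqs]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=line_width)
        writer.write_file(records)


def write_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_bed(table: pd.DataFrame, path: str | Path) -> None:
    """Write a BED table (0-based half-open), no header."""
    table.to_csv(path, sep="\t", index=False, header=False)
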