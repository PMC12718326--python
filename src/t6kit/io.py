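"""Shared on-disk formats: FASTA, FASTQ and header-validated TSV tables.

Conventions: TSV with UTF-8 and '.' for missing values; gene coordinates are
1-based inclusive on disk and converted to 0-based half-open on read; FASTA
sequences are uppercased on read. Generated files carry the generating seed
in a leading ``# seed=`` comment (tables) or in the record description
(FASTA/FASTQ).
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FastqRead(NamedTuple):
    """A minimal FASTQ record: identifier, sequence, per-base Phred qualities."""

    read_id: str
    sequence: str
    qualities: Sequence[int]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read FASTA into an ordered ``{id: uppercase sequence}`` mapping."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(records: Mapping[str, str], path: str | os.PathLike,
                seed: int | None = None) -> None:
    desc = f"seed={seed}" if seed is not None else ""
    seqs = [SeqRecord(Seq(s), id=name, description=desc)
            for name, s in records.items()]
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def read_fastq(path: str | os.PathLike) -> list[FastqRead]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = rec.letter_annotations["phred_quality"]
        reads.append(FastqRead(rec.id, str(rec.seq).upper(), quals))
    return reads


def write_fastq(reads: Iterable[FastqRead], path: str | os.PathLike,
                seed: int | None = None) -> None:
    desc = f"seed={seed}" if seed is not None else ""
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description=desc)
        rec.letter_annotations["phred_quality"] = list(r.qualities)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def read_table(path: str | os.PathLike,
               required: Sequence[str] | None = None) -> pd.DataFrame:
    """Read a TSV table, validating that ``required`` columns are present.

    Lines starting with '#' are treated as comments; '.' is read as missing.
    """
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["."],
                     keep_default_na=True)
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(
                f"table {path} is missing required column(s): {', '.join(missing)}"
            )
    return df


def write_table(df: pd.DataFrame, path: str | os.PathLike,
                seed: int | None = None) -> None:
    """Write a TSV table, '.' for missing values, optional seed comment."""
    with open(path, "w", encoding="utf-8") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep=".")
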