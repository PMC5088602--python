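"""FASTA/FASTQ/TSV readers and writers.

Sequence parsing is delegated to Biopython's SeqIO and then validated
against this package's stricter contract (non-empty, unique ids, uppercase
DNA). Matrices round-trip through pandas with deterministic lexicographic
row/column order so that output files diff cleanly between runs.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


class FormatError(ValueError):
    """A malformed FASTA/FASTQ/TSV input."""


@dataclass
class SequenceRecord:
    """A named DNA sequence (reference genome, gene, or marker)."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise FormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise FormatError(f"record {self.id!r}: invalid bases {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReadRecord:
    """A sequencing read with per-base Phred quality scores."""

    id: str
    sequence: str
    qualities: np.ndarray  # int array, same length as sequence

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        self.qualities = np.asarray(self.qualities, dtype=np.int16)
        if len(self.qualities) != len(self.sequence):
            raise FormatError(
                f"read {self.id!r}: {len(self.sequence)} bases but "
                f"{len(self.qualities)} quality scores"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def mean_quality(self) -> float:
        return float(self.qualities.mean())


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Parse a FASTA file, preserving record order.

    Multi-line sequences are concatenated and lower-case bases upper-cased.
    Empty sequences, duplicate ids and non-FASTA content raise FormatError.
    """
    path = Path(path)
    with _open_text(path) as fh:
        text_head = fh.read(1)
    if text_head and text_head != ">":
        raise FormatError(f"{path}: line 1: expected FASTA header starting with '>'")
    records = []
    seen: set[str] = set()
    try:
        with _open_text(path) as fh:
            parsed = list(SeqIO.parse(fh, "fasta"))
        for i, rec in enumerate(parsed, 1):
            if not rec.id:
                raise FormatError(f"{path}: record {i}: missing id in header")
            if rec.id in seen:
                raise FormatError(f"{path}: record {i}: duplicate id {rec.id!r}")
            seen.add(rec.id)
            try:
                records.append(
                    SequenceRecord(rec.id, str(rec.seq), rec.description[len(rec.id):].strip())
                )
            except FormatError as e:
                raise FormatError(f"{path}: record {i}: {e}") from None
    except ValueError as e:
        if isinstance(e, FormatError):
            raise
        raise FormatError(f"{path}: {e}") from None
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_fastq(path: str | Path) -> list[ReadRecord]:
    """Parse 4-line Phred+33 FASTQ; '@' in quality lines is handled by
    record framing (fixed 4-line records), not content sniffing."""
    reads = []
    try:
        with _open_text(Path(path)) as fh:
            parsed = list(SeqIO.parse(fh, "fastq"))
        for i, rec in enumerate(parsed, 1):
            quals = np.array(rec.letter_annotations["phred_quality"], dtype=np.int16)
            try:
                reads.append(ReadRecord(rec.id, str(rec.seq), quals))
            except FormatError as e:
                raise FormatError(f"{path}: record {i}: {e}") from None
    except ValueError as e:
        if isinstance(e, FormatError):
            raise
        raise FormatError(f"{path}: {e}") from None
    return reads


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            qual = "".join(chr(int(q) + 33) for q in read.qualities)
            fh.write(f"@{read.id}\n{read.sequence}\n+\n{qual}\n")


def write_matrix(
    matrix: np.ndarray | pd.DataFrame,
    row_ids: Sequence[str] | None,
    col_ids: Sequence[str] | None,
    path: str | Path,
    index_name: str = "id",
) -> None:
    """Write a labelled matrix as TSV, rows/columns sorted lexicographically.

    The first column holds row ids; the header row holds column ids.
    """
    if isinstance(matrix, pd.DataFrame):
        df = matrix.copy()
    else:
        df = pd.DataFrame(np.asarray(matrix), index=list(row_ids), columns=list(col_ids))
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate row ids: {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise FormatError(f"duplicate column ids: {dups}")
    df = df.sort_index(axis=0).sort_index(axis=1)
    df.index.name = index_name
    df.to_csv(path, sep="\t")


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a TSV matrix written by write_matrix (row ids in column 1)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise FormatError(f"{path}: duplicate row ids")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Plain TSV export of a record-style table (no index column)."""
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
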