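"""Sequence and table I/O: FASTA/FASTQ reading, the amplicon length filter,
and the clonotype round-table TSV dialect.

Reads are treated as already-merged full-length amplicons; one record per
template. Round tables store raw counts and representative coding sequences;
abundance is always recomputed from counts, never trusted from disk.
"""
from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, TextIO

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import FormatError, ParseError, UndefinedStatisticError

ROUND_TABLE_HEADER = ("cdr3_aa", "count", "abundance_pct", "rep_nt")


@dataclass
class Read:
    """One sequencing read (merged amplicon)."""

    id: str
    seq: str
    qual: Optional[str] = None

    def __post_init__(self):
        if not self.seq:
            raise ParseError(f"read {self.id!r}: empty sequence")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ParseError(
                f"read {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class FilterStats:
    kept: int = 0
    dropped: int = 0


@dataclass
class RoundTable:
    """Clonotype table for one library x round.

    counts maps CDR3 amino-acid string -> read count; rep_nt maps each CDR3
    to its representative coding nucleotide sequence (3x the aa length).
    """

    label: str
    counts: dict[str, int] = field(default_factory=dict)
    rep_nt: dict[str, str] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def n_unique(self) -> int:
        return len(self.counts)

    def validate(self) -> None:
        for cdr3, count in self.counts.items():
            if count <= 0 or count != int(count):
                raise FormatError(f"{self.label}: count for {cdr3!r} not a positive integer")
        for cdr3, nt in self.rep_nt.items():
            if cdr3 not in self.counts:
                raise FormatError(f"{self.label}: rep_nt key {cdr3!r} missing from counts")
            if len(nt) != 3 * len(cdr3):
                raise FormatError(
                    f"{self.label}: rep_nt for {cdr3!r} has length {len(nt)}, "
                    f"expected {3 * len(cdr3)}"
                )


def _open_text(path: str | os.PathLike) -> TextIO:
    path = os.fspath(path)
    if path.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="ascii")
    return open(path, "r", encoding="ascii")


def _detect_format(path: str) -> str:
    base = path[:-3] if path.endswith(".gz") else path
    ext = os.path.splitext(base)[1].lower()
    if ext in (".fastq", ".fq"):
        return "fastq"
    if ext in (".fasta", ".fa", ".fna"):
        return "fasta"
    raise ParseError(f"cannot auto-detect format from extension of {path!r}")


def read_sequences(path: str | os.PathLike, format: str = "auto") -> Iterator[Read]:
    """Yield reads from a FASTA/FASTQ file (optionally gzip-compressed).

    Lowercase bases are uppercased; N bases are preserved. Duplicate read ids
    within one file and malformed records raise :class:`ParseError`.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise ParseError(f"no such file: {path}")
    fmt = _detect_format(path) if format == "auto" else format
    if fmt not in ("fastq", "fasta"):
        raise ParseError(f"unknown format {fmt!r}")

    seen: set[str] = set()
    n_records = 0
    with _open_text(path) as handle:
        if fmt == "fastq":
            iterator = FastqGeneralIterator(handle)
            lines_per_record = 4
        else:
            iterator = ((title, seq, None) for title, seq in SimpleFastaParser(handle))
            lines_per_record = 2
        while True:
            try:
                item = next(iterator, None)
            except ValueError as exc:  # malformed record from the Bio parser
                raise ParseError(
                    f"{path}: malformed {fmt} record near line "
                    f"{n_records * lines_per_record + 1}: {exc}"
                ) from exc
            if item is None:
                break
            title, seq, qual = item
            n_records += 1
            read_id = title.split(None, 1)[0] if title else ""
            if not read_id:
                raise ParseError(
                    f"{path}: missing id in record near line "
                    f"{(n_records - 1) * lines_per_record + 1}"
                )
            if read_id in seen:
                raise ParseError(f"{path}: duplicate read id {read_id!r}")
            seen.add(read_id)
            try:
                yield Read(read_id, seq.upper(), qual)
            except ParseError as exc:
                raise ParseError(
                    f"{path}: record near line "
                    f"{(n_records - 1) * lines_per_record + 1}: {exc}"
                ) from exc


def filter_by_length(
    reads: Iterable[Read], min_len: int = 400, strict: bool = True
) -> tuple[list[Read], FilterStats]:
    """Keep reads longer than ``min_len`` bp (strictly by default).

    strict=True keeps length > min_len; strict=False keeps length >= min_len.
    Order is preserved; returns the kept reads and kept/dropped tallies.
    """
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    stats = FilterStats()
    kept: list[Read] = []
    for read in reads:
        ok = len(read) > min_len if strict else len(read) >= min_len
        if ok:
            kept.append(read)
            stats.kept += 1
        else:
            stats.dropped += 1
    return kept, stats


def sorted_clonotypes(table: RoundTable) -> list[str]:
    """Clonotypes sorted by count descending, then CDR3 lexicographic."""
    return sorted(table.counts, key=lambda c: (-table.counts[c], c))


def write_round_table(table: RoundTable, path: str | os.PathLike) -> None:
    table.validate()
    total = table.total
    with open(path, "w", encoding="utf-8") as out:
        out.write("\t".join(ROUND_TABLE_HEADER) + "\n")
        for cdr3 in sorted_clonotypes(table):
            count = table.counts[cdr3]
            pct = 100.0 * count / total
            out.write(f"{cdr3}\t{count}\t{pct:.6f}\t{table.rep_nt.get(cdr3, '')}\n")


def read_round_table(path: str | os.PathLike, label: Optional[str] = None) -> RoundTable:
    """Read a round-table TSV; counts are authoritative, abundance is ignored."""
    path = os.fspath(path)
    table = RoundTable(label=label or os.path.basename(path))
    with open(path, "r", encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if tuple(header) != ROUND_TABLE_HEADER:
            raise FormatError(f"{path}: bad header {header!r}")
        for lineno, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            cdr3, count_s, _pct, nt = parts
            try:
                count = int(count_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: count {count_s!r} is not an integer")
            if count <= 0:
                raise FormatError(f"{path}:{lineno}: count must be positive")
            if cdr3 in table.counts:
                raise FormatError(f"{path}:{lineno}: duplicate clonotype {cdr3!r}")
            if nt and len(nt) != 3 * len(cdr3):
                raise FormatError(
                    f"{path}:{lineno}: rep_nt length {len(nt)} != {3 * len(cdr3)}"
                )
            table.counts[cdr3] = count
            if nt:
                table.rep_nt[cdr3] = nt
    if not table.counts:
        raise UndefinedStatisticError(f"{path}: empty round table")
    return table


def write_fastq(reads: Iterable[Read], path: str | os.PathLike) -> None:
    """Write reads as FASTQ (gzip if the path ends in .gz)."""
    path = os.fspath(path)
    opener = (
        (lambda p: io.TextIOWrapper(gzip.open(p, "wb"), encoding="ascii"))
        if path.endswith(".gz")
        else (lambda p: open(p, "w", encoding="ascii"))
    )
    with opener(path) as out:
        for read in reads:
            qual = read.qual if read.qual is not None else "I" * len(read)
            out.write(f"@{read.id}\n{read.seq}\n+\n{qual}\n")


def write_fasta(reads: Iterable[Read], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="ascii") as out:
        for read in reads:
            out.write(f">{read.id}\n{read.seq}\n")
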