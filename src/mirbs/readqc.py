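"""FASTQ parsing, read quality filters and unique-read collapsing.

Small-RNA bisulfite libraries are filtered before alignment:

* length must exceed 16 nt (keep length >= 17);
* read-level quality must reach Q30 (mean Phred by default; an optional
  per-base mode rejects a read if any base is below the threshold);
* reads containing a single-nucleotide run longer than 12 bases are
  low-complexity artifacts and are dropped (N runs count too);
* reads with an undetermined (N) base at either end are dropped.

Surviving reads are collapsed: identical sequences merge into one record
with a multiplicity count, written as ``>u{rank}_x{count}`` FASTA. All
downstream quantification is multiplicity-weighted, so collapsing never
changes an estimate.
"""

from __future__ import annotations

import gzip
import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, TextIO

from Bio import SeqIO

from .refio import normalize_sequence

_HOMOPOLYMER = re.compile(r"(A+|C+|G+|T+|N+)")


@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"sequence/quality length mismatch for read {self.read_id!r}"
            )


@dataclass(frozen=True)
class QcConfig:
    """Thresholds for the read filters (defaults follow the study protocol)."""

    min_length: int = 17
    min_quality: int = 30
    max_homopolymer: int = 12
    drop_terminal_n: bool = True
    per_base_quality: bool = False  # False: mean-Phred criterion

    def __post_init__(self) -> None:
        if self.min_length < 1 or self.max_homopolymer < 1:
            raise ValueError("min_length and max_homopolymer must be >= 1")


@dataclass(frozen=True)
class CollapsedRead:
    collapsed_id: str
    sequence: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")


def _open_maybe_gzip(path: str | Path) -> TextIO:
    p = str(path)
    if p.endswith(".gz"):
        return gzip.open(p, "rt")
    return open(p)


def parse_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream Phred+33 FASTQ records (plain or gzip), normalized to DNA.

    Truncated records and sequence/quality length mismatches raise with the
    offending read named.
    """
    with _open_maybe_gzip(path) as fh:
        try:
            for rec in SeqIO.parse(fh, "fastq"):
                yield ReadRecord(
                    rec.id,
                    normalize_sequence(str(rec.seq)),
                    tuple(rec.letter_annotations["phred_quality"]),
                )
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ {path}: {exc}") from exc


def passes_filters(read: ReadRecord, cfg: QcConfig) -> tuple[bool, str | None]:
    """Apply the read filters; returns (pass, first triggered reject reason).

    Reasons, in evaluation order: ``too_short``, ``low_quality``,
    ``homopolymer``, ``terminal_n``.
    """
    if len(read.sequence) < cfg.min_length:
        return False, "too_short"
    if cfg.per_base_quality:
        ok = min(read.qualities) >= cfg.min_quality
    else:
        ok = sum(read.qualities) / len(read.qualities) >= cfg.min_quality
    if not ok:
        return False, "low_quality"
    longest = max(len(m.group(0)) for m in _HOMOPOLYMER.finditer(read.sequence))
    if longest > cfg.max_homopolymer:
        return False, "homopolymer"
    if cfg.drop_terminal_n and (
        read.sequence[0] == "N" or read.sequence[-1] == "N"
    ):
        return False, "terminal_n"
    return True, None


def filter_reads(
    reads: Iterable[ReadRecord], cfg: QcConfig
) -> tuple[list[ReadRecord], Counter]:
    """Partition a stream into passing reads and per-reason reject counts."""
    kept: list[ReadRecord] = []
    rejects: Counter = Counter()
    for read in reads:
        ok, reason = passes_filters(read, cfg)
        if ok:
            kept.append(read)
        else:
            rejects[reason] += 1
    return kept, rejects


def collapse_unique(reads: Iterable[ReadRecord]) -> list[CollapsedRead]:
    """Collapse identical sequences to unique records with counts.

    Ids are ``u{rank}_x{count}`` with rank by descending count, then
    lexicographic sequence — deterministic regardless of input order.
    """
    counts = Counter(r.sequence for r in reads)
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [
        CollapsedRead(f"u{rank}_x{count}", seq, count)
        for rank, (seq, count) in enumerate(ordered, start=1)
    ]


def write_collapsed_fasta(collapsed: Iterable[CollapsedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for cr in collapsed:
            fh.write(f">{cr.collapsed_id}\n{cr.sequence}\n")


def load_collapsed_fasta(path: str | Path) -> list[CollapsedRead]:
    """Re-load a collapsed FASTA; counts parsed from the ``_x{count}`` suffix."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            count = int(rec.id.rsplit("_x", 1)[1])
        except (IndexError, ValueError) as exc:
            raise ValueError(
                f"collapsed FASTA id {rec.id!r} lacks an _x<count> suffix"
            ) from exc
        out.append(CollapsedRead(rec.id, normalize_sequence(str(rec.seq)), count))
    return out


def write_qc_report(
    rejects: Counter, n_in: int, n_passed: int, path: str | Path
) -> None:
    """QC funnel TSV: one row per reject reason plus input/passed totals."""
    with open(path, "w") as fh:
        fh.write("category\tcount\n")
        fh.write(f"input_reads\t{n_in}\n")
        fh.write(f"passed\t{n_passed}\n")
        for reason in ("too_short", "low_quality", "homopolymer", "terminal_n"):
            fh.write(f"rejected_{reason}\t{rejects.get(reason, 0)}\n")
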