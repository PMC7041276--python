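"""Hairpin / mature miRNA reference handling.

Pre-miRNA hairpins are the mapping reference for small-RNA bisulfite reads.
Each hairpin carries the coordinates of its mature arm(s) and the positions
of its cytosines, split by dinucleotide context: CpG sites (where 5mC is
quantified) versus non-CpG cytosines (CpA/CpT/CpC, assumed unmethylated and
used to estimate bisulfite conversion efficiency).

Coordinates are 0-based, half-open throughout. RNA input (miRBase dialect)
is normalized to the DNA alphabet (U->T, uppercase) at load time, because
sequencer output is DNA-alphabet.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

_IUPAC_OK = set("ACGTN")


def normalize_sequence(seq: str) -> str:
    """Uppercase and convert RNA to DNA alphabet (U -> T)."""
    return str(seq).upper().replace("U", "T")


def count_cpg(sequence: str) -> int:
    """Number of CG dinucleotides in ``sequence`` (overlapping scan, step 1).

    Accepts RNA or DNA alphabet; ``U`` is treated as ``T`` so a CG in RNA
    spelling ("CG" after normalization) is counted. Empty input returns 0.
    """
    s = normalize_sequence(sequence)
    return s.count("CG")


@dataclass(frozen=True)
class MatureAnnotation:
    """Location of one mature miRNA on its hairpin (0-based, half-open)."""

    mature_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid mature span [{self.start}, {self.end}) for {self.mature_id!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class HairpinReference:
    """One pre-miRNA hairpin with mature annotations and cytosine context.

    ``cpg_positions`` holds the 0-based position of the C of every CG
    dinucleotide; ``noncpg_c_positions`` every other C with a defined
    successor base. A terminal C has no dinucleotide context and belongs to
    neither set.
    """

    hairpin_id: str
    sequence: str
    matures: list[MatureAnnotation] = field(default_factory=list)
    cpg_positions: list[int] = field(default_factory=list)
    noncpg_c_positions: list[int] = field(default_factory=list)

    @classmethod
    def from_sequence(
        cls,
        hairpin_id: str,
        sequence: str,
        matures: Sequence[MatureAnnotation] = (),
    ) -> "HairpinReference":
        seq = normalize_sequence(sequence)
        bad = [(i, b) for i, b in enumerate(seq) if b not in _IUPAC_OK]
        if bad:
            i, b = bad[0]
            raise ValueError(
                f"non-IUPAC character {b!r} at position {i} in record {hairpin_id!r}"
            )
        cpg, noncpg = [], []
        for i, base in enumerate(seq[:-1]):
            if base == "C":
                (cpg if seq[i + 1] == "G" else noncpg).append(i)
        for m in matures:
            if m.end > len(seq):
                raise ValueError(
                    f"mature {m.mature_id!r} span [{m.start}, {m.end}) exceeds "
                    f"hairpin {hairpin_id!r} length {len(seq)}"
                )
        return cls(hairpin_id, seq, list(matures), cpg, noncpg)


def load_hairpin_fasta(path: str | Path) -> list[HairpinReference]:
    """Load a hairpin FASTA (miRBase hairpin dialect accepted).

    The hairpin id is the first whitespace-delimited header token. Raises on
    an empty file, a duplicate id, or a non-IUPAC character.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    hairpins: list[HairpinReference] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate hairpin id {rec.id!r} in {path}")
        seen.add(rec.id)
        hairpins.append(HairpinReference.from_sequence(rec.id, str(rec.seq)))
    return hairpins


def write_hairpin_fasta(hairpins: Iterable[HairpinReference], path: str | Path) -> None:
    with open(path, "w") as fh:
        for hp in hairpins:
            fh.write(f">{hp.hairpin_id}\n{hp.sequence}\n")


def load_mature_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Load mature miRNA sequences as (mature_id, DNA-normalized sequence)."""
    out = [
        (rec.id, normalize_sequence(str(rec.seq)))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out


def _family_prefix(identifier: str) -> str:
    """Heuristic miR-family key: drop arm suffix and trailing paralog index.

    ``hsa-mir-181a-1`` and ``hsa-miR-181a-5p`` both reduce to ``hsa-mir-181a``
    so matures are searched first on the hairpins of their own family.
    """
    key = identifier.lower()
    for suffix in ("-5p", "-3p"):
        if key.endswith(suffix):
            key = key[: -len(suffix)]
    parts = key.split("-")
    if parts and parts[-1].isdigit():
        parts = parts[:-1]
    return "-".join(parts).replace("mir", "mir")


def annotate_matures(
    hairpins: list[HairpinReference],
    matures: Sequence[tuple[str, str]],
) -> list[HairpinReference]:
    """Place mature sequences on hairpins by exact substring search.

    Each mature is first searched in the hairpins sharing its miR-family
    prefix, then in all hairpins if the family search places nothing. Every
    exact occurrence yields one annotation (a mature occurring twice in one
    hairpin yields two). Unplaceable matures are logged, not fatal.

    Returns the same hairpin objects, annotations appended in place.
    """
    by_family: dict[str, list[HairpinReference]] = {}
    for hp in hairpins:
        by_family.setdefault(_family_prefix(hp.hairpin_id), []).append(hp)

    for mature_id, raw_seq in matures:
        seq = normalize_sequence(raw_seq)
        candidates = by_family.get(_family_prefix(mature_id), [])
        placed = _place_on(candidates, mature_id, seq)
        if not placed:
            placed = _place_on(hairpins, mature_id, seq)
        if not placed:
            logger.warning("mature %s could not be placed on any hairpin", mature_id)
    return hairpins


def _place_on(
    hairpins: Iterable[HairpinReference], mature_id: str, seq: str
) -> bool:
    placed = False
    for hp in hairpins:
        start = hp.sequence.find(seq)
        while start != -1:
            hp.matures.append(MatureAnnotation(mature_id, start, start + len(seq)))
            placed = True
            start = hp.sequence.find(seq, start + 1)
    return placed


def load_mature_coords(path: str | Path) -> dict[str, list[MatureAnnotation]]:
    """Read an explicit mature-coordinate TSV.

    Columns: ``hairpin_id  mature_id  start  end`` (0-based half-open), with
    header. Returns hairpin_id -> annotations. An explicit table overrides
    substring search.
    """
    out: dict[str, list[MatureAnnotation]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["hairpin_id", "mature_id", "start", "end"]
        if header[:4] != expected:
            raise ValueError(f"coordinate TSV header must be {expected}, got {header}")
        for line in fh:
            if not line.strip():
                continue
            hp_id, mat_id, start, end = line.rstrip("\n").split("\t")[:4]
            out.setdefault(hp_id, []).append(
                MatureAnnotation(mat_id, int(start), int(end))
            )
    return out


def apply_mature_coords(
    hairpins: list[HairpinReference],
    coords: dict[str, list[MatureAnnotation]],
) -> list[HairpinReference]:
    """Attach annotations from an explicit coordinate table."""
    for hp in hairpins:
        for ann in coords.get(hp.hairpin_id, []):
            if ann.end > len(hp.sequence):
                raise ValueError(
                    f"mature {ann.mature_id!r} span exceeds hairpin {hp.hairpin_id!r}"
                )
            hp.matures.append(ann)
    return hairpins


def reference_audit(matures: Sequence[tuple[str, str]]) -> dict[str, float]:
    """Summary of a mature reference set: unique sequences and CpG content.

    Returns ``n_unique`` (distinct sequences after DNA normalization),
    ``n_with_cpg`` (unique sequences with at least one CG dinucleotide) and
    ``pct_with_cpg``.
    """
    unique = {normalize_sequence(seq) for _, seq in matures}
    with_cpg = sum(1 for s in unique if count_cpg(s) > 0)
    return {
        "n_unique": len(unique),
        "n_with_cpg": with_cpg,
        "pct_with_cpg": 100.0 * with_cpg / len(unique) if unique else 0.0,
    }


def write_reference_audit(hairpins: Iterable[HairpinReference], path: str | Path) -> None:
    """Audit TSV: one row per mature annotation plus per-hairpin CpG counts."""
    with open(path, "w") as fh:
        fh.write(
            "hairpin_id\tmature_id\tstart\tend\tmature_length\t"
            "hairpin_cpg_count\thairpin_noncpg_c_count\n"
        )
        for hp in hairpins:
            rows = hp.matures or [None]
            for m in rows:
                mid = m.mature_id if m else "."
                start = m.start if m else "."
                end = m.end if m else "."
                length = m.length if m else "."
                fh.write(
                    f"{hp.hairpin_id}\t{mid}\t{start}\t{end}\t{length}\t"
                    f"{len(hp.cpg_positions)}\t{len(hp.noncpg_c_positions)}\n"
                )
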