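"""Bisulfite-aware ungapped alignment of collapsed reads to hairpins.

Bisulfite treatment converts unmethylated cytosine to uracil, sequenced as
T. A converted read therefore legitimately shows T where the reference has
C, and this is the ONLY tolerated substitution: the match rule is
asymmetric (read T over reference C is authorized; read C over reference T
is not), and every other mismatch rejects the placement. Alignment is
ungapped with clipping permitted only at the read ends.

Two aligners are provided with identical contracts:

* :func:`align_read_bruteforce` — exhaustive enumeration over every
  (hairpin, diagonal) placement; the independent oracle.
* :func:`align_read` — a seed-and-extend heuristic over a k-mer index whose
  reference k-mers are expanded over all C->T substitution variants, so a
  fully converted read still seeds. Falls back to brute force whenever the
  minimum acceptable alignment length is shorter than the seed, which keeps
  the two aligners exactly equivalent.

Acceptance rules: the aligned span must cover at least ``min_read_fraction``
(default 90 %) of the read, and an alignment enters quantification only for
mature miRNAs it covers at >= ``min_mature_fraction`` (default 80 %).
Multimapping reads are assigned to the hairpin with the longest alignment;
ties are conserved on all targets with the read's full count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Iterator, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .readqc import CollapsedRead
from .refio import HairpinReference

UNCONVERTED_C = "unconverted_C"
CONVERTED_T = "converted_T"

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_PAD = 5  # out-of-reference sentinel


@dataclass(frozen=True)
class MatchPolicy:
    """converted_mode=True authorizes read-T over reference-C; False is
    exact matching (the non-converted control sample)."""

    converted_mode: bool = True


@dataclass(frozen=True)
class AlignParams:
    min_read_fraction: float = 0.90
    min_mature_fraction: float = 0.80
    max_other_mismatches: int = 0
    seed_length: int = 12

    def __post_init__(self) -> None:
        for frac in (self.min_read_fraction, self.min_mature_fraction):
            if not 0 < frac <= 1:
                raise ValueError("alignment fractions must lie in (0, 1]")
        if self.seed_length < 8:
            raise ValueError("seed_length must be >= 8")
        if self.max_other_mismatches != 0:
            raise ValueError("only the authorized T-C substitution is supported")


@dataclass(frozen=True)
class BsAlignment:
    """One ungapped placement of a read on a hairpin.

    ``cytosine_calls`` classifies every reference-C position inside the
    aligned span: ``unconverted_C`` (read shows C) or ``converted_T`` (read
    shows T); any other read base would have failed the match rule.
    """

    collapsed_id: str
    count: int
    hairpin_id: str
    ref_start: int
    ref_end: int
    read_start: int
    read_end: int
    tc_conversions: int
    matched_matures: tuple[str, ...]
    cytosine_calls: tuple[tuple[int, str], ...]

    @property
    def aligned_length(self) -> int:
        return self.ref_end - self.ref_start


def base_match(ref_base: str, read_base: str, policy: MatchPolicy) -> bool:
    """Asymmetric single-base match rule. N never matches anything."""
    if ref_base == "N" or read_base == "N":
        return False
    if ref_base == read_base:
        return True
    return policy.converted_mode and ref_base == "C" and read_base == "T"


def min_aligned_length(read_length: int, params: AlignParams) -> int:
    return math.ceil(params.min_read_fraction * read_length)


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE[b] for b in seq], dtype=np.uint8)


def _leftmost_longest_run(mask: np.ndarray) -> tuple[int, int]:
    """(start, length) of the leftmost maximal run of True in a 1-D mask."""
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    lengths = ends - starts
    best = int(np.argmax(lengths))  # argmax returns the first maximum
    return int(starts[best]), int(lengths[best])


def _matched_matures(
    hairpin: HairpinReference, ref_start: int, ref_end: int, min_fraction: float
) -> tuple[str, ...]:
    out = []
    for m in hairpin.matures:
        overlap = min(ref_end, m.end) - max(ref_start, m.start)
        if overlap >= min_fraction * m.length:
            out.append(m.mature_id)
    return tuple(out)


def _make_alignment(
    read: CollapsedRead,
    hairpin: HairpinReference,
    shift: int,
    read_start: int,
    run_length: int,
    params: AlignParams,
) -> BsAlignment:
    read_end = read_start + run_length
    ref_start, ref_end = read_start + shift, read_end + shift
    calls = []
    tc = 0
    for p in range(ref_start, ref_end):
        if hairpin.sequence[p] == "C":
            rb = read.sequence[p - shift]
            if rb == "C":
                calls.append((p, UNCONVERTED_C))
            else:
                calls.append((p, CONVERTED_T))
                tc += 1
    return BsAlignment(
        collapsed_id=read.collapsed_id,
        count=read.count,
        hairpin_id=hairpin.hairpin_id,
        ref_start=ref_start,
        ref_end=ref_end,
        read_start=read_start,
        read_end=read_end,
        tc_conversions=tc,
        matched_matures=_matched_matures(
            hairpin, ref_start, ref_end, params.min_mature_fraction
        ),
        cytosine_calls=tuple(calls),
    )


def align_read_bruteforce(
    read: CollapsedRead,
    hairpins: Sequence[HairpinReference],
    policy: MatchPolicy,
    params: AlignParams,
) -> list[BsAlignment]:
    """Exhaustive aligner: every (hairpin, diagonal) placement is examined.

    For each diagonal the leftmost maximal run of matching positions is the
    retained placement; it is kept if it reaches ``min_read_fraction`` of
    the read length. Serves as the independent oracle for :func:`align_read`.
    """
    L = len(read.sequence)
    if L == 0:
        return []
    read_arr = _encode(read.sequence)
    min_len = min_aligned_length(L, params)
    out: list[BsAlignment] = []
    for hp in hairpins:
        H = len(hp.sequence)
        padded = np.full(H + 2 * L, _PAD, dtype=np.uint8)
        padded[L : L + H] = _encode(hp.sequence)
        # row r <-> diagonal shift s = r - L (read index j maps to ref j+s)
        windows = sliding_window_view(padded, L)
        match = (windows == read_arr) & (windows != _CODE["N"])
        if policy.converted_mode:
            match |= (windows == _CODE["C"]) & (read_arr == _CODE["T"])
        counts = match.sum(axis=1)
        for r in np.flatnonzero(counts >= min_len):
            start, length = _leftmost_longest_run(match[r])
            if length >= min_len:
                out.append(
                    _make_alignment(read, hp, int(r) - L, start, length, params)
                )
    return out


class SeedIndex:
    """k-mer index over the hairpin bank.

    In converted mode every reference k-mer is inserted under all of its
    C->T substitution variants (2^(#C) keys per k-mer), so the literal k-mer
    of an arbitrarily converted read hits the index directly. The expansion
    is affordable because pre-miRNA banks are small.
    """

    def __init__(
        self,
        hairpins: Sequence[HairpinReference],
        policy: MatchPolicy,
        k: int = 12,
    ) -> None:
        if not hairpins:
            raise ValueError("empty hairpin bank")
        shortest = min(len(hp.sequence) for hp in hairpins)
        if k > shortest:
            raise ValueError(
                f"seed length {k} exceeds shortest hairpin length {shortest}"
            )
        self.k = k
        self.policy = policy
        self.hairpins = list(hairpins)
        self._by_id = {hp.hairpin_id: hp for hp in hairpins}
        self._index: dict[str, set[tuple[str, int]]] = {}
        for hp in hairpins:
            seq = hp.sequence
            for p in range(len(seq) - k + 1):
                kmer = seq[p : p + k]
                for variant in self._variants(kmer):
                    self._index.setdefault(variant, set()).add((hp.hairpin_id, p))

    def _variants(self, kmer: str) -> Iterator[str]:
        if "N" in kmer:
            return  # N never matches; an N-containing window cannot seed
        yield kmer
        if self.policy.converted_mode:
            c_pos = [i for i, b in enumerate(kmer) if b == "C"]
            chars = list(kmer)
            for n in range(1, len(c_pos) + 1):
                for subset in combinations(c_pos, n):
                    for i in subset:
                        chars[i] = "T"
                    yield "".join(chars)
                    for i in subset:
                        chars[i] = "C"

    def lookup(self, kmer: str) -> set[tuple[str, int]]:
        return self._index.get(kmer, set())


def build_seed_index(
    hairpins: Sequence[HairpinReference], policy: MatchPolicy, k: int = 12
) -> SeedIndex:
    return SeedIndex(hairpins, policy, k)


def align_read(
    read: CollapsedRead,
    index: SeedIndex,
    policy: MatchPolicy,
    params: AlignParams,
) -> list[BsAlignment]:
    """Seed-and-extend aligner, exactly equivalent to the brute-force oracle.

    Every read k-mer is looked up in the index; each hit nominates a
    (hairpin, diagonal) candidate which is extended in both directions under
    the asymmetric match rule with end-clipping. When the minimum acceptable
    run is shorter than the seed (very short reads) the read is delegated to
    brute force, since such a run need not contain a full seed.
    """
    L = len(read.sequence)
    if L == 0:
        return []
    k = index.k
    min_len = min_aligned_length(L, params)
    if min_len < k:
        return align_read_bruteforce(read, index.hairpins, policy, params)

    # candidate runs per diagonal: {(hairpin_id, shift): set[(start, length)]}
    runs: dict[tuple[str, int], set[tuple[int, int]]] = {}
    seen_seeds: set[tuple[str, int, int]] = set()
    for j in range(L - k + 1):
        for hp_id, p in index.lookup(read.sequence[j : j + k]):
            shift = p - j
            key = (hp_id, shift)
            if (hp_id, shift, j) in seen_seeds:
                continue
            hp = index._by_id[hp_id]
            j0, j1 = _extend(read.sequence, hp.sequence, shift, j, j + k, policy)
            runs.setdefault(key, set()).add((j0, j1 - j0))
            for jj in range(j0, j1 - k + 1):
                seen_seeds.add((hp_id, shift, jj))

    out: list[BsAlignment] = []
    for (hp_id, shift), run_set in sorted(
        runs.items(), key=lambda kv: (_hp_order(index, kv[0][0]), kv[0][1])
    ):
        best_start, best_len = min(run_set, key=lambda r: (-r[1], r[0]))
        if best_len >= min_len:
            out.append(
                _make_alignment(
                    read, index._by_id[hp_id], shift, best_start, best_len, params
                )
            )
    return out


def _hp_order(index: SeedIndex, hp_id: str) -> int:
    if not hasattr(index, "_order"):
        index._order = {hp.hairpin_id: i for i, hp in enumerate(index.hairpins)}
    return index._order[hp_id]


def _extend(
    read_seq: str,
    ref_seq: str,
    shift: int,
    j_lo: int,
    j_hi: int,
    policy: MatchPolicy,
) -> tuple[int, int]:
    """Grow a matching run [j_lo, j_hi) outward along one diagonal."""
    while (
        j_lo > 0
        and j_lo - 1 + shift >= 0
        and base_match(ref_seq[j_lo - 1 + shift], read_seq[j_lo - 1], policy)
    ):
        j_lo -= 1
    L, H = len(read_seq), len(ref_seq)
    while (
        j_hi < L
        and j_hi + shift < H
        and base_match(ref_seq[j_hi + shift], read_seq[j_hi], policy)
    ):
        j_hi += 1
    return j_lo, j_hi


def resolve_multimap(alignments: list[BsAlignment]) -> list[BsAlignment]:
    """Keep only the longest alignment(s) of one read; ties all conserved.

    Tied placements each retain the read's full count (no fractional
    splitting), so a tied read contributes to every conserved hairpin.
    """
    if not alignments:
        return []
    best = max(a.aligned_length for a in alignments)
    return [a for a in alignments if a.aligned_length == best]


def align_collapsed(
    collapsed: Sequence[CollapsedRead],
    hairpins: Sequence[HairpinReference],
    policy: MatchPolicy,
    params: AlignParams | None = None,
    use_index: bool = True,
) -> dict[str, list[BsAlignment]]:
    """Align a collapsed read set; returns resolved alignments per read id.

    Reads with no acceptable placement are absent from the result.
    """
    params = params or AlignParams()
    index = build_seed_index(hairpins, policy, params.seed_length) if use_index else None
    out: dict[str, list[BsAlignment]] = {}
    for read in collapsed:
        if index is not None:
            alns = align_read(read, index, policy, params)
        else:
            alns = align_read_bruteforce(read, hairpins, policy, params)
        resolved = resolve_multimap(alns)
        if resolved:
            out[read.collapsed_id] = resolved
    return out


def write_alignment_tsv(
    resolved: dict[str, list[BsAlignment]], path: str
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "collapsed_id\tcount\thairpin_id\tref_start\tref_end\t"
            "read_start\tread_end\ttc_conversions\tmatched_matures\ttie_flag\n"
        )
        for read_id in sorted(resolved):
            alns = resolved[read_id]
            tie = int(len(alns) > 1)
            for a in alns:
                matures = ",".join(a.matched_matures) or "."
                fh.write(
                    f"{a.collapsed_id}\t{a.count}\t{a.hairpin_id}\t{a.ref_start}\t"
                    f"{a.ref_end}\t{a.read_start}\t{a.read_end}\t{a.tc_conversions}\t"
                    f"{matures}\t{tie}\n"
                )


def write_alignment_sam(
    resolved: dict[str, list[BsAlignment]],
    hairpins: Sequence[HairpinReference],
    collapsed: Sequence[CollapsedRead],
    path: str,
) -> None:
    """SAM export with XC:i = number of T-C conversion calls per alignment."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [
            {"SN": hp.hairpin_id, "LN": len(hp.sequence)} for hp in hairpins
        ],
    }
    tid = {hp.hairpin_id: i for i, hp in enumerate(hairpins)}
    seqs = {cr.collapsed_id: cr.sequence for cr in collapsed}
    with pysam.AlignmentFile(path, "wh", header=header) as sam:
        for read_id in sorted(resolved):
            for a in resolved[read_id]:
                seg = pysam.AlignedSegment(sam.header)
                seg.query_name = a.collapsed_id
                seg.query_sequence = seqs[a.collapsed_id]
                seg.reference_id = tid[a.hairpin_id]
                seg.reference_start = a.ref_start
                read_len = len(seqs[a.collapsed_id])
                cigar = []
                if a.read_start:
                    cigar.append((4, a.read_start))  # soft clip
                cigar.append((0, a.aligned_length))
                if read_len - a.read_end:
                    cigar.append((4, read_len - a.read_end))
                seg.cigartuples = cigar
                seg.mapping_quality = 255
                seg.set_tag("XC", a.tc_conversions, "i")
                sam.write(seg)
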