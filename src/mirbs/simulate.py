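"""Synthetic bisulfite small-RNA data with known ground truth.

Emulates the study design end to end: a bank of pre-miRNA hairpins with
embedded mature arms, paired converted / non-converted (control) samples,
per-CpG methylation fractions, incomplete bisulfite conversion at non-CpG
cytosines, and optional substitution sequencing error. Reads are drawn from
windows inside mature arms (small-RNA reality); adapter sequences are never
added (the pipeline assumes trimmed input).

Emission model for a cytosine in a converted read:

* CpG site with methylation fraction m: read as C with probability
  m*(1-e_m) + (1-m)*(1-c) — methylated-and-retained, or unmethylated but
  escaping conversion — otherwise T;
* non-CpG C: read as C with probability (1-c);

where c is the bisulfite conversion efficiency and e_m the inappropriate
conversion rate of methylated cytosines (default 0: the estimators carry no
term for it). Non-converted samples copy the reference bases. Sequencing
errors are substitution-only and applied last. Identical seeds yield
byte-identical output.
"""

from __future__ import annotations

import gzip
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .refio import HairpinReference, MatureAnnotation

_BASES = np.array(list("ACGT"))
DEFAULT_QUALITY = 37  # constant Phred per base


@dataclass
class SimulationTruth:
    """Everything needed to generate a sample and predict every estimate."""

    hairpins: list[HairpinReference]
    depth: dict[str, int]
    cpg_methylation: dict[tuple[str, int], float]
    conversion_efficiency: float = 0.99
    inappropriate_conversion: float = 0.0
    seq_error_rate: float = 0.0
    read_length: tuple[int, int] = (16, 30)
    seed: int = 0

    def __post_init__(self) -> None:
        for name, p in (
            ("conversion_efficiency", self.conversion_efficiency),
            ("inappropriate_conversion", self.inappropriate_conversion),
            ("seq_error_rate", self.seq_error_rate),
        ):
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if any(d < 0 for d in self.depth.values()):
            raise ValueError("depth must be >= 0")
        if any(not 0 <= m <= 1 for m in self.cpg_methylation.values()):
            raise ValueError("methylation fractions must lie in [0, 1]")

    @classmethod
    def uniform(
        cls,
        hairpins: Sequence[HairpinReference],
        depth: int = 1000,
        methylation: float | dict[str, float] = 0.1,
        **kwargs,
    ) -> "SimulationTruth":
        """Same depth for every hairpin; one methylation fraction per hairpin
        (scalar, or per-hairpin dict) applied to all of its CpG sites."""
        cpg_m: dict[tuple[str, int], float] = {}
        for hp in hairpins:
            m = methylation if isinstance(methylation, float) else methylation.get(
                hp.hairpin_id, 0.0
            )
            for pos in hp.cpg_positions:
                cpg_m[(hp.hairpin_id, pos)] = m
        return cls(
            hairpins=list(hairpins),
            depth={hp.hairpin_id: depth for hp in hairpins},
            cpg_methylation=cpg_m,
            **kwargs,
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "depth": self.depth,
            "cpg_methylation": {
                f"{hp}:{pos}": m for (hp, pos), m in self.cpg_methylation.items()
            },
            "conversion_efficiency": self.conversion_efficiency,
            "inappropriate_conversion": self.inappropriate_conversion,
            "seq_error_rate": self.seq_error_rate,
            "read_length": list(self.read_length),
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


@dataclass(frozen=True)
class SimRead:
    read_id: str
    sequence: str
    hairpin_id: str
    mature_id: str
    ref_start: int
    cpg_states: tuple[tuple[int, int], ...]  # (hairpin pos, methylated 0/1)


def _random_mature(
    rng: np.random.Generator,
    length: int,
    n_cpg: int,
    n_noncpg_c: int,
) -> str:
    """Mature arm with exactly n_cpg CG dinucleotides and n_noncpg_c
    cytosines in non-CpG context; the backbone uses A/G/T only so every C is
    deliberate."""
    need = 2 * n_cpg + 2 * n_noncpg_c  # each feature occupies 2 positions
    if need > length:
        raise ValueError(
            f"cannot fit {n_cpg} CpG + {n_noncpg_c} non-CpG C in {length} nt"
        )
    seq = list(rng.choice(list("AGT"), size=length))
    # non-overlapping 2-nt slots for CG and C[AT]
    n_slots = length // 2
    slots = rng.choice(n_slots, size=n_cpg + n_noncpg_c, replace=False)
    for s in slots[:n_cpg]:
        seq[2 * s], seq[2 * s + 1] = "C", "G"
    for s in slots[n_cpg:]:
        seq[2 * s], seq[2 * s + 1] = "C", rng.choice(list("AT"))
    return "".join(seq)


def generate_reference(
    n_hairpins: int,
    hairpin_length: tuple[int, int] = (60, 110),
    mature_length: tuple[int, int] = (20, 24),
    cpgs_per_mature: tuple[int, int] = (0, 4),
    noncpg_c_per_mature: tuple[int, int] = (2, 4),
    matures_per_hairpin: int = 1,
    seed: int = 0,
) -> tuple[list[HairpinReference], list[tuple[str, str]]]:
    """Random hairpin bank with embedded mature arms.

    Flanking sequence is C-free (A/G/T), so all cytosine context sits inside
    mature arms where reads actually fall. Mature sequences are kept unique
    across the bank. Deterministic under ``seed``.
    """
    if n_hairpins < 1:
        raise ValueError("n_hairpins must be >= 1")
    if matures_per_hairpin not in (1, 2):
        raise ValueError("matures_per_hairpin must be 1 or 2")
    rng = np.random.default_rng(seed)
    hairpins: list[HairpinReference] = []
    matures: list[tuple[str, str]] = []
    seen_mature: set[str] = set()
    for i in range(n_hairpins):
        hp_id = f"sim-mir-{i + 1}"
        hp_len = int(rng.integers(hairpin_length[0], hairpin_length[1] + 1))
        arms = []
        for arm_idx in range(matures_per_hairpin):
            for _ in range(100):
                m_len = int(rng.integers(mature_length[0], mature_length[1] + 1))
                n_cpg = int(rng.integers(cpgs_per_mature[0], cpgs_per_mature[1] + 1))
                n_nc = int(
                    rng.integers(noncpg_c_per_mature[0], noncpg_c_per_mature[1] + 1)
                )
                seq = _random_mature(rng, m_len, n_cpg, n_nc)
                if seq not in seen_mature:
                    seen_mature.add(seq)
                    break
            else:  # pragma: no cover - 100 collisions is astronomically unlikely
                raise RuntimeError("could not draw a unique mature sequence")
            arm = "5p" if arm_idx == 0 else "3p"
            arms.append((f"sim-miR-{i + 1}-{arm}", seq))
        total_arms = sum(len(s) for _, s in arms)
        n_flanks = len(arms) + 1
        spare = max(hp_len - total_arms, n_flanks * 4)
        cuts = sorted(rng.integers(0, spare + 1, size=n_flanks - 1).tolist())
        flank_lens = (
            [cuts[0]] + [b - a for a, b in zip(cuts, cuts[1:])] + [spare - cuts[-1]]
        )
        pieces, annotations, cursor = [], [], 0
        for (mid, mseq), flank_len in zip(arms, flank_lens):
            flank = "".join(rng.choice(list("AGT"), size=flank_len))
            pieces.append(flank)
            cursor += flank_len
            pieces.append(mseq)
            annotations.append(MatureAnnotation(mid, cursor, cursor + len(mseq)))
            cursor += len(mseq)
        pieces.append("".join(rng.choice(list("AGT"), size=flank_lens[-1])))
        hairpins.append(
            HairpinReference.from_sequence(hp_id, "".join(pieces), annotations)
        )
        matures.extend(arms)
    return hairpins, matures


def write_reference(
    hairpins: Sequence[HairpinReference],
    matures: Sequence[tuple[str, str]],
    outdir: str | Path,
) -> dict[str, Path]:
    """Write hairpin FASTA, mature FASTA and the mature-coordinate TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "hairpin_fasta": outdir / "hairpins.fa",
        "mature_fasta": outdir / "matures.fa",
        "mature_coords": outdir / "mature_coords.tsv",
    }
    with open(paths["hairpin_fasta"], "w") as fh:
        for hp in hairpins:
            fh.write(f">{hp.hairpin_id}\n{hp.sequence}\n")
    with open(paths["mature_fasta"], "w") as fh:
        for mid, seq in matures:
            fh.write(f">{mid}\n{seq}\n")
    with open(paths["mature_coords"], "w") as fh:
        fh.write("hairpin_id\tmature_id\tstart\tend\n")
        for hp in hairpins:
            for m in hp.matures:
                fh.write(f"{hp.hairpin_id}\t{m.mature_id}\t{m.start}\t{m.end}\n")
    return paths


def simulate_sample(
    truth: SimulationTruth,
    converted: bool,
    seed: int | None = None,
) -> list[SimRead]:
    """Draw one sample's reads from the truth model.

    ``seed`` defaults to ``truth.seed``; pass distinct seeds for replicates
    and for the paired control so samples are independent draws.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    lmin, lmax = truth.read_length
    c = truth.conversion_efficiency
    e_m = truth.inappropriate_conversion
    reads: list[SimRead] = []
    serial = 0
    for hp in truth.hairpins:
        if not hp.matures:
            raise ValueError(f"hairpin {hp.hairpin_id} has no mature arms")
        cpg_set = set(hp.cpg_positions)
        for _ in range(truth.depth.get(hp.hairpin_id, 0)):
            mature = hp.matures[int(rng.integers(len(hp.matures)))]
            length = min(int(rng.integers(lmin, lmax + 1)), mature.length)
            start = mature.start + int(rng.integers(mature.length - length + 1))
            window = hp.sequence[start : start + length]
            bases = list(window)
            states = []
            if converted:
                for off, base in enumerate(window):
                    if base != "C":
                        continue
                    pos = start + off
                    if pos in cpg_set:
                        m = truth.cpg_methylation.get((hp.hairpin_id, pos), 0.0)
                        methylated = int(rng.random() < m)
                        states.append((pos, methylated))
                        if methylated:
                            bases[off] = "T" if rng.random() < e_m else "C"
                        else:
                            bases[off] = "T" if rng.random() < c else "C"
                    else:
                        bases[off] = "T" if rng.random() < c else "C"
            else:
                states = [
                    (start + off, -1)
                    for off, b in enumerate(window)
                    if b == "C" and (start + off) in cpg_set
                ]
            if truth.seq_error_rate > 0:
                for off in range(len(bases)):
                    if rng.random() < truth.seq_error_rate:
                        alternatives = [b for b in "ACGT" if b != bases[off]]
                        bases[off] = alternatives[int(rng.integers(3))]
            serial += 1
            reads.append(
                SimRead(
                    read_id=f"sim{serial}_{hp.hairpin_id}",
                    sequence="".join(bases),
                    hairpin_id=hp.hairpin_id,
                    mature_id=mature.mature_id,
                    ref_start=start,
                    cpg_states=tuple(states),
                )
            )
    return reads


def to_read_records(reads: Iterable[SimRead], quality: int = DEFAULT_QUALITY):
    """In-memory bridge to the QC stage: SimRead -> ReadRecord with the
    simulator's constant base quality."""
    from .readqc import ReadRecord

    return [
        ReadRecord(r.read_id, r.sequence, (quality,) * len(r.sequence))
        for r in reads
    ]


def write_fastq(reads: Iterable[SimRead], path: str | Path) -> None:
    """Constant-quality Phred+33 FASTQ; gzip when the path ends in .gz."""
    p = str(path)
    opener = gzip.open if p.endswith(".gz") else open
    qual_char = chr(DEFAULT_QUALITY + 33)
    with opener(p, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual_char * len(r.sequence)}\n")


def write_read_truth(reads: Iterable[SimRead], path: str | Path) -> None:
    rows = [
        {
            "read_id": r.read_id,
            "hairpin_id": r.hairpin_id,
            "mature_id": r.mature_id,
            "ref_start": r.ref_start,
            "length": len(r.sequence),
            "cpg_states": ";".join(f"{pos}:{s}" for pos, s in r.cpg_states) or ".",
        }
        for r in reads
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_site_truth(truth: SimulationTruth, path: str | Path) -> None:
    rows = [
        {"hairpin_id": hp_id, "position": pos, "methylation_fraction": m}
        for (hp_id, pos), m in sorted(truth.cpg_methylation.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _quantifiable_windows(
    truth: SimulationTruth,
    mature: MatureAnnotation,
    qc_min_length: int,
    min_mature_fraction: float,
) -> list[tuple[int, int, float]]:
    """(start, length, probability) of read windows that survive QC and the
    mature-coverage rule, normalized over surviving windows."""
    lmin, lmax = truth.read_length
    entries: list[tuple[int, int, float]] = []
    total = 0.0
    p_len = 1.0 / (lmax - lmin + 1)
    for drawn in range(lmin, lmax + 1):
        length = min(drawn, mature.length)
        n_starts = mature.length - length + 1
        if length < qc_min_length or length < min_mature_fraction * mature.length:
            continue
        for start in range(mature.start, mature.start + n_starts):
            w = p_len / n_starts
            entries.append((start, length, w))
            total += w
    return [(s, l, w / total) for s, l, w in entries] if total else []


def expected_methylation(
    truth: SimulationTruth,
    hairpin: HairpinReference,
    mature: MatureAnnotation,
    qc_min_length: int = 17,
    min_mature_fraction: float = 0.80,
) -> float:
    """Closed-form methylation percentage the pipeline should recover.

    Probability that a random read surviving QC and the mature-coverage rule
    displays >= 1 unconverted CpG, marginalized over read windows. Each CpG
    reads as C independently with probability m*(1-e_m) + (1-m)*(1-c).
    Exact only without sequencing error (the default).
    """
    if truth.seq_error_rate > 0:
        raise ValueError("closed form assumes seq_error_rate = 0")
    c, e_m = truth.conversion_efficiency, truth.inappropriate_conversion
    cpg_in_mature = [
        p for p in hairpin.cpg_positions if mature.start <= p < mature.end
    ]
    pct = 0.0
    for start, length, weight in _quantifiable_windows(
        truth, mature, qc_min_length, min_mature_fraction
    ):
        p_all_t = 1.0
        for pos in cpg_in_mature:
            if start <= pos < start + length:
                m = truth.cpg_methylation.get((hairpin.hairpin_id, pos), 0.0)
                p_all_t *= 1.0 - (m * (1.0 - e_m) + (1.0 - m) * (1.0 - c))
        pct += weight * (1.0 - p_all_t)
    return 100.0 * pct
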