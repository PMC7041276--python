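"""Per-miRNA 5mC quantification, conversion-rate QC and discard filters.

For each mature miRNA expressed in the converted sample, the methylation
percentage is the ratio of reads displaying at least one unconverted CpG
cytosine to the total reads mapped to the pre-miRNA, on a 0-100 scale.
Bisulfite efficiency is estimated per hairpin from non-CpG cytosines
(CpA/CpT/CpC), which are assumed unmethylated: any C call there is a failed
conversion. Hairpins are discarded when (i) not expressed in the
non-converted control sample, (ii) covered by fewer than 25 reads, or
(iii) the estimated conversion rate falls below 95 %.

Two conversion-rate aggregations exist. The default, call-level, divides
unconverted base calls by all base calls at non-CpG C positions and is
depth-unbiased. The site-level mode flags any non-CpG C site with at least
one unconverted call among covered sites; it is depth-biased (the deeper a
site, the likelier a single stray C poisons it) and is provided for
fidelity audits. All counting is multiplicity-weighted by collapsed-read
counts, so read collapsing never changes an estimate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .bsalign import UNCONVERTED_C, BsAlignment
from .refio import HairpinReference


@dataclass(frozen=True)
class FilterConfig:
    min_reads: int = 25
    min_conversion_pct: float = 95.0
    require_control_expression: bool = True
    min_expression: int = 25  # control-sample expression floor

    def __post_init__(self) -> None:
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")
        if not 0 <= self.min_conversion_pct <= 100:
            raise ValueError("min_conversion_pct must lie in [0, 100]")


@dataclass(frozen=True)
class MiRMethylationReport:
    """One quantification row: a mature miRNA on its hairpin.

    ``methylated_reads`` counts reads whose alignment matched this mature
    and carried >= 1 unconverted CpG; ``methylated_reads_hairpin`` relaxes
    the numerator to any quantified read on the hairpin (the text is
    ambiguous about mature-arm restriction, so both are reported).
    ``methylation_pct`` may be None when the denominator is zero.
    """

    mature_id: str
    hairpin_id: str
    mapped_reads: int
    methylated_reads: int
    methylated_reads_hairpin: int
    methylation_pct: float | None
    methylation_pct_hairpin: float | None
    conversion_rate_pct: float | None
    control_reads: int = 0
    verdict: str = "kept"
    reason: str = ""


def read_has_unconverted_cpg(
    alignment: BsAlignment, cpg_positions: frozenset[int] | set[int]
) -> bool:
    return any(
        state == UNCONVERTED_C and pos in cpg_positions
        for pos, state in alignment.cytosine_calls
    )


def conversion_rate(
    alignments: Iterable[BsAlignment],
    hairpin: HairpinReference,
    mode: str = "call",
) -> float | None:
    """Percent of non-CpG cytosine calls (or sites) successfully converted.

    The underlying ratio counts UNconverted non-CpG cytosines; the rate
    reported here is its complement on a 0-100 scale, the scale on which
    the >= 95 % filter operates. Returns None when no non-CpG C is covered.
    """
    noncpg = set(hairpin.noncpg_c_positions)
    if mode == "call":
        total = unconv = 0
        for a in alignments:
            for pos, state in a.cytosine_calls:
                if pos in noncpg:
                    total += a.count
                    if state == UNCONVERTED_C:
                        unconv += a.count
        if total == 0:
            return None
        return 100.0 * (1.0 - unconv / total)
    if mode == "site":
        covered: set[int] = set()
        poisoned: set[int] = set()
        for a in alignments:
            for pos, state in a.cytosine_calls:
                if pos in noncpg:
                    covered.add(pos)
                    if state == UNCONVERTED_C:
                        poisoned.add(pos)
        if not covered:
            return None
        return 100.0 * (1.0 - len(poisoned) / len(covered))
    raise ValueError(f"unknown conversion-rate mode {mode!r}")


def quantify_hairpin(
    resolved: Mapping[str, Sequence[BsAlignment]],
    hairpin: HairpinReference,
    conversion_mode: str = "call",
    denominator: str = "all_mapped",
) -> list[MiRMethylationReport]:
    """Methylation reports for every mature annotated on one hairpin.

    The denominator ("total reads mapped to the pre-miRNA") is the
    multiplicity-weighted count of reads with >= 1 alignment on this hairpin
    satisfying the mature-coverage rule; ``denominator="cpg_covering"``
    restricts it to reads whose span covers >= 1 CpG site. Alignments that
    matched no mature are excluded from quantification but still feed the
    conversion-rate estimate.
    """
    if denominator not in ("all_mapped", "cpg_covering"):
        raise ValueError(f"unknown denominator mode {denominator!r}")
    cpg = frozenset(hairpin.cpg_positions)
    hp_id = hairpin.hairpin_id

    all_alns: list[BsAlignment] = []
    # per read: quantified alignments on this hairpin
    quant: dict[str, list[BsAlignment]] = {}
    for read_id, alns in resolved.items():
        here = [a for a in alns if a.hairpin_id == hp_id]
        all_alns.extend(here)
        matched = [a for a in here if a.matched_matures]
        if matched:
            quant[read_id] = matched

    def covers_cpg(alns: Sequence[BsAlignment]) -> bool:
        return any(pos in cpg for a in alns for pos, _ in a.cytosine_calls)

    if denominator == "cpg_covering":
        quant = {rid: alns for rid, alns in quant.items() if covers_cpg(alns)}

    mapped = sum(alns[0].count for alns in quant.values())
    meth_hairpin = sum(
        alns[0].count
        for alns in quant.values()
        if any(read_has_unconverted_cpg(a, cpg) for a in alns)
    )
    conv = conversion_rate(all_alns, hairpin, conversion_mode)

    reports = []
    for m in hairpin.matures:
        meth_mature = sum(
            alns[0].count
            for alns in quant.values()
            if any(
                m.mature_id in a.matched_matures and read_has_unconverted_cpg(a, cpg)
                for a in alns
            )
        )
        reports.append(
            MiRMethylationReport(
                mature_id=m.mature_id,
                hairpin_id=hp_id,
                mapped_reads=mapped,
                methylated_reads=meth_mature,
                methylated_reads_hairpin=meth_hairpin,
                methylation_pct=100.0 * meth_mature / mapped if mapped else None,
                methylation_pct_hairpin=100.0 * meth_hairpin / mapped if mapped else None,
                conversion_rate_pct=conv,
            )
        )
    return reports


def quantify(
    resolved: Mapping[str, Sequence[BsAlignment]],
    hairpins: Sequence[HairpinReference],
    conversion_mode: str = "call",
    denominator: str = "all_mapped",
) -> list[MiRMethylationReport]:
    out: list[MiRMethylationReport] = []
    for hp in hairpins:
        out.extend(quantify_hairpin(resolved, hp, conversion_mode, denominator))
    return out


def control_read_counts(
    resolved: Mapping[str, Sequence[BsAlignment]],
) -> dict[str, int]:
    """Multiplicity-weighted mapped-read count per hairpin (control run)."""
    counts: dict[str, int] = {}
    for alns in resolved.values():
        for hp_id in {a.hairpin_id for a in alns}:
            counts[hp_id] = counts.get(hp_id, 0) + alns[0].count
    return counts


def apply_filters(
    reports: Sequence[MiRMethylationReport],
    control_counts: Mapping[str, int] | None,
    cfg: FilterConfig | None = None,
) -> list[MiRMethylationReport]:
    """Attach a kept/discarded verdict to every report row.

    Discard reasons, first match recorded: ``no_control_expression`` when
    the hairpin's control-sample read count is below ``min_expression``;
    ``low_coverage`` when mapped reads < ``min_reads``; ``low_conversion``
    when the conversion rate is below ``min_conversion_pct`` or could not
    be evaluated (no covered non-CpG C — discarded conservatively).
    """
    cfg = cfg or FilterConfig()
    if cfg.require_control_expression and control_counts is None:
        raise ValueError(
            "control-sample counts are required (require_control_expression=True)"
        )
    control_counts = control_counts or {}
    out = []
    for rep in reports:
        ctrl = control_counts.get(rep.hairpin_id, 0)
        verdict, reason = "kept", ""
        if cfg.require_control_expression and ctrl < cfg.min_expression:
            verdict, reason = "discarded", "no_control_expression"
        elif rep.mapped_reads < cfg.min_reads:
            verdict, reason = "discarded", "low_coverage"
        elif rep.conversion_rate_pct is None or (
            rep.conversion_rate_pct < cfg.min_conversion_pct
        ):
            verdict, reason = "discarded", "low_conversion"
        out.append(replace(rep, control_reads=ctrl, verdict=verdict, reason=reason))
    return out


def replicate_concordance(
    report_sets: Sequence[Sequence[MiRMethylationReport]],
    min_shared: int = 3,
) -> pd.DataFrame:
    """Pairwise Pearson correlation of methylation % across replicates.

    Computed over the intersection of kept matures per replicate pair.
    ``r`` is NaN (flagged in ``note``) when the intersection is smaller
    than ``min_shared`` or a replicate has zero variance.
    """
    if len(report_sets) < 2:
        raise ValueError("need >= 2 replicate report sets")
    kept = [
        {
            r.mature_id: r.methylation_pct
            for r in reps
            if r.verdict == "kept" and r.methylation_pct is not None
        }
        for reps in report_sets
    ]
    rows = []
    for i, j in combinations(range(len(kept)), 2):
        shared = sorted(kept[i].keys() & kept[j].keys())
        note, r = "", float("nan")
        if len(shared) < min_shared:
            note = "too_few_shared"
        else:
            xs = [kept[i][m] for m in shared]
            ys = [kept[j][m] for m in shared]
            if len(set(xs)) == 1 or len(set(ys)) == 1:
                note = "zero_variance"
            else:
                r = float(stats.pearsonr(xs, ys).statistic)
        rows.append(
            {"rep_a": i, "rep_b": j, "n_shared": len(shared), "pearson_r": r,
             "note": note}
        )
    return pd.DataFrame(rows)


def reports_to_frame(reports: Sequence[MiRMethylationReport]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in reports])


def write_report_tsv(reports: Sequence[MiRMethylationReport], path: str | Path) -> None:
    reports_to_frame(reports).to_csv(path, sep="\t", index=False, na_rep="NA")


def write_run_summary(
    reports: Sequence[MiRMethylationReport],
    path: str | Path,
    concordance: pd.DataFrame | None = None,
) -> dict:
    """JSON run summary: filter funnel totals and optional concordance."""
    by_reason: dict[str, int] = {}
    for rep in reports:
        if rep.verdict == "discarded":
            by_reason[rep.reason] = by_reason.get(rep.reason, 0) + 1
    summary = {
        "n_reports": len(reports),
        "n_kept": sum(r.verdict == "kept" for r in reports),
        "n_discarded_by_reason": by_reason,
    }
    if concordance is not None:
        summary["replicate_concordance"] = concordance.to_dict(orient="records")
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary
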