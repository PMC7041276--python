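"""End-to-end orchestration: control + converted samples, replicates, reports.

A run executes reference loading -> read QC -> collapsing -> alignment
(exact matching on the non-converted control, asymmetric T/C matching on
the converted samples) -> methylation quantification -> discard filters,
and writes per-replicate report TSVs, a merged consensus table, a JSON
summary and a plain-text log carrying every filter count so the read
funnel is auditable. Execution is single-threaded and deterministic: the
same configuration always produces byte-identical reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import bsalign, methcall, readqc, refio

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    hairpin_fasta: str
    converted_fastqs: list[str]
    control_fastqs: list[str]
    outdir: str
    mature_fasta: str | None = None
    mature_coords: str | None = None
    ct_table: str | None = None
    qc: readqc.QcConfig = dataclass_field(default_factory=readqc.QcConfig)
    align: bsalign.AlignParams = dataclass_field(default_factory=bsalign.AlignParams)
    filters: methcall.FilterConfig = dataclass_field(
        default_factory=methcall.FilterConfig
    )
    conversion_mode: str = "call"
    denominator_mode: str = "all_mapped"

    def validate(self) -> None:
        if not self.converted_fastqs or not self.control_fastqs:
            raise ValueError("converted and control FASTQ lists must be non-empty")
        if self.mature_fasta is None and self.mature_coords is None:
            raise ValueError("provide mature_fasta and/or mature_coords")
        for path in [
            self.hairpin_fasta,
            *(p for p in (self.mature_fasta, self.mature_coords, self.ct_table) if p),
            *self.converted_fastqs,
            *self.control_fastqs,
        ]:
            if not Path(path).exists():
                raise FileNotFoundError(path)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for section, klass in (
            ("qc", readqc.QcConfig),
            ("align", bsalign.AlignParams),
            ("filters", methcall.FilterConfig),
        ):
            if section in raw:
                raw[section] = klass(**raw[section])
        return cls(**raw)


def load_reference(config: RunConfig) -> list[refio.HairpinReference]:
    hairpins = refio.load_hairpin_fasta(config.hairpin_fasta)
    if config.mature_coords:
        coords = refio.load_mature_coords(config.mature_coords)
        refio.apply_mature_coords(hairpins, coords)
    elif config.mature_fasta:
        matures = refio.load_mature_fasta(config.mature_fasta)
        refio.annotate_matures(hairpins, matures)
    return hairpins


def process_sample(
    fastq: str | Path,
    hairpins: Sequence[refio.HairpinReference],
    converted: bool,
    qc: readqc.QcConfig,
    align_params: bsalign.AlignParams,
) -> dict:
    """QC -> collapse -> align one FASTQ; returns every stage's artifacts."""
    reads = list(readqc.parse_fastq(fastq))
    kept, rejects = readqc.filter_reads(reads, qc)
    collapsed = readqc.collapse_unique(kept)
    policy = bsalign.MatchPolicy(converted_mode=converted)
    resolved = bsalign.align_collapsed(collapsed, hairpins, policy, align_params)
    if not converted:
        bad = [
            a.collapsed_id
            for alns in resolved.values()
            for a in alns
            if a.tc_conversions != 0
        ]
        if bad:  # exact matching cannot produce a T over C call
            raise AssertionError(
                f"non-converted run produced T-C conversion calls: {bad[:5]}"
            )
    return {
        "n_input": len(reads),
        "n_passed": len(kept),
        "rejects": rejects,
        "collapsed": collapsed,
        "resolved": resolved,
    }


def merge_replicates(
    report_sets: Sequence[Sequence[methcall.MiRMethylationReport]],
) -> dict:
    """Presence matrix over kept matures, their intersection, and pairwise
    concordance across replicate report sets."""
    if len(report_sets) < 2:
        raise ValueError("need >= 2 replicate report sets to merge")
    kept_sets = [
        {r.mature_id for r in reps if r.verdict == "kept"} for reps in report_sets
    ]
    all_matures = sorted(set().union(*kept_sets))
    presence = pd.DataFrame(
        {
            f"rep{i + 1}": [m in kept for m in all_matures]
            for i, kept in enumerate(kept_sets)
        },
        index=pd.Index(all_matures, name="mature_id"),
    )
    intersection = sorted(set.intersection(*kept_sets)) if kept_sets else []
    concordance = methcall.replicate_concordance(report_sets)
    return {
        "presence": presence,
        "intersection": intersection,
        "concordance": concordance,
    }


def run(config: RunConfig) -> dict:
    """Execute the full analysis; returns the in-memory results and writes
    all reports under ``config.outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    hairpins = load_reference(config)
    refio.write_reference_audit(hairpins, outdir / "reference_audit.tsv")
    log_lines.append(f"reference: {len(hairpins)} hairpins, "
                     f"{sum(len(h.matures) for h in hairpins)} mature annotations")

    # --- control (non-converted) samples: expression evidence -------------
    control_counts_per_rep: list[dict[str, int]] = []
    for i, fastq in enumerate(config.control_fastqs, start=1):
        res = process_sample(fastq, hairpins, False, config.qc, config.align)
        counts = methcall.control_read_counts(res["resolved"])
        control_counts_per_rep.append(counts)
        _log_funnel(log_lines, f"control_{i}", res)
    paired = len(config.control_fastqs) == len(config.converted_fastqs)
    if not paired:
        pooled: dict[str, int] = {}
        for counts in control_counts_per_rep:
            for hp_id, n in counts.items():
                pooled[hp_id] = pooled.get(hp_id, 0) + n
        log_lines.append(
            "control/converted replicate counts differ; using pooled control counts"
        )

    # --- converted samples -------------------------------------------------
    report_sets: list[list[methcall.MiRMethylationReport]] = []
    for i, fastq in enumerate(config.converted_fastqs, start=1):
        res = process_sample(fastq, hairpins, True, config.qc, config.align)
        _log_funnel(log_lines, f"converted_{i}", res)
        bsalign.write_alignment_tsv(
            res["resolved"], str(outdir / f"alignments_rep{i}.tsv")
        )
        reports = methcall.quantify(
            res["resolved"], hairpins, config.conversion_mode, config.denominator_mode
        )
        ctrl = control_counts_per_rep[i - 1] if paired else pooled
        reports = methcall.apply_filters(reports, ctrl, config.filters)
        methcall.write_report_tsv(reports, outdir / f"methylation_rep{i}.tsv")
        n_kept = sum(r.verdict == "kept" for r in reports)
        log_lines.append(
            f"converted_{i}: {len(reports)} mature rows, {n_kept} kept after filters"
        )
        report_sets.append(reports)

    merged = None
    concordance = None
    if len(report_sets) >= 2:
        merged = merge_replicates(report_sets)
        concordance = merged["concordance"]
        merged["presence"].to_csv(outdir / "presence_matrix.tsv", sep="\t")
        concordance.to_csv(outdir / "concordance.tsv", sep="\t", index=False)
        log_lines.append(
            f"merged: {len(merged['intersection'])} matures kept in all replicates"
        )

    all_reports = [r for reps in report_sets for r in reps]
    summary = methcall.write_run_summary(
        all_reports, outdir / "summary.json", concordance
    )
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return {
        "hairpins": hairpins,
        "report_sets": report_sets,
        "merged": merged,
        "summary": summary,
    }


def _log_funnel(log_lines: list[str], label: str, res: dict) -> None:
    rejects = ", ".join(f"{k}={v}" for k, v in sorted(res["rejects"].items())) or "none"
    n_aligned = len(res["resolved"])
    log_lines.append(
        f"{label}: input={res['n_input']} passed={res['n_passed']} "
        f"rejected[{rejects}] unique={len(res['collapsed'])} aligned={n_aligned}"
    )
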