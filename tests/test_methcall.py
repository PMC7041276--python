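"""Methylation quantification, conversion-rate estimation and filters."""

import math

import pytest

from mirbs import simulate
from mirbs.bsalign import CONVERTED_T, UNCONVERTED_C, BsAlignment, MatchPolicy, align_collapsed
from mirbs.methcall import (
    FilterConfig,
    MiRMethylationReport,
    apply_filters,
    conversion_rate,
    quantify,
    quantify_hairpin,
    replicate_concordance,
)
from mirbs.readqc import QcConfig, collapse_unique, filter_reads
from mirbs.refio import HairpinReference, MatureAnnotation

# hairpin: mature arm [2, 22); CpG at 5; non-CpG Cs at 12 (CA) and 17 (CT)
HP_SEQ = "AA" + "GTACGTAGGACATTGCTTAG" + "GAA"
MATURE = MatureAnnotation("miR-x", 2, 22)


@pytest.fixture
def hairpin():
    return HairpinReference.from_sequence("hp-x", HP_SEQ, [MATURE])


def _aln(read_id, count, calls, hp="hp-x", ref_start=2, ref_end=22,
         matures=("miR-x",)):
    return BsAlignment(
        collapsed_id=read_id, count=count, hairpin_id=hp,
        ref_start=ref_start, ref_end=ref_end, read_start=0,
        read_end=ref_end - ref_start,
        tc_conversions=sum(s == CONVERTED_T for _, s in calls),
        matched_matures=matures, cytosine_calls=tuple(calls),
    )


def _full_span_calls(cpg_state):
    """Calls over the whole mature span: CpG at 5 with the given state,
    non-CpG Cs at 12 and 17 converted."""
    return [(5, cpg_state), (12, CONVERTED_T), (17, CONVERTED_T)]


class TestMethylationPercentage:
    def test_three_of_twelve_reads_methylated(self, hairpin):
        resolved = {}
        for i in range(12):
            state = UNCONVERTED_C if i < 3 else CONVERTED_T
            resolved[f"u{i}_x1"] = [_aln(f"u{i}_x1", 1, _full_span_calls(state))]
        (rep,) = quantify_hairpin(resolved, hairpin)
        assert rep.mapped_reads == 12
        assert rep.methylated_reads == 3
        assert rep.methylation_pct == pytest.approx(25.0)

    def test_all_converted_is_zero(self, hairpin):
        resolved = {
            "u1_x7": [_aln("u1_x7", 7, _full_span_calls(CONVERTED_T))]
        }
        (rep,) = quantify_hairpin(resolved, hairpin)
        assert rep.methylation_pct == 0.0

    def test_zero_denominator_flagged_not_error(self, hairpin):
        (rep,) = quantify_hairpin({}, hairpin)
        assert rep.mapped_reads == 0
        assert rep.methylation_pct is None

    def test_multiplicity_weighting_matches_expansion(self, hairpin):
        """Collapsed counts give the same answer as duplicated unit reads."""
        collapsed = {
            "u1_x5": [_aln("u1_x5", 5, _full_span_calls(UNCONVERTED_C))],
            "u2_x15": [_aln("u2_x15", 15, _full_span_calls(CONVERTED_T))],
        }
        expanded = {}
        for i in range(5):
            expanded[f"a{i}"] = [_aln(f"a{i}", 1, _full_span_calls(UNCONVERTED_C))]
        for i in range(15):
            expanded[f"b{i}"] = [_aln(f"b{i}", 1, _full_span_calls(CONVERTED_T))]
        (r1,) = quantify_hairpin(collapsed, hairpin)
        (r2,) = quantify_hairpin(expanded, hairpin)
        assert (r1.mapped_reads, r1.methylated_reads, r1.methylation_pct) == (
            r2.mapped_reads, r2.methylated_reads, r2.methylation_pct
        )

    def test_cpg_covering_denominator_mode(self, hairpin):
        resolved = {
            # covers the CpG, methylated
            "u1_x1": [_aln("u1_x1", 1, _full_span_calls(UNCONVERTED_C))],
            # covers only the non-CpG tail [8, 22)
            "u2_x1": [_aln("u2_x1", 1,
                           [(12, CONVERTED_T), (17, CONVERTED_T)],
                           ref_start=8)],
        }
        (rep_all,) = quantify_hairpin(resolved, hairpin, denominator="all_mapped")
        (rep_cpg,) = quantify_hairpin(resolved, hairpin, denominator="cpg_covering")
        assert rep_all.mapped_reads == 2
        assert rep_all.methylation_pct == pytest.approx(50.0)
        assert rep_cpg.mapped_reads == 1
        assert rep_cpg.methylation_pct == pytest.approx(100.0)


class TestConversionRate:
    def test_complete_conversion_is_100(self, hairpin):
        alns = [_aln("u1_x4", 4, _full_span_calls(CONVERTED_T))]
        assert conversion_rate(alns, hairpin, "call") == pytest.approx(100.0)
        assert conversion_rate(alns, hairpin, "site") == pytest.approx(100.0)

    def test_site_level_boundary_95(self):
        # 20 non-CpG C sites, exactly one carries an unconverted call
        seq = "CA" * 20 + "AA"
        hp = HairpinReference.from_sequence("h20", seq,
                                            [MatureAnnotation("m", 0, 42)])
        assert len(hp.noncpg_c_positions) == 20
        calls = [(2 * i, CONVERTED_T) for i in range(20)]
        calls[0] = (0, UNCONVERTED_C)
        alns = [_aln("u1_x1", 1, calls, hp="h20", ref_start=0, ref_end=42,
                     matures=("m",))]
        rate = conversion_rate(alns, hp, "site")
        assert rate == pytest.approx(95.0)
        assert rate >= FilterConfig().min_conversion_pct

    def test_call_level_weighting(self, hairpin):
        # 1 unconverted call (count 1) among 4 calls total at non-CpG Cs
        alns = [
            _aln("u1_x1", 1, [(12, UNCONVERTED_C), (17, CONVERTED_T)]),
            _aln("u2_x1", 1, [(12, CONVERTED_T), (17, CONVERTED_T)]),
        ]
        assert conversion_rate(alns, hairpin, "call") == pytest.approx(75.0)
        # site-level: site 12 is poisoned -> 50 %
        assert conversion_rate(alns, hairpin, "site") == pytest.approx(50.0)

    def test_no_covered_noncpg_c_is_none(self, hairpin):
        alns = [_aln("u1_x1", 1, [(5, CONVERTED_T)], ref_start=2, ref_end=8)]
        assert conversion_rate(alns, hairpin, "call") is None

    def test_site_level_depth_bias(self):
        """At unconversion rate 0.02 per call, deep coverage drives the
        site-level estimate down (P(site poisoned) = 1 - 0.98^depth) while
        the call-level estimate stays near 98."""
        depth = 200
        p_poisoned = 1 - 0.98 ** depth
        assert p_poisoned > 0.97  # site-level estimate collapses with depth


class TestFilters:
    def _report(self, hairpin_id, mapped, conv):
        return MiRMethylationReport(
            mature_id=f"m-{hairpin_id}", hairpin_id=hairpin_id,
            mapped_reads=mapped, methylated_reads=0,
            methylated_reads_hairpin=0, methylation_pct=0.0,
            methylation_pct_hairpin=0.0, conversion_rate_pct=conv,
        )

    def test_reasons(self):
        reports = [
            self._report("h24", 24, 99.0),
            self._report("h-conv", 100, 94.9),
            self._report("h-noctrl", 100, 99.0),
            self._report("h-ok", 25, 95.0),
            self._report("h-na", 100, None),
        ]
        ctrl = {"h24": 50, "h-conv": 50, "h-noctrl": 0, "h-ok": 50, "h-na": 50}
        out = apply_filters(reports, ctrl, FilterConfig())
        verdicts = {r.hairpin_id: (r.verdict, r.reason) for r in out}
        assert verdicts["h24"] == ("discarded", "low_coverage")
        assert verdicts["h-conv"] == ("discarded", "low_conversion")
        assert verdicts["h-noctrl"] == ("discarded", "no_control_expression")
        assert verdicts["h-ok"] == ("kept", "")  # both thresholds inclusive
        assert verdicts["h-na"] == ("discarded", "low_conversion")

    def test_missing_control_run_is_error(self):
        with pytest.raises(ValueError, match="control"):
            apply_filters([self._report("h", 100, 99.0)], None, FilterConfig())

    def test_control_not_required(self):
        (out,) = apply_filters(
            [self._report("h", 100, 99.0)], None,
            FilterConfig(require_control_expression=False),
        )
        assert out.verdict == "kept"


class TestReplicateConcordance:
    def _reports(self, values):
        return [
            MiRMethylationReport(
                mature_id=m, hairpin_id=m, mapped_reads=100,
                methylated_reads=0, methylated_reads_hairpin=0,
                methylation_pct=v, methylation_pct_hairpin=v,
                conversion_rate_pct=99.0,
            )
            for m, v in values.items()
        ]

    def test_identical_replicates_r_one(self):
        vals = {"a": 5.0, "b": 10.0, "c": 20.0}
        df = replicate_concordance([self._reports(vals), self._reports(vals)])
        assert df.loc[0, "pearson_r"] == pytest.approx(1.0)
        assert df.loc[0, "n_shared"] == 3

    def test_zero_variance_flagged(self):
        flat = {"a": 5.0, "b": 5.0, "c": 5.0}
        vary = {"a": 1.0, "b": 2.0, "c": 3.0}
        df = replicate_concordance([self._reports(flat), self._reports(vary)])
        assert math.isnan(df.loc[0, "pearson_r"])
        assert df.loc[0, "note"] == "zero_variance"

    def test_small_intersection_flagged(self):
        df = replicate_concordance(
            [self._reports({"a": 1.0, "b": 2.0}), self._reports({"a": 1.0})]
        )
        assert df.loc[0, "note"] == "too_few_shared"

    def test_simulated_triplicates_concordant(self, small_bank):
        """Replicates drawn from shared truth with spread 0-25 % correlate."""
        hairpins, _ = small_bank
        spread = {hp.hairpin_id: 0.05 * i for i, hp in enumerate(hairpins)}
        truth = simulate.SimulationTruth.uniform(
            hairpins, depth=1000, methylation=spread, seed=77
        )
        report_sets = []
        for rep_seed in (1, 2, 3):
            reads = simulate.to_read_records(
                simulate.simulate_sample(truth, converted=True, seed=rep_seed)
            )
            kept, _ = filter_reads(reads, QcConfig())
            resolved = align_collapsed(
                collapse_unique(kept), hairpins, MatchPolicy(True)
            )
            reports = quantify(resolved, hairpins)
            ctrl = {hp.hairpin_id: 1000 for hp in hairpins}
            report_sets.append(apply_filters(reports, ctrl))
        df = replicate_concordance(report_sets)
        assert (df["pearson_r"] >= 0.9).all()


def test_zero_methylation_perfect_chemistry_is_exactly_zero(small_bank):
    hairpins, _ = small_bank
    truth = simulate.SimulationTruth.uniform(
        hairpins, depth=300, methylation=0.0, conversion_efficiency=1.0, seed=9
    )
    reads = simulate.to_read_records(simulate.simulate_sample(truth, True, seed=10))
    kept, _ = filter_reads(reads, QcConfig())
    resolved = align_collapsed(collapse_unique(kept), hairpins, MatchPolicy(True))
    for rep in quantify(resolved, hairpins):
        assert rep.methylation_pct == 0.0
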