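# Methods

## Problem and model

Small-RNA libraries are prepared from bisulfite-converted and non-converted
(control) RNA and sequenced single-end. Bisulfite chemistry deaminates
unmethylated cytosine to uracil (read as T) and leaves 5-methylcytosine
intact, so a converted read carries T wherever the template had an
unmethylated C. Mapping such reads against an unconverted pre-miRNA hairpin
reference therefore requires exactly one tolerated substitution — read T
over reference C — and that substitution is *asymmetric*: read C over
reference T would imply a sequencing or mapping error, never chemistry, and
is rejected. Methylation is quantified at CpG dinucleotides; cytosines in
CpA/CpT/CpC context are assumed unmethylated, so any C call at them
measures a bisulfite failure and drives the conversion-rate estimate.

Coordinates are 0-based half-open everywhere. RNA input is normalized to
the DNA alphabet (U→T, uppercase) at load time since sequencer output is
DNA-alphabet. A cytosine at the last position of a hairpin has no
dinucleotide context and belongs to neither the CpG nor the non-CpG set.

## Read QC

Defaults follow the small-RNA bisulfite protocol: keep reads with length
≥ 17 nt (the "> 16 bp" rule read literally), mean Phred ≥ 30, no
single-nucleotide run ≥ 13 (N runs included), and no N at the first or
last position. The quality criterion is read-level (mean Phred) because the
protocol filters reads, not bases, and performs no quality trimming; a
per-base minimum mode is available by configuration for users who prefer
it. Internal Ns survive QC but can never match any reference base at
alignment. Adapter trimming is out of scope: established trimmers do it
well, and the simulator emits trimmed reads.

Unique sequences are collapsed to `u{rank}_x{count}` records ordered by
descending count then lexicographic sequence, making collapsed output
order-independent and deterministic. All downstream counting is
multiplicity-weighted, and tests hold that collapsing never changes any
estimate.

## Alignment

Ungapped only: the mismatch budget beyond the authorized T–C substitution
is zero, so an interior gap could never be bridged, and miRNA-length reads
give indels no room. Clipping is allowed at read ends only. For each
(hairpin, diagonal) the retained placement is the maximal run of matching
positions — leftmost on the rare tie, a deterministic tie-break applied
identically in both aligners. A placement is accepted when its length
reaches ≥ 90 % of the read (`min_read_fraction`, configurable).

Two aligners share this contract. The brute-force aligner enumerates every
diagonal of every hairpin (vectorized over diagonals) and is the
independent correctness oracle. The production aligner is seed-and-extend:
reference k-mers (default k = 12) are indexed under all C→T substitution
variants — the expansion is 2^(#C per k-mer), affordable on a hairpin
bank — so the literal k-mer of an arbitrarily converted read hits the
index, and each candidate diagonal is extended in both directions under
the match rule. Any accepted run has length ≥ max(k, 90 % of the read) and
therefore contains a full seed, which makes the heuristic exhaustive; when
the minimum acceptable run is shorter than k (reads shorter than k/0.9)
the read is delegated to brute force. Equivalence of the two aligners on
simulated batches is a tested property, so correctness does not depend on
the seed length.

Reverse-complement mapping is deliberately absent: small-RNA reads are
sense-strand copies of the miRNA, and the asymmetric rule is only
meaningful on the sense strand.

A read quantifies a mature miRNA when its alignment covers ≥ 80 % of that
mature arm (`min_mature_fraction`, real-valued comparison, no rounding).
Whether this criterion gates mapping or only quantification is ambiguous
in the protocol; here it gates quantification — alignments matching no
mature still feed the conversion-rate audit. Multimapping reads are
assigned to the hairpin with the longest alignment; on ties every target
is conserved and receives the read's full count (no fractional splitting —
the resulting double counting across tied hairpins is a documented
property of the report, not hidden by renormalization).

## Methylation and conversion estimators

Per mature miRNA:

* numerator — multiplicity-weighted count of reads whose mature-matched
  alignment shows ≥ 1 unconverted CpG cytosine; a hairpin-level numerator
  (any quantified read on the hairpin) is emitted alongside because the
  protocol mixes mature- and pre-miRNA-level language;
* denominator — all reads quantified on the pre-miRNA, including reads
  covering no CpG (literal reading of "total reads mapped"); a
  configuration switch restricts the denominator to CpG-covering reads.

A zero denominator yields a flagged undefined percentage, never a division
error.

The conversion rate is reported on the converted scale, 100 × (1 −
unconverted fraction), because the ≥ 95 % filter only makes sense there
even though the defining ratio is the unconverted fraction. Two
aggregations exist. Call-level (default): unconverted base calls over all
base calls at non-CpG C positions; unbiased in depth, and the recovery
tests hold it within ±0.5 points of the true efficiency at depth ≥ 1,000.
Site-level (protocol-literal): sites with ≥ 1 unconverted call over
covered sites; since P(site flagged) = 1 − c^depth, deep hairpins are
poisoned by single stray calls — at c = 0.98 and depth 200 practically
every site is flagged — which is why call-level is the default and the
discrepancy is surfaced rather than silently adopted.

## Filters

Hairpins are discarded, first matching reason recorded: control read count
below `min_expression` (default 25; the protocol's expression threshold is
unstated, so it is exposed as configuration and this default is a
documented guess aligned with the coverage floor), mapped reads < 25
(`min_reads`), conversion rate < 95 % (`min_conversion_pct`). A hairpin
whose conversion rate cannot be evaluated (no covered non-CpG C) is
discarded conservatively under the conversion reason. Both thresholds are
strict ("less than"), so 25 reads and exactly 95.0 % pass. The
non-converted control is aligned in exact-match mode; the pipeline asserts
that control runs produce zero T-over-C calls and aborts otherwise.

Replicate concordance is the Pearson correlation of methylation
percentages over the intersection of kept matures per replicate pair;
pairs sharing < 3 matures or with zero variance are flagged undefined
rather than reported.

## ΔΔCt arithmetic

Expression fold change: 2^−[(Ct_target,s − Ct_norm,s) − (Ct_target,c −
Ct_norm,c)]. RIP enrichment references the IgG mock: 2^−[(Ct_IP − Ct_input)
− (Ct_IgG − Ct_input)] = 2^(Ct_IgG − Ct_IP); the input term cancels
algebraically but its presence is validated to keep the three-term
procedure explicit. Replicate Ct values are averaged arithmetically before
any ΔΔCt (standard practice; the protocol is silent). No
amplification-efficiency correction is modeled. Calls: fold ≥ 3
methylated, fold > 5 highly methylated, both boundaries exact.

## Simulator

The generator emulates the study design: hairpins of 60–110 nt with one or
two embedded mature arms of 20–24 nt; read lengths drawn uniformly on
16–30 nt from windows inside mature arms (so the 16-nt draws exercise the
QC length rule and short draws exercise the 80 % coverage rule); paired
converted/control samples from shared truth; per-CpG methylation fractions
m; conversion efficiency c (default 0.99, a realistic bisulfite
efficiency); inappropriate conversion of methylated C e_m (default 0 — the
estimators carry no term for it; nonzero values exist only to probe
robustness); substitution-only sequencing error (the aligner is ungapped);
constant base quality Q37. A converted CpG cytosine is emitted as C with
probability m(1−e_m) + (1−m)(1−c); a non-CpG C as C with probability 1−c.
Flanking sequence outside mature arms is C-free so all cytosine context is
deliberate and mature sequences stay unique. Identical seeds give
byte-identical FASTQ.

`expected_methylation` is the closed-form recovery target: the probability
that a read surviving QC (length ≥ 17) and the 80 % mature-coverage rule
shows ≥ 1 unconverted CpG, marginalized over the surviving (length, start)
windows. It conditions on exactly the read population the pipeline
quantifies, which is what makes the recovery tests sharp; it is exact only
at zero sequencing error and refuses to compute otherwise.

What the simulator does not emulate: adapter contamination, PhiX spike-in,
quality-score degradation along the read, ligation bias, expression
skew across miRNAs (depth is set per hairpin, not drawn), and cross-mapping
between homologous real miRNA families (flanks are random). Passing
recovery tests therefore demonstrate estimator correctness under the
stated generative model, not robustness to every artifact of real
libraries.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale chosen as representative
for a hairpin-bank analysis: banks of 1–50 hairpins, depths 100–1,000 for
behavioural checks, 10,000 for the bias check (estimated as the mean
deviation over three independent draws, since a single draw's sampling
noise at p ≈ 0.25 is of the same order as the 1-point bound). Binomial
intervals are used for stochastic recovery assertions; the methylated-read
count is a mixture of Bernoullis across windows, whose variance is bounded
by the binomial, so those intervals are conservative. All randomness flows
through seeded `numpy` generators; every reported number is recomputed at
run time.

## Known limitations

* Tied multimaps double-count reads across the tied hairpins, by design.
* The seed-index expansion is exponential in the C count of a k-mer; fine
  for hairpin banks, unsuitable for genome-scale references.
* The mature-placement fallback searches all hairpins, so a mature
  occurring verbatim in an unrelated hairpin is annotated there too; an
  explicit coordinate TSV overrides search when curated placements exist.
* No gapped alignment: a true indel in a read costs the whole read.
* The reference audit counts unique mature sequences after DNA
  normalization; it does not deduplicate near-identical family members.
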