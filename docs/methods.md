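# Methods

This note documents the models, the tunable parameters, and the design
choices behind `sbscreen`, in the spirit of a statistical methods appendix.

## The screen and its statistical structure

A Sleeping Beauty (SB) screen mobilises a mutagenic transposon (carrying a
strong internal CAG promoter, splice donor and polyadenylation elements)
in the tissue of interest; tumours are sequenced for transposon–genome
junctions, and genes hit more often than chance predicts are candidate
drivers. Three physical facts shape the analysis:

1. **TA integration.** The transposon inserts at TA dinucleotides, so both
   junction flanks begin with TA (its own reverse complement). Sites are
   reported 1-based at the T.
2. **Local hopping.** A remobilised transposon preferentially reinserts
   near its donor concatemer, inflating insertion density on the donor
   chromosome of each transgenic line. Two lines with different donor
   chromosomes are therefore screened, and a candidate must recur in both.
3. **Orientation encodes mechanism.** A sense-oriented insertion places the
   internal promoter in the gene's transcriptional direction and can drive
   an activated (often truncated) transcript; dispersed, orientation-
   unbiased insertions disrupt the gene via the poly(A) cassette.

## Synthetic data generator

The generator is first-class, tested code; its defaults define the study
conditions the test-suite measures.

**Screens.** Each tumour receives Poisson(background_rate) background
insertions; default `background_rate = 50` per tumour (per-tumour insertion
loads are not well standardised across screens; 50 gives genome-scale
per-gene expectations λ ≈ 0.05 for a 13 kb window at 200 tumours, a
realistic sparse-hit regime). Chromosomes are drawn proportionally to
length, with the strain's donor chromosome weighted by `hopping_factor`
(default 3, renormalised) — a single-multiplier stand-in for the local-
hopping excess. Planted drivers add, with per-strain probability
`penetrance`, one insertion: ONCOGENEs inside a hotspot exon span with
`sense_prob > 0.5`; TSGs uniformly over the gene with `sense_prob = 0.5`.
Coordinate-only screens use mouse-scale chromosome sizes
(`MOUSE_LIKE_CHROMS`, ~2.53 Gb) and arbitrary integer positions so that
genome-scale simulations stay fast; sequence-backed screens restrict
positions to TA sites of the generated genome. A ground-truth sidecar table
always accompanies the insertion table.

**Reads.** Single-end reads of 150 bp (the common junction-library read
length), laid out IRDR(5′)–genomic flank–linker(3′), with a 70 bp default
flank, iid substitution errors at `error_rate`, and a configurable fraction
of contaminant reads lacking the transposon end. Quality scores, indels and
paired ends are out of scope.

**Exon counts.** Counts are Poisson(depth × exon length × μ) with μ
stepped by `fold` from the trapped exon onward in trapped samples only.

**Patient cohorts.** Expression is standard normal per gene. For an effect
gene, `logit P(TNBC) = logit(base) + slope × (percentile − 0.5)`; default
`base_tnbc_rate = 0.15` (the typical TNBC fraction of unselected breast-
cancer cohorts) and `slope = 2.0`, giving cohort TNBC proportions rising
from ~7% to ~30% across expression deciles — a visible but noisy trend.
The link is a modelling stand-in: real cohorts give no generative model.
TNBC status forces ER/PR/HER2 all negative; basal-type status is correlated
with TNBC (0.8 vs 0.15); the BRCA1-mutant flag is independent.

What the generator does **not** emulate: insertion hotspot heterogeneity of
real genomes (TA density apart), clonal support-count structure, batch or
platform effects in expression, correlated receptor-status noise, or
survival endpoints. Passing recovery tests therefore demonstrates
correctness of the statistics under the stated model, not robustness to
every artefact of real screens.

## Read processing

IRDR and linker matching tolerate mismatches up to 10% of the matched
length (the common trimmer default; the tolerance is configurable). A read
matching both IRDR ends is treated as chemistry failure (`no_transposon`).
Location requires an exact, unique 25-nt seed and allows ≤ 3 substitutions
over the whole segment — the bounded-mismatch criterion applied to the full
read, which is the strictest reading of "allowing 3 mismatches" for a
short-read aligner. Two seed hits anywhere reject the read as ambiguous.
Dedupe collapses identical (chrom, pos, orientation, tumour) records,
summing read support; the merge window defaults to 0 bp (exact position)
and is configurable. Rejection reasons partition all non-accepted reads, so
per-stage counts are conserved.

The orientation convention is a fixed 2×2 table
(`sbscreen.adapters.ORIENTATION`) mapping (IRDR end, mapped strand) to the
genomic strand of the internal promoter. Only the pairing is observable;
the simulator and locator share the table, so a global relabelling of the
ends changes nothing downstream. Real, pre-mapped insertion tables enter
through the TSV interface and skip trimming/location entirely; full
short-read alignment is deliberately out of scope.

## CIS statistic

The per-gene window is the gene body plus 3 kb upstream (strand-aware,
clamped at chromosome start). The null is homogeneous: λ = N·w/L with L the
sum of chromosome lengths (or a user-supplied mappable length), and
p = P(Poisson(λ) ≥ k), computed by `scipy.stats.poisson.sf`. This is a
reconstruction of the classic CIS-statistic family (gene-centric Poisson on
uniform background) rather than a re-implementation of any specific
published tool; kernel-convolution and TA-corrected nulls are non-goals.
Because the test is discrete its size is at most α and usually below it; the
calibration test compares Monte-Carlo rejection rates to the analytic size
of the discrete test rather than to α itself. Raw p < 0.05 mirrors the
screen's published filter; BH q-values are reported for modern use but not
used for filtering. Donor-chromosome insertions are retained by default
(with an exclusion flag): their inflated λ is absorbed by the two-strain
recurrence filter, which requires a fraction ≥ θ = 0.05 of tumours in each
strain (boundary kept, ≥ not >). A site in two genes' overlapping extended
windows counts for both genes — annotation by interval overlap, with no
greedy assignment.

## Driver classification

Sense fraction uses scipy's exact two-sided binomial test (minlike
two-sidedness: sum of outcome probabilities ≤ the observed outcome's). The
cluster score is the maximum fraction of a gene's insertions inside any
half-open window of width 0.2 × region length; the maximising window can be
anchored at an insertion position, so the scan over anchored windows is
exhaustive. The thresholds — binomial p < 0.05 with f > 0.5, cluster score
≥ 0.5, minimum 5 insertions — operationalise a qualitative published rule
("clustered, sense-biased" vs "dispersed, unbiased"); all are configurable,
and conflicting evidence (significant sense bias without clustering) is
reported AMBIGUOUS rather than forced into a class. The sense-fraction
denominator is all insertions in the extended gene region.

## Breakpoint detection

Normalisation e_i = c_i/(T·l_i) uses per-sample total mapped reads T
(genome-wide totals; when a counts table covers a single gene, callers
should pass external library sizes, since within-table totals absorb the
step). Values may be rescaled (e.g. ×1e9) for readability; only the depth
and length invariances are contractual. The estimator is the exhaustive
two-segment mean-shift argmax on log-ratios with pseudocount ε = 1e-8 in
normalised units, gated at fold ≥ 2; the gate, ε, and the estimator's
simplicity (no significance beyond the fold gate) are deliberate — the goal
is to localise an obvious step, not to test for one.

## Subtype correlation

Cohort binning sorts ascending by expression with stable patient-id
tie-break; the first (n mod k) cohorts — the lowest-expression ones —
absorb the remainder (1898 patients at k = 10 gives eight cohorts of 190
and two of 189). Spearman's R between cohort index and cohort TNBC
proportion (average ranks on ties) is the screen statistic, chosen to match
the rank-correlation convention of the source analyses; Pearson is
available behind a flag. The two-sided p is an exact enumeration over all
k! orderings for k ≤ 8 and the t-approximation above; constant proportions
return (R = 0, p = 1, direction none) by convention. Correlating against
cohort index is equivalent in rank to correlating against median cohort
expression for monotone binning. Consensus requires p < α = 0.05 in both
databases with matching direction. The BRCA1-mutant sub-analysis is the
same pipeline with k = 6 on the flagged subset. Orthologue mapping keeps
strictly one-to-one pairs; unmapped, one-to-many and many-to-one entries
are dropped and logged.

## Problem sizes

The test-suite and acceptance script run at desk scale by design: 50-gene
catalogs on mouse-scale coordinates with 200 tumours per replicate screen
(50 replicates for driver recovery), ~10⁴ junction reads on a 200 kb
sequence-backed genome for the round trip, 500–1000 null genes at n = 1000
patients for calibration, 100–200 replicates for power and breakpoint
recovery. Screen-level counts from real datasets (total site counts,
candidate-list sizes) depend on the full sequencing and clinical cohorts
and are not desk-scale quantities; the package instead verifies the
statistics on published contingency counts and measures operating
characteristics on simulated screens.

## Known limitations

- The homogeneous Poisson null ignores TA-site density and mappability
  variation; on real data, supply an effective mappable length and treat
  donor chromosomes with the recurrence filter (or the exclusion flag).
- The locator is exact-seed based and intended for synthetic references;
  real reads should be aligned externally and imported as tables.
- Classification thresholds are heuristic reconstructions; counts of
  oncogene-featured genes are threshold-sensitive and should be read as
  such.
- The patient-cohort generator's logit-linear link is a convenience model;
  calibration/power results quantify the screen's behaviour under that
  model only.
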