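# Methods

## Problem and model

The package classifies consolidated large-SV calls from multi-caller WGS
into three classes: technical artifact (−1), germline variant (1), somatic
cytogenetic SV (2). Two modeling assumptions drive the design:

* **Evidence, not read data.** Classification operates on caller-level
  evidence (genotype, supporting reads, breakpoint confidence intervals)
  plus annotation resources; reads are never re-genotyped. Interval inputs
  from CNV callers that arrive without genotypes are treated as genotype
  `uncertain` and therefore removed by QC unless re-genotyped upstream.
* **Translocations are structurally different.** They have no length, two
  independent breakend contexts, and arrive as paired VCF breakend (BND)
  records; they are consolidated, labeled and modeled as their own group
  (`TRS`) alongside the interval group (`nonTRS`).

## Matching

Interval SVs are equivalent when they share a type and their reciprocal
overlap — `min(|a∩b|/|a|, |a∩b|/|b|)` on 1-based inclusive coordinates —
reaches `overlap_frac` (default 0.9, compared with ≥). Reciprocal rather
than one-directional overlap is used because a one-directional test would
match any small SV nested in a large one, defeating size-aware matching.
Translocations are equivalent when, after canonical breakend ordering
(end 1 is the lexicographically smaller `(chrom, pos)`), both per-breakend
distances are ≤ `bnd_dist` (default 1000 bp). The distance test is per
breakend, not summed. Confidence intervals do not expand the match test;
their widths enter the model as features instead. Cross-type matching is
off by default.

Consolidation across callers is single-linkage clustering under this
equivalence. The representative is the member with the highest QUAL, ties
broken toward the lexicographically smallest id, so the output is invariant
to input order. Database annotation uses an interval tree per chromosome
(translocations are bucketed by chromosome pair) and is tested to be
exactly equivalent to the brute-force all-pairs result.

## Labeling precedence

The three class definitions only become disjoint when read as a strict
ladder, which is how they are implemented: artifact evidence (flagged panel
match, donor carrier fraction ≥ `donor_af_threshold`, or a breakend inside
a centromere) is checked first; then a PASS-only germline match labels
germline; then a hotspot match with no germline match of any kind and a low
donor fraction labels somatic; everything else is unlabeled. Consequences
worth knowing:

* a call matching both a hotspot and a PASS germline entry is **germline**;
* a germline entry with a non-PASS, non-artifact flag (e.g. `LOWQUAL`)
  neither labels germline nor artifact, but still blocks the somatic rule;
* removing hotspot entries can only demote class 2 to 1/unlabeled, never
  to −1 (tested exhaustively over all evidence combinations).

`donor_af_threshold` defaults to 0.01 — the conventional cutoff for a
common variant — and is configurable. The centromere test uses breakend
positions only (no CI expansion). Unlabeled records are kept for prediction
but excluded from training.

## Features

Per record: `read_diff = alt − ref` and `read_ratio = alt/(alt+ref)`
(absent at zero depth; counts are averaged over the two breakends, which
reduces to the caller's single reported pair for interval SVs), QUAL, GQ,
CIPOS/CIEND widths, log10 length (absent for TRS), caller count; per
breakend: Shannon entropy of overlapping k-mers (k = 1, 2, 3, N-containing
k-mers excluded), linguistic complexity
`Π_k (distinct k-mers) / min(4^k, L−k+1)` for k = 1..3, and GC content,
all on the uppercased reference context ±100 bp around the breakend
(window configurable; 100 bp captures the local low-complexity context at
caller resolution). Both complexity metrics are invariant under reverse
complement, which the property tests exercise.

Missing values are imputed with training-set medians recorded in the model
artifact, so a saved model reproduces its predictions exactly.

## Classifier

One XGBoost multiclass model per group (`multi:softprob`, depth 4,
learning rate 0.1, single thread, histogram trees), trained on the 63%
train slice with early stopping (25 rounds) on the 27% test slice; the 10%
hold-out is only ever scored. Splits are stratified by class and
deterministic per seed. Metrics: macro-AUC (unweighted mean of one-vs-rest
AUCs; classes absent from a small hold-out are dropped with a warning),
micro-AUC (pooled one-hot expansion — the standard definition), somatic
one-vs-rest AUC, and the Youden point: the observed score threshold
maximizing sensitivity + specificity, with a ≥-threshold rule and ties
broken toward the smaller threshold (higher sensitivity). No probability
calibration is applied; thresholds act on raw scores. Feature importance
is permutation importance — the mean drop in somatic one-vs-rest AUC over
seeded column shuffles — which measures the same "contribution to somatic
discrimination" quantity as SHAP-style analyses while staying
model-agnostic and exactly reproducible.

A single fixed learner replaces any multi-model search: the endpoint of
such a search is one gradient-boosted model, and fixed documented
hyperparameters keep training bit-for-bit reproducible.

## Synthetic cohorts: what they emulate, and what not

`CohortConfig` defaults define the study conditions. The genome is 4
chromosomes × 10 Mb (large enough for many ≥ 1 Mb SVs, small enough that
every test runs in seconds) at GC 0.41, with eight 400 bp poly-A tracts
per chromosome and one centromere interval spanning 40–52% of each
chromosome. Per group, 80 artifact / 100 germline / 60 somatic / 20 decoy
SVs of 1.2–3 Mb are planted with rejection sampling that keeps same-type
placements below 0.8 reciprocal overlap, so distinct planted SVs never
cross-match under the 0.9 criterion even after jitter. Three callers each
detect an SV with probability 0.85 (at least one always does) and re-call
it with ±50 bp breakpoint jitter. Read counts are negative-binomial depth
(mean 60) with class-conditional alt fractions: germline het 0.5 / hom 1.0
(85% het), somatic 0.30 ± 0.04 (a subclonal fraction), artifact
0.10 ± 0.03; GQ, QUAL and CI widths are likewise class-conditional, and
half the non-centromeric artifacts anchor a breakend in a low-complexity
tract. Artifact evidence modes are drawn 40/30/30 between flagged panel
entry, centromeric placement and 20% donor frequency.

Planted germline SVs default to **zero** donor-cohort carriers: with 100
donors and the 1% donor-AF artifact threshold, any planted germline SV
carried by even one donor would — correctly, by the precedence ladder — be
labeled artifact and contradict its planted class. The donor-frequency
channel is therefore reserved for the artifact mode; a nonzero
`germline_donor_freq` is available for studying exactly that interaction.

What passing tests show: the matching, labeling, feature and training
machinery is correct, deterministic, and recovers planted classes when the
class signal exists. What they do not show: performance on real cohorts,
where class-conditional feature distributions overlap far more, database
completeness varies, callers disagree structurally (not just by jitter),
and breakpoint errors correlate with sequence context.

`generate_separable_features` is the direct classifier harness: Gaussian
features with the somatic class shifted 2.5 pooled SDs on four designated
features (≈2000 rows per group, 1/3 per class). It is used for the
classifier acceptance checks because end-to-end cohorts at desk scale
leave only ~24 hold-out records per group, where Youden operating points
fluctuate between seeds (the worked example in the README shows one such
dip); the harness's 200-record hold-out makes the performance readout
stable.

## Numerical and degenerate-input choices

* Zero-length (end < start) intervals are a domain error in
  `reciprocal_overlap`; zero-depth read ratios are absent, not 0.
* BND records pair via MATEID, falling back to reciprocal coordinate
  lookup; unpaired or intra-chromosomal BNDs are dropped with a warning
  and counted in the parse report.
* The QC rules apply in a fixed order (genotype → breakpoint completeness
  → read evidence) so removal reasons are deterministic; "read evidence at
  both breakpoints" is the strict reading (≥ 1 alt read at each end), with
  a lenient switch.
* BED is converted to 1-based inclusive on read; all internal coordinates
  are VCF-convention.
* Splits, training, permutation importance and every simulator draw run
  from explicit seeds; reruns are byte-identical, which the test suite
  verifies on files.

## Known limitations

* Multi-sample VCFs are reduced to one named sample; no cross-sample
  modeling.
* Database matching uses the consolidated representative, not every member
  call.
* The simulator emits caller-level VCFs only; no read-level (FASTQ/BAM)
  simulation, and no assembly liftover — all inputs must share one
  reference.
* The static HTML report replaces any interactive interface by design.
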