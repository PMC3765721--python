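# Methods

## The quantification model

The unit of measurement is the exon-level **rescaled RPKM**: an exon's RPKM
divided by its host gene's expression, where gene expression is the
arithmetic mean RPKM of the gene's *annotated* exons (classes C1–C3,
zero-count exons included). Un-annotated TE exons (C4) and simulated decoy
exons (C5) are rescaled against the host gene of their (paired) C4 exon but
never contribute to any gene's expression. Because the denominator is the
mean of the annotated exons' RPKMs, the uncapped rescaled values of a gene's
annotated exons average to exactly 1 — this identity is a built-in
self-check of the membership bookkeeping and explains why constitutive exons
sit at M ≈ 1 in the class summaries. Rescaled values are capped at 10
before any downstream statistic; the cap guards against near-zero
denominators in weakly expressed genes.

**RPKM denominator.** The library size used in RPKM is the number of
*filtered* reads (primary alignments of uniquely mapped reads), matching the
upstream ambiguity filter; a caller can pass raw mapped totals instead.
When quantifying from a count matrix without a stated library size, the
column sum is used — every rescaled quantity is invariant to this choice
because the denominator cancels.

**Expressed-gene cutoff.** Decoy (fictional) genes are assembled by sampling
4–40 C5 exons each (500 genes by default, exons reusable across genes but
unique within one). The per-sample cutoff is the 0.95 nearest-rank (type-1)
quantile of the fictional-gene expression distribution; genes below it are
excluded from all statistics for that sample. An upper quantile of a decoy
distribution is the standard false-positive-controlling choice; the quantile
is a config parameter.

**Counting rule.** A read increments an exon when any aligned block overlaps
it by ≥ 1 base; junction-spanning reads may increment several exons, but
each exon at most once per read. No minimum-overlap fraction is imposed.

## Exon classes and the C5 construction

C5 decoys are the intronic interval immediately *downstream* of each C4
exon, with equal length. Downstream is taken strand-relative (the 3′
direction of the host gene), which is the biologically meaningful reading;
`c5_strand_aware=False` reproduces a strand-ignorant, always-to-the-right
construction. Decoys clipped at a chromosome start are truncated with a
warning. The C5 list is index-paired with the C4 list — required by the
paired signed-rank comparison — and exact-coordinate matching for C3 status
compares (chrom, start, end) only; strand is not part of exon identity.

## Statistical tests

* Mann–Whitney (independent classes): exact U distribution when the pooled
  size is ≤ 20 with no ties, otherwise tie-corrected normal approximation
  with continuity correction. Two-sided throughout.
* Wilcoxon signed-rank (paired C4 vs C5): zero differences dropped by
  default (Pratt handling available); exact sign-enumeration for ≤ 15
  tie-free informative pairs, else normal approximation.
* The stepwise ladder compares whole rescaled-RPKM distributions *including
  zeros*: the un-expressed mass is part of a class's digital expression
  profile. `expressed_only=True` restricts to detected exons.
* Fisher's exact test: two-sided by default (sum of table probabilities not
  exceeding the observed one); a zero margin leaves the test undefined and
  the family is reported excluded rather than tested.
* Kendall's tau-b (tie-corrected) for the median-vs-CV association.

Undefined statistics (empty strata, zero pooled SD, zero-mean CV) are always
reported as missing, never as 0.

## The two-step (hurdle) regression

A single linear model cannot be fit to log expression when 30–80% of TE
exons have no reads; the analysis therefore splits into a logistic
presence/absence model (Model-1, Wald tests) and an OLS model of log₁₀
level among the detected exons (Model-2, t tests). The shared design is
[intercept, UTR3, UTR5, ERV1, ERVL, L1, L2, MaLR, MER1, MER2, MIR,
log₁₀ELN, RTE] with CDS and Alu as baselines pinned to zero by omission;
exons of the rare CR1 and other_DNA families are excluded before design
construction (an excluded family reaching the design raises, it is never
silently dropped). Presence is defined as count ≥ 1 within expressed genes
(equivalent to rescaled RPKM > 0 here). Newton fitting uses a 1e-8
relative-likelihood tolerance with at most 100 iterations; non-convergence
or a coefficient exceeding 30 in magnitude is reported as separation, naming
the offending column. Effect summaries discretize p-values into
{pos p<0.01, pos p<0.05, ns, neg p<0.05, neg p<0.01} — 0.01 and 0.05 are the
only thresholds the reporting uses.

The cross-sample summary fits reuse the design with the per-exon median m
(on log₁₀ scale, mirroring Model-2's transformation; rows with m = 0
excluded) and the CV v (raw scale, on the same row subset for
comparability) as dependent variables. Eligibility requires the host gene
expressed in at least half the samples (13 of 26 by default).

## The synthetic-data generator

The generator emulates the study design: ~600 genes with 5–11 annotated
exons on a toy chromosome; 210 C3 and 1190 C4 exons (1400 TE exons); C4
exons placed in introns with the strand-relative downstream interval left
free so C5 decoys never collide with an exon; 26 pseudo-samples with two
two-group contrasts (estrogen-receptor status in seven breast samples,
tumor/normal in six prostate samples) and an uncontrasted reference sample
used for recovery studies.

Counts are drawn from the same two-part process the analysis fits: presence
Bernoulli in the planted Model-1 logit, conditional level log-normal around
the planted Model-2 predictor (noise SD 0.4 dex), converted to an expected
read count through the host gene's expression (log₁₀ RPKM ~ N(1.3, 0.4),
with 0.15 dex per-sample wobble) and the library size, then sampled
**zero-truncated** Poisson (inverse-CDF; optional gamma–Poisson mixing for
negative-binomial robustness checks). Truncation makes the planted presence
indicator identical to the observed has-a-read indicator, keeping the
generative hurdle self-consistent; an untruncated count draw would
contradict the planted presence for weakly covered exons. Non-TE exons use
class retention multipliers (C1: presence 0.97, level 1.0; C2: 0.91, 0.85);
C5 decoys receive plain-Poisson background at 0.02 RPKM (the near-zero
pre-mRNA regime; raising it emulates pre-mRNA-rich samples).

Default library size is 80 million filtered reads, mid-range for deep bulk
RNA-seq experiments of this design; at much shallower depth the
count-sampling noise at expected counts of ~2 reads visibly distorts log
levels and the level-model coefficients stop being cleanly identifiable, so
shallow-depth settings should be treated as a stress test rather than the
reference condition. Covariate distributions differ by class — C3 exons
skew toward ancient families (MIR/L2/MaLR) with low RTE, C4 exons toward
Alu/L1 with high RTE — which is what produces the C3-vs-C4 expression gap
through the planted covariate effects alone, without any class-specific
term the fitted models could not see. TE exons in the 8% of genes marked as
ZNF receive a +0.6 dex level boost, planting the family-independent
enrichment signal. Group contrasts shift the level of a random 10–15%
subset of TE exons by ±0.4–0.6 dex in the affected samples.

What the generator does **not** emulate: mappability and multi-mapping
ambiguity (reads are placed uniquely; the ambiguity filter is exercised by
explicit decoy records), sequencing error, paired-end fragment structure,
batch effects, and correlated splicing across exons of one transcript.
Passing tests therefore demonstrate the correctness and calibration of the
estimators under the stated generative assumptions, not robustness to
alignment artefacts in real data.

## Numerical choices and edge cases

* Coordinates are 0-based half-open throughout; 1-based fully-closed input
  dialects convert at parse time (`one_based_closed=True`).
* Nearest-rank quantile: index ⌈q·n⌉ of the sorted decoy values; monotone in
  q by construction.
* Missing cells of the expression matrix (host gene un-expressed in a
  sample) are excluded from CV/median computations; clustering, which needs
  complete rows, zero-imputes them (configurable) — zeros are the natural
  imputation because an un-expressed gene's exons are operationally silent.
* Complete-linkage clustering uses Euclidean distance; merge heights are
  non-decreasing and ties resolve deterministically by lowest observation
  index. A Newick export of the dendrogram is provided.
* Sample SDs use the n−1 denominator everywhere.
* The log₁₀ histograms separate the zero mass (reported as a proportion)
  from the positive values, which are binned between the smallest positive
  value and the cap; values at the cap fall in the last bin.

## Known limitations

* The per-sample logistic fit needs every family and location stratum to
  contain both outcomes; on very small datasets rare families (single-digit
  exon counts) quasi-separate and Model-1 is reported as failed for that
  sample instead of returning divergent coefficients.
* The highly-expressed rule (> 0.25 in ≥ 2 samples) and the 13-sample
  eligibility threshold are study-design constants exposed as parameters;
  no multiple-testing correction is applied to the per-family Fisher tests,
  matching the descriptive intent of the enrichment table.
* Fictional-gene sampling reuses C5 exons across genes, so the decoy gene
  RPKMs are weakly dependent; with 500 genes over ~1200 decoys the effect
  on the upper quantile is negligible.
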