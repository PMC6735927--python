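# Methods

## Divergence measures

**ED.** Expression divergence of a duplicate pair is ED = (C₁ + C₂)/C with
C₁, C₂ the counts of conditions where only one copy is detected and C the
count where at least one is (the union — forced by the boundary semantics:
two copies never detected together must score 1, which an intersection-based
denominator cannot produce).  Pairs with C = 0 are excluded with reason
`not_detected`; pairs with a copy removed by the low-expression filter are
excluded with reason `missing_gene` and counted, since the fraction of pairs
with both copies represented is itself a quantity of interest.  "Detected"
defaults to raw count > 0 after filtering; a CPM matrix with a positive
threshold can be substituted (`detection_threshold`), since no single
detection rule is canonical for mixed compendia.

**SD.** Sequence divergence is the nonsynonymous rate Kₙ, taken from the
input catalog.  Estimating Kₛ/Kₙ from sequences (alignment, codon models) is
outside this package; the catalog consumes those numbers.

**ID.** Interaction divergence is ID = 1 − 2·I₁₂/(I₁ + I₂), one minus the
Sørensen–Dice coefficient of the two partner sets in a merged, deduplicated,
self-loop-free PPI graph.  By default each copy is removed from the other's
partner set first, so heterodimerizing paralogs do not score an automatic
shared partner (`exclude_partner_gene=False` restores the naive sets).
Because PPI data are false-negative-rich, eligibility requires
max(I₁, I₂) ≥ 4 and min(I₁, I₂) ≥ 1; both thresholds are parameters and
`sweep_id_cutoffs` recomputes eligibility for cutoffs 1..14.

## Filters and classification

- Ks analysis window [0.05, 5], boundaries inclusive (the discard rules are
  strict inequalities): the low cut removes near-identical pairs dominated
  by redundancy/artifacts, the high cut removes saturated Ks estimates.
- Tandem rule: same chromosome and at most 30 intervening genes
  (inclusive; both the gap and the boundary convention are parameters).
  Collinearity ("block") evidence is consumed from input.  A pair flagged
  both tandem and block, or neither, is `unclassified` and excluded from all
  comparative partitions.
- Low-expression filter: a gene is kept iff its summed count over all
  conditions is at least 2 × the number of conditions (strictly-lower rule;
  multiplier configurable).
- Young-duplicate subsets use strict Ks < 5 / Ks < 1.

## Saturation model and model comparison

Divergence versus Ks is fit with y = a·Ks/(b + Ks): through the origin
(functional redundancy at duplication), monotone, asymptote a, half
saturation b.  Ordinary (unweighted) least squares, bounded trust-region
optimization with multi-start — a₀ ∈ {max(y), mean(y)},
b₀ ∈ {median(Ks), 1} — best SSE wins, ties (relative 1e-9) broken toward the
smaller b.  Bounds: a ∈ [0, 1] for ED/ID, a ∈ [0, 10] for SD;
b ∈ (1e-6, 100].  All-zero responses return a = 0 with b flagged
unidentified.  The a–b SSE surface has a flat, diagonally oriented valley
when b approaches the upper end of the observed Ks range; in that regime b
is estimated with wide uncertainty (the bootstrap bands show it) even though
the fitted curve itself is stable.

Partitions are compared with the extra-sum-of-squares F-test:
F = ((SSE_comb − SSE_sep)/df₁)/(SSE_sep/df₂), df₁ = 2(k−1),
df₂ = n − 2k for k two-parameter partitions.  The pooled parameters are
injected as an extra start into each per-partition fit, which makes the
nesting inequality SSE_comb ≥ Σ SSE_sep hold by construction; it is also
asserted on every comparison.  Under the crossed mode × PPI scheme the
with/without-PPI curves are compared *within* tandem and within block
separately.  Partitions under 10 points (configurable) are skipped and
reported.

Confidence bands are case-resampling bootstrap percentile envelopes
(default 95%, seedable).  Bootstrap refits start from the point estimate
only — the two-parameter surface is well behaved near the optimum and the
resample stays close to the original sample — and the band is widened to
contain the point-estimate curve, so the envelope's trivial containment
property holds structurally.  Fewer than 50 successful refits is an error.

## Association statistics

Correlation panels compute Pearson's r and Spearman's ρ (average ranks on
ties) for every variable pair × partition × Ks subset, flagging cells with
fewer than 3 complete observations, with stars at p < 1e-10 / 1e-5 / 0.05.
Representation tests are two-sided Fisher exact tests of each category
against the rest (sidedness is a choice; two-sided is the conservative
default), BH-corrected across categories.  GO enrichment uses flat GO-slim
annotation sets — no DAG propagation, matching how a slim is used — and
reports both hypergeometric tails per term; the smaller tail names the
direction and feeds BH across all tested terms.  The enrichment background
defaults to all duplicate genes in the analysis set and is configurable,
as no universal background exists.  The mode × PPI 2×2 construction is
ambiguous in two ways (pairs vs genes as counting units; whether
unclassified pairs join the background); both variants sit behind flags on
`representation_test_table1` rather than being silently resolved.
BH is the step-up rule q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ m·p₍ⱼ₎/j clipped at 1 (cross-checked
against statsmodels in the tests).

## Synthetic-data generator

The generator emulates the statistical structure of a multi-species
duplicate study; all distributional choices are its own and are labeled as
such in the ground-truth sidecar.

- **Ks.** Block pairs: truncated Gaussian mixture (default peaks at 0.8 and
  2.5) — discrete WGD waves.  Tandem pairs: truncated exponential (rate 1) —
  continuous ongoing duplication.  Truncation to the [0.05, 5] window.
- **Latent divergence.** Per measure and mode, the curve value a·Ks/(b+Ks)
  plus Gaussian noise (default sd 0.05), clamped to [0, 1] for ED/ID and to
  ≥ 0 for SD; Kₙ is recorded as the SD value.  Default asymptotes put block
  below tandem (SD 0.6 vs 0.9, ED 0.25 vs 0.45, ID 0.75 vs 0.95).  Pairs
  engaged in PPIs can additionally have their asymptote scaled by
  `ppi_asymptote_factor ≤ 1`, which is how the generator realizes the
  with-PPI-diverge-slower condition; per-mode with-PPI fractions default to
  0.35 (tandem) / 0.65 (block), echoing the asymmetry real catalogs show.
- **ED realization.** Each pair gets C = round(detection_prob·n_conditions)
  union conditions; U = round(ED·C) of them are private, split evenly (odd
  remainder to the lexicographically first gene); realized ED = U/C, so the
  statistic recovers the latent value within 1/C.  Detected cells receive a
  count floor of ⌈2·n_conditions/|detected|⌉ plus negative-binomial noise
  (mean 30, dispersion 0.3), guaranteeing survival of the low-expression
  filter.  Defaults: 60 conditions, detection probability 0.7 — the scale of
  a real RNA-seq compendium of a few dozen experiments.
- **ID realization.** Ancestral partner count N ~ Poisson(6) truncated ≥ 1
  (the degree model is mode-independent, so degree differences cannot
  confound mode comparisons); S = round((1−ID)·N) shared partners give both
  copies degree N and realized ID = 1 − S/N.  Pairs with N < 4 fall below
  the default eligibility cutoff, as in real sparse networks.
- **Families and species.** One family per duplicate pair, shared across
  species (the reference species carries the actual network; other species
  receive PPI status only through family projection).  Families beyond the
  pair count are singleton background genes, giving the expression matrix
  and enrichment background non-duplicate genes.  Unclassified pairs follow
  the tandem process and exist to prove downstream stages drop them.
- **GO.** Per-term base annotation probability with multiplicative
  per-mode bias factors (defaults bias DNA-binding/kinase terms into block
  and transporter/hydrolase terms into tandem duplicates, with two unbiased
  terms).
- **Determinism.** One integer seed; substreams for Ks, noise, expression,
  PPI, GO and positions are spawned from it, so identical configs give
  byte-identical files.

What the generator does **not** emulate: batch effects or condition
correlation within compendia, mapping ambiguity between young paralogs
(which depresses detection of recent tandem pairs in real data), PPI false
positives, study-specific Ks estimation error, or GO term co-occurrence
structure.  Passing tests therefore demonstrate that the estimators recover
what the statistics are defined to measure under a faithful generative
model — not that real compendia are free of these confounders.

## Simulation study sizes

The packaged statistical checks use desk-scale analogues of a real study
(which has thousands of pairs per species): curve recovery at n = 2000
points (noise sd 0.1, 20 seeds), F-test size at 1000 replicates of two
n = 500 partitions and power at 200 replicates of asymptotes 0.2 vs 0.4,
bootstrap coverage at 200 simulations × 200 resamples, end-to-end recovery
over 100 generator seeds of 200 + 200 pairs with 60 conditions and a PPI
asymptote factor of 0.6.

## Known limitations

- b (half-saturation) is weakly identified when divergence has not begun to
  plateau inside the observed Ks range; compare asymptotes, not b, across
  shallow partitions.
- ED depends on the detection rule; with very deep compendia, count > 0
  approaches "everything detected" and ED compresses toward 0.  Use a CPM
  threshold in that regime.
- The F-test compares mean curves under homoscedastic Gaussian error;
  divergence measures are bounded and heteroscedastic, so p-values are
  approximations (the simulated size stays within its nominal band).
- Ortholog-family PPI projection transfers status, not partner identity;
  projected "with PPI" labels inherit any family-assignment errors.
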