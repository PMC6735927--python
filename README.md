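# dupdiverge

Divergence dynamics of gene duplicates: do duplicates born from whole-genome
duplication (WGD, "block" duplicates found in collinear regions) diverge more
slowly than tandem duplicates from small-scale duplication — and does being
wired into protein–protein interactions (PPIs) constrain divergence further?

The package is for comparative genomicists who have (or want to simulate) a
catalog of duplicate gene pairs with substitution-rate estimates, expression
compendia and a PPI network, and who want to quantify and compare divergence
across duplicate classes the way the dosage-balance literature does.

## The statistics at its core

For a duplicate pair with detection profiles (sets of conditions where each
copy is expressed) and partner sets in a PPI network:

- **Expression divergence**  ED = (C₁ + C₂) / C, where C₁ and C₂ count
  conditions in which only one copy is detected and C the conditions where at
  least one is.  ED = 0: always co-expressed; ED = 1: never detected together.
- **Sequence divergence**  SD = Kₙ, the nonsynonymous substitution rate.
- **Interaction divergence**  ID = 1 − 2·I₁₂/(I₁ + I₂), one minus the
  Sørensen–Dice retention rate of shared partners; computed only for pairs
  where one copy has ≥ 4 partners and the other ≥ 1 (sweepable cutoff).

Divergence is modeled against Ks (a proxy for time since duplication) with an
origin-constrained Michaelis–Menten-type saturation curve y = a·Ks/(b + Ks):
zero divergence at duplication, asymptote *a*, half-saturation *b*.
Duplicate classes are compared with the extra-sum-of-squares F-test (separate
curves per class versus one pooled curve), with 95% bootstrap confidence
bands.  Around this sit the standard supporting analyses: CPM transform and
low-expression filtering, the tandem-gap classification rule, the Ks ∈
[0.05, 5] analysis window, Pearson/Spearman correlation panels,
Fisher/hypergeometric representation tests and flat GO-slim enrichment with
Benjamini–Hochberg correction.

A first-class synthetic-data generator produces multi-species datasets with
known latent curves — realized ED/ID match their latent values up to
rounding by construction — so every estimator is testable without external
downloads.

## Worked example

```sh
python examples/04_saturation_fits.py
```

generates a one-species dataset (150 tandem + 150 block pairs), computes ED
from the count matrix, and fits/compares the curves:

```
fits (a = asymptote, b = half-saturation Ks):
measure scheme group partition        a        b      sse   n
     sd   mode   all    tandem 0.874832 1.121012 0.364298 150
     sd   mode   all     block 0.597191 1.202789 0.286875 150
     ed   mode   all    tandem 0.409898 0.620228 0.288081 150
     ed   mode   all     block 0.265068 0.969465 0.348164 150

nested-model F-tests (separate curves vs one pooled curve):
measure scheme group          f  df1  df2            p
     sd   mode   all 351.970398    2  296 5.688251e-79
     ed   mode   all 211.925697    2  296 7.572364e-58
```

Block duplicates plateau at lower sequence divergence (asymptote 0.60 vs
0.87) and lower expression divergence (0.27 vs 0.41) than tandem duplicates,
and the F-tests reject a single shared curve decisively — the qualitative
signature of stronger constraint on WGD duplicates.  The other examples
cover dataset generation, ED and ID step by step, correlation panels with
GO enrichment, and the one-call pipeline (`examples/06_full_pipeline.py`, or
the `dupdiverge` CLI with stages `simulate | filter | ed | id | project |
fit | correlate | enrich | report | all`).

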