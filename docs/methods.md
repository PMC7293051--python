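# Methods

This note documents the models, conventions, and defaults behind
`gradprof`, and what the synthetic-gradient tests do and do not establish
about real data.

## Profiles and normalization

The carrier type is an entity × fraction matrix of nonnegative abundances
(TPM for RNA, normalized peptide quantity for protein), with physical
fraction numbers kept explicit — RNA data typically span fractions 3–24
and peptide data 3–19, and all cross-kind operations run on the
intersection of fraction indices. Missing cells are imputed as 0 with a
logged warning; negative values are a hard error.

"Relative expression" is defined as **row sum-to-one**: each retained
profile is divided by its raw row sum, making profiles directly comparable
as distributions over the gradient and making fold enrichment readable as
deviation from the uniform profile 1/F. Max-scaling or z-scoring were the
alternatives; sum-to-one was chosen because it preserves the
distributional reading and is idempotent. Rows whose raw sum falls below
an expression floor (default 1 total TPM for RNA, 0 for curated protein
tables) are dropped rather than zero-padded: a profile without signal has
no shape to analyze.

All-pairs correlation between fractions is computed on log2(v+1) raw
abundances by default (configurable), which keeps a few very abundant
transcripts from dominating; a smooth gradient shows correlation decaying
with fraction distance.

## Co-sedimentation clustering

Agglomerative clustering on **correlation distance** (1 − Pearson r) with
**average linkage**, cut at cophenetic distance 0.3 by default, so
within-cluster mean pairwise r stays roughly above 0.7. Correlation
distance matches the scientific object — profile *shape*, not amplitude.
Metric, linkage, and cut are all exposed because no single choice is
canonical for this assay. Determinism: scipy's linkage breaks merge ties
by lowest pair index; cluster ids are assigned by decreasing size (1 =
largest) for stable reporting. The conventional size floor of 20 members
gates clusters before enrichment testing.

## Enrichment

Over-representation is one-sided Fisher's exact (upper hypergeometric
tail P(X ≥ k)), Bonferroni-corrected across the sets tested; fold
enrichment is observed/expected overlap k/(nK/N). The universe is the set
of genes surviving the expression floor (i.e. everything that could have
clustered), not a whole genome.

The ranked-list score is the minimal hypergeometric tail over all
prefixes of the list, with the optimizing prefix recorded and BH q-values
across sets. No correction is applied across prefixes, so the score is
**anti-conservative** relative to an exact min-HG p-value; computing the
exact multi-threshold null is out of scope and the output is labeled
accordingly.

## Gradient statistics

The weighted count `W = Σ_{i=x}^{y} i·n_i` runs on **raw** abundances:
its point is mass-weighted depth, which row normalization would destroy.
Default range x=3, y=24 covers the full RNA gradient; x=1, y=7 fits a
seven-peak polysome profile. Comparisons of W against an external
per-gene scalar (e.g. ribosome-footprint totals) use log2(v+1) by default
because both axes span orders of magnitude; off-diagonal structure is
quantified by signed residuals from the orthogonal (total-least-squares)
line, since neither axis is an error-free predictor.

RNA-vs-encoded-protein correlations are Pearson over the shared fraction
range. Percentile annotation rates rank genes by r with ties broken by
gene id (documented, reproducible); the selection size is ⌊pct·n/100⌋
with a floor of 1.

Per-cluster protein coherence is the median pairwise Pearson r among the
cluster's proteins, exact over all C(k,2) pairs for k ≤ 200 and computed
on a seeded 200-member subsample above that. The null distribution
reassigns protein profiles to genes by uniform random permutation
(default 100 permutations, seeded), recomputes every cluster median, and
pools them; observed medians are compared to the pool by one-sided
Wilcoxon rank-sum.

## Rank-sum testing

One rank-sum implementation serves every comparison in the package. For
small groups (up to ~10 per group) the p-value is exact: full enumeration
of all C(n1+n2, n1) assignments of the pooled mid-ranks, with the
two-sided p counting assignments at least as far from the null mean as
observed. Ties are handled by mid-ranks in both the exact and the
large-sample path; the latter uses the normal approximation with the
standard tie correction on the rank variance.

## RBP-target prediction

An RBP's peptide profile is correlated against every RNA profile (or
against cluster means) over the shared fractions; the correlated set
holds RNAs with r strictly above the threshold (default 0.85, a stringent
near-shape-identity cut). Raising the threshold can only shrink the set.

Hexamer enrichment counts **overlapping** occurrences over all positions
(the standard k-mer convention; total count for an N-free sequence of
length L is exactly L−5, which the code asserts). The enrichment score is
`log2((fg_c+pc)/(fg_tot+4096·pc)) − log2((bg_c+pc)/(bg_tot+4096·pc))`
with pseudocount 1: normalizing by totals means unequal UTR volumes
between foreground and background cannot masquerade as enrichment. The
per-gene alternative (presence/absence counting) is noted but not the
default. Background is all expressed RNAs outside the correlated set. A
hexamer occurrence is "fully conserved" iff all six positions of its
per-base conservation mask are true; the rate is conserved/total
occurrences.

CLIP density is binding sites per unit expression, with expression
summarized as the mean TPM across gradient fractions (configurable);
genes are binned by correlation to the RBP, bins covering [−1, 1], and
every bin pair is compared by two-sided rank-sum with BH correction.

## Isoform ΔΨ screen

An isoform is kept only if its CI width stays **strictly below** 0.2 in
every fraction; events left with fewer than two isoforms are dropped.
ΔΨ is the per-isoform span (max Ψ − min Ψ across fractions), maximized
over the event's isoforms — for two-isoform events, whose Ψs sum to one,
the two spans coincide, so this agrees with any pairwise reading; the
multi-isoform behavior is this package's documented choice. Classes:
strong iff ΔΨ > 0.5, moderate iff 0.25 < ΔΨ ≤ 0.5, else non-regulated —
a ΔΨ exactly at a boundary falls to the lower class because the defining
inequalities are strict and leave the boundary unassigned. Conservation
comparisons test each regulated class against the non-regulated class,
one-sided "greater" by default (the hypothesis is stronger selection on
regulated events), BH across the two comparisons.

## Synthetic gradients

The generator emulates the data-generating structure of a fractionation
experiment at desk scale: 24 fractions with RNA in 3–24 and peptides in
3–19; six compartments of 150 genes each plus 50 unstructured "noise"
genes with private random kernels. Compartment kernels are truncated
Gaussians at successively denser positions plus one center-depleted
(edge-heavy) shape, each mixed with a uniform floor so the compartment
mean peaks 2.5–4-fold over uniform — the modest enrichments characteristic
of velocity sedimentation, not the sharp peaks of equilibrium gradients.
Gene totals are log-uniform over 10^0.5–10^2.5 TPM; measurement noise is
multiplicative log-normal with σ = 0.2 (abundance data are positive and
heavy-tailed).

400 genes carry paired protein profiles. A gene flagged "secreted"
(probability 0.8 inside the designated secretory compartment, 0.1
elsewhere) gets a co-sedimenting protein; all others get the
fraction-reversed kernel (anti-sedimentation), yielding roughly the
80/20 anti/co split and a negative-median RNA–protein correlation
histogram. Five RBP peptide profiles track one compartment each; the
first carries the hexamer TGCATG planted into 60% of its targets' 3′ UTRs
(three copies each) over an i.i.d. ACGT background of 300–600 nt.
Conservation masks are Bernoulli(0.5) per base with planted motif
instances fully conserved. CLIP site counts are Poisson with rate
proportional to mean TPM, scaled by 1 + 2·max(0, ρ) where ρ is the true
shape correlation between gene and RBP kernels — planted targets get the
3× rate and intermediately correlated genes get intermediate rates, so
density should rise monotonically across correlation bins. Ψ events
(20 per class per event type) follow sigmoids across the gradient with
true spans drawn inside each class band, small observation noise
(σ = 0.01), and CI widths of 0.02–0.15; 15% of events are emitted with
wide CIs (0.25–0.5) to exercise the confidence filter. Conservation
scores are N(1,1) for regulated and N(0,1) for non-regulated events.

Every random draw flows through purpose-keyed RNG streams derived from
one seed, so adding an output never perturbs the others and identical
seeds give byte-identical files (floats are written with a fixed %.10g
format).

**What passing tests show — and don't.** Recovery of planted structure
(ARI ≈ 1, perfect enrichment hits, motif rank 1) demonstrates that the
analysis code is correct and well-calibrated under the stated generative
model. Real gradients have correlated noise between neighboring
fractions, compartments of very unequal size and overlap, genes belonging
to multiple microenvironments, UTR composition far from i.i.d., and
batch structure — none of which the generator models. Passing here does
not certify performance on real data; it certifies the implementation.

## Problem sizes

Default simulations (950 genes × 22 fractions, 400 proteins, 5 RBPs,
120 Ψ events) keep the full pipeline under ~3 s and the complete test
suite under ~10 s on one CPU, while leaving every recovery metric far
from its threshold. Power for the conservation comparison is estimated
over 200 seeded replicates at n = 50 per group.

## Known limitations

- The min-HG score is anti-conservative across prefixes (see above).
- The shuffled-assignment null permutes whole protein profiles; it does
  not model fraction-level measurement error in the null.
- Orthogonal-regression residuals assume comparable error scales on both
  log axes.
- `cluster_median_pairwise` subsamples above 200 members; medians are
  stable at that depth but extreme-tail pairs may be missed.
- The CLI's `simulate` stage always uses the generator defaults with the
  run seed; custom generative configs are reachable through the API.
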