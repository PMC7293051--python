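# gradprof

Analysis of RNA and protein co-sedimentation across density gradients.

When a detergent-free tissue lysate is resolved over a continuous sucrose
gradient and each collected fraction is profiled by RNA-seq and mass
spectrometry, every transcript and protein acquires a *sedimentation
profile*: its relative abundance across the ordered fractions, light to
dense. RNAs sharing a subcellular microenvironment — the ER membrane, the
mitochondrion, proteasome-rich cytosol, lipoprotein particles — co-sediment
and share profile shape, so the profiles carry a transcriptome-wide map of
subcellular organization. `gradprof` implements the downstream analysis of
such experiments for computational biologists working from fraction-level
abundance tables (TPM and normalized peptide quantities; alignment and
quantification are upstream of this package):

- **Profiles** — loading/writing entity × fraction TSV matrices,
  row-normalization to relative (sum-to-one) profiles, Pearson correlation
  between profiles and between whole fractions.
- **Co-sedimentation clustering** — agglomerative clustering on correlation
  distance (1 − r) with a dendrogram cut, size filtering, and cluster mean
  profiles.
- **Gene-set enrichment** — one-sided Fisher's exact test per cluster with
  Bonferroni correction, and a threshold-free ranked-list scan using the
  minimal hypergeometric (min-HG) tail over list prefixes with BH q-values;
  per-cluster proportions of externally annotated genes (proximity-labeling
  membership, signal-peptide calls).
- **Gradient statistics** — the weighted-count statistic
  `W = Σ_{i=x}^{y} i·n_i` (n_i = raw abundance in physical fraction i)
  summarizing how deep an entity sits in the gradient; comparison of W
  against external per-gene scalars with orthogonal-regression residuals;
  per-gene RNA-vs-encoded-protein Pearson correlations over shared
  fractions; annotation rates in top/bottom correlation percentiles; and a
  shuffled-assignment permutation null for per-cluster protein coherence.
- **RBP-target prediction** — correlating an RNA-binding protein's peptide
  profile against all RNA profiles or cluster means (default threshold
  r > 0.85), with two sequence-level validations: 3′ UTR hexamer enrichment
  (composition-normalized log2 foreground/background ratios over all 4096
  hexamers, overlapping occurrences counted) with per-hexamer conservation
  rates, and CLIP binding-site density per unit expression stratified by
  correlation bin.
- **Isoform ΔΨ screen** — confidence filtering of per-fraction Ψ estimates
  (CI width < 0.2 in every fraction), the across-gradient span
  ΔΨ = max Ψ − min Ψ, classification into strong (ΔΨ > 0.5) / moderate
  (0.25 < ΔΨ ≤ 0.5) / non-regulated events, and conservation-score
  comparison of regulated vs non-regulated classes by Wilcoxon rank-sum.
- **Synthetic gradients** — a fully seeded generator that plants
  compartments, RNA–protein couplings, RBP targets with a 3′ UTR motif, and
  Ψ switches, and emits every file the loaders consume plus the ground
  truth, so each analysis stage can be scored against a known answer.

## Worked example

```python
import gradprof as gp

ds = gp.simulate(gp.SimulationConfig(seed=1))     # 950 genes, 22 fractions
norm = gp.normalize_profiles(ds.rna, min_total=1.0)
clusters = gp.filter_clusters_by_size(gp.hierarchical_cluster(norm), min_size=20)
print(clusters.n_clusters)
# 6

for cid in clusters.cluster_ids():
    top = gp.fisher_enrichment(clusters.members(cid), ds.gene_sets)[0]
    print(cid, top.set_name, f"fold={top.fold_enrichment:.2f}",
          f"p_adj={top.p_adjusted:.2e}")
# 1 set_cytosolic_rnp fold=5.83 p_adj=2.84e-159
# 2 set_er_secretory fold=6.05 p_adj=2.05e-166
# 3 set_mitochondrion fold=6.05 p_adj=2.05e-166
# 4 set_golgi_vesicle fold=6.09 p_adj=9.15e-168
# 5 set_proteasome fold=6.09 p_adj=9.15e-168
# 6 set_lipoprotein_particle fold=6.33 p_adj=5.04e-178
```

Each of the six size-filtered clusters recovers one planted compartment:
the fold enrichment is observed/expected overlap (~6× because each
compartment holds ~1/6 of the genes), and the Bonferroni-corrected Fisher
p-values are vanishingly small. The same run gives a negative median
RNA-to-encoded-protein correlation (−0.175 across 400 paired genes —
most proteins do not co-sediment with their mRNA) while genes carrying a
signal peptide concentrate in the top correlation percentile (87.5% of
the top 20% vs 0% of the bottom 20%), the signature of co-translational
ER insertion.

## CLI

```bash
gradprof run-all --seed 1 --outdir out/        # simulate + every stage
gradprof isoforms --config cfg.yaml            # one stage, from file artifacts
gradprof validate --config cfg.yaml
```

Stages communicate only through declared TSV/JSON artifacts, every output
carries a parameter header, and reruns with the same seed are
byte-identical.

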