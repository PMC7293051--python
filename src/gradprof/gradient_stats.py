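"""Gradient-level statistics: weighted counts, reference comparisons,
RNA-protein co-sedimentation, and the shuffled-assignment null.

The weighted-count statistic collapses a whole fraction profile into one
scalar, Σ_{i=x}^{y} i·n_i, where n_i is the raw abundance in physical
fraction i.  Because denser material sediments to higher fraction numbers,
the statistic summarizes how deep in the gradient an entity's mass sits,
and is directly comparable to the analogous statistic from polysome
profiling (x=1..7) or to a per-gene ribosome-footprint total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import ClusterAssignment
from .exceptions import ValidationError
from .profiles import FractionProfileMatrix, NormalizedProfileMatrix, pearson
from .stats import wilcoxon_rank_sum

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WeightedCountConfig:
    """Fraction range [x, y] over which the weighted sum runs.

    Defaults cover the full RNA gradient (fractions 3-24); use x=1, y=7
    for a seven-peak polysome profile.
    """

    x: int = 3
    y: int = 24

    def __post_init__(self) -> None:
        if self.x > self.y:
            raise ValidationError("weighted-count range requires x <= y")


@dataclass
class GenePairCorrelation:
    """Pearson r between one gene's RNA profile and its encoded protein's
    profile over their shared fractions."""

    gene_id: str
    r: float
    n_fractions_used: int

    def __post_init__(self) -> None:
        if not (-1.0 <= self.r <= 1.0):
            raise ValidationError(f"{self.gene_id}: r outside [-1,1]")
        if self.n_fractions_used < 3:
            raise ValidationError(f"{self.gene_id}: fewer than 3 shared fractions")


def weighted_counts(m: FractionProfileMatrix, cfg: WeightedCountConfig) -> pd.Series:
    """Per-entity Σ_{i=x}^{y} i·n_i on raw (unnormalized) abundances."""
    have = set(int(f) for f in m.fraction_indices)
    wanted = list(range(cfg.x, cfg.y + 1))
    missing = [f for f in wanted if f not in have]
    if missing:
        raise ValidationError(f"weighted_counts: fractions missing from matrix: {missing}")
    sub = m.subset_fractions(wanted)
    weights = sub.fraction_indices.astype(float)
    vals = sub.values @ weights
    return pd.Series(vals, index=pd.Index(sub.entity_ids, name="entity_id"), name="weighted_count")


def compare_weighted_to_reference(
    weighted: pd.Series, reference: pd.Series, log_transform: bool = True
) -> dict:
    """Correlate per-gene weighted counts against an external per-gene scalar.

    Both vectors are restricted to shared gene ids; with ``log_transform``
    (the default, since both axes span orders of magnitude) values go
    through log2(v+1) first.  Returns the Pearson r plus per-gene signed
    residuals from the orthogonal (total-least-squares) line, which flag
    subsets sitting off the main diagonal — e.g. membrane-associated RNAs
    sedimenting lighter than their ribosome load predicts give negative
    residuals.
    """
    shared = sorted(set(weighted.index) & set(reference.index))
    if len(shared) < 10:
        raise ValidationError(f"only {len(shared)} shared genes; need >= 10")
    w = weighted.loc[shared].to_numpy(dtype=float)
    ref = reference.loc[shared].to_numpy(dtype=float)
    if log_transform:
        w = np.log2(w + 1.0)
        ref = np.log2(ref + 1.0)
    r = pearson(ref, w)
    # orthogonal regression via principal axis of the centered 2-D cloud
    x = ref - ref.mean()
    y = w - w.mean()
    cov = np.cov(np.vstack([x, y]))
    evals, evecs = np.linalg.eigh(cov)
    major = evecs[:, np.argmax(evals)]
    if major[0] < 0:
        major = -major
    slope = major[1] / major[0] if major[0] != 0 else np.inf
    if np.isfinite(slope):
        resid = (y - slope * x) / np.sqrt(1.0 + slope**2)
    else:
        resid = -x
    return {
        "r": r,
        "n": len(shared),
        "slope": float(slope),
        "residuals": pd.Series(resid, index=pd.Index(shared, name="entity_id"), name="residual"),
    }


def rna_protein_correlations(
    rna: NormalizedProfileMatrix,
    prot: NormalizedProfileMatrix,
    id_map: dict[str, str] | None = None,
) -> list[GenePairCorrelation]:
    """Pearson r between each gene's RNA and encoded-protein profiles.

    Profiles are compared over the intersection of fraction indices (the
    proteomic gradient typically stops earlier than the RNA one).
    ``id_map`` maps gene id -> protein id; by default identical ids are
    paired.  Pairs referencing absent ids, or with a constant profile over
    the shared fractions, are skipped with a warning.
    """
    shared_fracs = sorted(set(map(int, rna.fraction_indices)) & set(map(int, prot.fraction_indices)))
    if len(shared_fracs) < 3:
        raise ValidationError("need >= 3 shared fractions between RNA and protein")
    rna_s = rna.subset_fractions(shared_fracs)
    prot_s = prot.subset_fractions(shared_fracs)
    if id_map is None:
        id_map = {g: g for g in rna.entity_ids if g in prot}
    out = []
    skipped = 0
    for gene, pid in sorted(id_map.items()):
        if gene not in rna_s or pid not in prot_s:
            skipped += 1
            continue
        a = rna_s.row(gene)
        b = prot_s.row(pid)
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            skipped += 1
            continue
        out.append(GenePairCorrelation(gene_id=gene, r=pearson(a, b),
                                       n_fractions_used=len(shared_fracs)))
    if skipped:
        logger.warning("rna_protein_correlations: skipped %d unusable pairs", skipped)
    if not out:
        raise ValidationError("no usable RNA-protein pairs")
    return out


def percentile_annotation_rate(
    corrs: list[GenePairCorrelation],
    annotation: dict[str, bool],
    pct: float = 20.0,
) -> dict:
    """Annotation rates in the top and bottom ``pct`` percent of genes by r.

    Used to ask, e.g., how often the most RNA-protein-correlated genes
    carry a signal sequence versus the most anti-correlated ones.  Ties at
    the percentile boundary are broken by gene-id lexicographic order so
    the selection is reproducible.
    """
    if not (0 < pct < 50):
        raise ValidationError("pct must lie in (0, 50)")
    if len(corrs) < 10:
        raise ValidationError("need >= 10 genes")
    ranked = sorted(corrs, key=lambda c: (-c.r, c.gene_id))
    n = len(ranked)
    n_sel = max(1, int(np.floor(pct * n / 100.0)))
    top = ranked[:n_sel]
    bottom = ranked[-n_sel:]
    top_rate = sum(bool(annotation.get(c.gene_id, False)) for c in top) / n_sel
    bottom_rate = sum(bool(annotation.get(c.gene_id, False)) for c in bottom) / n_sel
    return {"top_rate": top_rate, "bottom_rate": bottom_rate, "n_selected": n_sel}


_MAX_EXACT_PAIRWISE = 200


def cluster_median_pairwise(
    m: NormalizedProfileMatrix, members: list[str], seed: int = 0
) -> float:
    """Median Pearson r over all member pairs of one cluster.

    Exact over all C(k,2) pairs for k <= 200; above that a seeded random
    subsample of 200 members is used (documented approximation; the median
    is stable at that depth).
    """
    members = list(members)
    if len(members) < 2:
        raise ValidationError("need >= 2 members for pairwise correlations")
    if len(members) > _MAX_EXACT_PAIRWISE:
        rng = np.random.default_rng(seed)
        members = sorted(rng.choice(sorted(members), size=_MAX_EXACT_PAIRWISE, replace=False))
        logger.info("cluster_median_pairwise: subsampled to %d members", _MAX_EXACT_PAIRWISE)
    rows = np.vstack([m.row(e) for e in members])
    if np.any(np.ptp(rows, axis=1) == 0):
        raise ValidationError("constant member profile; correlation undefined")
    corr = np.corrcoef(rows)
    iu = np.triu_indices(len(members), k=1)
    return float(np.median(corr[iu]))


def shuffled_assignment_null(
    clusters: ClusterAssignment,
    prot: NormalizedProfileMatrix,
    n_perm: int = 100,
    seed: int = 0,
    min_proteins: int = 2,
    _permutation_hook=None,
) -> dict:
    """Null distribution of per-cluster median pairwise protein correlations
    under shuffled RNA-protein assignments.

    Each permutation reassigns protein profiles to genes by a uniform
    random permutation of the proteins present, then recomputes the median
    pairwise correlation for every cluster holding >= ``min_proteins``
    proteins.  The pooled medians form the null against which observed
    cluster coherence is judged.  ``_permutation_hook`` lets tests force a
    specific permutation (e.g. the identity).
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    genes_with_protein = sorted(g for g in clusters.assignments if g in prot)
    if len(genes_with_protein) < min_proteins:
        raise ValidationError("too few clustered genes with protein profiles")
    rng = np.random.default_rng(seed)
    observed = _per_cluster_medians(clusters, prot, dict(zip(genes_with_protein, genes_with_protein)),
                                    min_proteins)
    null_medians: list[float] = []
    n_skipped = 0
    for _ in range(n_perm):
        if _permutation_hook is not None:
            perm = _permutation_hook(genes_with_protein)
        else:
            perm = list(rng.permutation(genes_with_protein))
        mapping = dict(zip(genes_with_protein, perm))
        meds = _per_cluster_medians(clusters, prot, mapping, min_proteins)
        n_skipped += sum(1 for v in meds.values() if v is None)
        null_medians.extend(v for v in meds.values() if v is not None)
    return {
        "observed": {c: v for c, v in observed.items() if v is not None},
        "null": np.asarray(null_medians, dtype=float),
        "n_perm": n_perm,
        "seed": seed,
        "n_cluster_skips": n_skipped,
    }


def _per_cluster_medians(clusters, prot, mapping, min_proteins):
    out = {}
    for cid in clusters.cluster_ids():
        members = [mapping[g] for g in clusters.members(cid) if g in mapping]
        if len(members) < min_proteins:
            out[cid] = None
            continue
        try:
            out[cid] = cluster_median_pairwise(prot, members)
        except ValidationError:
            out[cid] = None
    return out


def observed_vs_null_test(result: dict) -> dict:
    """One-sided rank-sum test that observed cluster medians exceed the
    shuffled-assignment null."""
    obs = np.array(sorted(result["observed"].values()), dtype=float)
    null = np.asarray(result["null"], dtype=float)
    if obs.size == 0 or null.size == 0:
        raise ValidationError("nothing to compare")
    stat, p = wilcoxon_rank_sum(obs, null, alternative="greater")
    return {"statistic": stat, "p": p, "n_observed": int(obs.size), "n_null": int(null.size)}
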