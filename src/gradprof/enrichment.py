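"""Gene-set enrichment for co-sedimentation clusters.

Two flavours are provided, matching the two ways cluster biology is
usually interrogated:

* Fisher's exact over-representation of a query gene list (a cluster)
  against each set, Bonferroni-corrected across sets.
* A threshold-free ranked-list scan: for a list ordered by, e.g., Pearson
  correlation to an RBP profile, the minimal hypergeometric (min-HG) tail
  over all list prefixes, with BH q-values across sets.  The min-HG score
  is reported as an uncorrected tail probability; it is anti-conservative
  across prefixes and is flagged as an approximation in the output.

Also here: the per-cluster annotation-proportion summary used to compare
clusters against external compartment annotations (proximity-labeling
membership, signal-peptide calls).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .clustering import ClusterAssignment
from .exceptions import EmptyResultError, ValidationError
from .stats import bh_adjust, bonferroni_adjust

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets over a universe; members outside the universe are
    dropped at construction (the usual intersection step)."""

    sets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValidationError("empty gene universe")
        self.universe = set(self.universe)
        clean = {}
        for name, members in self.sets.items():
            inter = set(members) & self.universe
            if not inter:
                logger.warning("gene set %r has no members in universe; dropped", name)
                continue
            clean[name] = inter
        if not clean:
            raise ValidationError("no gene set overlaps the universe")
        self.sets = clean

    @classmethod
    def from_gmt(cls, path, universe) -> "GeneSetCollection":
        """Read GMT: one set per line, tab-separated name, description, members."""
        sets = {}
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValidationError(f"{path}:{ln}: GMT line needs name, description, members")
                sets[parts[0]] = set(p for p in parts[2:] if p)
        return cls(sets=sets, universe=set(universe))

    def write_gmt(self, path, descriptions: dict[str, str] | None = None) -> None:
        descriptions = descriptions or {}
        with open(path, "w") as fh:
            for name in sorted(self.sets):
                desc = descriptions.get(name, "na")
                members = "\t".join(sorted(self.sets[name]))
                fh.write(f"{name}\t{desc}\t{members}\n")


@dataclass
class EnrichmentRecord:
    set_name: str
    k: int          # overlap
    n: int          # query size
    K: int          # set size
    N: int          # universe size
    fold_enrichment: float
    p_raw: float
    p_adjusted: float
    method: str
    prefix: int | None = None   # optimizing prefix length (ranked method only)

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.n, self.K)):
            raise ValidationError("overlap k out of range")
        if not (0.0 <= self.p_raw <= 1.0 and 0.0 <= self.p_adjusted <= 1.0):
            raise ValidationError("p-values must lie in [0,1]")


def records_to_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set": r.set_name, "k": r.k, "n": r.n, "K": r.K, "N": r.N,
                "fold": r.fold_enrichment, "p_raw": r.p_raw,
                "p_adj": r.p_adjusted, "method": r.method, "prefix": r.prefix,
            }
            for r in records
        ]
    )


def fisher_enrichment(
    query, sets: GeneSetCollection, alpha: float = 0.05
) -> list[EnrichmentRecord]:
    """One-sided (over-representation) Fisher's exact test per set, with
    Bonferroni correction across the sets tested.

    The p-value is the upper hypergeometric tail P(X >= k) with X ~
    HG(N, K, n); fold enrichment is observed/expected overlap, k/(nK/N).
    Records are sorted by raw p, ties by set name.
    """
    query = set(query)
    outside = query - sets.universe
    if outside:
        logger.warning("fisher_enrichment: %d query ids outside universe dropped", len(outside))
    query &= sets.universe
    if not query:
        raise EmptyResultError("query is empty after intersecting with universe")
    N = len(sets.universe)
    n = len(query)
    recs = []
    names = sorted(sets.sets)
    m = len(names)
    raw = []
    for name in names:
        members = sets.sets[name]
        K = len(members)
        k = len(query & members)
        # upper tail including k itself
        p = float(hypergeom.sf(k - 1, N, K, n))
        raw.append((name, k, K, p))
    padj = bonferroni_adjust([p for _, _, _, p in raw])
    for (name, k, K, p), pa in zip(raw, padj):
        fold = k / (n * K / N)
        recs.append(
            EnrichmentRecord(set_name=name, k=k, n=n, K=K, N=N,
                             fold_enrichment=fold, p_raw=p, p_adjusted=float(pa),
                             method="fisher_bonferroni")
        )
    recs.sort(key=lambda r: (r.p_raw, r.set_name))
    return recs


def ranked_enrichment(ranked, sets: GeneSetCollection) -> list[EnrichmentRecord]:
    """Minimal hypergeometric tail over all prefixes of a ranked gene list.

    For each set, every prefix length b of the list is treated as a
    candidate threshold; the reported score is the smallest upper-tail
    hypergeometric p over b, with the optimizing prefix recorded.  BH
    q-values are computed across sets; no correction is applied across
    prefixes, so the score is an anti-conservative approximation to an
    exact min-HG p-value.
    """
    ranked = list(ranked)
    if len(ranked) != len(set(ranked)):
        raise ValidationError("ranked list contains duplicates")
    if not set(ranked) <= sets.universe:
        raise ValidationError("ranked list must be a subset of the universe")
    N = len(ranked)
    if N < 2:
        raise ValidationError("ranked list too short")
    recs = []
    raws = []
    for name in sorted(sets.sets):
        members = sets.sets[name]
        member_mask = np.array([g in members for g in ranked])
        K = int(member_mask.sum())
        if K == 0:
            logger.warning("ranked_enrichment: set %r has no members in list; skipped", name)
            continue
        cum_k = np.cumsum(member_mask)
        b = np.arange(1, N + 1)
        tails = hypergeom.sf(cum_k - 1, N, K, b)
        j = int(np.argmin(tails))
        raws.append((name, int(cum_k[j]), int(b[j]), K, float(tails[j])))
    if not raws:
        raise EmptyResultError("no set overlaps the ranked list")
    q = bh_adjust([p for *_, p in raws])
    for (name, k, b, K, p), qv in zip(raws, q):
        fold = k / (b * K / N) if b else 0.0
        recs.append(
            EnrichmentRecord(set_name=name, k=k, n=b, K=K, N=N,
                             fold_enrichment=fold, p_raw=p, p_adjusted=float(qv),
                             method="min_hg_bh", prefix=b)
        )
    recs.sort(key=lambda r: (r.p_raw, r.set_name))
    return recs


def cluster_annotation_scatter(
    a: ClusterAssignment,
    annotations: dict[str, dict[str, bool]],
    enriched_flags: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Per-cluster proportions of externally annotated genes.

    ``annotations`` maps gene -> {'in_apex': bool, 'has_signal': bool}
    (proximity-labeling membership and signal-peptide call); genes without
    an entry count as False with a warning.  ``enriched_flags`` optionally
    labels clusters as 'target_go' / 'other_go' / 'none' for plotting.
    Returns a tidy frame ready to write as TSV.
    """
    enriched_flags = enriched_flags or {}
    n_missing = sum(1 for g in a.assignments if g not in annotations)
    if n_missing:
        logger.warning("cluster_annotation_scatter: %d genes without annotations "
                       "counted as un-annotated", n_missing)
    rows = []
    for cid in a.cluster_ids():
        members = a.members(cid)
        apex = sum(bool(annotations.get(g, {}).get("in_apex", False)) for g in members)
        sig = sum(bool(annotations.get(g, {}).get("has_signal", False)) for g in members)
        rows.append(
            {
                "cluster_id": cid,
                "n_genes": len(members),
                "proportion_apex": apex / len(members),
                "proportion_signal": sig / len(members),
                "flag": enriched_flags.get(cid, "none"),
            }
        )
    return pd.DataFrame(rows)
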