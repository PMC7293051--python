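"""Co-sedimentation clustering of normalized gradient profiles.

RNAs that share a microenvironment sediment alike, so agglomerative
clustering on profile-shape similarity (correlation distance, average
linkage by default) groups them into co-sedimentation clusters.  Cluster
ids are assigned by decreasing size (1 = largest) for stable reporting.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .exceptions import ValidationError
from .profiles import FractionProfileMatrix, NormalizedProfileMatrix

logger = logging.getLogger(__name__)

METRICS = ("correlation", "euclidean")
LINKAGES = ("average", "complete", "ward")
CUT_CRITERIA = ("distance", "n_clusters")


@dataclass
class ClusterAssignment:
    """Mapping entity -> cluster id (contiguous positive ints) plus the
    clustering parameters that produced it."""

    assignments: dict[str, int]
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = set(self.assignments.values())
        if not ids:
            raise ValidationError("empty cluster assignment")
        if min(ids) < 1:
            raise ValidationError("cluster ids must be positive")

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignments.values()))

    def members(self, cluster_id: int) -> list[str]:
        return sorted(e for e, c in self.assignments.items() if c == cluster_id)

    def cluster_ids(self) -> list[int]:
        return sorted(set(self.assignments.values()))

    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for c in self.assignments.values():
            out[c] = out.get(c, 0) + 1
        return out

    def write(self, path, sidecar_path=None) -> None:
        with open(path, "w") as fh:
            fh.write("entity_id\tcluster_id\n")
            for e in sorted(self.assignments):
                fh.write(f"{e}\t{self.assignments[e]}\n")
        if sidecar_path is not None:
            with open(sidecar_path, "w") as fh:
                json.dump(self.parameters, fh, indent=2, sort_keys=True)
                fh.write("\n")


@dataclass
class ClusterProfile:
    """Mean normalized profile of one cluster's members."""

    cluster_id: int
    mean_profile: np.ndarray
    member_count: int

    def __post_init__(self) -> None:
        self.mean_profile = np.asarray(self.mean_profile, dtype=float)
        if not np.isclose(self.mean_profile.sum(), 1.0, atol=1e-9):
            raise ValidationError(
                f"cluster {self.cluster_id}: mean profile does not sum to 1"
            )


def hierarchical_cluster(
    m: NormalizedProfileMatrix,
    metric: str = "correlation",
    method: str = "average",
    cut_criterion: str = "distance",
    cut_value: float = 0.3,
    seed: int = 0,
) -> ClusterAssignment:
    """Agglomerative clustering of profile rows into co-sedimentation groups.

    ``cut_criterion='distance'`` cuts the dendrogram at cophenetic distance
    ``cut_value`` (with correlation distance, 0.3 keeps within-cluster mean
    pairwise r roughly above 0.7); ``'n_clusters'`` asks for a fixed count.
    Deterministic for fixed inputs; scipy breaks merge ties by lowest pair
    index.  ``seed`` is recorded for provenance only — the algorithm itself
    is deterministic.
    """
    if metric not in METRICS:
        raise ValidationError(f"metric must be one of {METRICS}")
    if method not in LINKAGES:
        raise ValidationError(f"linkage must be one of {LINKAGES}")
    if cut_criterion not in CUT_CRITERIA:
        raise ValidationError(f"cut criterion must be one of {CUT_CRITERIA}")
    if m.n_entities < 2:
        raise ValidationError("need >=2 entities to cluster")
    if metric == "correlation":
        const = np.nonzero(np.ptp(m.values, axis=1) == 0)[0]
        if const.size:
            bad = [m.entity_ids[i] for i in const[:10]]
            raise ValidationError(
                f"constant rows have no correlation distance: {bad}"
            )
    dist = pdist(m.values, metric=metric)
    link = linkage(dist, method=method)
    if cut_criterion == "distance":
        labels = fcluster(link, t=float(cut_value), criterion="distance")
    else:
        k = int(cut_value)
        if k < 1 or k > m.n_entities:
            raise ValidationError("n_clusters must be in [1, n_entities]")
        labels = fcluster(link, t=k, criterion="maxclust")
    labels = _relabel_by_size(labels, m.entity_ids)
    params = {
        "metric": metric,
        "linkage": method,
        "cut_criterion": cut_criterion,
        "cut_value": float(cut_value),
        "seed": int(seed),
        "n_entities": m.n_entities,
        "n_clusters": int(labels.max()),
    }
    assignments = {e: int(c) for e, c in zip(m.entity_ids, labels)}
    return ClusterAssignment(assignments=assignments, parameters=params)


def _relabel_by_size(labels: np.ndarray, entity_ids) -> np.ndarray:
    """Rank clusters by decreasing size; ties by smallest first-member index."""
    uniq, counts = np.unique(labels, return_counts=True)
    first_idx = {c: int(np.argmax(labels == c)) for c in uniq}
    order = sorted(uniq, key=lambda c: (-counts[list(uniq).index(c)], first_idx[c]))
    remap = {old: new for new, old in enumerate(order, start=1)}
    return np.array([remap[c] for c in labels], dtype=int)


def filter_clusters_by_size(a: ClusterAssignment, min_size: int = 20) -> ClusterAssignment:
    """Keep clusters with at least ``min_size`` members (default 20, the
    conventional floor for enrichment testing on cluster gene lists)."""
    if min_size < 1:
        raise ValidationError("min_size must be >= 1")
    sizes = a.sizes()
    keep = {c for c, s in sizes.items() if s >= min_size}
    logger.info(
        "filter_clusters_by_size: retained %d/%d clusters (min_size=%d)",
        len(keep), len(sizes), min_size,
    )
    assignments = {e: c for e, c in a.assignments.items() if c in keep}
    params = dict(a.parameters)
    params.update(min_size=min_size, n_clusters_retained=len(keep),
                  n_clusters_dropped=len(sizes) - len(keep))
    if not assignments:
        logger.warning("filter_clusters_by_size: no cluster reached min_size=%d", min_size)
        return _empty_assignment(params)
    return ClusterAssignment(assignments=assignments, parameters=params)


def _empty_assignment(params: dict) -> ClusterAssignment:
    obj = ClusterAssignment.__new__(ClusterAssignment)
    obj.assignments = {}
    obj.parameters = params
    return obj


def cluster_mean_profiles(
    a: ClusterAssignment, m: NormalizedProfileMatrix
) -> list[ClusterProfile]:
    """Arithmetic mean of member rows per cluster, ordered by cluster id.

    Means of sum-to-one rows themselves sum to one, so a cluster mean is
    directly comparable to any single normalized profile.
    """
    missing = [e for e in a.assignments if e not in m]
    if missing:
        raise ValidationError(f"clustered entities missing from matrix: {missing[:5]}")
    out = []
    for cid in a.cluster_ids():
        members = a.members(cid)
        rows = np.vstack([m.row(e) for e in members])
        out.append(ClusterProfile(cluster_id=cid, mean_profile=rows.mean(axis=0),
                                  member_count=len(members)))
    return out
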