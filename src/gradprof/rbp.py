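"""RBP-target prediction from co-sedimentation, with sequence-level checks.

An RNA-binding protein that escorts its targets through the cell should
co-sediment with them, so correlating an RBP's peptide profile against
every RNA profile (or against cluster mean profiles) nominates candidate
targets.  Two orthogonal validations are provided: enrichment of 3' UTR
hexamers in the correlated set versus background (binding motifs should
surface), and CLIP binding-site density stratified by correlation bin
(better-correlated RNAs should carry more sites per unit expression).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import EmptyResultError, UndefinedCorrelationError, ValidationError
from .profiles import FractionProfileMatrix, NormalizedProfileMatrix, pearson
from .stats import bh_adjust, wilcoxon_rank_sum

logger = logging.getLogger(__name__)

HEXAMER_K = 6
N_HEXAMERS = 4 ** HEXAMER_K

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": -1}
_POWERS = 4 ** np.arange(HEXAMER_K - 1, -1, -1)


@dataclass
class RBPCorrelationResult:
    """Per-RNA correlations to one RBP's peptide profile, plus the set of
    RNAs exceeding the correlation threshold."""

    rbp_id: str
    correlations: pd.Series          # RNA id -> Pearson r
    threshold: float
    correlated_set: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        expected = set(self.correlations.index[self.correlations > self.threshold])
        if self.correlated_set != expected:
            raise ValidationError("correlated_set inconsistent with threshold")


@dataclass
class HexamerStats:
    hexamer: str
    fg_count: int
    bg_count: int
    log2_ratio: float
    conservation_rate: float | None = None

    def __post_init__(self) -> None:
        if self.fg_count < 0 or self.bg_count < 0:
            raise ValidationError("negative hexamer count")


# -- profile correlation ------------------------------------------------------


def correlate_rbp_to_rnas(
    rbp_id: str,
    rbp_profile: FractionProfileMatrix | tuple,
    rna: NormalizedProfileMatrix,
    threshold: float = 0.85,
) -> RBPCorrelationResult:
    """Correlate one RBP peptide profile against every RNA profile.

    The RBP profile may come as a (fraction_indices, values) pair or as a
    single-row matrix.  Correlations run over the intersection of fraction
    indices (peptide data usually stop at a lighter fraction than RNA);
    at least 3 shared fractions are required.  The correlated set holds
    RNAs with r strictly greater than ``threshold`` (default 0.85, a
    stringent cut that in practice selects near-identical shapes).
    """
    frac, vals = _as_profile(rbp_profile)
    shared = sorted(set(map(int, frac)) & set(map(int, rna.fraction_indices)))
    if len(shared) < 3:
        raise ValidationError("need >= 3 shared fractions between RBP and RNA")
    keep = [i for i, f in enumerate(frac) if int(f) in set(shared)]
    rbp_vec = np.asarray(vals, dtype=float)[keep]
    if np.ptp(rbp_vec) == 0:
        raise UndefinedCorrelationError(f"RBP {rbp_id}: constant peptide profile")
    rna_s = rna.subset_fractions(shared)
    rs = {}
    for gene in rna_s.entity_ids:
        row = rna_s.row(gene)
        if np.ptp(row) == 0:
            continue
        rs[gene] = pearson(rbp_vec, row)
    corr = pd.Series(rs, name=rbp_id).sort_index()
    return RBPCorrelationResult(
        rbp_id=rbp_id,
        correlations=corr,
        threshold=float(threshold),
        correlated_set=set(corr.index[corr > threshold]),
    )


def _as_profile(p):
    if isinstance(p, FractionProfileMatrix):
        if p.n_entities != 1:
            raise ValidationError("expected a single-row profile")
        return p.fraction_indices, p.values[0]
    frac, vals = p
    return np.asarray(frac, dtype=int), np.asarray(vals, dtype=float)


def correlate_rbps_to_clusters(
    rbp_matrix: FractionProfileMatrix,
    cluster_profiles,
    cluster_fractions,
    threshold: float = 0.85,
) -> pd.DataFrame:
    """All (RBP, cluster) pairs with peptide-to-cluster-mean r > threshold.

    ``cluster_profiles`` is the list of ClusterProfile from
    ``cluster_mean_profiles``; ``cluster_fractions`` the fraction indices
    those means are defined over.  Each RBP may match several clusters;
    the strongest match per RBP is flagged ``best``.
    """
    cluster_fractions = np.asarray(cluster_fractions, dtype=int)
    shared = sorted(set(map(int, rbp_matrix.fraction_indices)) & set(map(int, cluster_fractions)))
    if len(shared) < 3:
        raise ValidationError("need >= 3 shared fractions between RBPs and cluster means")
    col_of = {int(f): j for j, f in enumerate(cluster_fractions)}
    cols = [col_of[f] for f in shared]
    rbp_s = rbp_matrix.subset_fractions(shared)
    rows = []
    for rbp_id in rbp_s.entity_ids:
        vec = rbp_s.row(rbp_id)
        if np.ptp(vec) == 0:
            logger.warning("RBP %s constant over shared fractions; skipped", rbp_id)
            continue
        matches = []
        for cp in cluster_profiles:
            mean = np.asarray(cp.mean_profile, dtype=float)[cols]
            if np.ptp(mean) == 0:
                continue
            r = pearson(vec, mean)
            matches.append((cp.cluster_id, r))
        above = [(c, r) for c, r in matches if r > threshold]
        if not above:
            continue
        best_cluster = max(above, key=lambda t: t[1])[0]
        for c, r in sorted(above):
            rows.append({"rbp": rbp_id, "cluster": c, "r": r, "best": c == best_cluster})
    return pd.DataFrame(rows, columns=["rbp", "cluster", "r", "best"])


# -- hexamer machinery --------------------------------------------------------


def encode_sequence(seq: str) -> np.ndarray:
    """Map an ACGTN string to integer codes (N and anything else -> -1)."""
    return np.array([_BASE_CODE.get(b, -1) for b in seq.upper()], dtype=np.int64)


def hexamer_index(hexamer: str) -> int:
    codes = encode_sequence(hexamer)
    if codes.size != HEXAMER_K or (codes < 0).any():
        raise ValidationError(f"not a valid ACGT hexamer: {hexamer!r}")
    return int(codes @ _POWERS)


def index_to_hexamer(idx: int) -> str:
    if not (0 <= idx < N_HEXAMERS):
        raise ValidationError("hexamer index out of range")
    bases = "ACGT"
    out = []
    for _ in range(HEXAMER_K):
        out.append(bases[idx % 4])
        idx //= 4
    return "".join(reversed(out))


def hexamer_counts(sequences) -> np.ndarray:
    """Occurrence counts of all 4096 hexamers over a sequence collection.

    Overlapping occurrences are counted; any window containing an N (or
    other non-ACGT character) is skipped.  For an N-free sequence of
    length L the window counts total L-5.
    """
    counts = np.zeros(N_HEXAMERS, dtype=np.int64)
    for seq in sequences:
        codes = encode_sequence(seq)
        if codes.size < HEXAMER_K:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(codes, HEXAMER_K)
        valid = (windows >= 0).all(axis=1)
        if not valid.any():
            continue
        idx = windows[valid] @ _POWERS
        counts += np.bincount(idx, minlength=N_HEXAMERS)
    return counts


def hexamer_enrichment(fg_utrs, bg_utrs, pseudocount: float = 1.0) -> list[HexamerStats]:
    """Foreground-vs-background hexamer frequency enrichment.

    log2_ratio compares *composition-normalized* frequencies,
    log2((fg_c+pc)/(fg_total+4096*pc)) - log2((bg_c+pc)/(bg_total+4096*pc)),
    so differing total UTR lengths between the two sets cannot masquerade
    as motif enrichment.  Returned sorted by descending log2_ratio, ties
    by hexamer string.
    """
    fg_utrs = list(fg_utrs)
    bg_utrs = list(bg_utrs)
    if not fg_utrs:
        raise EmptyResultError("empty foreground sequence set")
    fg = hexamer_counts(fg_utrs)
    bg = hexamer_counts(bg_utrs)
    fg_total = int(fg.sum())
    bg_total = int(bg.sum())
    log2_fg = np.log2(fg + pseudocount) - np.log2(fg_total + N_HEXAMERS * pseudocount)
    log2_bg = np.log2(bg + pseudocount) - np.log2(bg_total + N_HEXAMERS * pseudocount)
    ratio = log2_fg - log2_bg
    order = sorted(range(N_HEXAMERS), key=lambda i: (-ratio[i], index_to_hexamer(i)))
    return [
        HexamerStats(hexamer=index_to_hexamer(i), fg_count=int(fg[i]),
                     bg_count=int(bg[i]), log2_ratio=float(ratio[i]))
        for i in order
    ]


def hexamer_conservation_rate(utrs, masks) -> dict[str, float]:
    """Fraction of each hexamer's occurrences that are fully conserved.

    ``masks`` holds one boolean per-base conservation track per sequence
    (True = conserved in the multi-species alignment); an occurrence is
    fully conserved iff all six of its positions are True.  Only hexamers
    with at least one occurrence appear in the result.
    """
    utrs = list(utrs)
    masks = [np.asarray(m, dtype=bool) for m in masks]
    if len(utrs) != len(masks):
        raise ValidationError("need one conservation mask per sequence")
    totals = np.zeros(N_HEXAMERS, dtype=np.int64)
    conserved = np.zeros(N_HEXAMERS, dtype=np.int64)
    for rec_no, (seq, mask) in enumerate(zip(utrs, masks)):
        if len(seq) != mask.size:
            raise ValidationError(f"record {rec_no}: mask length {mask.size} != "
                                  f"sequence length {len(seq)}")
        codes = encode_sequence(seq)
        if codes.size < HEXAMER_K:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(codes, HEXAMER_K)
        valid = (windows >= 0).all(axis=1)
        if not valid.any():
            continue
        idx = windows[valid] @ _POWERS
        mwin = np.lib.stride_tricks.sliding_window_view(mask, HEXAMER_K)
        full = mwin[valid].all(axis=1)
        totals += np.bincount(idx, minlength=N_HEXAMERS)
        conserved += np.bincount(idx[full], minlength=N_HEXAMERS)
    out = {}
    for i in np.nonzero(totals)[0]:
        out[index_to_hexamer(int(i))] = float(conserved[i] / totals[i])
    return out


# -- CLIP density -------------------------------------------------------------


def clip_density_by_bin(
    clip_sites: dict[str, float],
    expression: dict[str, float],
    corrs: dict[str, float],
    bin_edges=( -1.0, 0.0, 0.5, 0.85, 1.0),
) -> dict:
    """CLIP binding-site density per correlation bin, with pairwise tests.

    Density = sites / expression summary per gene (sites per unit TPM);
    genes are grouped by their correlation to the RBP into the half-open
    bins (edges[i], edges[i+1]], the lowest bin closed below.  Every bin
    pair is compared by two-sided Wilcoxon rank-sum with BH correction
    across pairs.  Empty bins are excluded from testing with a warning.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValidationError("bin_edges must be strictly increasing")
    if edges[0] > -1.0 or edges[-1] < 1.0:
        raise ValidationError("bins must cover [-1, 1]")
    genes = sorted(set(clip_sites) & set(expression) & set(corrs))
    densities: dict[int, list[float]] = {i: [] for i in range(edges.size - 1)}
    for g in genes:
        expr = expression[g]
        if expr <= 0:
            logger.warning("gene %s has non-positive expression; skipped", g)
            continue
        r = corrs[g]
        b = int(np.clip(np.searchsorted(edges, r, side="left") - 1, 0, edges.size - 2))
        densities[b].append(clip_sites[g] / expr)
    occupied = [i for i in range(edges.size - 1) if densities[i]]
    empty = [i for i in range(edges.size - 1) if not densities[i]]
    if empty:
        logger.warning("clip_density_by_bin: empty bins excluded from tests: %s", empty)
    tests = []
    for a_i in range(len(occupied)):
        for b_i in range(a_i + 1, len(occupied)):
            i, j = occupied[a_i], occupied[b_i]
            _, p = wilcoxon_rank_sum(densities[i], densities[j], alternative="two-sided")
            tests.append({"bin_low": i, "bin_high": j, "p_raw": p})
    if tests:
        q = bh_adjust([t["p_raw"] for t in tests])
        for t, qv in zip(tests, q):
            t["p_adj"] = float(qv)
    return {
        "bin_edges": edges,
        "densities": {i: np.asarray(v, dtype=float) for i, v in densities.items() if v},
        "medians": {i: float(np.median(v)) for i, v in densities.items() if v},
        "tests": tests,
    }
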