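"""Seeded synthetic gradient datasets with planted ground truth.

The generator emulates the structure of a density-gradient fractionation
experiment on tissue: 24 collected fractions with usable RNA in fractions
3-24 and usable peptide data in fractions 3-19; genes grouped into
compartments whose sedimentation kernels are unimodal bumps or
edge-monotone shapes, mixed with a uniform floor so compartment mean
profiles peak at most ~4-fold over uniform; multiplicative log-normal
measurement noise; proteins that either co-sediment with their RNA
(secreted/membrane genes) or anti-sediment (everything else); RBP peptide
profiles tracking one compartment each, one with a hexamer planted into
its targets' 3' UTRs; CLIP site counts scaling with true RBP affinity;
and isoform Ψ tables with configured across-gradient switches.

Everything derives from one integer seed through purpose-keyed RNG
streams, so adding an output never perturbs the others and identical
seeds give byte-identical files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .profiles import FractionProfileMatrix, write_profile_table
from .enrichment import GeneSetCollection

logger = logging.getLogger(__name__)

# purpose keys for independent RNG streams
_STREAMS = {
    "gene_scales": 11, "gene_noise": 12, "noise_kernels": 13,
    "coupling": 21, "protein_noise": 22,
    "rbp_noise": 31, "utr": 32, "mask": 33, "clip": 34,
    "psi": 41, "conservation": 42, "decoy_sets": 51, "annotations": 52,
}

COUPLING_CO = "co_sediment"
COUPLING_ANTI = "anti"
COUPLING_INDEPENDENT = "independent"


@dataclass(frozen=True)
class KernelSpec:
    """One compartment's sedimentation kernel.

    ``kind`` is 'gaussian' (bump at ``center`` with ``width``),
    'light_edge'/'dense_edge' (geometric decay from the light or dense end
    with decay ``rate``), or 'depleted_center' (mass pushed to both edges,
    the shape of lipoprotein-particle-like material depleted mid-gradient).
    ``target_fold`` sets the compartment's peak enrichment over uniform
    after mixing with the uniform floor.
    """

    name: str
    kind: str = "gaussian"
    center: float = 10.0
    width: float = 2.5
    rate: float = 0.85
    target_fold: float = 3.0


DEFAULT_KERNELS = (
    KernelSpec("er_secretory", "gaussian", center=6.0, width=2.5, target_fold=3.5),
    KernelSpec("golgi_vesicle", "gaussian", center=10.0, width=2.5, target_fold=3.0),
    KernelSpec("cytosolic_rnp", "gaussian", center=14.0, width=2.5, target_fold=3.0),
    KernelSpec("proteasome", "gaussian", center=18.0, width=2.5, target_fold=3.0),
    KernelSpec("mitochondrion", "gaussian", center=22.0, width=2.5, target_fold=3.5),
    KernelSpec("lipoprotein_particle", "depleted_center", target_fold=2.5),
)


@dataclass(frozen=True)
class RBPSpec:
    """An RBP whose peptide profile tracks one compartment; optionally a
    hexamer planted into its target genes' 3' UTRs."""

    name: str
    compartment: int
    hexamer: str | None = None
    plant_rate: float = 0.6
    copies: int = 3


DEFAULT_RBPS = (
    RBPSpec("rbp_er", 0, hexamer="TGCATG", plant_rate=0.6, copies=3),
    RBPSpec("rbp_golgi", 1),
    RBPSpec("rbp_rnp", 2),
    RBPSpec("rbp_proteasome", 3),
    RBPSpec("rbp_mito", 4),
)


@dataclass(frozen=True)
class PsiSwitchSpec:
    """Counts of isoform events per ΔΨ class (per event type) and the true
    ΔΨ ranges the classes are drawn from."""

    n_per_class: int = 20
    strong_range: tuple = (0.55, 0.92)
    moderate_range: tuple = (0.30, 0.47)
    non_range: tuple = (0.03, 0.20)
    psi_noise_sd: float = 0.01
    ci_width_range: tuple = (0.02, 0.15)
    low_conf_fraction: float = 0.15
    low_conf_width_range: tuple = (0.25, 0.5)


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 1
    rna_fractions: tuple = tuple(range(3, 25))
    protein_fractions: tuple = tuple(range(3, 20))
    kernels: tuple = DEFAULT_KERNELS
    genes_per_compartment: int = 150
    n_noise_genes: int = 50
    noise_sigma: float = 0.2
    tpm_log10_range: tuple = (0.5, 2.5)
    secreted_compartment: int = 0
    secreted_prob_in: float = 0.8
    secreted_prob_out: float = 0.1
    apex_prob_in: float = 0.8
    apex_prob_out: float = 0.1
    n_paired_genes: int = 400
    independent_coupling_fraction: float = 0.0
    rbp_specs: tuple = DEFAULT_RBPS
    utr_length_range: tuple = (300, 600)
    conservation_p: float = 0.5
    clip_rate_per_tpm: float = 2.0
    clip_boost: float = 3.0
    psi_spec: PsiSwitchSpec = field(default_factory=PsiSwitchSpec)
    conservation_shift: float = 1.0
    n_decoy_sets: int = 10
    decoy_set_size: int = 100

    def validate(self) -> None:
        if self.genes_per_compartment < 1:
            raise ValidationError("genes_per_compartment must be >= 1")
        if not self.kernels:
            raise ValidationError("need at least one compartment kernel")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        for p in (self.secreted_prob_in, self.secreted_prob_out,
                  self.apex_prob_in, self.apex_prob_out, self.conservation_p):
            if not (0.0 <= p <= 1.0):
                raise ValidationError("probabilities must lie in [0,1]")
        if not set(self.protein_fractions) <= set(self.rna_fractions):
            raise ValidationError("protein fractions must be a subset of RNA fractions")
        for spec in self.rbp_specs:
            if not (0 <= spec.compartment < len(self.kernels)):
                raise ValidationError(f"RBP {spec.name}: compartment out of range")


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted alongside the simulated data."""

    gene_compartment: dict[str, str]        # gene -> compartment name ('noise' for none)
    gene_coupling: dict[str, str]           # paired gene -> coupling mode
    gene_secreted: dict[str, bool]
    rbp_targets: dict[str, list[str]]       # rbp -> target gene ids
    rbp_hexamer: dict[str, str]             # rbp -> planted hexamer (if any)
    rbp_compartment: dict[str, str]         # rbp -> tracked compartment name
    event_class: dict[str, str]             # event -> true ΔΨ class
    event_excluded: dict[str, bool]         # event -> planted as low-confidence

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    rna: FractionProfileMatrix
    protein: FractionProfileMatrix
    rbp_peptides: FractionProfileMatrix
    utrs: dict[str, str]
    masks: dict[str, np.ndarray]
    clip_counts: dict[str, int]
    psi_table: pd.DataFrame
    gene_sets: GeneSetCollection
    annotations: dict[str, dict[str, bool]]
    conservation_scores: dict[str, float]
    truth: SyntheticTruth


# -- kernels -----------------------------------------------------------------


def make_kernel(spec: KernelSpec, fractions) -> np.ndarray:
    """Nonnegative kernel over the fraction axis, summing to one."""
    f = np.asarray(fractions, dtype=float)
    if spec.kind == "gaussian":
        k = np.exp(-0.5 * ((f - spec.center) / spec.width) ** 2)
    elif spec.kind == "light_edge":
        k = spec.rate ** (f - f.min())
    elif spec.kind == "dense_edge":
        k = spec.rate ** (f.max() - f)
    elif spec.kind == "depleted_center":
        mid = (f.min() + f.max()) / 2.0
        k = ((f - mid) / (f.max() - mid)) ** 2
    else:
        raise ValidationError(f"unknown kernel kind {spec.kind!r}")
    return k / k.sum()


def mixture_shape(kernel: np.ndarray, target_fold: float) -> np.ndarray:
    """Mix a kernel with the uniform floor so the peak sits at
    ``target_fold`` times uniform (capped by the pure kernel's own peak)."""
    n = kernel.size
    peak_fold = kernel.max() * n
    if peak_fold <= 1.0:
        return np.full(n, 1.0 / n)
    alpha = min(1.0, (target_fold - 1.0) / (peak_fold - 1.0))
    shape = alpha * kernel + (1.0 - alpha) / n
    return shape / shape.sum()


def _rng(config: SimulationConfig, purpose: str) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), _STREAMS[purpose]])


# -- generation --------------------------------------------------------------


def simulate(config: SimulationConfig = SimulationConfig()) -> SimulatedDataset:
    """Generate a full synthetic gradient dataset with ground truth."""
    config.validate()
    rna_f = np.array(config.rna_fractions, dtype=int)
    prot_f = np.array(config.protein_fractions, dtype=int)
    n_rf = rna_f.size
    comp_names = [k.name for k in config.kernels]
    shapes = {i: mixture_shape(make_kernel(k, rna_f), k.target_fold)
              for i, k in enumerate(config.kernels)}

    # -- genes and RNA matrix
    gene_ids: list[str] = []
    gene_comp: dict[str, int | None] = {}
    for ci, spec in enumerate(config.kernels):
        for g in range(config.genes_per_compartment):
            gid = f"gene_{spec.name}_{g:04d}"
            gene_ids.append(gid)
            gene_comp[gid] = ci
    rng_nk = _rng(config, "noise_kernels")
    noise_shapes: dict[str, np.ndarray] = {}
    for g in range(config.n_noise_genes):
        gid = f"gene_noise_{g:04d}"
        gene_ids.append(gid)
        gene_comp[gid] = None
        spec = KernelSpec(name=gid, kind="gaussian",
                          center=float(rng_nk.uniform(rna_f.min() + 1, rna_f.max() - 1)),
                          width=float(rng_nk.uniform(1.5, 4.0)),
                          target_fold=float(rng_nk.uniform(2.0, 4.0)))
        noise_shapes[gid] = mixture_shape(make_kernel(spec, rna_f), spec.target_fold)

    rng_scale = _rng(config, "gene_scales")
    lo, hi = config.tpm_log10_range
    totals = 10.0 ** rng_scale.uniform(lo, hi, size=len(gene_ids))
    gene_total = dict(zip(gene_ids, totals))

    rng_noise = _rng(config, "gene_noise")
    rna_values = np.empty((len(gene_ids), n_rf))
    gene_shape: dict[str, np.ndarray] = {}
    for i, gid in enumerate(gene_ids):
        shape = shapes[gene_comp[gid]] if gene_comp[gid] is not None else noise_shapes[gid]
        gene_shape[gid] = shape
        noise = np.exp(rng_noise.normal(0.0, config.noise_sigma, size=n_rf))
        rna_values[i] = gene_total[gid] * shape * noise
    rna = FractionProfileMatrix(entity_ids=list(gene_ids), fraction_indices=rna_f,
                                values=rna_values, entity_kind="rna")

    # -- annotations (secreted / proximity labeling)
    rng_ann = _rng(config, "annotations")
    secreted: dict[str, bool] = {}
    annotations: dict[str, dict[str, bool]] = {}
    for gid in gene_ids:
        in_sec = gene_comp[gid] == config.secreted_compartment
        p_sig = config.secreted_prob_in if in_sec else config.secreted_prob_out
        p_apx = config.apex_prob_in if in_sec else config.apex_prob_out
        has_signal = bool(rng_ann.random() < p_sig)
        in_apex = bool(rng_ann.random() < p_apx)
        secreted[gid] = has_signal
        annotations[gid] = {"in_apex": in_apex, "has_signal": has_signal}

    # -- paired proteins
    rng_coup = _rng(config, "coupling")
    n_paired = min(config.n_paired_genes, len(gene_ids))
    paired = sorted(rng_coup.choice(np.array(gene_ids), size=n_paired, replace=False).tolist())
    coupling: dict[str, str] = {}
    prot_cols = np.array([int(np.nonzero(rna_f == f)[0][0]) for f in prot_f])
    rng_pnoise = _rng(config, "protein_noise")
    prot_values = np.empty((n_paired, prot_f.size))
    for i, gid in enumerate(paired):
        if config.independent_coupling_fraction > 0 and \
                rng_coup.random() < config.independent_coupling_fraction:
            mode = COUPLING_INDEPENDENT
        else:
            mode = COUPLING_CO if secreted[gid] else COUPLING_ANTI
        coupling[gid] = mode
        base = gene_shape[gid][prot_cols]
        if mode == COUPLING_ANTI:
            base = base[::-1]
        elif mode == COUPLING_INDEPENDENT:
            spec = KernelSpec(name=gid, kind="gaussian",
                              center=float(rng_coup.uniform(prot_f.min(), prot_f.max())),
                              width=float(rng_coup.uniform(1.5, 4.0)), target_fold=3.0)
            base = mixture_shape(make_kernel(spec, prot_f), spec.target_fold)
        base = base / base.sum()
        noise = np.exp(rng_pnoise.normal(0.0, config.noise_sigma, size=prot_f.size))
        prot_values[i] = 100.0 * base * noise
    protein = FractionProfileMatrix(entity_ids=paired, fraction_indices=prot_f,
                                    values=prot_values, entity_kind="protein")

    # -- RBP peptide profiles
    rng_rbp = _rng(config, "rbp_noise")
    rbp_ids = [s.name for s in config.rbp_specs]
    rbp_values = np.empty((len(rbp_ids), prot_f.size))
    rbp_targets: dict[str, list[str]] = {}
    rbp_hexamer: dict[str, str] = {}
    rbp_compartment: dict[str, str] = {}
    for i, spec in enumerate(config.rbp_specs):
        base = shapes[spec.compartment][prot_cols]
        base = base / base.sum()
        noise = np.exp(rng_rbp.normal(0.0, config.noise_sigma, size=prot_f.size))
        rbp_values[i] = 100.0 * base * noise
        rbp_targets[spec.name] = sorted(g for g, c in gene_comp.items()
                                        if c == spec.compartment)
        rbp_compartment[spec.name] = comp_names[spec.compartment]
        if spec.hexamer:
            rbp_hexamer[spec.name] = spec.hexamer
    rbp_peptides = FractionProfileMatrix(entity_ids=rbp_ids, fraction_indices=prot_f,
                                         values=rbp_values, entity_kind="protein")

    # -- 3' UTR sequences, planted motifs, conservation masks
    rng_utr = _rng(config, "utr")
    rng_mask = _rng(config, "mask")
    lo_len, hi_len = config.utr_length_range
    utrs: dict[str, str] = {}
    planted_positions: dict[str, list[int]] = {g: [] for g in gene_ids}
    planted_by_gene: dict[str, set[str]] = {}
    for spec in config.rbp_specs:
        if spec.hexamer:
            for g in rbp_targets[spec.name]:
                planted_by_gene.setdefault(g, set()).add(spec.hexamer)
    bases = np.array(list("ACGT"))
    for gid in gene_ids:
        L = int(rng_utr.integers(lo_len, hi_len + 1))
        seq = rng_utr.choice(bases, size=L)
        for spec in config.rbp_specs:
            if spec.hexamer and spec.hexamer in planted_by_gene.get(gid, set()):
                if rng_utr.random() < spec.plant_rate:
                    for _ in range(spec.copies):
                        pos = int(rng_utr.integers(0, L - 6 + 1))
                        seq[pos:pos + 6] = list(spec.hexamer)
                        planted_positions[gid].append(pos)
        utrs[gid] = "".join(seq)
    masks: dict[str, np.ndarray] = {}
    for gid in gene_ids:
        m = rng_mask.random(len(utrs[gid])) < config.conservation_p
        for pos in planted_positions[gid]:
            m[pos:pos + 6] = True
        masks[gid] = m

    # -- CLIP site counts for the motif-bearing RBP (affinity-scaled Poisson)
    rng_clip = _rng(config, "clip")
    clip_counts: dict[str, int] = {}
    motif_rbps = [s for s in config.rbp_specs if s.hexamer]
    clip_spec = motif_rbps[0] if motif_rbps else config.rbp_specs[0]
    rbp_shape_p = shapes[clip_spec.compartment][prot_cols]
    for gid in gene_ids:
        g_shape_p = gene_shape[gid][prot_cols]
        rho = float(np.corrcoef(g_shape_p, rbp_shape_p)[0, 1])
        mult = 1.0 + (config.clip_boost - 1.0) * max(0.0, rho)
        mean_tpm = gene_total[gid] / n_rf
        lam = config.clip_rate_per_tpm * mean_tpm * mult
        clip_counts[gid] = int(rng_clip.poisson(lam))

    # -- isoform Ψ switches
    psi_table, event_class, event_excluded = _simulate_psi(config, rna_f)

    # -- conservation scores per event (regulated classes shifted up)
    rng_cons = _rng(config, "conservation")
    conservation_scores: dict[str, float] = {}
    for ev in sorted(event_class):
        shift = config.conservation_shift if event_class[ev] in ("strong", "moderate") else 0.0
        conservation_scores[ev] = float(rng_cons.normal(shift, 1.0))

    # -- gene sets: compartments + decoys
    sets = {f"set_{name}": set(g for g, c in gene_comp.items() if c == ci)
            for ci, name in enumerate(comp_names)}
    rng_decoy = _rng(config, "decoy_sets")
    for d in range(config.n_decoy_sets):
        size = min(config.decoy_set_size, len(gene_ids))
        sets[f"decoy_{d:02d}"] = set(
            rng_decoy.choice(np.array(gene_ids), size=size, replace=False).tolist())
    gene_sets = GeneSetCollection(sets=sets, universe=set(gene_ids))

    truth = SyntheticTruth(
        gene_compartment={g: (comp_names[c] if c is not None else "noise")
                          for g, c in gene_comp.items()},
        gene_coupling=coupling,
        gene_secreted=secreted,
        rbp_targets=rbp_targets,
        rbp_hexamer=rbp_hexamer,
        rbp_compartment=rbp_compartment,
        event_class=event_class,
        event_excluded=event_excluded,
    )
    return SimulatedDataset(
        config=config, rna=rna, protein=protein, rbp_peptides=rbp_peptides,
        utrs=utrs, masks=masks, clip_counts=clip_counts, psi_table=psi_table,
        gene_sets=gene_sets, annotations=annotations,
        conservation_scores=conservation_scores, truth=truth,
    )


def _simulate_psi(config: SimulationConfig, rna_f: np.ndarray):
    """Two-isoform AFE/ALE events whose Ψ follows a sigmoid across the
    gradient with a configured true span per class; a slice of events is
    emitted with wide CIs to exercise the confidence filter."""
    spec = config.psi_spec
    rng = _rng(config, "psi")
    rows = []
    event_class: dict[str, str] = {}
    event_excluded: dict[str, bool] = {}
    n_f = rna_f.size
    x = np.linspace(-4.0, 4.0, n_f)
    sigmoid = 1.0 / (1.0 + np.exp(-x))
    classes = [("strong", spec.strong_range), ("moderate", spec.moderate_range),
               ("non_regulated", spec.non_range)]
    for etype in ("AFE", "ALE"):
        for cname, (lo, hi) in classes:
            for e in range(spec.n_per_class):
                ev = f"{etype.lower()}_{cname}_{e:03d}"
                delta = float(rng.uniform(lo, hi))
                p0 = float(rng.uniform(0.02, 0.98 - delta))
                direction = 1 if rng.random() < 0.5 else -1
                traj = p0 + delta * (sigmoid if direction > 0 else sigmoid[::-1])
                noisy = np.clip(traj + rng.normal(0.0, spec.psi_noise_sd, size=n_f),
                                0.0, 1.0)
                low_conf = bool(rng.random() < spec.low_conf_fraction)
                wlo, whi = (spec.low_conf_width_range if low_conf
                            else spec.ci_width_range)
                event_class[ev] = cname
                event_excluded[ev] = low_conf
                for iso, psis in (("A", noisy), ("B", 1.0 - noisy)):
                    widths = rng.uniform(wlo, whi, size=n_f)
                    for f, p, w in zip(rna_f, psis, widths):
                        rows.append({
                            "event_id": ev, "event_type": etype,
                            "isoform_id": f"{ev}.{iso}", "fraction_index": int(f),
                            "psi": round(float(p), 6),
                            "ci_low": round(float(max(0.0, p - w / 2)), 6),
                            "ci_high": round(float(min(1.0, p + w / 2)), 6),
                        })
    return pd.DataFrame(rows), event_class, event_excluded


# -- file emission and readers ------------------------------------------------


def write_dataset(ds: SimulatedDataset, outdir) -> dict[str, str]:
    """Emit every artifact in the dialect the loaders consume.  Returns a
    name -> path manifest."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {}

    def p(name):
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    hdr = f"seed={ds.config.seed}"
    write_profile_table(ds.rna, p("rna_profiles.tsv"), header_comment=hdr)
    write_profile_table(ds.protein, p("protein_profiles.tsv"), header_comment=hdr)
    write_profile_table(ds.rbp_peptides, p("rbp_peptides.tsv"), header_comment=hdr)

    with open(p("utrs.fasta"), "w") as fh:
        for gid in sorted(ds.utrs):
            fh.write(f">{gid}\n{ds.utrs[gid]}\n")
    with open(p("conservation_mask.tsv"), "w") as fh:
        fh.write("record_id\tstart\tend\n")
        for gid in sorted(ds.masks):
            for start, end in _true_runs(ds.masks[gid]):
                fh.write(f"{gid}\t{start}\t{end}\n")
    with open(p("clip_counts.tsv"), "w") as fh:
        fh.write("gene_id\tsite_count\n")
        for gid in sorted(ds.clip_counts):
            fh.write(f"{gid}\t{ds.clip_counts[gid]}\n")
    with open(p("annotations.tsv"), "w") as fh:
        fh.write("gene_id\tin_apex\thas_signal\n")
        for gid in sorted(ds.annotations):
            a = ds.annotations[gid]
            fh.write(f"{gid}\t{int(a['in_apex'])}\t{int(a['has_signal'])}\n")
    with open(p("event_conservation.tsv"), "w") as fh:
        fh.write("event_id\tconservation_score\n")
        for ev in sorted(ds.conservation_scores):
            fh.write(f"{ev}\t{ds.conservation_scores[ev]:.10g}\n")
    ds.psi_table.to_csv(p("psi_table.tsv"), sep="\t", index=False, float_format="%.10g")
    ds.gene_sets.write_gmt(p("gene_sets.gmt"))
    ds.truth.to_json(p("truth.json"))
    return paths


def _true_runs(mask: np.ndarray):
    """(start, end) half-open runs of True in a boolean array."""
    m = np.asarray(mask, dtype=bool)
    if m.size == 0:
        return []
    diff = np.diff(m.astype(int))
    starts = list(np.nonzero(diff == 1)[0] + 1)
    ends = list(np.nonzero(diff == -1)[0] + 1)
    if m[0]:
        starts = [0] + starts
    if m[-1]:
        ends = ends + [m.size]
    return list(zip(starts, ends))


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_mask_intervals(path, lengths: dict[str, int]) -> dict[str, np.ndarray]:
    """Rebuild per-base boolean masks from 0-based half-open intervals."""
    masks = {rid: np.zeros(L, dtype=bool) for rid, L in lengths.items()}
    df = pd.read_csv(path, sep="\t", comment="#")
    for rid, start, end in df.itertuples(index=False):
        if rid not in masks:
            raise ValidationError(f"mask record {rid!r} has no sequence")
        if not (0 <= start < end <= masks[rid].size):
            raise ValidationError(f"mask interval out of bounds for {rid!r}")
        masks[rid][start:end] = True
    return masks


def read_clip_counts(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(int)))


def read_annotations(path) -> dict[str, dict[str, bool]]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return {str(r.gene_id): {"in_apex": bool(r.in_apex), "has_signal": bool(r.has_signal)}
            for r in df.itertuples(index=False)}


def read_event_conservation(path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float)))


# -- truth metrics -----------------------------------------------------------


def truth_metrics(truth: SyntheticTruth, results: dict) -> dict:
    """Score pipeline outputs against the planted truth.

    ``results`` may hold any of: ``cluster_assignment`` (entity -> cluster
    id mapping or ClusterAssignment), ``rbp_correlated`` (rbp ->
    correlated RNA id set), ``hexamer_ranking`` (hexamer strings in
    descending enrichment order), ``event_labels`` (event -> predicted
    class).  Returns ARI over compartment genes, per-RBP recall/FPR at
    the correlation threshold, the planted hexamer's rank, and the ΔΨ
    class confusion matrix.
    """
    from sklearn.metrics import adjusted_rand_score

    out: dict = {}
    if "cluster_assignment" in results:
        assign = results["cluster_assignment"]
        mapping = getattr(assign, "assignments", assign)
        genes = sorted(g for g, comp in truth.gene_compartment.items()
                       if comp != "noise" and g in mapping)
        if not genes:
            raise ValidationError("no clustered genes overlap the truth")
        labels_true = [truth.gene_compartment[g] for g in genes]
        labels_pred = [mapping[g] for g in genes]
        out["ari"] = float(adjusted_rand_score(labels_true, labels_pred))
    if "rbp_correlated" in results:
        recall = {}
        fpr = {}
        all_genes = set(truth.gene_compartment)
        for rbp_id, predicted in results["rbp_correlated"].items():
            if rbp_id not in truth.rbp_targets:
                raise ValidationError(f"unknown RBP {rbp_id!r} in results")
            targets = set(truth.rbp_targets[rbp_id])
            predicted = set(predicted)
            if predicted - all_genes:
                raise ValidationError("predicted RNAs not in truth universe")
            recall[rbp_id] = len(predicted & targets) / len(targets) if targets else 0.0
            non_targets = all_genes - targets
            fpr[rbp_id] = (len(predicted - targets) / len(non_targets)
                           if non_targets else 0.0)
        out["rbp_recall"] = recall
        out["rbp_fpr"] = fpr
    if "hexamer_ranking" in results:
        ranking = list(results["hexamer_ranking"])
        ranks = {}
        for rbp_id, hexamer in truth.rbp_hexamer.items():
            ranks[rbp_id] = ranking.index(hexamer) + 1 if hexamer in ranking else None
        out["motif_rank"] = ranks
    if "event_labels" in results:
        pred = results["event_labels"]
        common = sorted(set(pred) & set(truth.event_class))
        if set(pred) - set(truth.event_class):
            raise ValidationError("predicted events not in truth")
        confusion: dict[str, dict[str, int]] = {}
        correct = 0
        for ev in common:
            t = truth.event_class[ev]
            p_lab = pred[ev]
            confusion.setdefault(t, {}).setdefault(p_lab, 0)
            confusion[t][p_lab] += 1
            correct += int(t == p_lab)
        out["psi_confusion"] = confusion
        out["psi_accuracy"] = correct / len(common) if common else 0.0
    return out
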