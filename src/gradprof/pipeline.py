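"""End-to-end orchestration: simulate -> cluster -> enrich -> gradient
stats -> RBP screen -> isoform screen, with file artifacts between stages.

Every stage reads its inputs from files and writes its outputs to files,
so any stage can be rerun in isolation; the run manifest records stage
status, parameters, and the seed.  All thresholds default to the
conventional values for this assay family: cluster size floor 20, RBP
correlation threshold 0.85, ΔΨ cuts 0.5/0.25, CI width 0.2, weighted-count
range 3-24.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
import yaml

from . import clustering, enrichment, gradient_stats, isoforms, rbp
from .simulate import (
    SimulationConfig,
    read_annotations,
    read_clip_counts,
    read_event_conservation,
    read_fasta,
    read_mask_intervals,
    simulate as run_simulation,
    write_dataset,
)
from .exceptions import GradprofError, ValidationError
from .profiles import load_profile_table, normalize_profiles, write_profile_table

logger = logging.getLogger(__name__)

STAGES = ("simulate", "cluster", "enrich", "gradstats", "rbp", "isoforms")


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 1
    data_dir: str | None = None          # defaults to <outdir>/data
    stages: tuple = STAGES
    min_total_rna: float = 1.0
    min_total_protein: float = 0.0
    cluster_metric: str = "correlation"
    cluster_linkage: str = "average"
    cluster_cut_criterion: str = "distance"
    cluster_cut_value: float = 0.3
    cluster_min_size: int = 20
    rbp_threshold: float = 0.85
    delta_psi_strong: float = 0.5
    delta_psi_moderate: float = 0.25
    max_ci_width: float = 0.2
    weighted_x: int = 3
    weighted_y: int = 24
    percentile: float = 20.0
    n_perm: int = 100
    enrichment_alpha: float = 0.05

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        issues = validate_config(d)
        fatal = [i for i in issues if not i.startswith("warning")]
        if fatal:
            raise ValidationError("invalid config: " + "; ".join(fatal))
        known = {f.name for f in fields(cls)}
        kwargs = {k: v for k, v in d.items() if k in known}
        if "stages" in kwargs:
            kwargs["stages"] = tuple(kwargs["stages"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def resolved_data_dir(self) -> str:
        return self.data_dir or os.path.join(self.outdir, "data")


def validate_config(d: dict) -> list[str]:
    """Return a list of problems; empty iff the config is runnable."""
    issues = []
    known = {f.name for f in fields(PipelineConfig)}
    for k in d:
        if k not in known:
            issues.append(f"unknown key {k!r}")
    if "outdir" not in d:
        issues.append("missing required key 'outdir'")
    stages = d.get("stages", STAGES)
    for s in stages:
        if s not in STAGES:
            issues.append(f"unknown stage {s!r}")
    strong = d.get("delta_psi_strong", 0.5)
    moderate = d.get("delta_psi_moderate", 0.25)
    if not (0 < moderate < strong < 1):
        issues.append("delta-psi cuts must satisfy 0 < moderate < strong < 1")
    if not (0 < d.get("max_ci_width", 0.2) <= 1):
        issues.append("max_ci_width must lie in (0,1]")
    if not (-1 <= d.get("rbp_threshold", 0.85) <= 1):
        issues.append("rbp_threshold must lie in [-1,1]")
    if d.get("cluster_min_size", 20) < 1:
        issues.append("cluster_min_size must be >= 1")
    if d.get("weighted_x", 3) > d.get("weighted_y", 24):
        issues.append("weighted-count range requires x <= y")
    if d.get("n_perm", 100) < 1:
        issues.append("n_perm must be >= 1")
    if "simulate" not in stages:
        data_dir = d.get("data_dir")
        if not data_dir:
            issues.append("data_dir required when the simulate stage is disabled")
        elif not os.path.isdir(data_dir):
            issues.append(f"data_dir {data_dir!r} does not exist")
    return issues


def _params_header(config: PipelineConfig, extra: dict | None = None) -> str:
    skip = ("stages", "outdir", "data_dir")   # paths vary per run location
    d = {k: v for k, v in dataclasses.asdict(config).items() if k not in skip}
    d.update(extra or {})
    return "\n".join(f"{k}={d[k]}" for k in sorted(d))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages in dependency order.

    Returns the run manifest (also written to <outdir>/manifest.json).
    Reruns with the same config and seed reproduce every numeric output
    byte for byte.
    """
    os.makedirs(config.outdir, exist_ok=True)
    data_dir = config.resolved_data_dir()
    manifest = {
        "seed": config.seed,
        "parameters": dataclasses.asdict(config),
        "stages": {},
        "outputs": {},
        "version": _package_version(),
    }
    runners = {
        "simulate": _stage_simulate,
        "cluster": _stage_cluster,
        "enrich": _stage_enrich,
        "gradstats": _stage_gradstats,
        "rbp": _stage_rbp,
        "isoforms": _stage_isoforms,
    }
    failed = False
    for stage in STAGES:
        if stage not in config.stages:
            manifest["stages"][stage] = "skipped"
            continue
        if failed:
            manifest["stages"][stage] = "not_run"
            continue
        try:
            outputs = runners[stage](config, data_dir)
            manifest["stages"][stage] = "ok"
            manifest["outputs"].update(outputs)
        except GradprofError as exc:
            logger.error("stage %s failed: %s", stage, exc)
            manifest["stages"][stage] = f"failed: {exc}"
            failed = True
    manifest_path = os.path.join(config.outdir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    manifest["manifest_path"] = manifest_path
    if failed:
        raise GradprofError("pipeline failed; see manifest for partial completion")
    return manifest


def _package_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("gradprof")
    except PackageNotFoundError:
        return "unknown"


# -- stages ------------------------------------------------------------------


def _stage_simulate(config: PipelineConfig, data_dir: str) -> dict:
    ds = run_simulation(SimulationConfig(seed=config.seed))
    paths = write_dataset(ds, data_dir)
    return {f"data/{k}": v for k, v in paths.items()}


def _load_normalized(config: PipelineConfig, data_dir: str, which: str):
    if which == "rna":
        m = load_profile_table(os.path.join(data_dir, "rna_profiles.tsv"), "rna")
        return normalize_profiles(m, min_total=config.min_total_rna), m
    m = load_profile_table(os.path.join(data_dir, "protein_profiles.tsv"), "protein")
    return normalize_profiles(m, min_total=config.min_total_protein), m


def _stage_cluster(config: PipelineConfig, data_dir: str) -> dict:
    norm, _ = _load_normalized(config, data_dir, "rna")
    assign = clustering.hierarchical_cluster(
        norm, metric=config.cluster_metric, method=config.cluster_linkage,
        cut_criterion=config.cluster_cut_criterion, cut_value=config.cluster_cut_value,
        seed=config.seed)
    filtered = clustering.filter_clusters_by_size(assign, min_size=config.cluster_min_size)
    out = {}
    for name, a in (("clusters_all", assign), ("clusters_filtered", filtered)):
        path = os.path.join(config.outdir, f"{name}.tsv")
        side = os.path.join(config.outdir, f"{name}.params.json")
        a.write(path, side)
        out[name] = path
    if filtered.assignments:
        profiles = clustering.cluster_mean_profiles(filtered, norm)
        mp = np.vstack([cp.mean_profile for cp in profiles])
        mean_matrix = type(norm)(
            entity_ids=[f"cluster_{cp.cluster_id}" for cp in profiles],
            fraction_indices=norm.fraction_indices, values=mp, entity_kind="rna")
        path = os.path.join(config.outdir, "cluster_mean_profiles.tsv")
        write_profile_table(mean_matrix, path, header_comment=_params_header(config))
        out["cluster_mean_profiles"] = path
    return out


def _read_clusters(config: PipelineConfig) -> clustering.ClusterAssignment:
    path = os.path.join(config.outdir, "clusters_filtered.tsv")
    df = pd.read_csv(path, sep="\t")
    return clustering.ClusterAssignment(
        assignments=dict(zip(df["entity_id"].astype(str), df["cluster_id"].astype(int))),
        parameters={"source": path})


def _stage_enrich(config: PipelineConfig, data_dir: str) -> dict:
    norm, _ = _load_normalized(config, data_dir, "rna")
    clusters = _read_clusters(config)
    sets = enrichment.GeneSetCollection.from_gmt(
        os.path.join(data_dir, "gene_sets.gmt"), universe=norm.entity_ids)
    frames = []
    for cid in clusters.cluster_ids():
        recs = enrichment.fisher_enrichment(clusters.members(cid), sets,
                                            alpha=config.enrichment_alpha)
        df = enrichment.records_to_frame(recs)
        df.insert(0, "cluster_id", cid)
        frames.append(df)
    result = pd.concat(frames, ignore_index=True)
    path = os.path.join(config.outdir, "cluster_enrichment.tsv")
    _write_tsv(result, path, config)
    annotations = read_annotations(os.path.join(data_dir, "annotations.tsv"))
    scatter = enrichment.cluster_annotation_scatter(clusters, annotations)
    spath = os.path.join(config.outdir, "cluster_annotation_scatter.tsv")
    _write_tsv(scatter, spath, config)
    return {"cluster_enrichment": path, "cluster_annotation_scatter": spath}


def _stage_gradstats(config: PipelineConfig, data_dir: str) -> dict:
    rna_norm, rna_raw = _load_normalized(config, data_dir, "rna")
    prot_norm, _ = _load_normalized(config, data_dir, "protein")
    out = {}
    cfg = gradient_stats.WeightedCountConfig(x=config.weighted_x, y=config.weighted_y)
    wc = gradient_stats.weighted_counts(rna_raw, cfg)
    path = os.path.join(config.outdir, "weighted_counts.tsv")
    _write_tsv(wc.reset_index(), path, config)
    out["weighted_counts"] = path

    pairs = gradient_stats.rna_protein_correlations(rna_norm, prot_norm)
    pair_df = pd.DataFrame([{"gene_id": c.gene_id, "r": c.r,
                             "n_fractions": c.n_fractions_used} for c in pairs])
    path = os.path.join(config.outdir, "rna_protein_correlations.tsv")
    _write_tsv(pair_df, path, config)
    out["rna_protein_correlations"] = path

    annotations = read_annotations(os.path.join(data_dir, "annotations.tsv"))
    signal = {g: a["has_signal"] for g, a in annotations.items()}
    rates = gradient_stats.percentile_annotation_rate(pairs, signal, pct=config.percentile)
    clusters = _read_clusters(config)
    null = gradient_stats.shuffled_assignment_null(
        clusters, prot_norm, n_perm=config.n_perm, seed=config.seed)
    test = gradient_stats.observed_vs_null_test(null)
    path = os.path.join(config.outdir, "protein_cluster_null.tsv")
    null_df = pd.DataFrame({"null_median": np.sort(null["null"])})
    _write_tsv(null_df, path, config, extra={"n_perm": config.n_perm})
    out["protein_cluster_null"] = path
    summary = {
        "percentile_rates": rates,
        "observed_cluster_medians": null["observed"],
        "observed_vs_null": test,
        "median_rna_protein_r": float(np.median([c.r for c in pairs])),
    }
    path = os.path.join(config.outdir, "gradstats_summary.json")
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=float)
        fh.write("\n")
    out["gradstats_summary"] = path
    return out


def _stage_rbp(config: PipelineConfig, data_dir: str) -> dict:
    rna_norm, _ = _load_normalized(config, data_dir, "rna")
    rbps = load_profile_table(os.path.join(data_dir, "rbp_peptides.tsv"), "protein")
    out = {}
    rows = []
    correlated: dict[str, set[str]] = {}
    for rbp_id in rbps.entity_ids:
        res = rbp.correlate_rbp_to_rnas(
            rbp_id, (rbps.fraction_indices, rbps.row(rbp_id)), rna_norm,
            threshold=config.rbp_threshold)
        correlated[rbp_id] = res.correlated_set
        for gene, r in res.correlations.items():
            rows.append({"rbp": rbp_id, "gene_id": gene, "r": r,
                         "in_set": gene in res.correlated_set})
    corr_df = pd.DataFrame(rows)
    path = os.path.join(config.outdir, "rbp_rna_correlations.tsv")
    _write_tsv(corr_df, path, config)
    out["rbp_rna_correlations"] = path

    mean_path = os.path.join(config.outdir, "cluster_mean_profiles.tsv")
    if os.path.exists(mean_path):
        means = load_profile_table(mean_path, "rna")
        profiles = [clustering.ClusterProfile(
            cluster_id=int(e.split("_")[1]), mean_profile=means.row(e),
            member_count=0) for e in means.entity_ids]
        pairs = rbp.correlate_rbps_to_clusters(rbps, profiles, means.fraction_indices,
                                               threshold=config.rbp_threshold)
        path = os.path.join(config.outdir, "rbp_cluster_matches.tsv")
        _write_tsv(pairs, path, config)
        out["rbp_cluster_matches"] = path

    utrs = read_fasta(os.path.join(data_dir, "utrs.fasta"))
    masks = read_mask_intervals(os.path.join(data_dir, "conservation_mask.tsv"),
                                    {g: len(s) for g, s in utrs.items()})
    # hexamer screen for every RBP with a non-empty correlated set;
    # conservation rates are a property of all expressed UTRs, computed once
    hex_rows = []
    expressed = set(rna_norm.entity_ids) & set(utrs)
    cons = rbp.hexamer_conservation_rate(
        [utrs[g] for g in sorted(expressed)],
        [masks[g] for g in sorted(expressed)])
    for rbp_id, cset in sorted(correlated.items()):
        fg_genes = sorted(cset & expressed)
        bg_genes = sorted(expressed - cset)
        if not fg_genes or not bg_genes:
            logger.warning("RBP %s: empty fg or bg; hexamer screen skipped", rbp_id)
            continue
        stats = rbp.hexamer_enrichment([utrs[g] for g in fg_genes],
                                       [utrs[g] for g in bg_genes])
        for rank, st in enumerate(stats[:50], start=1):
            hex_rows.append({
                "rbp": rbp_id, "rank": rank, "hexamer": st.hexamer,
                "fg_count": st.fg_count, "bg_count": st.bg_count,
                "log2_ratio": st.log2_ratio,
                "conservation_rate": cons.get(st.hexamer, float("nan")),
            })
    if hex_rows:
        path = os.path.join(config.outdir, "hexamer_enrichment.tsv")
        _write_tsv(pd.DataFrame(hex_rows), path, config)
        out["hexamer_enrichment"] = path

    clip = read_clip_counts(os.path.join(data_dir, "clip_counts.tsv"))
    raw = load_profile_table(os.path.join(data_dir, "rna_profiles.tsv"), "rna")
    expr = {g: float(raw.row(g).mean()) for g in raw.entity_ids}
    first_rbp = rbps.entity_ids[0]
    corrs = {r["gene_id"]: r["r"] for _, r in
             corr_df[corr_df["rbp"] == first_rbp].iterrows()}
    dens = rbp.clip_density_by_bin(clip, expr, corrs)
    path = os.path.join(config.outdir, "clip_density_bins.json")
    with open(path, "w") as fh:
        json.dump({"medians": {str(k): v for k, v in dens["medians"].items()},
                   "tests": dens["tests"],
                   "bin_edges": list(map(float, dens["bin_edges"]))},
                  fh, indent=1, sort_keys=True, default=float)
        fh.write("\n")
    out["clip_density_bins"] = path
    return out


def _stage_isoforms(config: PipelineConfig, data_dir: str) -> dict:
    table = isoforms.load_psi_table(os.path.join(data_dir, "psi_table.tsv"))
    events = isoforms.screen_events(table, max_ci_width=config.max_ci_width)
    labeled = isoforms.classify_events(events, strong_cut=config.delta_psi_strong,
                                       moderate_cut=config.delta_psi_moderate)
    df = isoforms.events_to_frame(labeled)
    path = os.path.join(config.outdir, "event_delta_psi.tsv")
    _write_tsv(df, path, config)
    out = {"event_delta_psi": path}
    cons_path = os.path.join(data_dir, "event_conservation.tsv")
    if os.path.exists(cons_path):
        scores = read_event_conservation(cons_path)
        labels = {e.event_id: e.label for e in labeled}
        res = isoforms.conservation_group_test(labels, scores)
        jpath = os.path.join(config.outdir, "conservation_tests.json")
        with open(jpath, "w") as fh:
            json.dump({"tests": res["tests"]}, fh, indent=1, sort_keys=True, default=float)
            fh.write("\n")
        out["conservation_tests"] = jpath
        for lab, table_ in res["ecdf"].items():
            epath = os.path.join(config.outdir, f"conservation_ecdf_{lab}.tsv")
            _write_tsv(pd.DataFrame(table_, columns=["score", "cum_frac"]), epath, config)
            out[f"conservation_ecdf_{lab}"] = epath
    return out


def _write_tsv(df: pd.DataFrame, path: str, config: PipelineConfig,
               extra: dict | None = None) -> None:
    with open(path, "w") as fh:
        for line in _params_header(config, extra).splitlines():
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")
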