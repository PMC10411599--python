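"""Single-process orchestration of the full analysis.

Stages run in dependency order: simulate/load -> pool -> cluster ->
quantify -> filter -> annotate -> links -> stretches -> tissue
specificity -> populations.  Every stage output is a TSV/BED/GFF3 file
under the output directory, and a manifest records the resolved
configuration, its hash and the sha256 of every file, so a rerun with an
identical configuration reproduces identical deterministic outputs.

The configuration is a YAML file with one block per stage; unknown keys
are rejected, and the fully resolved configuration (defaults included)
is written next to the outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import annotation, clustering, coexpression, populations, specificity, stretches
from .ctss_io import load_tracks, read_gene_models_gff3, read_sample_sheet, write_clusters_bed
from .simulate import SimConfig, generate_dataset, write_dataset

log = logging.getLogger("cagecall")


@dataclass
class ClusteringConfig:
    merge_dist: int = 20
    radius: int = 500
    balance_threshold: float = 0.95
    max_span: int = 1000
    min_pooled_count: int = 10
    # 2/3 of the 12-sample default design; always an explicit count, never a fraction
    min_samples: int = 8


@dataclass
class AnnotationBlock:
    promoter_halfwidth: int = 100
    proximal_upstream: int = 1000


@dataclass
class LinksConfig:
    max_gap: int = 10000
    p_threshold: float = 0.05
    fdr_threshold: float = 0.01


@dataclass
class StretchesConfig:
    merge_dist: int = 10000
    min_members: int = 3


@dataclass
class SpecificityConfig:
    min_pooled_count: int = 10
    min_support: int = 2


@dataclass
class PopulationsConfig:
    min_pooled_count: int = 10


@dataclass
class IoConfig:
    sample_sheet: str | None = None
    gff3: str | None = None
    base_dir: str | None = None


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "cagecall_out"
    io: IoConfig = field(default_factory=IoConfig)
    simulate: SimConfig | None = None
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    annotation: AnnotationBlock = field(default_factory=AnnotationBlock)
    links: LinksConfig = field(default_factory=LinksConfig)
    stretches: StretchesConfig = field(default_factory=StretchesConfig)
    specificity: SpecificityConfig = field(default_factory=SpecificityConfig)
    populations: PopulationsConfig = field(default_factory=PopulationsConfig)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        return _build(cls, dict(raw), "config")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def resolved(self) -> dict:
        out = dataclasses.asdict(self)
        return out

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.resolved(), sort_keys=True, default=str).encode()).hexdigest()[:16]


def _build(cls, raw: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(raw) - set(fields)
    if unknown:
        raise ValueError(f"unknown configuration keys under {path}: {sorted(unknown)}")
    kwargs = {}
    for name, value in raw.items():
        ftype = fields[name].type
        if name == "simulate" and value is not None:
            kwargs[name] = _build(SimConfig, dict(value), f"{path}.simulate")
        elif dataclasses.is_dataclass(_block_type(name)) and isinstance(value, dict):
            kwargs[name] = _build(_block_type(name), value, f"{path}.{name}")
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


_BLOCKS = {
    "io": IoConfig,
    "clustering": ClusteringConfig,
    "annotation": AnnotationBlock,
    "links": LinksConfig,
    "stretches": StretchesConfig,
    "specificity": SpecificityConfig,
    "populations": PopulationsConfig,
}


def _block_type(name: str):
    return _BLOCKS.get(name)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    t0 = time.time()
    outdir = cfg.outdir
    os.makedirs(outdir, exist_ok=True)
    outputs: dict[str, str] = {}

    def _emit(name: str, path: str) -> None:
        outputs[name] = path

    # -- stage: inputs -------------------------------------------------
    if cfg.simulate is not None:
        sim_cfg = dataclasses.replace(cfg.simulate, seed=cfg.seed)
        log.info("simulate: generating synthetic data set (seed %d)", cfg.seed)
        sim = generate_dataset(sim_cfg)
        sim_dir = os.path.join(outdir, "sim")
        write_dataset(sim, sim_dir)
        _emit("simulate", sim_dir)
        tracks = sim.tracks
        sheet = sim.sample_sheet
        models = sim.models
    else:
        if not cfg.io.sample_sheet or not cfg.io.gff3:
            raise ValueError("stage 'inputs': need io.sample_sheet and io.gff3 (or a simulate block)")
        sheet = read_sample_sheet(cfg.io.sample_sheet)
        base = cfg.io.base_dir or os.path.dirname(os.path.abspath(cfg.io.sample_sheet))
        tracks = load_tracks(sheet, base_dir=base)
        models = read_gene_models_gff3(cfg.io.gff3)

    # -- stage: clustering --------------------------------------------
    cl = cfg.clustering
    log.info("cluster: pooling %d samples", len(tracks))
    pooled = clustering.pool_and_normalize(tracks)
    tss = clustering.cluster_unidirectional(pooled, merge_dist=cl.merge_dist)
    enh = clustering.cluster_bidirectional(
        pooled, radius=cl.radius, balance_threshold=cl.balance_threshold, max_span=cl.max_span
    )
    log.info("cluster: %d unidirectional, %d bidirectional", len(tss), len(enh))

    # -- stage: quantify + filter -------------------------------------
    tss_m = clustering.quantify(tss, tracks)
    enh_m = clustering.quantify(enh, tracks)
    tss_f = clustering.filter_by_support(tss_m, cl.min_pooled_count, cl.min_samples)
    enh_f = clustering.filter_by_support(enh_m, cl.min_pooled_count, cl.min_samples)
    log.info("filter: kept %d TSS, %d enhancers (pooled >= %d, support >= %d)",
             len(tss_f.clusters), len(enh_f.clusters), cl.min_pooled_count, cl.min_samples)

    # -- stage: annotate ----------------------------------------------
    ann_cfg = annotation.AnnotationConfig(
        promoter_halfwidth=cfg.annotation.promoter_halfwidth,
        proximal_upstream=cfg.annotation.proximal_upstream,
    )
    tss_ann = annotation.annotate_clusters(tss_f.clusters, models, ann_cfg)
    enh_ann = annotation.annotate_clusters(enh_f.clusters, models, ann_cfg)
    # re-align matrices with the (genome-sorted) annotated cluster order
    tss_f = clustering.ExpressionMatrix(
        values=tss_f.values.loc[tss_ann["cluster_id"]], clusters=tss_ann, kind="tss"
    )
    enh_f = clustering.ExpressionMatrix(
        values=enh_f.values.loc[enh_ann["cluster_id"]], clusters=enh_ann, kind="enhancer"
    )
    path = os.path.join(outdir, "tss_annotated.tsv")
    tss_ann.to_csv(path, sep="\t", index=False)
    _emit("tss_annotated", path)
    path = os.path.join(outdir, "enhancers_annotated.tsv")
    enh_ann.to_csv(path, sep="\t", index=False)
    _emit("enhancers_annotated", path)
    path = os.path.join(outdir, "tss.bed")
    write_clusters_bed(tss_ann, path)
    _emit("tss_bed", path)
    path = os.path.join(outdir, "enhancers.bed")
    write_clusters_bed(enh_ann.drop(columns=["strand"], errors="ignore"), path)
    _emit("enhancers_bed", path)
    path = os.path.join(outdir, "tss_expression.tsv")
    tss_f.values.to_csv(path, sep="\t")
    _emit("tss_expression", path)
    path = os.path.join(outdir, "enhancer_expression.tsv")
    enh_f.values.to_csv(path, sep="\t")
    _emit("enhancer_expression", path)

    # -- stage: links --------------------------------------------------
    lk = cfg.links
    links = coexpression.find_links(
        enh_f, tss_f, max_gap=lk.max_gap, p_threshold=lk.p_threshold, fdr_threshold=lk.fdr_threshold
    )
    links = coexpression.classify_links(links, tss_ann, enh_ann)
    log.info("links: %d retained (FDR < %g)", len(links), lk.fdr_threshold)
    path = os.path.join(outdir, "links.tsv")
    links.to_csv(path, sep="\t", index=False)
    _emit("links", path)
    if len(links) >= 2 and links["gap"].std(ddof=1) > 0 and links["tau"].std(ddof=1) > 0:
        gx, gy, dens = coexpression.kde2d_gap_tau(links)
        kde = pd.DataFrame(dens, index=pd.Index(gx, name="gap"), columns=pd.Index(gy, name="tau"))
        path = os.path.join(outdir, "links_kde.tsv")
        kde.to_csv(path, sep="\t")
        _emit("links_kde", path)

    # -- stage: stretches ----------------------------------------------
    # minimum pooled count applies, but NOT the pervasiveness (2/3-support)
    # filter: enhancer activity is inherently tissue restricted
    st = cfg.stretches
    enh_np = clustering.filter_by_support(enh_m, cl.min_pooled_count, 1)
    enh_sorted = enh_np.clusters.sort_values(["chrom", "midpoint"], kind="mergesort").reset_index(drop=True)
    enh_m_sorted = clustering.ExpressionMatrix(
        values=enh_np.values.loc[enh_sorted["cluster_id"]], clusters=enh_sorted, kind="enhancer"
    )
    stretch_df = stretches.find_stretches(
        enh_sorted, enh_m_sorted, merge_dist=st.merge_dist, min_members=st.min_members
    )
    log.info("stretches: %d found", len(stretch_df))
    path = os.path.join(outdir, "stretches.tsv")
    stretch_df.to_csv(path, sep="\t", index=False)
    _emit("stretches", path)

    # -- stage: tissue specificity ------------------------------------
    labels = pd.Series(sheet["tissue"].to_numpy(), index=sheet["sample_id"].to_numpy())
    tsi = specificity.tsi_profile(tss_f, labels)
    path = os.path.join(outdir, "tsi.tsv")
    tsi.to_csv(path, sep="\t", index=False)
    _emit("tsi", path)
    sp = cfg.specificity
    by_tissue = {
        t: [tr for tr, tt in zip(tracks, sheet["tissue"]) if tt == t] for t in sorted(sheet["tissue"].unique())
    }
    per_tissue = specificity.tissue_specific_clusters(
        by_tissue,
        min_pooled_count=sp.min_pooled_count,
        min_support=sp.min_support,
        merge_dist=cl.merge_dist,
        radius=cl.radius,
        balance_threshold=cl.balance_threshold,
        max_span=cl.max_span,
    )
    rows = []
    for tissue, mats in per_tissue.items():
        for kind in ("tss", "enhancer"):
            sub = mats[kind].clusters.copy()
            sub.insert(0, "tissue", tissue)
            sub.insert(1, "kind", kind)
            rows.append(sub)
    per_tissue_df = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    path = os.path.join(outdir, "tissue_clusters.tsv")
    per_tissue_df.to_csv(path, sep="\t", index=False)
    _emit("tissue_clusters", path)

    # -- stage: populations -------------------------------------------
    pp = cfg.populations
    pop_sets_tss: dict[str, pd.DataFrame] = {}
    pop_sets_enh: dict[str, pd.DataFrame] = {}
    for pop in sorted(sheet["population"].unique()):
        pop_tracks = [tr for tr, p in zip(tracks, sheet["population"]) if p == pop]
        mats = populations.population_clusters(
            pop_tracks,
            min_pooled_count=pp.min_pooled_count,
            merge_dist=cl.merge_dist,
            radius=cl.radius,
            balance_threshold=cl.balance_threshold,
            max_span=cl.max_span,
        )
        pop_sets_tss[pop] = mats["tss"].clusters
        pop_sets_enh[pop] = mats["enhancer"].clusters
    sig_tss = populations.build_signatures(pop_sets_tss, match_rule="exact")
    sig_enh = populations.build_signatures(pop_sets_enh, match_rule="exact")
    path = os.path.join(outdir, "population_signatures_tss.tsv")
    sig_tss["membership"].to_csv(path, sep="\t", index=False)
    _emit("population_signatures_tss", path)
    path = os.path.join(outdir, "population_signature_counts_tss.tsv")
    sig_tss["counts"].to_csv(path, sep="\t", index=False)
    _emit("population_signature_counts_tss", path)
    path = os.path.join(outdir, "population_signature_counts_enh.tsv")
    sig_enh["counts"].to_csv(path, sep="\t", index=False)
    _emit("population_signature_counts_enh", path)

    # -- manifest ------------------------------------------------------
    manifest = {
        "config": cfg.resolved(),
        "config_hash": cfg.config_hash(),
        "elapsed_s": round(time.time() - t0, 2),
        "files": {
            name: {"path": os.path.relpath(p, outdir), "sha256": _sha256(p)}
            for name, p in outputs.items()
            if os.path.isfile(p)
        },
        "dirs": {name: os.path.relpath(p, outdir) for name, p in outputs.items() if os.path.isdir(p)},
    }
    with open(os.path.join(outdir, "resolved_config.yaml"), "w") as fh:
        yaml.safe_dump(cfg.resolved(), fh, sort_keys=True)
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    log.info("pipeline done in %.1f s; %d outputs", time.time() - t0, len(outputs))
    return manifest


def default_synthetic_config(outdir: str, seed: int = 0, **sim_overrides) -> PipelineConfig:
    """The default desk-scale synthetic run, end-to-end in minutes."""
    return PipelineConfig(seed=seed, outdir=outdir, simulate=SimConfig(seed=seed, **sim_overrides))
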