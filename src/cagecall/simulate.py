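"""Synthetic multi-sample CAGE data with ground truth.

The generator emulates the data regime of a multi-tissue, multi-population
CAGE study at desk scale: per-sample, per-strand base-pair 5'-end count
tracks, matching GFF3 gene models, a sample sheet, and truth tables for
every planted feature, so that each pipeline stage can be tested without
any external download.

What is emulated
----------------
* negative-binomial tag counts per TSS per sample, modulated by lognormal
  per-tissue activity and a lognormal per-sample latent factor;
* positional spread of tags around a dominant TSS base with geometric
  decay;
* divergent enhancer pairs: a minus-strand arm left and a plus-strand arm
  right of a midpoint, 400-950 bp apart (the upper default stays under
  the 1 kb span cap once arm spread is added);
* latent-activity coupling between planted enhancer-TSS pairs: both
  emitters share a fraction rho of their per-sample latent variance, so
  their rank correlation increases in rho without being degenerate;
* tissue-restricted and population-restricted clusters (structural zero
  activity outside their group);
* superenhancer stretches (>= 3 enhancers with < 10 kb midpoint gaps) and
  2-enhancer decoys, with all other enhancers placed > 10 kb apart;
* uniform background noise as singleton tags, which the minimum pooled
  count filter must remove.

Layout is block-based: genes, enhancers, stretches and decoys are placed
sequentially along the chromosomes with a wide margin after every
enhancer-bearing block, which guarantees that no unintended enhancer
chain or enhancer-TSS pair arises by construction.  Everything is
deterministic under a fixed seed, down to byte-identical bedGraph output.
"""

from __future__ import annotations

from dataclasses import dataclass
import os

import numpy as np
import pandas as pd

from .clustering import ExpressionMatrix
from .ctss_io import CtssTrack, GeneModels, derive_utrs, write_ctss_bedgraph, write_gene_models_gff3


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic data set.

    Defaults are the desk-scale study conditions: 2 chromosomes of 1 Mb,
    200 genes, 12 samples (4 tissues x 3 populations, one sample per
    cell), 60 enhancers of which 30 are coexpression-linked to a TSS, 3
    planted stretches and 2 two-enhancer decoys.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 200
    tissues: tuple[str, ...] = ("brain", "liver", "muscle", "kidney")
    populations: tuple[str, ...] = ("holstein", "charolais", "kinsella")
    library_size: int = 1_000_000
    tss_per_gene_probs: tuple[float, ...] = (0.6, 0.3, 0.1)  # P(1), P(2), P(3)
    spread_decay: float = 0.35  # geometric decay of tag mass per bp from the dominant base
    spread_halfwidth: int = 10
    nb_mean: float = 20.0  # expected per-sample tags of a baseline TSS
    nb_dispersion: float = 10.0  # NB size parameter (smaller = noisier)
    tissue_sigma: float = 0.4  # lognormal sd of per-tissue activity
    latent_sigma: float = 1.2  # lognormal sd of the per-sample latent factor
    n_enhancers: int = 60
    arm_separation: tuple[int, int] = (400, 950)
    arm_nb_mean: float = 15.0
    arm_spread_halfwidth: int = 5
    n_linked_pairs: int = 30
    rho: float = 0.6  # latent correlation of planted enhancer-TSS pairs
    link_gap: tuple[int, int] = (1500, 4500)
    n_stretches: int = 3
    stretch_members: int = 3
    stretch_gap: tuple[int, int] = (2500, 4000)
    n_decoy_pairs: int = 2
    n_tissue_private: int = 8
    n_population_private: int = 6
    background_noise_per_mb: float = 30.0
    gene_length: tuple[int, int] = (2000, 3500)
    enhancer_margin: int = 13000  # margin after enhancer-bearing blocks (> stretch window)
    gene_margin: int = 1000

    def __post_init__(self) -> None:
        if not -1 <= self.rho <= 1:
            raise ValueError("rho must lie in [-1, 1]")
        if self.arm_separation[0] < 2 * self.arm_spread_halfwidth:
            raise ValueError("arm separation must exceed twice the arm spread")
        if self.n_linked_pairs + self.n_stretches * self.stretch_members + 2 * self.n_decoy_pairs > self.n_enhancers:
            raise ValueError("n_enhancers too small for the requested linked/stretch/decoy counts")
        if self.n_linked_pairs + self.n_tissue_private + self.n_population_private > self.n_genes:
            raise ValueError("n_genes too small for the requested linked/private counts")

    @property
    def sample_table(self) -> pd.DataFrame:
        rows = [
            (f"{pop}_{tis}", tis, pop, self.library_size)
            for pop in self.populations
            for tis in self.tissues
        ]
        return pd.DataFrame(rows, columns=["sample_id", "tissue", "population", "library_size"])


@dataclass
class TruthTable:
    """Planted features, in the same 0-based coordinates as BED output."""

    tss: pd.DataFrame
    enhancers: pd.DataFrame
    links: pd.DataFrame
    stretches: pd.DataFrame


@dataclass
class SimResult:
    tracks: list[CtssTrack]
    models: GeneModels
    sample_sheet: pd.DataFrame
    truth: TruthTable
    config: SimConfig


# ---------------------------------------------------------------------------
# latent-activity machinery (shared with the pair-matrix helper)
# ---------------------------------------------------------------------------


def _coupled_normals(rng: np.random.Generator, n: int, rho: float) -> tuple[np.ndarray, np.ndarray]:
    """Two standard-normal vectors with correlation ``rho``.

    Both load sqrt(rho) on a shared factor, so corr(a, b) = rho while each
    stays marginally N(0, 1).
    """
    z = rng.standard_normal(n)
    e1 = rng.standard_normal(n)
    e2 = rng.standard_normal(n)
    a = np.sqrt(max(rho, 0.0)) * z + np.sqrt(1 - max(rho, 0.0)) * e1
    b = np.sign(rho) * np.sqrt(abs(rho)) * z + np.sqrt(1 - abs(rho)) * e2
    return a, b


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    """Negative-binomial counts with the given means and dispersion ``size_param``."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if np.any(pos):
        p = size_param / (size_param + mean[pos])
        out[pos] = rng.negative_binomial(size_param, p)
    return out


def _spread_weights(halfwidth: int, decay: float) -> np.ndarray:
    offsets = np.arange(-halfwidth, halfwidth + 1)
    w = decay ** np.abs(offsets)
    return w / w.sum()


# ---------------------------------------------------------------------------
# genome layout
# ---------------------------------------------------------------------------


def _build_blocks(cfg: SimConfig, rng: np.random.Generator) -> list[dict]:
    n_isolated = cfg.n_enhancers - cfg.n_linked_pairs - cfg.n_stretches * cfg.stretch_members - 2 * cfg.n_decoy_pairs
    n_plain = cfg.n_genes - cfg.n_linked_pairs
    blocks: list[dict] = []
    blocks += [{"kind": "linked"} for _ in range(cfg.n_linked_pairs)]
    blocks += [{"kind": "stretch"} for _ in range(cfg.n_stretches)]
    blocks += [{"kind": "decoy"} for _ in range(cfg.n_decoy_pairs)]
    blocks += [{"kind": "enhancer"} for _ in range(n_isolated)]
    # first plain genes host the private clusters (single TSS each for clean truth)
    private = [{"kind": "gene", "private": ("tissue", t)} for t in _cycle(cfg.tissues, cfg.n_tissue_private)]
    private += [
        {"kind": "gene", "private": ("population", p)} for p in _cycle(cfg.populations, cfg.n_population_private)
    ]
    plain = [{"kind": "gene", "private": None} for _ in range(n_plain - len(private))]
    blocks += private + plain
    order = rng.permutation(len(blocks))
    return [blocks[i] for i in order]


def _cycle(items: tuple[str, ...], n: int) -> list[str]:
    return [items[i % len(items)] for i in range(n)]


def generate_dataset(cfg: SimConfig) -> SimResult:
    """Generate tracks, gene models, sample sheet and truth tables."""
    rng = np.random.default_rng(cfg.seed)
    samples = cfg.sample_table
    n_samples = len(samples)

    blocks = _build_blocks(cfg, rng)

    genes = []  # (gene_id, symbol, chrom, start, end, strand)
    transcripts = []
    features = []
    tss_records = []  # emitter dicts
    enh_records = []
    link_rows = []
    stretch_rows = []

    gene_i = 0
    enh_i = 0
    tss_i = 0
    stretch_i = 0
    chrom_i = 0
    cursor = 200  # keep a little headroom at chromosome start

    def chrom_name(i: int) -> str:
        return f"chr{i + 1}"

    def _advance(extent: int, margin: int) -> tuple[str, int]:
        """Return (chrom, start) for a block of the given extent, moving chroms as needed."""
        nonlocal chrom_i, cursor
        while cursor + extent + margin > cfg.chrom_length:
            chrom_i += 1
            cursor = 200
            if chrom_i >= cfg.n_chroms:
                raise ValueError("genome too small for the requested block layout")
        start = cursor
        cursor += extent + margin
        return chrom_name(chrom_i), start

    def _make_gene(chrom: str, start: int, private, n_tss: int) -> tuple[int, list[int]]:
        """Register one gene at ``start``; returns (gene end, tss emitter indices)."""
        nonlocal gene_i, tss_i
        length = int(rng.integers(cfg.gene_length[0], cfg.gene_length[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        end = start + length
        gene_id = f"G{gene_i:04d}"
        gene_i += 1
        genes.append((gene_id, f"SYM{gene_id}", chrom, start, end, strand))
        tx_id = f"{gene_id}.t1"
        transcripts.append((tx_id, gene_id, chrom, start, end, strand))
        e1 = int(length * 0.4)
        intron = int(length * 0.2)
        exons = [(start, start + e1), (start + e1 + intron, end)]
        cds = [(start + e1 // 2, start + e1), (start + e1 + intron, end - (length - e1 - intron) // 2)]
        for s, e in exons:
            features.append((tx_id, "exon", chrom, s, e, strand))
        for s, e in cds:
            features.append((tx_id, "CDS", chrom, s, e, strand))
        for kind, s, e in derive_utrs(exons, cds, strand):
            features.append((tx_id, kind, chrom, s, e, strand))
        five_prime = start if strand == "+" else end - 1
        inward = 1 if strand == "+" else -1
        emitters = []
        for k in range(n_tss):
            pos = five_prime if k == 0 else five_prime + inward * int(rng.integers(200, 800))
            tss_records.append(
                {
                    "tss_id": f"TSS{tss_i:04d}",
                    "gene_id": gene_id,
                    "chrom": chrom,
                    "pos": int(pos),
                    "strand": strand,
                    "private": private,
                }
            )
            emitters.append(tss_i)
            tss_i += 1
        return end, emitters

    def _make_enhancer(chrom: str, midpoint: int, role: str, stretch_id: str = "") -> int:
        nonlocal enh_i
        sep = int(rng.integers(cfg.arm_separation[0], cfg.arm_separation[1] + 1))
        minus_arm = midpoint - sep // 2
        plus_arm = midpoint + (sep - sep // 2)
        enh_records.append(
            {
                "enhancer_id": f"ENH{enh_i:04d}",
                "chrom": chrom,
                "midpoint": int(midpoint),
                "minus_arm": int(minus_arm),
                "plus_arm": int(plus_arm),
                "separation": sep,
                "role": role,
                "stretch_id": stretch_id,
            }
        )
        enh_i += 1
        return enh_i - 1

    n_tss_draws = rng.choice(len(cfg.tss_per_gene_probs), size=cfg.n_genes, p=cfg.tss_per_gene_probs) + 1

    for block in blocks:
        kind = block["kind"]
        if kind == "gene":
            n_tss = 1 if block["private"] else int(n_tss_draws[gene_i])
            length_max = cfg.gene_length[1]
            chrom, start = _advance(length_max, cfg.gene_margin)
            _make_gene(chrom, start, block["private"], n_tss)
        elif kind == "linked":
            gap = int(rng.integers(cfg.link_gap[0], cfg.link_gap[1] + 1))
            extent = cfg.gene_length[1] + gap + cfg.arm_separation[1] // 2 + cfg.arm_spread_halfwidth + 10
            chrom, start = _advance(extent, cfg.enhancer_margin)
            gene_end, emitters = _make_gene(chrom, start, None, 1)
            e_idx = _make_enhancer(chrom, gene_end + gap, "linked")
            link_rows.append(
                (
                    enh_records[e_idx]["enhancer_id"],
                    tss_records[emitters[0]]["tss_id"],
                    cfg.rho,
                )
            )
        elif kind in ("stretch", "decoy"):
            n_members = cfg.stretch_members if kind == "stretch" else 2
            gaps = [int(rng.integers(cfg.stretch_gap[0], cfg.stretch_gap[1] + 1)) for _ in range(n_members - 1)]
            pad = cfg.arm_separation[1] // 2 + cfg.arm_spread_halfwidth + 10
            extent = sum(gaps) + 2 * pad
            chrom, start = _advance(extent, cfg.enhancer_margin)
            sid = f"STR{stretch_i:03d}" if kind == "stretch" else ""
            midpoint = start + pad
            member_ids = []
            for m in range(n_members):
                e_idx = _make_enhancer(chrom, midpoint, kind, sid)
                member_ids.append(enh_records[e_idx]["enhancer_id"])
                if m < n_members - 1:
                    midpoint += gaps[m]
            if kind == "stretch":
                stretch_rows.append((sid, chrom, ",".join(member_ids), n_members))
                stretch_i += 1
        elif kind == "enhancer":
            pad = cfg.arm_separation[1] // 2 + cfg.arm_spread_halfwidth + 10
            chrom, start = _advance(2 * pad, cfg.enhancer_margin)
            _make_enhancer(chrom, start + pad, "isolated")

    # ------------------------------------------------------------------
    # activities and counts
    # ------------------------------------------------------------------
    tissue_of = samples["tissue"].to_numpy()
    pop_of = samples["population"].to_numpy()

    # per-sample latent factors; linked pairs get coupled latents
    tss_latent = rng.standard_normal((len(tss_records), n_samples))
    enh_latent = rng.standard_normal((len(enh_records), n_samples))
    tss_index = {r["tss_id"]: i for i, r in enumerate(tss_records)}
    enh_index = {r["enhancer_id"]: i for i, r in enumerate(enh_records)}
    for enh_id, tss_id, rho in link_rows:
        a, b = _coupled_normals(rng, n_samples, rho)
        enh_latent[enh_index[enh_id]] = a
        tss_latent[tss_index[tss_id]] = b

    def _tss_means(record, latent_row):
        t_eff = {t: rng.normal(0.0, cfg.tissue_sigma) for t in cfg.tissues}
        log_mean = (
            np.log(cfg.nb_mean)
            + np.array([t_eff[t] for t in tissue_of])
            + cfg.latent_sigma * latent_row
        )
        mean = np.exp(log_mean)
        if record.get("private"):
            scope, value = record["private"]
            member = tissue_of == value if scope == "tissue" else pop_of == value
            mean = np.where(member, mean, 0.0)
        return mean

    spread_tss = _spread_weights(cfg.spread_halfwidth, cfg.spread_decay)
    spread_arm = _spread_weights(cfg.arm_spread_halfwidth, cfg.spread_decay)

    per_sample: list[dict[tuple[str, int, str], int]] = [dict() for _ in range(n_samples)]

    def _deposit(s: int, chrom: str, center: int, strand: str, total: int, weights: np.ndarray, half: int):
        if total == 0:
            return
        alloc = rng.multinomial(total, weights)
        store = per_sample[s]
        for off, c in zip(range(-half, half + 1), alloc):
            if c:
                key = (chrom, center + off, strand)
                store[key] = store.get(key, 0) + int(c)

    for i, record in enumerate(tss_records):
        mean = _tss_means(record, tss_latent[i])
        counts = _nb_draw(rng, mean, cfg.nb_dispersion)
        record["n_support_true"] = int((counts > 0).sum())
        record["pooled_count_true"] = int(counts.sum())
        for s in range(n_samples):
            _deposit(s, record["chrom"], record["pos"], record["strand"], int(counts[s]), spread_tss, cfg.spread_halfwidth)

    for i, record in enumerate(enh_records):
        t_eff = {t: rng.normal(0.0, cfg.tissue_sigma) for t in cfg.tissues}
        asym = np.exp(rng.normal(0.0, 0.15))
        log_mean = (
            np.log(cfg.arm_nb_mean)
            + np.array([t_eff[t] for t in tissue_of])
            + cfg.latent_sigma * enh_latent[i]
        )
        mean = np.exp(log_mean)
        minus_counts = _nb_draw(rng, mean * asym, cfg.nb_dispersion)
        plus_counts = _nb_draw(rng, mean / asym, cfg.nb_dispersion)
        both = minus_counts + plus_counts
        record["n_support_true"] = int((both > 0).sum())
        record["pooled_count_true"] = int(both.sum())
        for s in range(n_samples):
            _deposit(s, record["chrom"], record["minus_arm"], "-", int(minus_counts[s]), spread_arm, cfg.arm_spread_halfwidth)
            _deposit(s, record["chrom"], record["plus_arm"], "+", int(plus_counts[s]), spread_arm, cfg.arm_spread_halfwidth)

    # uniform background noise: singleton tags
    genome_mb = cfg.n_chroms * cfg.chrom_length / 1e6
    for s in range(n_samples):
        n_noise = rng.poisson(cfg.background_noise_per_mb * genome_mb)
        chroms = rng.integers(0, cfg.n_chroms, size=n_noise)
        positions = rng.integers(0, cfg.chrom_length, size=n_noise)
        strands = rng.integers(0, 2, size=n_noise)
        store = per_sample[s]
        for c, p, st in zip(chroms, positions, strands):
            key = (chrom_name(int(c)), int(p), "+" if st else "-")
            store[key] = store.get(key, 0) + 1

    tracks = []
    for s, row in enumerate(samples.itertuples()):
        store = per_sample[s]
        if store:
            keys = sorted(store)
            data = pd.DataFrame(
                {
                    "chrom": [k[0] for k in keys],
                    "pos": np.array([k[1] for k in keys], dtype=np.int64),
                    "strand": [k[2] for k in keys],
                    "count": np.array([store[k] for k in keys], dtype=np.int64),
                }
            )
        else:
            data = pd.DataFrame({"chrom": [], "pos": [], "strand": [], "count": []})
        tracks.append(CtssTrack(sample_id=row.sample_id, library_size=int(row.library_size), data=data))

    models = GeneModels(
        genes=pd.DataFrame(genes, columns=["gene_id", "symbol", "chrom", "start", "end", "strand"]),
        transcripts=pd.DataFrame(transcripts, columns=["tx_id", "gene_id", "chrom", "start", "end", "strand"]),
        features=pd.DataFrame(features, columns=["tx_id", "kind", "chrom", "start", "end", "strand"]),
    )

    tss_truth = pd.DataFrame(
        [
            {
                "tss_id": r["tss_id"],
                "gene_id": r["gene_id"],
                "chrom": r["chrom"],
                "pos": r["pos"],
                "strand": r["strand"],
                "private_tissue": r["private"][1] if r["private"] and r["private"][0] == "tissue" else "",
                "private_population": r["private"][1] if r["private"] and r["private"][0] == "population" else "",
                "n_support_true": r["n_support_true"],
                "pooled_count_true": r["pooled_count_true"],
            }
            for r in tss_records
        ]
    )
    enh_truth = pd.DataFrame(enh_records)
    links_truth = pd.DataFrame(link_rows, columns=["enhancer_id", "tss_id", "rho"])
    stretches_truth = pd.DataFrame(stretch_rows, columns=["stretch_id", "chrom", "members", "n_members"])

    sheet = samples.copy()
    sheet["path_plus"] = [f"{sid}.plus.bedgraph" for sid in sheet["sample_id"]]
    sheet["path_minus"] = [f"{sid}.minus.bedgraph" for sid in sheet["sample_id"]]
    sheet = sheet[["sample_id", "tissue", "population", "path_plus", "path_minus", "library_size"]]

    return SimResult(
        tracks=tracks,
        models=models,
        sample_sheet=sheet,
        truth=TruthTable(tss=tss_truth, enhancers=enh_truth, links=links_truth, stretches=stretches_truth),
        config=cfg,
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def write_dataset(sim: SimResult, outdir: str) -> None:
    """Write bedGraph tracks, GFF3, sample sheet and truth tables to ``outdir``."""
    os.makedirs(outdir, exist_ok=True)
    for track, row in zip(sim.tracks, sim.sample_sheet.itertuples()):
        write_ctss_bedgraph(
            track, os.path.join(outdir, row.path_plus), os.path.join(outdir, row.path_minus)
        )
    write_gene_models_gff3(sim.models, os.path.join(outdir, "genes.gff3"))
    sim.sample_sheet.to_csv(os.path.join(outdir, "samples.tsv"), sep="\t", index=False)
    write_truth(sim.truth, os.path.join(outdir, "truth"))


def write_truth(truth: TruthTable, outdir: str) -> None:
    """One TSV per truth category, coordinates matching BED conventions."""
    os.makedirs(outdir, exist_ok=True)
    truth.tss.to_csv(os.path.join(outdir, "tss.tsv"), sep="\t", index=False)
    truth.enhancers.to_csv(os.path.join(outdir, "enhancers.tsv"), sep="\t", index=False)
    truth.links.to_csv(os.path.join(outdir, "links.tsv"), sep="\t", index=False)
    truth.stretches.to_csv(os.path.join(outdir, "stretches.tsv"), sep="\t", index=False)


def read_truth(outdir: str) -> TruthTable:
    def _read(name, cols=None):
        df = pd.read_csv(os.path.join(outdir, name), sep="\t", keep_default_na=False)
        return df

    return TruthTable(
        tss=_read("tss.tsv"),
        enhancers=_read("enhancers.tsv"),
        links=_read("links.tsv"),
        stretches=_read("stretches.tsv"),
    )


# ---------------------------------------------------------------------------
# matrix-only pair helper (for link power / error-control studies)
# ---------------------------------------------------------------------------


def linked_pair_matrices(
    n_pairs: int,
    n_samples: int,
    rho: float,
    seed: int,
    nb_mean: float = 20.0,
    nb_dispersion: float = 10.0,
    latent_sigma: float = 1.2,
    spacing: int = 30000,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Expression matrices for ``n_pairs`` isolated enhancer-TSS pairs.

    Pair *i* sits at ``i * spacing`` on one chromosome with a 1.4 kb gap
    between the pair's spans, so only the planted pairs fall within the
    default 10 kb link-testing window.  Counts follow the same NB /
    lognormal-latent model as the full generator, with latent correlation
    ``rho`` inside each pair; with one tag = one CTPM unit (library size
    1e6), values double as CTPM.
    """
    rng = np.random.default_rng(seed)
    sample_ids = [f"s{i:03d}" for i in range(n_samples)]
    enh_rows, tss_rows = [], []
    enh_vals = np.zeros((n_pairs, n_samples))
    tss_vals = np.zeros((n_pairs, n_samples))
    for i in range(n_pairs):
        a, b = _coupled_normals(rng, n_samples, rho)
        enh_mean = nb_mean * np.exp(latent_sigma * a)
        tss_mean = nb_mean * np.exp(latent_sigma * b)
        enh_vals[i] = _nb_draw(rng, enh_mean, nb_dispersion)
        tss_vals[i] = _nb_draw(rng, tss_mean, nb_dispersion)
        base = i * spacing
        enh_rows.append(
            {
                "cluster_id": f"enh{i:04d}",
                "chrom": "chrS",
                "start": base + 1000,
                "end": base + 1600,
                "midpoint": base + 1300,
                "pooled_count": int(enh_vals[i].sum()),
            }
        )
        tss_rows.append(
            {
                "cluster_id": f"tss{i:04d}",
                "chrom": "chrS",
                "start": base + 3000,
                "end": base + 3050,
                "strand": "+",
                "peak_pos": base + 3000,
                "pooled_count": int(tss_vals[i].sum()),
            }
        )
    enh_meta = pd.DataFrame(enh_rows)
    tss_meta = pd.DataFrame(tss_rows)
    enh_meta["n_support"] = (enh_vals > 0).sum(axis=1)
    tss_meta["n_support"] = (tss_vals > 0).sum(axis=1)
    enh_matrix = ExpressionMatrix(
        values=pd.DataFrame(enh_vals, index=enh_meta["cluster_id"].tolist(), columns=sample_ids),
        clusters=enh_meta,
        kind="enhancer",
    )
    tss_matrix = ExpressionMatrix(
        values=pd.DataFrame(tss_vals, index=tss_meta["cluster_id"].tolist(), columns=sample_ids),
        clusters=tss_meta,
        kind="tss",
    )
    return enh_matrix, tss_matrix
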