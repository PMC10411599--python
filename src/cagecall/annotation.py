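"""Transcript-feature annotation of called clusters.

Each cluster is anchored on a single base pair — the peak for TSS
clusters, the midpoint for enhancers — and tested against a fixed
hierarchy of nine categories; the first hit wins, so every cluster gets
exactly one category:

    promoter > proximal > fiveUTR > threeUTR > CDS > exon > intron
             > antisense > intergenic

"promoter" means within +-promoter_halfwidth of a same-strand annotated
transcript start; "proximal" within proximal_upstream bp upstream of one;
the feature categories are same-strand overlaps; "antisense" is overlap
with a gene span on the opposite strand only.  Enhancers are strandless:
they are tested against both strands and can never be antisense.

Clusters whose anchor falls outside every (upstream-extended) gene span
receive a deterministic novel gene id, numbered in genome order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ctss_io import GeneModels

HIERARCHY = (
    "promoter",
    "proximal",
    "fiveUTR",
    "threeUTR",
    "CDS",
    "exon",
    "intron",
    "antisense",
    "intergenic",
)

_FEATURE_KINDS = {"fiveUTR": "five_prime_UTR", "threeUTR": "three_prime_UTR", "CDS": "CDS", "exon": "exon"}


@dataclass
class AnnotationConfig:
    promoter_halfwidth: int = 100
    proximal_upstream: int = 1000
    hierarchy: tuple[str, ...] = HIERARCHY

    def __post_init__(self) -> None:
        if self.promoter_halfwidth <= 0 or self.proximal_upstream <= 0:
            raise ValueError("annotation window widths must be > 0")
        if tuple(self.hierarchy) != HIERARCHY:
            raise ValueError(f"hierarchy must be exactly {HIERARCHY}")


class _ModelIndex:
    """Per-chromosome numpy arrays for fast anchored lookups."""

    def __init__(self, models: GeneModels):
        tx = models.transcripts.copy()
        # strand-aware transcript 5' starts (0-based bp of the first transcribed base)
        tx["tss"] = np.where(tx["strand"] == "+", tx["start"], tx["end"] - 1)
        self.tx_starts: dict[tuple[str, str], np.ndarray] = {}
        self.tx_ids: dict[tuple[str, str], np.ndarray] = {}
        self.tx_spans: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
        for (chrom, strand), sub in tx.groupby(["chrom", "strand"]):
            self.tx_starts[(chrom, strand)] = sub["tss"].to_numpy()
            self.tx_ids[(chrom, strand)] = sub["tx_id"].to_numpy()
            self.tx_spans[(chrom, strand)] = (sub["start"].to_numpy(), sub["end"].to_numpy())
        self.features: dict[tuple[str, str, str], tuple[np.ndarray, np.ndarray]] = {}
        for (chrom, strand, kind), sub in models.features.groupby(["chrom", "strand", "kind"]):
            self.features[(chrom, strand, kind)] = (sub["start"].to_numpy(), sub["end"].to_numpy())
        g = models.genes
        self.genes: dict[tuple[str, str], pd.DataFrame] = {
            (chrom, strand): sub for (chrom, strand), sub in g.groupby([g["chrom"], g["strand"]])
        }

    def tx_start_distance(self, chrom: str, strand: str, anchor: int) -> int | None:
        starts = self.tx_starts.get((chrom, strand))
        if starts is None or len(starts) == 0:
            return None
        return int(np.abs(starts - anchor).min())

    def is_upstream_proximal(self, chrom: str, strand: str, anchor: int, width: int) -> bool:
        starts = self.tx_starts.get((chrom, strand))
        if starts is None or len(starts) == 0:
            return False
        if strand == "+":
            return bool(np.any((anchor >= starts - width) & (anchor < starts)))
        return bool(np.any((anchor > starts) & (anchor <= starts + width)))

    def overlaps_feature(self, chrom: str, strand: str, kind: str, anchor: int) -> bool:
        arrs = self.features.get((chrom, strand, kind))
        if arrs is None:
            return False
        starts, ends = arrs
        return bool(np.any((starts <= anchor) & (anchor < ends)))

    def overlaps_tx_span(self, chrom: str, strand: str, anchor: int) -> bool:
        spans = self.tx_spans.get((chrom, strand))
        if spans is None:
            return False
        starts, ends = spans
        return bool(np.any((starts <= anchor) & (anchor < ends)))

    def overlaps_gene_span(self, chrom: str, strand: str, anchor: int) -> bool:
        sub = self.genes.get((chrom, strand))
        if sub is None:
            return False
        return bool(np.any((sub["start"].to_numpy() <= anchor) & (anchor < sub["end"].to_numpy())))

    def containing_genes_extended(self, chrom: str, strand: str, anchor: int, upstream: int) -> pd.DataFrame:
        sub = self.genes.get((chrom, strand))
        if sub is None:
            return pd.DataFrame(columns=["gene_id", "start", "end", "strand"])
        starts = sub["start"].to_numpy().copy()
        ends = sub["end"].to_numpy().copy()
        if strand == "+":
            starts = starts - upstream
        else:
            ends = ends + upstream
        hit = (starts <= anchor) & (anchor < ends)
        return sub[hit]


def _anchor(cluster) -> int:
    return int(cluster.peak_pos) if hasattr(cluster, "peak_pos") else int(cluster.midpoint)


def assign_tx_type(cluster, index_or_models, cfg: AnnotationConfig) -> str:
    """Category for one cluster row (a namedtuple from ``itertuples``)."""
    index = index_or_models if isinstance(index_or_models, _ModelIndex) else _ModelIndex(index_or_models)
    anchor = _anchor(cluster)
    stranded = hasattr(cluster, "strand") and cluster.strand in ("+", "-")
    strands = (cluster.strand,) if stranded else ("+", "-")
    chrom = cluster.chrom
    for strand in strands:
        d = index.tx_start_distance(chrom, strand, anchor)
        if d is not None and d <= cfg.promoter_halfwidth:
            return "promoter"
    for strand in strands:
        if index.is_upstream_proximal(chrom, strand, anchor, cfg.proximal_upstream):
            return "proximal"
    for category in ("fiveUTR", "threeUTR", "CDS", "exon"):
        kind = _FEATURE_KINDS[category]
        if any(index.overlaps_feature(chrom, strand, kind, anchor) for strand in strands):
            return category
    if any(index.overlaps_tx_span(chrom, strand, anchor) for strand in strands):
        return "intron"
    if stranded:
        opposite = "-" if cluster.strand == "+" else "+"
        if index.overlaps_gene_span(chrom, opposite, anchor):
            return "antisense"
    return "intergenic"


def annotate_clusters(
    clusters: pd.DataFrame, models: GeneModels, cfg: AnnotationConfig | None = None
) -> pd.DataFrame:
    """Assign tx_type, gene_id and is_novel to every cluster.

    Novel ids are minted as NOVELG%06d in genome order over the novel
    clusters of this call, so re-running on the same input is
    deterministic and idempotent.
    """
    cfg = cfg or AnnotationConfig()
    index = _ModelIndex(models)
    out = clusters.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True).copy()
    tx_types = []
    gene_ids = []
    novel_flags = []
    novel_counter = 0
    tx_by_gene = models.transcripts.groupby("gene_id", sort=False)
    for r in out.itertuples():
        tx_types.append(assign_tx_type(r, index, cfg))
        anchor = _anchor(r)
        stranded = hasattr(r, "strand") and r.strand in ("+", "-")
        strands = (r.strand,) if stranded else ("+", "-")
        hits = pd.concat(
            [index.containing_genes_extended(r.chrom, s, anchor, cfg.proximal_upstream) for s in strands]
        )
        if len(hits) == 0:
            novel_counter += 1
            gene_ids.append(f"NOVELG{novel_counter:06d}")
            novel_flags.append(True)
        else:
            best_gene, best_dist = None, None
            for g in hits.itertuples():
                if g.gene_id in tx_by_gene.groups:
                    tx = tx_by_gene.get_group(g.gene_id)
                    starts = np.where(tx["strand"] == "+", tx["start"], tx["end"] - 1)
                    dist = int(np.abs(starts - anchor).min())
                else:
                    dist = int(min(abs(g.start - anchor), abs(g.end - 1 - anchor)))
                if best_dist is None or dist < best_dist or (dist == best_dist and g.gene_id < best_gene):
                    best_gene, best_dist = g.gene_id, dist
            gene_ids.append(best_gene)
            novel_flags.append(False)
    out["tx_type"] = tx_types
    out["gene_id"] = gene_ids
    out["is_novel"] = novel_flags
    return out


def category_counts(annotated: pd.DataFrame) -> pd.DataFrame:
    """Novel/annotated counts per category (rows follow the hierarchy order)."""
    rows = []
    for category in HIERARCHY:
        sub = annotated[annotated["tx_type"] == category]
        rows.append((category, int(sub["is_novel"].sum()), int((~sub["is_novel"]).sum()), len(sub)))
    return pd.DataFrame(rows, columns=["category", "novel", "annotated", "total"])


def tss_per_gene_summary(annotated: pd.DataFrame) -> pd.Series:
    """Distribution of cluster counts per assigned (non-novel) gene."""
    named = annotated[~annotated["is_novel"]]
    counts = named.groupby("gene_id").size()
    return counts.describe()
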