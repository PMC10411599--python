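"""I/O for CAGE 5'-end signal and the annotation formats around it.

The native signal format is the strand-specific bedGraph: one file per
sample per strand holding positive integer counts of CAGE tag 5' ends at
base-pair resolution.  Gene models arrive as GFF3, called clusters leave
as BED6/BED12, matrices and sample sheets as TSV.

All in-memory coordinates are 0-based half-open; GFF3's 1-based closed
coordinates are converted on the way in and out.  A CTSS position is a
single base pair.  The 5'-end convention (minus-strand 5' end = rightmost
base of the read) is assumed to have been applied by the upstream mapper,
since the inputs are per-strand 5'-coverage tracks.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import gffutils
import numpy as np
import pandas as pd

STRANDS = ("+", "-")

#: columns of the per-track / pooled signal frames
SIGNAL_COLUMNS = ["chrom", "pos", "strand", "count"]


class FormatError(ValueError):
    """A file violates its declared format."""


class GffParseError(FormatError):
    """A GFF3 file is structurally invalid (orphans, bad nesting)."""


@dataclass
class CtssTrack:
    """One sample's per-strand per-bp 5'-end tag counts.

    ``library_size`` is the sample's total mapped tags.  It is taken from
    the sample sheet rather than recomputed from the track, because
    tags-per-million normalization is relative to *all* mapped tags,
    including those outside retained positions — so ``library_size`` may
    exceed the stored tag mass.
    """

    sample_id: str
    library_size: int
    data: pd.DataFrame  # columns: chrom, pos, strand, count

    def __post_init__(self) -> None:
        if self.library_size <= 0:
            raise ValueError(f"library_size must be positive, got {self.library_size}")
        if list(self.data.columns) != SIGNAL_COLUMNS:
            self.data = self.data[SIGNAL_COLUMNS]
        if len(self.data) and (self.data["count"] < 1).any():
            raise ValueError("CTSS counts must be >= 1 (zero positions are absent)")
        self.data = self.data.sort_values(["chrom", "strand", "pos"], kind="mergesort").reset_index(drop=True)

    @property
    def total_tags(self) -> int:
        return int(self.data["count"].sum())


@dataclass
class GeneModels:
    """Gene/transcript/feature model derived from a GFF3 file.

    All intervals 0-based half-open.  ``features`` holds per-transcript
    exon/CDS/five_prime_UTR/three_prime_UTR intervals; UTRs are derived
    from exon-minus-CDS when not explicit in the source file.
    """

    genes: pd.DataFrame  # gene_id, symbol, chrom, start, end, strand
    transcripts: pd.DataFrame  # tx_id, gene_id, chrom, start, end, strand
    features: pd.DataFrame  # tx_id, kind, chrom, start, end, strand


def read_ctss_bedgraph(path_plus: str, path_minus: str, sample_id: str, library_size: int) -> CtssTrack:
    """Read a pair of per-strand bedGraph files into a :class:`CtssTrack`.

    Intervals wider than 1 bp are expanded to per-bp entries carrying the
    same value, so total tag mass is conserved:
    ``sum(per-bp counts) == sum((end - start) * value)`` over input lines.
    """
    frames = [_read_bedgraph_strand(path_plus, "+"), _read_bedgraph_strand(path_minus, "-")]
    data = pd.concat(frames, ignore_index=True)
    return CtssTrack(sample_id=sample_id, library_size=library_size, data=data)


def _read_bedgraph_strand(path: str, strand: str) -> pd.DataFrame:
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    values: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns, got {len(parts)}")
            chrom, s, e, v = parts[0], parts[1], parts[2], parts[3]
            try:
                start, end = int(s), int(e)
                value = float(v)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: unparsable coordinates or value") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start {start} >= end {end}")
            if value <= 0 or value != int(value):
                raise FormatError(f"{path}:{lineno}: value must be a positive integer, got {v}")
            chroms.append(chrom)
            starts.append(start)
            ends.append(end)
            values.append(int(value))
    if not chroms:
        return pd.DataFrame({"chrom": [], "pos": [], "strand": [], "count": []}).astype(
            {"chrom": str, "pos": np.int64, "count": np.int64}
        )[SIGNAL_COLUMNS]
    start_a = np.asarray(starts, dtype=np.int64)
    width = np.asarray(ends, dtype=np.int64) - start_a
    # expand each interval [start, end) to per-bp rows
    total = int(width.sum())
    offsets = np.arange(total) - np.repeat(np.cumsum(width) - width, width)
    pos = np.repeat(start_a, width) + offsets
    out = pd.DataFrame(
        {
            "chrom": np.repeat(np.asarray(chroms, dtype=object), width),
            "pos": pos,
            "strand": strand,
            "count": np.repeat(np.asarray(values, dtype=np.int64), width),
        }
    )
    return out[SIGNAL_COLUMNS]


def write_ctss_bedgraph(track: CtssTrack, path_plus: str, path_minus: str) -> None:
    """Write a track back to a pair of per-strand bedGraph files (1-bp lines)."""
    for path, strand in ((path_plus, "+"), (path_minus, "-")):
        sub = track.data[track.data["strand"] == strand].sort_values(["chrom", "pos"], kind="mergesort")
        with open(path, "w") as fh:
            for chrom, pos, count in zip(sub["chrom"], sub["pos"], sub["count"]):
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{count}\n")


def read_ctss_bigwig(path_plus: str, path_minus: str, sample_id: str, library_size: int) -> CtssTrack:
    """Optional bigWig reader behind the same contract as the bedGraph one.

    Requires pyBigWig.  Values must be positive integers (raw tag counts,
    not pre-normalized tags-per-million).
    """
    try:
        import pyBigWig
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("pyBigWig is required for bigWig input; install the 'bigwig' extra") from exc

    frames = []
    for path, strand in ((path_plus, "+"), (path_minus, "-")):
        bw = pyBigWig.open(path)
        try:
            for chrom, length in bw.chroms().items():
                for start, end, value in bw.intervals(chrom, 0, length) or []:
                    if value <= 0 or value != int(value):
                        raise FormatError(f"{path}:{chrom}:{start}: value must be a positive integer")
                    pos = np.arange(start, end, dtype=np.int64)
                    frames.append(
                        pd.DataFrame({"chrom": chrom, "pos": pos, "strand": strand, "count": int(value)})
                    )
        finally:
            bw.close()
    if frames:
        data = pd.concat(frames, ignore_index=True)[SIGNAL_COLUMNS]
    else:
        data = pd.DataFrame({"chrom": [], "pos": [], "strand": [], "count": []})[SIGNAL_COLUMNS]
    return CtssTrack(sample_id=sample_id, library_size=library_size, data=data)


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

_TX_TYPES = ("mRNA", "transcript")
_UTR5 = "five_prime_UTR"
_UTR3 = "three_prime_UTR"


def read_gene_models_gff3(path: str) -> GeneModels:
    """Parse GFF3 gene models into a :class:`GeneModels` object.

    Coordinates are converted from GFF3's 1-based closed to 0-based
    half-open.  UTRs are derived from exon-minus-CDS when not explicit;
    transcripts without CDS are treated as non-coding (exon features only).
    A child feature whose Parent is absent raises :class:`GffParseError`
    naming the orphan.
    """
    _check_orphans(path)
    db = gffutils.create_db(
        str(path), ":memory:", keep_order=True, merge_strategy="create_unique", force=True
    )
    genes = []
    transcripts = []
    features = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        gene_id = gene.id
        symbol = gene.attributes.get("Name", [gene_id])[0]
        g_start, g_end = gene.start - 1, gene.end
        genes.append((gene_id, symbol, gene.seqid, g_start, g_end, gene.strand))
        for tx in db.children(gene, featuretype=_TX_TYPES, order_by="start"):
            t_start, t_end = tx.start - 1, tx.end
            if t_start < g_start or t_end > g_end:
                raise GffParseError(f"transcript {tx.id} extends outside its gene {gene_id}")
            transcripts.append((tx.id, gene_id, tx.seqid, t_start, t_end, tx.strand))
            exons = sorted(
                (f.start - 1, f.end) for f in db.children(tx, featuretype="exon")
            )
            for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                if s2 < e1:
                    raise GffParseError(f"transcript {tx.id} has overlapping exons")
            cds = sorted((f.start - 1, f.end) for f in db.children(tx, featuretype="CDS"))
            explicit_utrs = [
                (f.featuretype, f.start - 1, f.end)
                for f in db.children(tx, featuretype=(_UTR5, _UTR3))
            ]
            for s, e in exons:
                features.append((tx.id, "exon", tx.seqid, s, e, tx.strand))
            for s, e in cds:
                features.append((tx.id, "CDS", tx.seqid, s, e, tx.strand))
            if explicit_utrs:
                for kind, s, e in explicit_utrs:
                    features.append((tx.id, kind, tx.seqid, s, e, tx.strand))
            elif cds:
                for kind, s, e in derive_utrs(exons, cds, tx.strand):
                    features.append((tx.id, kind, tx.seqid, s, e, tx.strand))
    return GeneModels(
        genes=pd.DataFrame(genes, columns=["gene_id", "symbol", "chrom", "start", "end", "strand"]),
        transcripts=pd.DataFrame(
            transcripts, columns=["tx_id", "gene_id", "chrom", "start", "end", "strand"]
        ),
        features=pd.DataFrame(features, columns=["tx_id", "kind", "chrom", "start", "end", "strand"]),
    )


def _check_orphans(path: str) -> None:
    ids: set[str] = set()
    parents: list[tuple[str, str]] = []  # (child ID or '?', parent)
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise GffParseError(f"{path}: GFF3 line with fewer than 9 columns")
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            if "ID" in attrs:
                ids.add(attrs["ID"])
            if "Parent" in attrs:
                child = attrs.get("ID", f"<{cols[2]} {cols[0]}:{cols[3]}>")
                for parent in attrs["Parent"].split(","):
                    parents.append((child, parent))
    orphans = sorted({child for child, parent in parents if parent not in ids})
    if orphans:
        raise GffParseError(f"{path}: features reference missing parents: {', '.join(orphans)}")


def derive_utrs(
    exons: list[tuple[int, int]], cds: list[tuple[int, int]], strand: str
) -> list[tuple[str, int, int]]:
    """Split exonic-minus-CDS intervals into 5' and 3' UTR pieces.

    Exonic sequence left of the CDS span is 5' UTR on the plus strand and
    3' UTR on the minus strand (and vice versa on the right).
    """
    if not cds:
        return []
    cds_lo = min(s for s, _ in cds)
    cds_hi = max(e for _, e in cds)
    left_kind = _UTR5 if strand == "+" else _UTR3
    right_kind = _UTR3 if strand == "+" else _UTR5
    out = []
    for s, e in exons:
        if s < cds_lo:
            out.append((left_kind, s, min(e, cds_lo)))
        if e > cds_hi:
            out.append((right_kind, max(s, cds_hi), e))
    return out


def write_gene_models_gff3(models: GeneModels, path: str) -> None:
    """Write gene/mRNA/exon/CDS records (UTRs are derivable, not written)."""
    tx_by_gene = models.transcripts.groupby("gene_id", sort=False)
    feat_by_tx = models.features.groupby("tx_id", sort=False)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in models.genes.sort_values(["chrom", "start"], kind="mergesort").itertuples():
            fh.write(
                f"{g.chrom}\t.\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id};Name={g.symbol}\n"
            )
            if g.gene_id not in tx_by_gene.groups:
                continue
            for tx in tx_by_gene.get_group(g.gene_id).itertuples():
                fh.write(
                    f"{tx.chrom}\t.\tmRNA\t{tx.start + 1}\t{tx.end}\t.\t{tx.strand}\t.\t"
                    f"ID={tx.tx_id};Parent={g.gene_id}\n"
                )
                if tx.tx_id not in feat_by_tx.groups:
                    continue
                feats = feat_by_tx.get_group(tx.tx_id)
                for kind in ("exon", "CDS"):
                    for f in feats[feats["kind"] == kind].sort_values("start").itertuples():
                        fh.write(
                            f"{f.chrom}\t.\t{kind}\t{f.start + 1}\t{f.end}\t.\t{f.strand}\t.\t"
                            f"Parent={tx.tx_id}\n"
                        )


# ---------------------------------------------------------------------------
# BED cluster tracks
# ---------------------------------------------------------------------------


def write_clusters_bed(clusters: pd.DataFrame, path: str) -> None:
    """Write called clusters to BED.

    TSS clusters (frames with a ``peak_pos`` column) become BED12 with the
    1-bp peak as thickStart/thickEnd and score = min(1000, round(pooled
    CTPM)).  Enhancer clusters (frames with a ``midpoint`` column) become
    BED6 with strand ".".  Input must already be sorted by (chrom, start);
    unsorted input is an error, never silently sorted.
    """
    order = clusters[["chrom", "start"]]
    if not order.equals(order.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)):
        raise ValueError("clusters must be sorted by (chrom, start) before writing BED")
    is_tss = "peak_pos" in clusters.columns
    with open(path, "w") as fh:
        for c in clusters.itertuples():
            score = min(1000, int(round(c.pooled_ctpm)))
            if is_tss:
                size = c.end - c.start
                fh.write(
                    f"{c.chrom}\t{c.start}\t{c.end}\t{c.cluster_id}\t{score}\t{c.strand}\t"
                    f"{c.peak_pos}\t{c.peak_pos + 1}\t0\t1\t{size}\t0\n"
                )
            else:
                fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.cluster_id}\t{score}\t.\n")


def read_clusters_bed(path: str) -> pd.DataFrame:
    """Read a BED file written by :func:`write_clusters_bed`.

    Returns a frame with chrom/start/end/cluster_id/score/strand and, for
    BED12 input, the peak position (``peak_pos``).
    """
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) not in (6, 12):
                raise FormatError(f"{path}:{lineno}: expected BED6 or BED12, got {len(parts)} columns")
            row = {
                "chrom": parts[0],
                "start": int(parts[1]),
                "end": int(parts[2]),
                "cluster_id": parts[3],
                "score": int(parts[4]),
                "strand": parts[5],
            }
            if len(parts) == 12:
                row["peak_pos"] = int(parts[6])
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Sample sheets and matrices
# ---------------------------------------------------------------------------

SAMPLE_SHEET_REQUIRED = ["sample_id", "tissue", "population", "path_plus", "path_minus", "library_size"]


def read_sample_sheet(path: str) -> pd.DataFrame:
    """Read the TSV sample sheet (sample_id, tissue, population, sex?, paths, library_size)."""
    sheet = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "tissue": str, "population": str})
    missing = [c for c in SAMPLE_SHEET_REQUIRED if c not in sheet.columns]
    if missing:
        raise FormatError(f"{path}: sample sheet missing columns: {', '.join(missing)}")
    if sheet["sample_id"].duplicated().any():
        dups = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"{path}: duplicate sample ids: {dups}")
    if (sheet["library_size"] <= 0).any():
        raise FormatError(f"{path}: library_size must be positive for all samples")
    return sheet


def load_tracks(sheet: pd.DataFrame, base_dir: str | None = None) -> list[CtssTrack]:
    """Load every sample's track pair listed in a sample sheet."""
    tracks = []
    for row in sheet.itertuples():
        p_plus, p_minus = row.path_plus, row.path_minus
        if base_dir is not None:
            p_plus = os.path.join(base_dir, p_plus)
            p_minus = os.path.join(base_dir, p_minus)
        tracks.append(
            read_ctss_bedgraph(p_plus, p_minus, sample_id=row.sample_id, library_size=int(row.library_size))
        )
    return tracks


def write_tsv(frame: pd.DataFrame, path: str, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index)


def read_tsv(path: str, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
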