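"""Pooling, normalization and cluster calling for CAGE 5'-end signal.

The workflow mirrors the standard CAGE tag-clustering recipe:

1. pool per-sample counts across the data set and normalize each sample to
   CAGE tags per million mapped (CTPM = count * 1e6 / library_size);
2. call *unidirectional* clusters — maximal same-strand runs of nonzero
   positions whose successive gaps stay within a merge distance — as
   putative TSS, each with a dominant peak position;
3. call *bidirectional* clusters — loci where minus-strand signal sits
   upstream and plus-strand signal downstream of a midpoint — as putative
   enhancers, scored by a Bhattacharyya balance against the ideal
   divergent profile;
4. quantify per-sample CTPM over each cluster span and filter clusters by
   pooled tag count and sample support.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ctss_io import SIGNAL_COLUMNS, CtssTrack


@dataclass
class PooledSignal:
    """Pooled raw counts and CTPM on the union of nonzero CTSS positions."""

    data: pd.DataFrame  # columns: chrom, pos, strand, count, ctpm

    def strand_arrays(self, chrom: str, strand: str) -> tuple[np.ndarray, np.ndarray]:
        """Sorted positions and CTPM values for one (chrom, strand)."""
        sub = self.data[(self.data["chrom"] == chrom) & (self.data["strand"] == strand)]
        return sub["pos"].to_numpy(), sub["ctpm"].to_numpy()

    @property
    def chroms(self) -> list[str]:
        return sorted(self.data["chrom"].unique())


@dataclass
class ExpressionMatrix:
    """Per-cluster, per-sample CTPM with aligned cluster metadata.

    ``values`` is indexed by cluster_id with one column per sample, in
    sample-sheet order; ``clusters`` carries coordinates and bookkeeping
    in the same row order.
    """

    values: pd.DataFrame
    clusters: pd.DataFrame
    kind: str  # "tss" or "enhancer"

    def __post_init__(self) -> None:
        if list(self.values.index) != list(self.clusters["cluster_id"]):
            raise ValueError("matrix rows must align with the cluster list")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def pool_and_normalize(tracks: list[CtssTrack]) -> PooledSignal:
    """Sum raw counts and per-sample CTPM over samples, per (chrom, pos, strand)."""
    if not tracks:
        raise ValueError("at least one track is required")
    parts = []
    for t in tracks:
        part = t.data.copy()
        part["ctpm"] = part["count"] * 1e6 / t.library_size
        parts.append(part)
    pooled = (
        pd.concat(parts, ignore_index=True)
        .groupby(["chrom", "strand", "pos"], as_index=False, sort=True)[["count", "ctpm"]]
        .sum()
    )
    pooled = pooled[["chrom", "pos", "strand", "count", "ctpm"]]
    return PooledSignal(data=pooled)


# ---------------------------------------------------------------------------
# Unidirectional (TSS) clusters
# ---------------------------------------------------------------------------


def cluster_unidirectional(pooled: PooledSignal, merge_dist: int = 20) -> pd.DataFrame:
    """Call unidirectional tag clusters per strand.

    On each strand independently, maximal runs of nonzero positions whose
    successive position differences are <= ``merge_dist`` form one
    cluster.  The peak is the member position with maximal pooled CTPM,
    ties broken toward the strand's 5' side.  Returns a frame sorted by
    (chrom, start, strand) with columns cluster_id, chrom, start, end,
    strand, peak_pos, pooled_count, pooled_ctpm.
    """
    if merge_dist < 0:
        raise ValueError("merge_dist must be >= 0")
    df = pooled.data
    if df.empty:
        return _empty_tss_frame()
    rows = []
    for (chrom, strand), sub in df.groupby(["chrom", "strand"], sort=True):
        pos = sub["pos"].to_numpy()
        count = sub["count"].to_numpy()
        ctpm = sub["ctpm"].to_numpy()
        bounds = np.flatnonzero(np.diff(pos) > merge_dist) + 1
        starts_idx = np.concatenate([[0], bounds])
        ends_idx = np.concatenate([bounds, [len(pos)]])
        count_sums = np.add.reduceat(count, starts_idx)
        ctpm_sums = np.add.reduceat(ctpm, starts_idx)
        for k, (i, j) in enumerate(zip(starts_idx, ends_idx)):
            c = ctpm[i:j]
            best = np.flatnonzero(c == c.max())
            peak = pos[i + (best[0] if strand == "+" else best[-1])]
            rows.append(
                (chrom, int(pos[i]), int(pos[j - 1]) + 1, strand, int(peak), int(count_sums[k]), float(ctpm_sums[k]))
            )
    out = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "peak_pos", "pooled_count", "pooled_ctpm"]
    ).sort_values(["chrom", "start", "strand"], kind="mergesort").reset_index(drop=True)
    out.insert(
        0,
        "cluster_id",
        [f"{r.chrom}:{r.start}-{r.end};{r.strand}" for r in out.itertuples()],
    )
    return out


def _empty_tss_frame() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["cluster_id", "chrom", "start", "end", "strand", "peak_pos", "pooled_count", "pooled_ctpm"]
    )


# ---------------------------------------------------------------------------
# Bidirectional (enhancer) clusters
# ---------------------------------------------------------------------------


def balance_score(pooled: PooledSignal, chrom: str, midpoint: int, radius: int) -> float:
    """Bhattacharyya balance of divergent transcription around ``midpoint``.

    With M_U = minus-strand CTPM in [midpoint - radius, midpoint), P_D =
    plus-strand CTPM in (midpoint, midpoint + radius], P_U / M_D their
    wrong-side counterparts and T the total:

        score = sqrt(0.5 * M_U / T) + sqrt(0.5 * P_D / T)

    i.e. the Bhattacharyya coefficient between the observed arm
    proportions and the ideal divergent profile (half minus-upstream,
    half plus-downstream).  Score is 0 when T == 0 and 1 for perfect
    balanced divergence; it is invariant to uniform scaling of the arms.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    m_pos, m_val = pooled.strand_arrays(chrom, "-")
    p_pos, p_val = pooled.strand_arrays(chrom, "+")

    def wsum(pos, val, lo, hi):  # sum over [lo, hi)
        i, j = np.searchsorted(pos, (lo, hi))
        return float(val[i:j].sum())

    m_u = wsum(m_pos, m_val, midpoint - radius, midpoint)
    p_d = wsum(p_pos, p_val, midpoint + 1, midpoint + radius + 1)
    p_u = wsum(p_pos, p_val, midpoint - radius, midpoint)
    m_d = wsum(m_pos, m_val, midpoint + 1, midpoint + radius + 1)
    total = m_u + p_d + p_u + m_d
    if total == 0:
        return 0.0
    return math.sqrt(0.5 * m_u / total) + math.sqrt(0.5 * p_d / total)


def cluster_bidirectional(
    pooled: PooledSignal,
    radius: int = 500,
    balance_threshold: float = 0.95,
    max_span: int = 1000,
    tss_mask: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Call bidirectional (enhancer) clusters from pooled signal.

    Every genomic position within the signal's extent is scored with
    :func:`balance_score`; positions at or above ``balance_threshold``
    are candidate midpoints.  Overlapping candidate windows
    [midpoint - radius, midpoint + radius) are merged keeping the
    maximally balanced midpoint (ties: the middle of the tied run).  The
    cluster span is trimmed to the outermost nonzero position (either
    strand) within the window; spans wider than ``max_span`` are
    discarded.  When ``tss_mask`` (a frame of cluster spans) is supplied,
    enhancers overlapping any masked span are dropped.
    """
    if not (0 < balance_threshold <= 1):
        raise ValueError("balance_threshold must lie in (0, 1]")
    if radius <= 0 or radius > max_span:
        raise ValueError("require 0 < radius <= max_span")
    rows = []
    for chrom in pooled.chroms:
        m_pos, m_val = pooled.strand_arrays(chrom, "-")
        p_pos, p_val = pooled.strand_arrays(chrom, "+")
        if len(m_pos) == 0 or len(p_pos) == 0:
            continue
        all_pos = np.union1d(m_pos, p_pos)
        lo = int(all_pos.min())
        hi = int(all_pos.max())
        mid = np.arange(lo, hi + 1, dtype=np.int64)

        m_cum = np.concatenate([[0.0], np.cumsum(m_val)])
        p_cum = np.concatenate([[0.0], np.cumsum(p_val)])

        def wsum(pos, cum, lo_a, hi_a):  # vectorized sum over [lo_a, hi_a)
            return cum[np.searchsorted(pos, hi_a)] - cum[np.searchsorted(pos, lo_a)]

        m_u = wsum(m_pos, m_cum, mid - radius, mid)
        p_d = wsum(p_pos, p_cum, mid + 1, mid + radius + 1)
        p_u = wsum(p_pos, p_cum, mid - radius, mid)
        m_d = wsum(m_pos, m_cum, mid + 1, mid + radius + 1)
        total = m_u + p_d + p_u + m_d
        with np.errstate(invalid="ignore", divide="ignore"):
            score = np.where(
                total > 0, np.sqrt(0.5 * m_u / np.maximum(total, 1e-300)) + np.sqrt(0.5 * p_d / np.maximum(total, 1e-300)), 0.0
            )
        cand = np.flatnonzero(score >= balance_threshold - 1e-12)
        if len(cand) == 0:
            continue
        # resolve overlapping candidate windows greedily: take the maximally
        # balanced midpoint, suppress candidates whose windows overlap it
        # (gap < 2 * radius), repeat.  Ties are broken deterministically by
        # the middle of the first contiguous run of tied candidates.
        alive = np.ones(len(cand), dtype=bool)
        cand_mid = mid[cand]
        cand_score = score[cand]
        chosen_list = []
        while alive.any():
            live = np.flatnonzero(alive)
            smax = cand_score[live].max()
            tied = live[cand_score[live] >= smax - 1e-12]
            run_end = 1
            while run_end < len(tied) and tied[run_end] == tied[run_end - 1] + 1:
                run_end += 1
            run = tied[:run_end]
            pick = run[len(run) // 2]
            chosen_list.append(int(cand_mid[pick]))
            alive &= np.abs(cand_mid - cand_mid[pick]) >= 2 * radius
        for chosen in sorted(chosen_list):
            win_lo, win_hi = chosen - radius, chosen + radius  # inclusive window edges
            members = all_pos[(all_pos >= win_lo) & (all_pos <= win_hi)]
            if len(members) == 0:
                continue
            start, end = int(members.min()), int(members.max()) + 1
            if end - start > max_span:
                continue
            if not (start < chosen < end):
                continue
            rows.append((chrom, start, end, chosen, float(score[chosen - lo])))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "midpoint", "balance"])
    if not out.empty and tss_mask is not None and len(tss_mask):
        keep = []
        for r in out.itertuples():
            sub = tss_mask[tss_mask["chrom"] == r.chrom]
            overlaps = ((sub["start"] < r.end) & (sub["end"] > r.start)).any()
            keep.append(not overlaps)
        out = out[keep]
    out = out.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    if out.empty:
        return pd.DataFrame(
            columns=["cluster_id", "chrom", "start", "end", "midpoint", "balance", "pooled_count", "pooled_ctpm"]
        )
    # pooled mass over the span, both strands
    counts = []
    ctpms = []
    for r in out.itertuples():
        sub = pooled.data[
            (pooled.data["chrom"] == r.chrom)
            & (pooled.data["pos"] >= r.start)
            & (pooled.data["pos"] < r.end)
        ]
        counts.append(int(sub["count"].sum()))
        ctpms.append(float(sub["ctpm"].sum()))
    out["pooled_count"] = counts
    out["pooled_ctpm"] = ctpms
    out.insert(0, "cluster_id", [f"{r.chrom}:{r.start}-{r.end}" for r in out.itertuples()])
    return out


# ---------------------------------------------------------------------------
# Quantification and filtering
# ---------------------------------------------------------------------------


def quantify(clusters: pd.DataFrame, tracks: list[CtssTrack]) -> ExpressionMatrix:
    """Per-sample CTPM summed over each cluster's span.

    Strand-matched for TSS clusters (frames with a ``strand`` column of
    +/-); both strands for enhancers.  ``n_support`` is (re)computed as
    the number of samples with at least one raw tag in the span.  A
    cluster chromosome absent from a track simply contributes 0.
    """
    is_tss = "strand" in clusters.columns and set(clusters["strand"].unique()) <= {"+", "-"}
    kind = "tss" if is_tss else "enhancer"
    values = np.zeros((len(clusters), len(tracks)))
    for j, track in enumerate(tracks):
        index: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
        for (chrom, strand), sub in track.data.groupby(["chrom", "strand"], sort=False):
            pos = sub["pos"].to_numpy()
            cum = np.concatenate([[0], np.cumsum(sub["count"].to_numpy())])
            index[(chrom, strand)] = (pos, cum)
        scale = 1e6 / track.library_size
        for i, r in enumerate(clusters.itertuples()):
            strands = (r.strand,) if is_tss else ("+", "-")
            tags = 0
            for strand in strands:
                if (r.chrom, strand) not in index:
                    continue
                pos, cum = index[(r.chrom, strand)]
                a, b = np.searchsorted(pos, (r.start, r.end))
                tags += cum[b] - cum[a]
            values[i, j] = tags * scale
    vals = pd.DataFrame(values, index=list(clusters["cluster_id"]), columns=[t.sample_id for t in tracks])
    meta = clusters.reset_index(drop=True).copy()
    meta["n_support"] = (values > 0).sum(axis=1)
    return ExpressionMatrix(values=vals, clusters=meta, kind=kind)


def filter_by_support(
    matrix: ExpressionMatrix, min_pooled_count: int = 10, min_samples: int = 1
) -> ExpressionMatrix:
    """Keep clusters with pooled_count >= ``min_pooled_count`` AND support >= ``min_samples``.

    Row order is preserved.  Raising either threshold never adds a
    cluster (monotone).
    """
    if min_samples > len(matrix.sample_ids):
        raise ValueError("min_samples exceeds the number of samples")
    meta = matrix.clusters
    keep = (meta["pooled_count"] >= min_pooled_count) & (meta["n_support"] >= min_samples)
    return ExpressionMatrix(
        values=matrix.values.loc[keep.to_numpy()],
        clusters=meta[keep.to_numpy()].reset_index(drop=True),
        kind=matrix.kind,
    )
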