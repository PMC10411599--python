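"""Superenhancer stretch detection.

A stretch is a maximal chain of at least ``min_members`` enhancer
clusters on one chromosome in which every successive midpoint-to-midpoint
gap is at most ``merge_dist`` (default 10 kb) — a window-scan reading of
"several enhancers close together".  Chains are maximal and disjoint, so
no enhancer belongs to two stretches.  Each stretch is scored by the mean
pairwise Kendall tau-b between its members' per-sample expression rows.

The pervasiveness (sample-support) filter is deliberately *not* applied
before stretch detection: enhancer activity is inherently tissue
restricted, so stretches are scanned over the unfiltered enhancer set.

Stretches can be intersected with arbitrary interval sets (copy-number
variants, QTL windows, ...) via :func:`overlap_intervals`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .clustering import ExpressionMatrix
from .coexpression import kendall_tau_b


def find_stretches(
    enhancers: pd.DataFrame,
    enh_matrix: ExpressionMatrix | None = None,
    merge_dist: int = 10000,
    min_members: int = 3,
    use_edges: bool = False,
) -> pd.DataFrame:
    """Chain enhancers into stretches of >= ``min_members``.

    ``enhancers`` must be sorted by (chrom, midpoint).  Gaps are measured
    midpoint-to-midpoint by default; ``use_edges=True`` switches to
    edge-to-edge span distances.  Returns one row per stretch with member
    ids (in midpoint order), span, length and mean pairwise tau (NaN when
    no expression matrix is given).
    """
    order = enhancers[["chrom", "midpoint"]].reset_index(drop=True)
    if not order.equals(order.sort_values(["chrom", "midpoint"], kind="mergesort").reset_index(drop=True)):
        raise ValueError("enhancers must be sorted by (chrom, midpoint)")
    rows = []
    for chrom, sub in enhancers.groupby("chrom", sort=True):
        sub = sub.reset_index(drop=True)
        if use_edges:
            gaps = sub["start"].to_numpy()[1:] - sub["end"].to_numpy()[:-1]
            gaps = np.maximum(gaps, 0)
        else:
            gaps = np.diff(sub["midpoint"].to_numpy())
        group = np.concatenate([[0], np.cumsum(gaps > merge_dist)])
        for g in np.unique(group):
            members = sub[group == g]
            if len(members) < min_members:
                continue
            start = int(members["start"].min())
            end = int(members["end"].max())
            member_ids = list(members["cluster_id"])
            tau = _mean_pairwise_tau(member_ids, enh_matrix) if enh_matrix is not None else float("nan")
            rows.append(
                (
                    f"stretch:{chrom}:{start}-{end}",
                    chrom,
                    start,
                    end,
                    ",".join(member_ids),
                    len(member_ids),
                    end - start,
                    tau,
                )
            )
    return pd.DataFrame(
        rows,
        columns=["stretch_id", "chrom", "start", "end", "members", "n_members", "length", "mean_pairwise_tau"],
    )


def _mean_pairwise_tau(member_ids: list[str], matrix: ExpressionMatrix) -> float:
    taus = []
    for i, a in enumerate(member_ids):
        for b in member_ids[i + 1 :]:
            res = kendall_tau_b(matrix.values.loc[a].to_numpy(), matrix.values.loc[b].to_numpy())
            if res.tested:
                taus.append(res.tau)
    return float(np.mean(taus)) if taus else float("nan")


def overlap_intervals(stretches: pd.DataFrame, regions: pd.DataFrame) -> pd.DataFrame:
    """Intersect stretches with a set of 0-based half-open regions.

    ``regions`` needs columns chrom, start, end and region_id.  Every
    overlapping pair is reported with its exact overlap in bp (>= 1).
    """
    if (regions["start"] >= regions["end"]).any():
        bad = regions[regions["start"] >= regions["end"]].iloc[0]
        raise ValueError(f"malformed region {bad['region_id']}: start >= end")
    trees: dict[str, IntervalTree] = {}
    for r in regions.itertuples():
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, r.region_id)
    rows = []
    for s in stretches.itertuples():
        tree = trees.get(s.chrom)
        if tree is None:
            continue
        for hit in sorted(tree.overlap(s.start, s.end)):
            overlap = min(s.end, hit.end) - max(s.start, hit.begin)
            rows.append((s.stretch_id, hit.data, int(overlap)))
    return pd.DataFrame(rows, columns=["stretch_id", "region_id", "overlap_bp"])
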