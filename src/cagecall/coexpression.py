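"""Enhancer-TSS coexpression links.

Candidate links are all enhancer/TSS cluster pairs on the same chromosome
whose edge-to-edge gap is at most ``max_gap`` (default 10 kb).  Each pair
is tested with Kendall's tau-b over the per-sample CTPM rows; p-values
come from the tie-adjusted normal approximation and are adjusted with
Benjamini-Hochberg over all tested pairs.  Retained links satisfy both
p < p_threshold and q < fdr_threshold — the double criterion mirrors the
standard procedure even though the FDR cut dominates.

Links are classified by annotation and distance: *novel* when neither
endpoint has a non-novel gene id, otherwise *cis* (gap < 1 kb) or *trans*
(gap >= 1 kb).  The gap-versus-tau landscape can be summarized by a 2-D
product-Gaussian KDE, and per-class mean correlations compared with
Welch's unequal-variance t-test.
"""

from __future__ import annotations

import math
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .clustering import ExpressionMatrix


class TauResult(NamedTuple):
    tau: float
    p_value: float
    tested: bool


def kendall_tau_b(x, y) -> TauResult:
    """Kendall tau-b with tie correction and two-sided asymptotic p.

    A constant vector leaves tau undefined; the result is flagged
    ``tested=False`` (never NaN in output files).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("vectors must have equal length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return TauResult(0.0, 1.0, False)
    res = stats.kendalltau(x, y, variant="b", method="asymptotic")
    tau, p = float(res.statistic), float(res.pvalue)
    if math.isnan(tau):
        return TauResult(0.0, 1.0, False)
    return TauResult(tau, p, True)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _edge_gap(s1: int, e1: int, s2: int, e2: int) -> int:
    """Unsigned edge-to-edge distance between [s1,e1) and [s2,e2); 0 if touching."""
    if e1 <= s2:
        return s2 - e1
    if e2 <= s1:
        return s1 - e2
    return 0


def test_links(
    enh_matrix: ExpressionMatrix, tss_matrix: ExpressionMatrix, max_gap: int = 10000
) -> pd.DataFrame:
    """Kendall-test every same-chromosome enhancer/TSS pair within ``max_gap``.

    Returns all *tested* pairs (constant rows are untestable and skipped)
    with tau, p and BH q computed over the tested set.  ``signed_gap`` is
    negative when the enhancer lies upstream of the TSS on the TSS
    strand.
    """
    if list(enh_matrix.sample_ids) != list(tss_matrix.sample_ids):
        raise ValueError("enhancer and TSS matrices must share identical sample columns")
    enh = enh_matrix.clusters
    tss = tss_matrix.clusters
    rows = []
    for chrom, enh_sub in enh.groupby("chrom", sort=True):
        tss_sub = tss[tss["chrom"] == chrom]
        if tss_sub.empty:
            continue
        t_start = tss_sub["start"].to_numpy()
        t_end = tss_sub["end"].to_numpy()
        for e in enh_sub.itertuples():
            gap_up = t_start - e.end  # >0 when TSS right of enhancer
            gap_dn = e.start - t_end  # >0 when TSS left of enhancer
            gaps = np.maximum(np.maximum(gap_up, gap_dn), 0)
            near = np.flatnonzero(gaps <= max_gap)
            for k in near:
                t = tss_sub.iloc[k]
                res = kendall_tau_b(
                    enh_matrix.values.loc[e.cluster_id].to_numpy(),
                    tss_matrix.values.loc[t["cluster_id"]].to_numpy(),
                )
                if not res.tested:
                    continue
                gap = int(gaps[k])
                if t["strand"] == "+":
                    upstream = e.end <= t["start"]
                else:
                    upstream = e.start >= t["end"]
                signed = -gap if upstream else gap
                rows.append(
                    (e.cluster_id, t["cluster_id"], chrom, e.start, gap, signed, res.tau, res.p_value)
                )
    out = pd.DataFrame(
        rows,
        columns=["enhancer_id", "tss_id", "chrom", "enh_start", "gap", "signed_gap", "tau", "p"],
    )
    if out.empty:
        out["q"] = pd.Series(dtype=float)
        return out
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values(["chrom", "enh_start"], kind="mergesort").reset_index(drop=True)


def find_links(
    enh_matrix: ExpressionMatrix,
    tss_matrix: ExpressionMatrix,
    max_gap: int = 10000,
    p_threshold: float = 0.05,
    fdr_threshold: float = 0.01,
) -> pd.DataFrame:
    """Retained coexpression links: p < p_threshold and BH q < fdr_threshold."""
    tested = test_links(enh_matrix, tss_matrix, max_gap=max_gap)
    if tested.empty:
        return tested
    keep = (tested["p"] < p_threshold) & (tested["q"] < fdr_threshold)
    return tested[keep].reset_index(drop=True)


def classify_links(
    links: pd.DataFrame, tss_annotated: pd.DataFrame, enh_annotated: pd.DataFrame
) -> pd.DataFrame:
    """Assign cis/trans/novel categories.

    *novel*: no gene annotation at either endpoint (both novel); otherwise
    *cis* for gap < 1 kb and *trans* beyond.  An ``either_novel`` flag is
    reported alongside since membership rules for partially annotated
    links vary between conventions.
    """
    tss_novel = dict(zip(tss_annotated["cluster_id"], tss_annotated["is_novel"]))
    enh_novel = dict(zip(enh_annotated["cluster_id"], enh_annotated["is_novel"]))
    out = links.copy()
    categories = []
    either = []
    for r in out.itertuples():
        t_nov = bool(tss_novel.get(r.tss_id, True))
        e_nov = bool(enh_novel.get(r.enhancer_id, True))
        either.append(t_nov or e_nov)
        if t_nov and e_nov:
            categories.append("novel")
        elif r.gap < 1000:
            categories.append("cis")
        else:
            categories.append("trans")
    out["category"] = categories
    out["either_novel"] = either
    return out


def kde2d_gap_tau(links: pd.DataFrame, grid_n: int = 100) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2-D product-Gaussian KDE of (gap, tau) over an axis-aligned grid.

    Bandwidths follow the bivariate normal reference rule per axis
    (sigma * n^(-1/6)).  Returns (x grid, y grid, density) with density
    integrating to ~1 over the grid.
    """
    if len(links) < 2:
        raise ValueError("need at least 2 links for a KDE")
    x = links["gap"].to_numpy(dtype=float)
    y = links["tau"].to_numpy(dtype=float)
    n = len(x)
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero-variance axis; jitter the inputs before density estimation")
    hx = sx * n ** (-1 / 6)
    hy = sy * n ** (-1 / 6)
    gx = np.linspace(x.min() - 3 * hx, x.max() + 3 * hx, grid_n)
    gy = np.linspace(y.min() - 3 * hy, y.max() + 3 * hy, grid_n)
    kx = np.exp(-0.5 * ((gx[:, None] - x[None, :]) / hx) ** 2) / (hx * math.sqrt(2 * math.pi))
    ky = np.exp(-0.5 * ((gy[:, None] - y[None, :]) / hy) ** 2) / (hy * math.sqrt(2 * math.pi))
    density = kx @ ky.T / n  # (grid_n, grid_n): rows follow x, columns y
    return gx, gy, density


def compare_group_means(tau_groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Welch's t-test for every pair of labeled tau groups.

    Reports per-group mean and standard error alongside the statistic.
    """
    if len(tau_groups) < 2:
        raise ValueError("need at least 2 groups")
    for name, values in tau_groups.items():
        if len(values) < 2:
            raise ValueError(f"group {name!r} needs n >= 2")
    names = list(tau_groups)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            xa = np.asarray(tau_groups[a], dtype=float)
            xb = np.asarray(tau_groups[b], dtype=float)
            res = stats.ttest_ind(xa, xb, equal_var=False)
            rows.append(
                (
                    a,
                    b,
                    xa.mean(),
                    xb.mean(),
                    xa.std(ddof=1) / math.sqrt(len(xa)),
                    xb.std(ddof=1) / math.sqrt(len(xb)),
                    float(res.statistic),
                    float(res.pvalue),
                )
            )
    return pd.DataFrame(
        rows, columns=["group_a", "group_b", "mean_a", "mean_b", "se_a", "se_b", "t", "p"]
    )
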