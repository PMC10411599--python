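"""Tissue specificity of called clusters.

The tissue specificity profile of a cluster is the vector of per-tissue
fractions f_t = mean_t / sum_u mean_u, where mean_t is the cluster's mean
CTPM over the samples of tissue t.  Fractions run from 0 (no expression
in that tissue) to 1 (expressed only there) and sum to 1; the scalar
tissue specificity index (TSI) is the maximum fraction.  Averaging within
tissue first makes the profile robust to unbalanced replicate counts, and
the whole profile is invariant to rescaling all samples by one constant.

Per-tissue cluster calling reruns the clustering stage on only one
tissue's samples with a relaxed support threshold (a tissue has few
replicates, so pervasiveness across the whole data set cannot be asked
of it).
"""

from __future__ import annotations

import warnings

import pandas as pd

from .clustering import (
    ExpressionMatrix,
    cluster_bidirectional,
    cluster_unidirectional,
    filter_by_support,
    pool_and_normalize,
    quantify,
)
from .ctss_io import CtssTrack


def tsi_profile(matrix: ExpressionMatrix, tissue_labels: pd.Series) -> pd.DataFrame:
    """Per-tissue expression fractions and scalar TSI for every cluster.

    ``tissue_labels`` maps sample_id -> tissue and must cover every
    matrix column; at least 2 tissues are required.  Clusters with no
    expression anywhere get ``zero_flag=True`` and all-zero fractions.
    """
    labels = tissue_labels.reindex(matrix.sample_ids)
    if labels.isna().any():
        missing = [s for s, t in labels.items() if pd.isna(t)]
        raise ValueError(f"samples without a tissue label: {missing}")
    tissues = sorted(labels.unique())
    if len(tissues) < 2:
        raise ValueError("need at least 2 tissues")
    means = pd.DataFrame(
        {t: matrix.values.loc[:, labels[labels == t].index].mean(axis=1) for t in tissues}
    )
    totals = means.sum(axis=1)
    zero = totals == 0
    fractions = means.div(totals.where(~zero, 1.0), axis=0)
    fractions[zero] = 0.0
    out = fractions.copy()
    out.columns = [f"f_{t}" for t in tissues]
    out.insert(0, "cluster_id", matrix.values.index)
    out["scalar_tsi"] = fractions.max(axis=1)
    out["zero_flag"] = zero.to_numpy()
    return out.reset_index(drop=True)


def tissue_specific_clusters(
    tracks_by_tissue: dict[str, list[CtssTrack]],
    min_pooled_count: int = 10,
    min_support: int = 2,
    merge_dist: int = 20,
    radius: int = 500,
    balance_threshold: float = 0.95,
    max_span: int = 1000,
) -> dict[str, dict[str, ExpressionMatrix]]:
    """Run cluster calling independently per tissue with relaxed support.

    Each tissue is processed with min_samples = min(min_support,
    n_samples of that tissue); a single-sample tissue triggers a warning
    and support 1.  Returns per tissue the filtered TSS and enhancer
    expression matrices.
    """
    out: dict[str, dict[str, ExpressionMatrix]] = {}
    for tissue in sorted(tracks_by_tissue):
        tracks = tracks_by_tissue[tissue]
        if not tracks:
            raise ValueError(f"tissue {tissue!r} has no samples")
        n = len(tracks)
        if n < 2:
            warnings.warn(f"tissue {tissue!r} has a single sample; support threshold lowered to 1")
        min_samples = min(min_support, n)
        pooled = pool_and_normalize(tracks)
        tss = cluster_unidirectional(pooled, merge_dist=merge_dist)
        enh = cluster_bidirectional(
            pooled, radius=radius, balance_threshold=balance_threshold, max_span=max_span
        )
        tss_m = filter_by_support(quantify(tss, tracks), min_pooled_count, min_samples)
        enh_m = filter_by_support(quantify(enh, tracks), min_pooled_count, min_samples)
        out[tissue] = {"tss": tss_m, "enhancer": enh_m}
    return out
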