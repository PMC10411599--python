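"""Population-level cluster calling and intersection signatures.

Per-population calling requires 100% within-population support: a cluster
counts as belonging to a population only if every one of that
population's samples carries at least one tag in it.  The per-population
cluster sets are then intersected into disjoint signature classes
(UpSet-style): each population alone, every pairwise combination, and the
all-populations class.  Matching across sets is by exact
start-end-strand coordinates by default, with a 1-bp same-strand overlap
rule available because cluster boundaries jitter between runs on real
data.
"""

from __future__ import annotations

from itertools import combinations

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


def population_clusters(
    tracks: list[CtssTrack],
    min_pooled_count: int = 10,
    merge_dist: int = 20,
    radius: int = 500,
    balance_threshold: float = 0.95,
    max_span: int = 1000,
) -> dict[str, ExpressionMatrix]:
    """Cluster calling for one population at 100% support (min_samples = n)."""
    if not tracks:
        raise ValueError("population has no samples")
    n = len(tracks)
    pooled = pool_and_normalize(tracks)
    tss = cluster_unidirectional(pooled, merge_dist=merge_dist)
    enh = cluster_bidirectional(pooled, radius=radius, balance_threshold=balance_threshold, max_span=max_span)
    return {
        "tss": filter_by_support(quantify(tss, tracks), min_pooled_count, n),
        "enhancer": filter_by_support(quantify(enh, tracks), min_pooled_count, n),
    }


class _UnionFind:
    def __init__(self):
        self.parent: dict = {}

    def find(self, a):
        self.parent.setdefault(a, a)
        root = a
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[a] != root:
            self.parent[a], a = root, self.parent[a]
        return root

    def union(self, a, b):
        self.parent[self.find(a)] = self.find(b)


def build_signatures(sets: dict[str, pd.DataFrame], match_rule: str = "exact") -> dict[str, pd.DataFrame]:
    """Assign every cluster to exactly one intersection class.

    ``sets`` maps population name -> cluster frame (chrom/start/end and,
    for TSS, strand).  Under the ``exact`` rule clusters match when their
    (chrom, start, end, strand) coincide; under ``overlap`` when they
    share >= 1 bp on the same strand, with transitive matches merged into
    one component.  Returns ``membership`` (one row per input cluster
    with its class) and ``counts`` (UpSet-style class sizes, keyed by the
    sorted population names joined with ':').
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 named cluster sets")
    if match_rule not in ("exact", "overlap"):
        raise ValueError(f"unknown match_rule {match_rule!r}")
    records = []
    for name, df in sets.items():
        for r in df.itertuples():
            strand = getattr(r, "strand", ".")
            records.append((name, r.cluster_id, r.chrom, r.start, r.end, strand))
    rec = pd.DataFrame(records, columns=["population", "cluster_id", "chrom", "start", "end", "strand"])

    if match_rule == "exact":
        rec["component"] = [f"{r.chrom}:{r.start}-{r.end};{r.strand}" for r in rec.itertuples()]
    else:
        uf = _UnionFind()
        keys = list(rec.index)
        for k in keys:
            uf.find(k)
        for (_, _), sub in rec.groupby(["chrom", "strand"]):
            sub = sub.sort_values("start")
            idx = list(sub.index)
            active: list[int] = []
            for k in idx:
                s, e = rec.at[k, "start"], rec.at[k, "end"]
                active = [a for a in active if rec.at[a, "end"] > s]
                for a in active:
                    uf.union(a, k)
                active.append(k)
        rec["component"] = [uf.find(k) for k in rec.index]

    class_of_component = (
        rec.groupby("component")["population"]
        .apply(lambda pops: ":".join(sorted(set(pops))))
        .to_dict()
    )
    rec["signature_class"] = rec["component"].map(class_of_component)
    names = sorted(sets)
    all_classes = [":".join(sorted(c)) for k in range(1, len(names) + 1) for c in combinations(names, k)]
    counts = (
        rec.drop_duplicates("component")
        .groupby("signature_class")
        .size()
        .reindex(all_classes, fill_value=0)
        .rename("n_regions")
        .reset_index()
    )
    membership = rec[["population", "cluster_id", "chrom", "start", "end", "strand", "signature_class"]]
    return {"membership": membership, "counts": counts}
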