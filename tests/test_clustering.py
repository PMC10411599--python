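import math

import numpy as np
import pandas as pd
import pytest

import cagecall as cc
from cagecall.clustering import filter_by_support, quantify

from conftest import make_pooled, make_track


def brute_force_gap_split(positions, merge_dist):
    """Independent oracle: sort positions, split where the gap exceeds merge_dist."""
    clusters = []
    current = [positions[0]]
    for p in positions[1:]:
        if p - current[-1] > merge_dist:
            clusters.append(current)
            current = [p]
        else:
            current.append(p)
    clusters.append(current)
    return [(c[0], c[-1] + 1) for c in clusters]


class TestPooling:
    def test_ctpm_unit_normalization(self):
        pooled = make_pooled([("chr1", 10, "+", 5)], library_size=1_000_000)
        assert pooled.data.loc[0, "ctpm"] == 5.0

    def test_ctpm_scales_with_library_size(self):
        pooled = make_pooled([("chr1", 10, "+", 5)], library_size=2_000_000)
        assert pooled.data.loc[0, "ctpm"] == 2.5

    def test_counts_add_across_samples(self):
        t1 = make_track([("chr1", 10, "+", 3)], sample_id="a")
        t2 = make_track([("chr1", 10, "+", 4)], sample_id="b")
        pooled = cc.pool_and_normalize([t1, t2])
        assert pooled.data.loc[0, "count"] == 7

    def test_empty_track_list_is_an_error(self):
        with pytest.raises(ValueError):
            cc.pool_and_normalize([])


class TestUnidirectional:
    def test_splits_on_gap_above_merge_dist(self):
        pooled = make_pooled([("chr1", 100, "+", 5), ("chr1", 101, "+", 3), ("chr1", 130, "+", 2)])
        out = cc.cluster_unidirectional(pooled, merge_dist=20)
        assert [(r.start, r.end, r.peak_pos) for r in out.itertuples()] == [(100, 102, 100), (130, 131, 130)]

    def test_merges_when_gap_within_merge_dist(self):
        pooled = make_pooled([("chr1", 100, "+", 5), ("chr1", 101, "+", 3), ("chr1", 130, "+", 2)])
        out = cc.cluster_unidirectional(pooled, merge_dist=30)
        assert [(r.start, r.end, r.peak_pos) for r in out.itertuples()] == [(100, 131, 100)]

    def test_empty_signal_gives_empty_list(self):
        pooled = make_pooled([("chr1", 100, "+", 1)])
        pooled.data = pooled.data.iloc[0:0]
        assert len(cc.cluster_unidirectional(pooled)) == 0

    def test_peak_ties_break_toward_5prime(self):
        plus = make_pooled([("chr1", 10, "+", 4), ("chr1", 12, "+", 4)])
        minus = make_pooled([("chr1", 10, "-", 4), ("chr1", 12, "-", 4)])
        assert cc.cluster_unidirectional(plus).loc[0, "peak_pos"] == 10
        assert cc.cluster_unidirectional(minus).loc[0, "peak_pos"] == 12

    def test_strands_cluster_independently(self):
        pooled = make_pooled([("chr1", 100, "+", 2), ("chr1", 105, "-", 2)])
        out = cc.cluster_unidirectional(pooled, merge_dist=20)
        assert len(out) == 2

    def test_matches_brute_force_oracle_on_random_signals(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = rng.integers(1, 200)
            positions = np.unique(rng.integers(0, 5000, size=n))
            merge_dist = int(rng.integers(0, 50))
            counts = rng.integers(1, 10, size=len(positions))
            pooled = make_pooled([("chr1", int(p), "+", int(c)) for p, c in zip(positions, counts)])
            got = cc.cluster_unidirectional(pooled, merge_dist=merge_dist)
            expected = brute_force_gap_split(list(positions), merge_dist)
            assert [(r.start, r.end) for r in got.itertuples()] == expected

    def test_tag_mass_is_conserved(self, called_clusters):
        pooled = called_clusters["pooled"]
        tss = cc.cluster_unidirectional(pooled)
        assert tss["pooled_count"].sum() == pooled.data["count"].sum()


class TestBalanceScore:
    def _signal(self, m_u=0, p_d=0, p_u=0, m_d=0):
        entries = []
        if m_u:
            entries.append(("chr1", 900, "-", m_u))
        if p_d:
            entries.append(("chr1", 1100, "+", p_d))
        if p_u:
            entries.append(("chr1", 900, "+", p_u))
        if m_d:
            entries.append(("chr1", 1100, "-", m_d))
        return make_pooled(entries)

    def test_perfect_divergence_saturates(self):
        pooled = self._signal(m_u=10, p_d=10)
        assert cc.balance_score(pooled, "chr1", 1000, 400) == pytest.approx(1.0)

    def test_one_armed_limit(self):
        pooled = self._signal(p_d=25)
        assert cc.balance_score(pooled, "chr1", 1000, 400) == pytest.approx(math.sqrt(0.5))

    def test_asymmetric_arms_closed_form(self):
        pooled = self._signal(m_u=10, p_d=30)
        expected = math.sqrt(0.5 * 0.25) + math.sqrt(0.5 * 0.75)
        assert cc.balance_score(pooled, "chr1", 1000, 400) == pytest.approx(expected, abs=1e-9)

    def test_zero_signal_scores_zero(self):
        pooled = self._signal(m_u=1)
        assert cc.balance_score(pooled, "chr1", 500000, 400) == 0.0

    def test_invariant_to_uniform_scaling(self):
        a = self._signal(m_u=3, p_d=9, p_u=1, m_d=2)
        b = self._signal(m_u=30, p_d=90, p_u=10, m_d=20)
        sa = cc.balance_score(a, "chr1", 1000, 400)
        sb = cc.balance_score(b, "chr1", 1000, 400)
        assert sa == pytest.approx(sb, abs=1e-12)


class TestBidirectional:
    def test_divergent_pair_called_at_central_midpoint(self):
        pooled = make_pooled([("chr1", 600, "-", 10), ("chr1", 1200, "+", 10)])
        out = cc.cluster_bidirectional(pooled, radius=400)
        assert len(out) == 1
        row = out.iloc[0]
        assert row["balance"] == pytest.approx(1.0)
        assert row["midpoint"] == 900
        assert row["start"] == 600 and row["end"] == 1201

    def test_one_stranded_signal_yields_nothing(self):
        pooled = make_pooled([("chr1", 600, "+", 10), ("chr1", 1200, "+", 10)])
        assert len(cc.cluster_bidirectional(pooled, radius=400)) == 0

    def test_arms_beyond_window_not_called(self):
        pooled = make_pooled([("chr1", 600, "-", 10), ("chr1", 2000, "+", 10)])
        assert len(cc.cluster_bidirectional(pooled, radius=400)) == 0

    def test_wrong_orientation_not_called(self):
        # plus arm left, minus arm right: convergent, not divergent
        pooled = make_pooled([("chr1", 600, "+", 10), ("chr1", 1200, "-", 10)])
        assert len(cc.cluster_bidirectional(pooled, radius=400)) == 0

    def test_span_wider_than_max_span_discarded(self):
        pooled = make_pooled(
            [("chr1", 400, "-", 10), ("chr1", 1600, "+", 10)]
        )
        assert len(cc.cluster_bidirectional(pooled, radius=700, max_span=1000)) == 0

    def test_tss_mask_drops_overlapping_enhancers(self):
        pooled = make_pooled([("chr1", 600, "-", 10), ("chr1", 1200, "+", 10)])
        mask = pd.DataFrame({"chrom": ["chr1"], "start": [1150], "end": [1250]})
        assert len(cc.cluster_bidirectional(pooled, radius=400, tss_mask=mask)) == 0

    def test_bad_threshold_rejected(self):
        pooled = make_pooled([("chr1", 600, "-", 10)])
        with pytest.raises(ValueError):
            cc.cluster_bidirectional(pooled, balance_threshold=1.5)

    def test_planted_midpoints_recovered_noise_free(self):
        from cagecall.simulate import SimConfig, generate_dataset

        sim = generate_dataset(
            SimConfig(seed=3, background_noise_per_mb=0.0, n_genes=40, n_enhancers=12,
                      n_linked_pairs=6, n_stretches=1, n_decoy_pairs=1,
                      n_tissue_private=2, n_population_private=2)
        )
        pooled = cc.pool_and_normalize(sim.tracks)
        enh = cc.cluster_bidirectional(pooled)
        for r in sim.truth.enhancers.itertuples():
            hit = enh[(enh["chrom"] == r.chrom) & (enh["start"] <= r.midpoint) & (enh["end"] > r.midpoint)]
            assert len(hit) == 1, f"planted enhancer at {r.chrom}:{r.midpoint} not recovered"


class TestQuantifyAndFilter:
    def test_quantify_sums_strand_matched_span(self):
        clusters = pd.DataFrame(
            {"cluster_id": ["c1"], "chrom": ["chr1"], "start": [100], "end": [102],
             "strand": ["+"], "peak_pos": [100], "pooled_count": [8]}
        )
        track = make_track([("chr1", 100, "+", 5), ("chr1", 101, "+", 3), ("chr1", 101, "-", 9)])
        matrix = quantify(clusters, [track])
        assert matrix.values.iloc[0, 0] == pytest.approx(8.0)

    def test_quantify_enhancer_sums_both_strands(self):
        clusters = pd.DataFrame(
            {"cluster_id": ["e1"], "chrom": ["chr1"], "start": [100], "end": [200],
             "midpoint": [150], "pooled_count": [10]}
        )
        track = make_track([("chr1", 110, "-", 4), ("chr1", 190, "+", 6)])
        matrix = quantify(clusters, [track])
        assert matrix.values.iloc[0, 0] == pytest.approx(10.0)

    def test_sample_without_tags_scores_zero_and_missing_chrom_ok(self):
        clusters = pd.DataFrame(
            {"cluster_id": ["c1"], "chrom": ["chrX"], "start": [0], "end": [10],
             "strand": ["+"], "peak_pos": [0], "pooled_count": [1]}
        )
        track = make_track([("chr1", 5, "+", 2)])
        matrix = quantify(clusters, [track])
        assert matrix.values.iloc[0, 0] == 0.0
        assert matrix.clusters.loc[0, "n_support"] == 0

    def test_filter_boundary_at_pooled_ten(self):
        clusters = pd.DataFrame(
            {"cluster_id": ["a", "b"], "chrom": ["chr1"] * 2, "start": [0, 50], "end": [10, 60],
             "strand": ["+"] * 2, "peak_pos": [0, 50], "pooled_count": [9, 10]}
        )
        track = make_track([("chr1", 1, "+", 9), ("chr1", 55, "+", 10)])
        matrix = quantify(clusters, [track])
        kept = filter_by_support(matrix, min_pooled_count=10, min_samples=1)
        assert list(kept.clusters["cluster_id"]) == ["b"]

    def test_filter_support_threshold(self, called_clusters):
        tss_m = called_clusters["tss"]
        kept = filter_by_support(tss_m, min_pooled_count=10, min_samples=8)
        assert (kept.clusters["n_support"] >= 8).all()
        assert (kept.clusters["pooled_count"] >= 10).all()

    def test_zero_thresholds_keep_everything(self, called_clusters):
        tss_m = called_clusters["tss"]
        kept = filter_by_support(tss_m, min_pooled_count=0, min_samples=0)
        assert len(kept.clusters) == len(tss_m.clusters)

    def test_filter_is_monotone_in_both_thresholds(self, called_clusters):
        tss_m = called_clusters["tss"]
        base = set(filter_by_support(tss_m, 10, 6).clusters["cluster_id"])
        assert set(filter_by_support(tss_m, 20, 6).clusters["cluster_id"]) <= base
        assert set(filter_by_support(tss_m, 10, 9).clusters["cluster_id"]) <= base
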