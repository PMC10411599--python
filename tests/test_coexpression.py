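import itertools
import math

import numpy as np
import pandas as pd
import pytest

from cagecall.coexpression import (
    bh_adjust,
    classify_links,
    compare_group_means,
    find_links,
    kde2d_gap_tau,
    kendall_tau_b,
    test_links as score_links,
)
from cagecall.simulate import linked_pair_matrices


def kendall_tau_b_oracle(x, y):
    """Exhaustive pair counting with the tie-corrected tau-b denominator."""
    n = len(x)
    concordant = discordant = ties_x = ties_y = 0
    for i, j in itertools.combinations(range(n), 2):
        dx = x[i] - x[j]
        dy = y[i] - y[j]
        if dx == 0 and dy == 0:
            ties_x += 1
            ties_y += 1
        elif dx == 0:
            ties_x += 1
        elif dy == 0:
            ties_y += 1
        elif dx * dy > 0:
            concordant += 1
        else:
            discordant += 1
    n0 = n * (n - 1) / 2
    denom = math.sqrt((n0 - ties_x) * (n0 - ties_y))
    return (concordant - discordant) / denom


class TestKendall:
    def test_perfect_concordance_and_discordance(self):
        assert kendall_tau_b([1, 2, 3], [1, 2, 3]).tau == pytest.approx(1.0)
        assert kendall_tau_b([1, 2, 3], [3, 2, 1]).tau == pytest.approx(-1.0)

    def test_four_point_example(self):
        res = kendall_tau_b([1, 2, 3, 4], [1, 3, 2, 4])
        assert res.tau == pytest.approx(4 / 6)

    def test_tied_example(self):
        res = kendall_tau_b([1, 2, 2, 3], [1, 2, 3, 3])
        assert res.tau == pytest.approx(0.8)

    def test_constant_vector_flagged_untested(self):
        res = kendall_tau_b([1, 1, 1, 1], [1, 2, 3, 4])
        assert not res.tested
        assert not math.isnan(res.tau)

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = int(rng.integers(3, 30))
            x = rng.integers(0, 8, size=n)
            y = rng.integers(0, 8, size=n)
            if len(set(x)) == 1 or len(set(y)) == 1:
                continue
            res = kendall_tau_b(x, y)
            assert res.tau == pytest.approx(kendall_tau_b_oracle(x, y), abs=1e-12)

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            kendall_tau_b([1, 2], [1, 2])


class TestBH:
    def test_step_up_worked_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_two_value_example(self):
        q = bh_adjust([0.005, 0.1])
        assert np.allclose(q, [0.01, 0.1])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_invariant_to_permutation(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=50)
        order = rng.permutation(50)
        q = bh_adjust(p)
        q_perm = bh_adjust(p[order])
        assert np.allclose(q[order], q_perm)

    def test_monotone_in_sorted_p(self):
        rng = np.random.default_rng(6)
        p = np.sort(rng.uniform(size=40))
        q = bh_adjust(p)
        assert (np.diff(q) >= -1e-12).all()


class TestFindLinks:
    def test_mismatched_sample_columns_rejected(self):
        enh_m, tss_m = linked_pair_matrices(3, 12, 0.5, seed=1)
        tss_m.values.columns = [f"x{i}" for i in range(12)]
        with pytest.raises(ValueError, match="sample columns"):
            find_links(enh_m, tss_m)

    def test_pairs_beyond_max_gap_not_tested(self):
        enh_m, tss_m = linked_pair_matrices(5, 12, 0.9, seed=2, spacing=50000)
        tested = score_links(enh_m, tss_m, max_gap=500)  # planted gap is 1400
        assert len(tested) == 0

    def test_planted_pairs_highly_retained_at_rho08(self):
        enh_m, tss_m = linked_pair_matrices(100, 24, 0.8, seed=3)
        links = find_links(enh_m, tss_m)
        planted = {(f"enh{i:04d}", f"tss{i:04d}") for i in range(100)}
        got = set(zip(links["enhancer_id"], links["tss_id"]))
        assert got <= planted  # spacing isolates the pairs
        assert len(got) >= 80

    def test_null_pairs_controlled(self):
        enh_m, tss_m = linked_pair_matrices(300, 24, 0.0, seed=4)
        links = find_links(enh_m, tss_m)
        assert len(links) / 300 <= 0.02

    def test_tau_invariant_to_sample_permutation(self):
        enh_m, tss_m = linked_pair_matrices(10, 12, 0.6, seed=5)
        base = score_links(enh_m, tss_m)
        order = np.random.default_rng(0).permutation(12)
        cols = [enh_m.values.columns[i] for i in order]
        enh_m.values = enh_m.values[cols]
        tss_m.values = tss_m.values[cols]
        perm = score_links(enh_m, tss_m)
        merged = base.merge(perm, on=["enhancer_id", "tss_id"], suffixes=("_a", "_b"))
        assert np.allclose(merged["tau_a"], merged["tau_b"])


class TestClassify:
    def _links(self, gap):
        return pd.DataFrame(
            {"enhancer_id": ["e1"], "tss_id": ["t1"], "chrom": ["chr1"], "enh_start": [0],
             "gap": [gap], "signed_gap": [gap], "tau": [0.5], "p": [0.001], "q": [0.005]}
        )

    def _annotated(self, tss_novel, enh_novel):
        tss = pd.DataFrame({"cluster_id": ["t1"], "is_novel": [tss_novel]})
        enh = pd.DataFrame({"cluster_id": ["e1"], "is_novel": [enh_novel]})
        return tss, enh

    def test_annotated_short_gap_is_cis(self):
        tss, enh = self._annotated(False, False)
        out = classify_links(self._links(500), tss, enh)
        assert out.loc[0, "category"] == "cis"

    def test_annotated_long_gap_is_trans(self):
        tss, enh = self._annotated(False, True)
        out = classify_links(self._links(5000), tss, enh)
        assert out.loc[0, "category"] == "trans"
        assert bool(out.loc[0, "either_novel"])

    def test_both_novel_is_novel_regardless_of_gap(self):
        tss, enh = self._annotated(True, True)
        for gap in (100, 9000):
            out = classify_links(self._links(gap), tss, enh)
            assert out.loc[0, "category"] == "novel"


class TestKde:
    def _links_frame(self, rng, n=200, symmetric=False):
        tau = rng.normal(0, 0.3, size=n)
        if symmetric:
            tau = np.concatenate([tau, -tau])
        gap = rng.uniform(0, 10000, size=len(tau))
        return pd.DataFrame({"gap": gap, "tau": tau})

    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(9)
        links = self._links_frame(rng)
        gx, gy, dens = kde2d_gap_tau(links, grid_n=150)
        mass = dens.sum() * (gx[1] - gx[0]) * (gy[1] - gy[0])
        assert mass == pytest.approx(1.0, abs=1e-2)
        assert (dens >= 0).all()

    def test_argmax_near_cloud_center(self):
        rng = np.random.default_rng(10)
        links = pd.DataFrame(
            {"gap": rng.normal(5000, 50, size=300), "tau": rng.normal(0.4, 0.01, size=300)}
        )
        gx, gy, dens = kde2d_gap_tau(links)
        i, j = np.unravel_index(dens.argmax(), dens.shape)
        assert abs(gx[i] - 5000) < 200
        assert abs(gy[j] - 0.4) < 0.05

    def test_zero_variance_axis_suggests_jitter(self):
        links = pd.DataFrame({"gap": [100.0, 100.0, 100.0], "tau": [0.1, 0.2, 0.3]})
        with pytest.raises(ValueError, match="jitter"):
            kde2d_gap_tau(links)


class TestWelch:
    def test_identical_groups_give_zero_t_unit_p(self):
        rng = np.random.default_rng(2)
        g = rng.normal(size=30)
        out = compare_group_means({"a": g, "b": g.copy()})
        assert out.loc[0, "t"] == pytest.approx(0.0)
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_swapping_groups_flips_sign_same_p(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0.4, 0.1, 50), rng.normal(0.3, 0.2, 80)
        out_ab = compare_group_means({"a": a, "b": b})
        out_ba = compare_group_means({"b": b, "a": a})
        assert out_ab.loc[0, "t"] == pytest.approx(-out_ba.loc[0, "t"])
        assert out_ab.loc[0, "p"] == pytest.approx(out_ba.loc[0, "p"])

    def test_detects_paper_scale_shift(self):
        # mean 0.44 vs 0.38, sd 0.1, n=500 per group: essentially always rejected
        rng = np.random.default_rng(4)
        rejections = 0
        for _ in range(50):
            a = rng.normal(0.44, 0.1, 500)
            b = rng.normal(0.38, 0.1, 500)
            out = compare_group_means({"short": a, "long": b})
            rejections += out.loc[0, "p"] < 0.01
        assert rejections >= 49

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            compare_group_means({"a": np.arange(5.0)})
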