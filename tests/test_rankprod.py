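import itertools
import math

import numpy as np
import pandas as pd
import pytest

from uncoupling import (
    SyntheticConfig,
    call_degs,
    estimate_pfp,
    generate_paired_dataset,
    rank_product_statistic,
    rankprod_deg_table,
    ttest_bh_caller,
)
from uncoupling.rankprod import RankProdError, RankProductResult


def two_group(values_control, values_treated, genes=None):
    genes = genes or [f"g{i}" for i in range(len(values_control))]
    c = pd.DataFrame(values_control, index=genes, dtype=float)
    t = pd.DataFrame(values_treated, index=genes, dtype=float)
    return c, t


class TestRankProductStatistic:
    def test_top_gene_in_every_pairing_has_rp_one(self):
        # gene a has the largest fold change in all 4 pairings
        c, t = two_group([[0, 0], [0, 0], [0, 0]], [[9, 9], [2, 2], [1, 1]], list("abc"))
        res = rank_product_statistic(c, t, "up")
        assert res.rp["a"] == 1.0

    def test_geometric_mean_of_ranks(self):
        # gene b alternates between rank 2 and rank 3 across pairings:
        # RP = (2*3*2*3)**(1/4) = sqrt(6)
        # identical control columns duplicate the two treated rankings, so
        # gene c gets ranks (2, 3, 2, 3) over the four pairings
        c, t = two_group(
            [[0, 0], [0, 0], [0, 0], [0, 0]],
            [[10, 10], [4, 5], [5, 4], [1, 1]],
            list("abcd"),
        )
        res = rank_product_statistic(c, t, "up")
        assert sorted(res.ranks[:, 2]) == [2.0, 2.0, 3.0, 3.0]
        assert res.rp["c"] == pytest.approx(math.sqrt(6))

    def test_direction_reversal_equals_negated_data(self):
        rng = np.random.default_rng(5)
        c = pd.DataFrame(rng.normal(size=(10, 3)))
        t = pd.DataFrame(rng.normal(size=(10, 3)))
        rp_down = rank_product_statistic(c, t, "down").rp
        rp_up_neg = rank_product_statistic(-c, -t, "up").rp
        pd.testing.assert_series_equal(
            rp_down, rp_up_neg, check_names=False
        )

    def test_invariant_under_increasing_affine_transform(self):
        rng = np.random.default_rng(8)
        c = pd.DataFrame(rng.normal(size=(12, 3)))
        t = pd.DataFrame(rng.normal(size=(12, 3)))
        rp = rank_product_statistic(c, t, "up").rp
        rp_affine = rank_product_statistic(3 * c + 2, 3 * t + 2, "up").rp
        pd.testing.assert_series_equal(rp, rp_affine)

    def test_constant_gene_flagged_with_middle_rank(self):
        c, t = two_group([[5, 5], [0, 0], [1, 1]], [[5, 5], [2, 2], [0, 0]], list("abc"))
        res = rank_product_statistic(c, t, "up")
        assert res.constant_features == ["a"]
        assert res.rp["a"] == 2.0  # average rank in every pairing

    def test_single_replicate_rejected(self):
        c = pd.DataFrame(np.zeros((3, 1)))
        t = pd.DataFrame(np.ones((3, 2)))
        with pytest.raises(RankProdError, match="replicates"):
            rank_product_statistic(c, t, "up")


def exhaustive_pfp_oracle(ranks: np.ndarray, rp_obs: np.ndarray) -> np.ndarray:
    """Brute-force pfp: enumerate every tuple of per-row permutations."""
    K, G = ranks.shape
    n_tuples = 0
    count_le = np.zeros(G)
    for rows in itertools.product(*(itertools.permutations(row) for row in ranks)):
        perm_rp = np.prod(np.asarray(rows), axis=0) ** (1.0 / K)
        n_tuples += 1
        for g in range(G):
            count_le[g] += np.sum(perm_rp <= rp_obs[g] + 1e-12)
    expected_fp = count_le / n_tuples
    order_rank = np.array([(rp_obs <= rp_obs[g] + 1e-12).sum() for g in range(G)])
    pfp = expected_fp / order_rank
    order = np.argsort(rp_obs, kind="mergesort")
    pfp[order] = np.maximum.accumulate(pfp[order])
    return pfp


class TestEstimatePfp:
    def test_matches_exhaustive_enumeration_on_tiny_instance(self):
        # 5 genes, 2 replicate pairings: (5!)^2 = 14400 permutation tuples
        ranks = np.array([[1, 2, 3, 4, 5], [2, 1, 4, 5, 3]], dtype=float)
        rp = np.exp(np.mean(np.log(ranks), axis=0))
        res = RankProductResult(
            rp=pd.Series(rp, index=list("abcde")),
            ranks=ranks,
            direction="up",
            constant_features=[],
        )
        pfp = estimate_pfp(res, exhaustive=True)
        oracle = exhaustive_pfp_oracle(ranks, rp)
        np.testing.assert_allclose(pfp.to_numpy(), oracle, rtol=1e-12)

    def test_sampled_pfp_converges_to_exhaustive(self):
        ranks = np.array([[1, 2, 3, 4], [3, 1, 2, 4]], dtype=float)
        rp = np.exp(np.mean(np.log(ranks), axis=0))
        res = RankProductResult(
            rp=pd.Series(rp, index=list("abcd")),
            ranks=ranks,
            direction="up",
            constant_features=[],
        )
        exact = estimate_pfp(res, exhaustive=True)
        sampled = estimate_pfp(res, n_permutations=20000, seed=0, scheme="ranking")
        np.testing.assert_allclose(sampled, exact, atol=0.03)

    def test_few_permutations_warns(self, caplog):
        ranks = np.array([[1.0, 2.0, 3.0]] * 2)
        res = RankProductResult(
            rp=pd.Series([1.0, 2.0, 3.0]), ranks=ranks, direction="up",
            constant_features=[],
        )
        with caplog.at_level("WARNING"):
            estimate_pfp(res, n_permutations=10, seed=0, scheme="ranking")
        assert "unstable" in caplog.text

    def test_pfp_monotone_in_rank_product_order(self):
        rng = np.random.default_rng(2)
        c = pd.DataFrame(rng.normal(size=(50, 3)))
        t = pd.DataFrame(rng.normal(size=(50, 3)))
        res = rank_product_statistic(c, t, "up")
        pfp = estimate_pfp(res, n_permutations=200, seed=1)
        order = np.argsort(res.rp.to_numpy())
        assert (np.diff(pfp.to_numpy()[order]) >= -1e-12).all()

    def test_null_data_yields_few_calls(self):
        # with no planted effects pfp stays near 1: almost nothing passes 0.2
        rng = np.random.default_rng(4)
        c = pd.DataFrame(rng.normal(size=(300, 3)))
        t = pd.DataFrame(rng.normal(size=(300, 3)))
        table = rankprod_deg_table(c, t, n_permutations=200, seed=0)
        assert table["significant"].mean() < 0.05


class TestCallDegs:
    def test_zero_threshold_empty(self):
        rng = np.random.default_rng(0)
        c = pd.DataFrame(rng.normal(size=(20, 3)))
        t = pd.DataFrame(rng.normal(size=(20, 3)))
        table = rankprod_deg_table(c, t, n_permutations=100, seed=0)
        sig, _ = call_degs(table, 0.0)
        assert sig == set()

    def test_noiseless_planted_data_recovered_exactly(self):
        cfg = SyntheticConfig(
            n_genes=60, noise_sd=0.0, effect_size=1.0, seed=2,
            class_fractions={"coupled": 0.2, "antidirectional": 0.0,
                             "transcriptome_only": 0.0, "translatome_only": 0.0,
                             "unchanged": 0.8},
        )
        pes, truth = generate_paired_dataset(cfg)
        c = pes.matrices[("transcriptome", "control")]
        t = pes.matrices[("transcriptome", "treated")]
        table = rankprod_deg_table(c, t, n_permutations=300, seed=0)
        sig, directions = call_degs(table, 0.2)
        planted = set(truth.planted_degs("transcriptome"))
        assert sig == planted
        for g in sig:
            planted_dir = "up" if truth.table.loc[g, "effect_transcriptome"] > 0 else "down"
            assert directions[g] == planted_dir

    def test_recall_on_noisy_planted_data(self):
        cfg = SyntheticConfig(
            n_genes=500, noise_sd=0.3, effect_size=2.0, seed=6, n_replicates=3,
            class_fractions={"coupled": 0.1, "antidirectional": 0.0,
                             "transcriptome_only": 0.0, "translatome_only": 0.0,
                             "unchanged": 0.9},
        )
        pes, truth = generate_paired_dataset(cfg)
        c = pes.matrices[("transcriptome", "control")]
        t = pes.matrices[("transcriptome", "treated")]
        table = rankprod_deg_table(c, t, n_permutations=300, seed=0)
        sig, _ = call_degs(table, 0.2)
        planted = set(truth.planted_degs("transcriptome"))
        recall = len(sig & planted) / len(planted)
        assert recall >= 0.9


class TestTTestBH:
    def test_identical_groups_no_calls(self):
        rng = np.random.default_rng(1)
        c = pd.DataFrame(rng.normal(size=(30, 3)))
        t = c.copy()
        table = ttest_bh_caller(c, t, alpha=0.5)
        assert not table["significant"].any()

    def test_three_gene_fixture_matches_hand_computation(self):
        c, t = two_group(
            [[0.0, 0.1, -0.1], [0.0, 0.1, -0.1], [0.0, 0.1, -0.1]],
            [[3.0, 3.1, 2.9], [0.5, 0.7, 0.3], [0.05, 0.15, -0.05]],
            list("abc"),
        )
        table = ttest_bh_caller(c, t)
        # hand two-sample pooled-variance t per gene
        for g in "abc":
            x, y = t.loc[g].to_numpy(), c.loc[g].to_numpy()
            n1, n2 = len(x), len(y)
            sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
            t_hand = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
            assert table.loc[g, "t_stat"] == pytest.approx(t_hand)
        # hand BH step-up on the three raw p-values
        p = table["p_value"].to_numpy()
        order = np.argsort(p)
        adj = np.empty(3)
        running = 1.0
        for i in (2, 1, 0):
            running = min(running, p[order[i]] * 3 / (i + 1))
            adj[order[i]] = running
        np.testing.assert_allclose(table["p_adjusted"].to_numpy(), adj)

    def test_zero_variance_handling(self):
        c, t = two_group([[1.0, 1.0], [1.0, 1.0]], [[1.0, 1.0], [2.0, 2.0]], list("ab"))
        table = ttest_bh_caller(c, t)
        assert table.loc["a", "p_value"] == 1.0
        assert table.loc["b", "p_value"] < 1e-6

    def test_null_type_one_error_rate(self):
        # pooled over 60 null datasets x 200 genes the raw p<0.05 rate is ~5%
        rng = np.random.default_rng(9)
        rejections = []
        for _ in range(60):
            c = pd.DataFrame(rng.normal(size=(200, 3)))
            t = pd.DataFrame(rng.normal(size=(200, 3)))
            table = ttest_bh_caller(c, t)
            rejections.append((table["p_value"] < 0.05).mean())
        rate = np.mean(rejections)
        assert abs(rate - 0.05) < 0.01

    def test_rankprod_and_ttest_agree_on_planted_data(self):
        cfg = SyntheticConfig(
            n_genes=300, noise_sd=0.3, effect_size=2.0, seed=3,
            class_fractions={"coupled": 0.15, "antidirectional": 0.0,
                             "transcriptome_only": 0.0, "translatome_only": 0.0,
                             "unchanged": 0.85},
        )
        pes, _ = generate_paired_dataset(cfg)
        c = pes.matrices[("transcriptome", "control")]
        t = pes.matrices[("transcriptome", "treated")]
        rp_sig, _ = call_degs(rankprod_deg_table(c, t, n_permutations=200, seed=0), 0.2)
        tt = ttest_bh_caller(c, t, alpha=0.2)
        tt_sig = set(tt.index[tt["significant"]])
        agreement = len(rp_sig & tt_sig) / max(len(rp_sig | tt_sig), 1)
        # loose sanity bound: the two callers target the same planted genes
        assert agreement >= 0.5
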