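"""Signature scoring, gene ranking, GSEA, ORA, nonparametric group tests,
exhaustion panel — each checked against hand arithmetic or enumeration."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tregstrat import (
    GeneSet,
    TREG_SIGNATURE,
    exhaustion_panel,
    generate_multiomics,
    group_tests,
    gsea,
    gsea_collection,
    ora,
    ora_collection,
    rank_genes,
    signature_score,
)
from tregstrat.characterize import _running_es, as_ranked, filter_de_table

from .conftest import small_omics_config


def expr_frame(values, genes):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(
        values, index=[f"s{i}" for i in range(values.shape[0])], columns=genes
    )


class TestSignatureScore:
    def test_single_gene_set_equals_zscore(self, rng):
        X = expr_frame(rng.standard_normal((20, 3)), ["A", "B", "C"])
        score = signature_score(X, GeneSet("one", ["B"]))
        z = (X["B"] - X["B"].mean()) / X["B"].std(ddof=1)
        np.testing.assert_allclose(score, z)

    def test_degenerate_constant_matrix_scores_zero(self):
        X = expr_frame(np.full((5, 4), 7.0), list("ABCD"))
        score = signature_score(X, GeneSet("s", ["A", "B"]))
        np.testing.assert_array_equal(score, np.zeros(5))

    def test_gene_order_and_absent_gene_invariance(self, rng):
        X = expr_frame(rng.standard_normal((15, 4)), list("ABCD"))
        a = signature_score(X, GeneSet("s", ["A", "C"]))
        b = signature_score(X, GeneSet("s", ["C", "A"]))
        with pytest.warns(UserWarning, match="absent"):
            c = signature_score(X, GeneSet("s", ["A", "C", "ZZZ"]))
        np.testing.assert_allclose(a, b)
        np.testing.assert_allclose(a, c)

    def test_no_overlap_error_names_the_set(self, rng):
        X = expr_frame(rng.standard_normal((5, 2)), ["A", "B"])
        with pytest.raises(ValueError, match="MISSING_SET"):
            signature_score(X, GeneSet("MISSING_SET", ["X1", "X2"]))

    def test_spiked_cluster_scores_highest(self):
        """treg_effect=2, ~100 samples/cluster: the spiked cluster's Treg
        score dominates every other cluster (Wilcoxon p < 0.001)."""
        dataset, truth = generate_multiomics(
            small_omics_config(seed=21, n_samples=300)
        )
        expr = dataset.layer("mRNA").values
        score = signature_score(expr, TREG_SIGNATURE)
        spiked = truth.labels == truth.treg_cluster
        assert score[spiked].mean() > score[~spiked].mean()
        for c in set(truth.labels) - {truth.treg_cluster}:
            _, p = stats.mannwhitneyu(
                score[spiked], score[truth.labels == c], alternative="greater"
            )
            assert p < 1e-3

    def test_ssgsea_like_orders_spiked_samples_high(self):
        dataset, truth = generate_multiomics(small_omics_config(seed=22))
        expr = dataset.layer("mRNA").values
        score = signature_score(expr, TREG_SIGNATURE, method="ssgsea_like")
        spiked = truth.labels == truth.treg_cluster
        assert score[spiked].mean() > score[~spiked].mean()


class TestRankGenes:
    def test_identical_gene_scores_zero(self, rng):
        X = expr_frame(rng.standard_normal((10, 2)), ["VAR", "FLAT"])
        X["FLAT"] = 1.0
        labels = np.array([0] * 5 + [1] * 5)
        ranked = rank_genes(X, labels, 0)
        assert ranked["FLAT"] == 0.0

    def test_unit_signal_to_noise_arithmetic(self):
        # group means 2 and 0, SDs 1 and 1 -> (2-0)/(1+1) = 1
        g1 = np.array([1.0, 3.0])  # mean 2, sd sqrt(2)
        g0 = np.array([-1.0, 1.0])  # mean 0, sd sqrt(2)
        X = expr_frame(np.concatenate([g1, g0])[:, None], ["G"])
        labels = np.array([1, 1, 0, 0])
        ranked = rank_genes(X, labels, 1)
        expected = (2.0 - 0.0) / (np.sqrt(2) + np.sqrt(2))
        assert ranked["G"] == pytest.approx(expected)

    def test_ordering_matches_recomputed_statistics(self, rng):
        X = expr_frame(rng.standard_normal((30, 20)), [f"g{i:02d}" for i in range(20)])
        labels = np.array([0] * 15 + [1] * 15)
        ranked = rank_genes(X, labels, 1)
        A, B = X.iloc[15:], X.iloc[:15]
        mu1, mu0 = A.mean(), B.mean()
        sd1 = np.maximum(A.std(ddof=1), np.maximum(0.2 * mu1.abs(), 1e-8))
        sd0 = np.maximum(B.std(ddof=1), np.maximum(0.2 * mu0.abs(), 1e-8))
        s2n = ((mu1 - mu0) / (sd1 + sd0)).sort_values(ascending=False)
        assert list(ranked.index) == list(s2n.index)
        np.testing.assert_allclose(ranked.to_numpy(), s2n.to_numpy())

    def test_small_group_rejected(self, rng):
        X = expr_frame(rng.standard_normal((5, 2)), ["A", "B"])
        with pytest.raises(ValueError):
            rank_genes(X, np.array([0, 1, 1, 1, 1]), 0)

    def test_tie_break_is_lexicographic(self):
        s = pd.Series({"B": 1.0, "A": 1.0, "C": 2.0})
        ranked = as_ranked(s)
        assert list(ranked.index) == ["C", "A", "B"]


class TestGSEA:
    def test_hand_computed_running_sum_peak(self):
        """N=10, |S|=3 planted at the top with positive scores: ES equals
        the closed-form running-sum maximum."""
        genes = [f"G{i}" for i in range(10)]
        scores = np.array([5.0, 4.0, 3.0, 2.0, 1.0, 0.5, 0.4, 0.3, 0.2, 0.1])
        ranked = pd.Series(scores, index=genes)
        gs = GeneSet("top3", ["G0", "G1", "G2"])
        res = gsea(ranked, gs, n_perm=0)
        # hand arithmetic: hit increments 5/12, 4/12, 3/12; misses -1/7
        running = np.cumsum([5 / 12, 4 / 12, 3 / 12] + [-1 / 7] * 7)
        assert res.es == pytest.approx(running.max())
        assert res.es == pytest.approx(1.0)
        assert res.leading_edge == ["G0", "G1", "G2"]

    def test_bottom_set_has_negative_es(self):
        genes = [f"G{i}" for i in range(10)]
        ranked = pd.Series(np.linspace(2, -2, 10), index=genes)
        res = gsea(ranked, GeneSet("bot", ["G8", "G9"]), n_perm=0)
        assert res.es < 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_es_bounded_and_sign_flips_under_negation(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"G{i}" for i in range(40)]
        scores = pd.Series(rng.standard_normal(40), index=genes)
        members = [genes[i] for i in rng.choice(40, 6, replace=False)]
        res = gsea(scores, GeneSet("s", members), n_perm=0)
        res_neg = gsea(-scores, GeneSet("s", members), n_perm=0)
        assert -1 <= res.es <= 1
        assert np.sign(res_neg.es) == -np.sign(res.es)

    def test_permutation_p_converges_to_exhaustive_enumeration(self):
        """weight=0, N=6, |S|=2: all C(6,2)=15 memberships enumerable."""
        genes = [f"G{i}" for i in range(6)]
        scores = np.array([3.0, 2.0, 1.0, -1.0, -2.0, -3.0])
        ranked = pd.Series(scores, index=genes)
        obs = gsea(ranked, GeneSet("s", ["G0", "G1"]), n_perm=20000, weight=0, seed=0)
        null = []
        for combo in itertools.combinations(range(6), 2):
            mask = np.zeros(6, dtype=bool)
            mask[list(combo)] = True
            null.append(_running_es(mask, scores, 0)[0])
        null = np.array(null)
        same = null * np.sign(obs.es) > 0
        p_exact = (np.abs(null[same]) >= abs(obs.es)).mean()
        assert obs.p == pytest.approx(p_exact, abs=0.02)

    def test_set_covering_whole_list_rejected(self):
        ranked = pd.Series([2.0, 1.0], index=["A", "B"])
        with pytest.raises(ValueError):
            gsea(ranked, GeneSet("all", ["A", "B"]), n_perm=0)

    def test_collection_applies_bh_across_sets(self, rng):
        genes = [f"G{i}" for i in range(30)]
        ranked = pd.Series(np.linspace(3, -3, 30), index=genes)
        sets = {
            "top": genes[:5], "mid": genes[12:17], "bottom": genes[-5:],
        }
        results = gsea_collection(ranked, sets, n_perm=200, seed=0)
        qs = {r.set_name: r.fdr_q for r in results}
        ps = {r.set_name: r.p for r in results}
        assert all(qs[k] >= ps[k] - 1e-12 for k in qs)
        assert all(q <= 1 for q in qs.values())


class TestORA:
    def test_zero_overlap_gives_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        p = ora(universe[:3], universe, GeneSet("s", universe[5:8]))
        assert 0 < p <= 1
        assert p == pytest.approx(
            1 - stats.hypergeom.cdf(-1, 10, 3, 3)
        )  # upper tail includes >= 0 -> p = 1
        assert p == 1.0

    def test_direct_combinatorics_1_over_252(self):
        universe = [f"g{i}" for i in range(10)]
        p = ora(universe[:5], universe, GeneSet("s", universe[:5]))
        assert p == pytest.approx(1 / 252)

    def test_hits_equal_universe_degenerate(self):
        universe = [f"g{i}" for i in range(8)]
        p = ora(universe, universe, GeneSet("s", universe[:3]))
        assert p == 1.0

    @pytest.mark.parametrize("n_universe,n_set,n_hits", [(8, 3, 4), (10, 5, 5), (12, 4, 6)])
    def test_matches_exhaustive_enumeration(self, n_universe, n_set, n_hits):
        universe = [f"g{i}" for i in range(n_universe)]
        gs = GeneSet("s", universe[:n_set])
        hits = universe[n_universe - n_hits :]
        k_obs = len(set(hits) & set(gs.genes))
        p = ora(hits, universe, gs)
        count = total = 0
        for combo in itertools.combinations(universe, n_hits):
            total += 1
            if len(set(combo) & set(gs.genes)) >= k_obs:
                count += 1
        assert p == pytest.approx(count / total, rel=1e-9)

    def test_hits_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            ora(["x"], ["a", "b"], GeneSet("s", ["a"]))

    def test_collection_bh_monotone_and_bounded(self, rng):
        universe = [f"g{i}" for i in range(50)]
        hits = universe[:10]
        sets = {f"s{j}": universe[j * 4 : j * 4 + 8] for j in range(6)}
        df = ora_collection(hits, universe, sets)
        merged = df.sort_values("p")
        assert (merged["fdr_q"].to_numpy() >= merged["p"].to_numpy() - 1e-12).all()
        assert (df["fdr_q"] <= 1).all()


class TestGroupTests:
    def test_identical_groups_give_small_h(self):
        vals = np.tile(np.arange(10.0), 3)
        labels = np.repeat([0, 1, 2], 10)
        res = group_tests(vals, labels)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_kruskal_wallis_h(self):
        """Ranks 1..12 split into thirds: H = 12/(N(N+1)) sum n_i (rbar_i - rbar)^2."""
        vals = np.arange(1.0, 13.0)
        labels = np.repeat([0, 1, 2], 4)
        res = group_tests(vals, labels)
        h_hand = 12.0 / (12 * 13) * 4 * ((2.5 - 6.5) ** 2 + 0 + (10.5 - 6.5) ** 2)
        assert res.statistic == pytest.approx(h_hand)

    def test_shifted_group_flagged_by_posthocs(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(20)
        b = rng.standard_normal(20) + 10.0
        c = rng.standard_normal(20)
        vals = np.concatenate([a, b, c])
        labels = np.repeat(["A", "B", "C"], 20)
        res = group_tests(vals, labels)
        wil = res.pairwise[res.pairwise["test"] == "wilcoxon"].set_index(
            ["group_a", "group_b"]
        )
        assert wil.loc[("A", "B"), "p"] < 1e-6
        dunn = res.pairwise[res.pairwise["test"] == "dunn"].set_index(
            ["group_a", "group_b"]
        )
        assert dunn.loc[("A", "B"), "p_adj"] < 0.05
        assert dunn.loc[("B", "C"), "p_adj"] < 0.05
        assert dunn.loc[("A", "C"), "p_adj"] > 0.2

    def test_all_identical_values_defined_as_null(self):
        vals = np.full(12, 3.0)
        labels = np.repeat([0, 1, 2], 4)
        res = group_tests(vals, labels)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            group_tests(np.arange(3.0), np.array([0, 1, 1]))


class TestExhaustionPanel:
    def test_identical_vectors_give_rho_one(self, rng):
        from tregstrat import EXHAUSTION_MARKERS

        n = 30
        base = rng.standard_normal(n)
        X = expr_frame(
            np.column_stack([base + 0.01 * k for k in range(6)]),
            list(EXHAUSTION_MARKERS),
        )
        treg = signature_score(X, GeneSet("exh", list(EXHAUSTION_MARKERS)))
        out = exhaustion_panel(X, treg, np.zeros(n, dtype=int))
        assert out["correlations"].loc[0, "spearman_rho"] == pytest.approx(1.0)

    def test_independent_vectors_have_small_rho(self):
        """|rho| < 0.2 in at least 19/20 seeds for n=200 independent draws."""
        ok = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            rho, _ = stats.spearmanr(
                rng.standard_normal(200), rng.standard_normal(200)
            )
            ok += abs(rho) < 0.2
        assert ok >= 19

    def test_planted_cluster_has_max_correlation(self):
        dataset, truth = generate_multiomics(
            small_omics_config(seed=23, n_samples=300)
        )
        expr = dataset.layer("mRNA").values
        treg = signature_score(expr, TREG_SIGNATURE)
        out = exhaustion_panel(expr, treg, truth.labels)
        corr = out["correlations"]["spearman_rho"]
        assert corr.idxmax() == truth.treg_cluster

    def test_constant_vector_flagged_zero(self):
        from tregstrat import EXHAUSTION_MARKERS

        X = expr_frame(np.ones((10, 6)), list(EXHAUSTION_MARKERS))
        treg = pd.Series(np.arange(10.0), index=X.index)
        out = exhaustion_panel(X, treg, np.zeros(10, dtype=int))
        row = out["correlations"].loc[0]
        assert row["spearman_rho"] == 0.0 and bool(row["constant_flag"])


class TestDeTableFilter:
    def test_volcano_thresholds(self):
        de = pd.DataFrame(
            {
                "gene": ["a", "b", "c", "d"],
                "log2FoldChange": [2.0, 0.5, -3.0, 1.5],
                "padj": [0.01, 0.01, 0.2, 0.04],
            }
        )
        out = filter_de_table(de)
        assert list(out["gene"]) == ["a", "d"]
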