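import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metaboclust import genes as G
from metaboclust import synthcohort as sc


class TestCollapseProbes:
    def test_two_probes_averaged(self):
        m = pd.DataFrame([[4.0, 8.0], [6.0, 10.0]], index=["p1", "p2"], columns=["s1", "s2"])
        out = G.collapse_probes(m, {"p1": "gA", "p2": "gA"})
        assert out.loc["gA"].tolist() == [5.0, 9.0]

    def test_unmapped_probe_dropped(self):
        m = pd.DataFrame([[1.0], [2.0]], index=["p1", "p2"], columns=["s1"])
        out = G.collapse_probes(m, {"p1": "gA"})
        assert list(out.index) == ["gA"]

    def test_empty_mapping_errors(self):
        m = pd.DataFrame([[1.0]], index=["p1"], columns=["s1"])
        with pytest.raises(ValueError, match="no probes"):
            G.collapse_probes(m, {"px": "gA"})


class TestQuantileNormalize:
    def test_hand_computed_example(self):
        m = pd.DataFrame([[1.0, 3.0], [2.0, 4.0]], index=["g1", "g2"], columns=["s1", "s2"])
        out = G.quantile_normalize(m)
        assert out.to_numpy().tolist() == [[2.0, 2.0], [3.0, 3.0]]

    def test_identical_columns_unchanged(self, rng):
        col = rng.normal(size=20)
        m = pd.DataFrame({f"s{i}": col for i in range(4)})
        out = G.quantile_normalize(m)
        np.testing.assert_allclose(out.to_numpy(), m.to_numpy(), rtol=1e-12)

    def test_columns_share_multiset(self, rng):
        m = pd.DataFrame(rng.normal(size=(50, 5)))
        out = G.quantile_normalize(m).to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 5):
            np.testing.assert_allclose(np.sort(out[:, j]), ref, rtol=1e-12)

    def test_ties_get_mean_of_quantile_values(self):
        m = pd.DataFrame({"s1": [1.0, 1.0, 5.0], "s2": [2.0, 4.0, 6.0]})
        out = G.quantile_normalize(m)
        assert out.loc[0, "s1"] == out.loc[1, "s1"]

    def test_single_sample_errors(self):
        with pytest.raises(ValueError, match="two samples"):
            G.quantile_normalize(pd.DataFrame({"s1": [1.0, 2.0]}))


class TestSam:
    def test_d_proportional_to_t_with_zero_s0(self, rng):
        """With s0 = 0 the two-class d equals the pooled-variance t statistic."""
        m = pd.DataFrame(rng.normal(size=(30, 16)),
                         columns=[f"s{i}" for i in range(16)])
        y = pd.Series(["a"] * 7 + ["b"] * 9, index=m.columns)
        res = G.sam_test(m, y, n_perm=5, seed=0, s0=0.0)
        t = stats.ttest_ind(m.loc[:, y == "b"], m.loc[:, y == "a"], axis=1).statistic
        np.testing.assert_allclose(res.table["d"].to_numpy(), t, rtol=1e-9)

    def test_pure_null_few_discoveries(self, rng):
        """No planted effects: at most ~5 % of genes at q < 0.25."""
        m = pd.DataFrame(rng.normal(size=(400, 40)),
                         columns=[f"s{i}" for i in range(40)])
        y = pd.Series(["a"] * 20 + ["b"] * 20, index=m.columns)
        res = G.sam_test(m, y, n_perm=50, seed=1)
        assert (res.table.q < 0.25).mean() <= 0.05

    def test_zero_effect_contrast_zero_genes(self, expression_cohort):
        """Mc2 vs Mc3 has no planted effects: 0 genes at q < 0.01."""
        expr, _, truth = expression_cohort
        sub = truth.true_cluster[truth.true_cluster != "Mc1"]
        res = G.sam_test(expr[sub.index], sub, n_perm=100, seed=5)
        assert int((res.table.q < 0.01).sum()) == 0

    def test_planted_contrast_recovers_genes(self, expression_cohort):
        expr, _, truth = expression_cohort
        y = truth.true_cluster.map(lambda c: "Mc1" if c == "Mc1" else "rest")
        res = G.sam_test(expr, y, n_perm=100, seed=5)
        hits = set(res.table.index[res.table.q < 0.01])
        planted = {g for g, _ in truth.de_genes["Mc1_vs_rest"]}
        assert len(hits & planted) >= 0.9 * len(planted)
        assert len(hits - planted) <= 0.02 * len(expr)

    def test_multiclass_runs_and_detects(self, expression_cohort):
        expr, _, truth = expression_cohort
        res = G.sam_test(expr, truth.true_cluster, design="multiclass",
                         n_perm=50, seed=2)
        planted = {g for g, _ in truth.de_genes["Mc1_vs_rest"]}
        hits = set(res.table.index[res.table.q < 0.01])
        assert len(hits & planted) >= 0.8 * len(planted)

    def test_sample_order_invariance(self, rng):
        m = pd.DataFrame(rng.normal(size=(50, 12)), columns=[f"s{i}" for i in range(12)])
        y = pd.Series(["a"] * 6 + ["b"] * 6, index=m.columns)
        res1 = G.sam_test(m, y, n_perm=20, seed=3)
        perm = rng.permutation(12)
        res2 = G.sam_test(m.iloc[:, perm], y.iloc[perm], n_perm=20, seed=3)
        np.testing.assert_allclose(res1.table["d"], res2.table["d"], rtol=1e-12)

    def test_small_class_errors(self, rng):
        m = pd.DataFrame(rng.normal(size=(10, 5)), columns=[f"s{i}" for i in range(5)])
        y = pd.Series(["a"] * 4 + ["b"], index=m.columns)
        with pytest.raises(ValueError, match="at least 2"):
            G.sam_test(m, y)


class TestS2N:
    def test_formula_arithmetic(self):
        """mu_A=2, sd_A=1, mu_B=1, sd_B=1 -> 0.5 (floor inactive)."""
        m = pd.DataFrame([[1.0, 2.0, 3.0, 0.0, 1.0, 2.0]], index=["g"],
                         columns=list("abcdef"))
        r = G.s2n_rank(m, [0, 1, 2], [3, 4, 5])
        assert r.loc["g", "score"] == pytest.approx(0.5)

    def test_equal_means_zero(self):
        m = pd.DataFrame([[1.0, 2.0, 1.0, 2.0]], index=["g"], columns=list("abcd"))
        r = G.s2n_rank(m, [0, 1], [2, 3])
        assert r.loc["g", "score"] == 0.0

    def test_constant_gene_finite_via_floor(self):
        m = pd.DataFrame([[3.0, 3.0, 3.0, 3.0]], index=["g"], columns=list("abcd"))
        r = G.s2n_rank(m, [0, 1], [2, 3])
        assert np.isfinite(r.loc["g", "score"])

    def test_sorted_descending_with_id_tiebreak(self, rng):
        m = pd.DataFrame(rng.normal(size=(20, 10)),
                         index=[f"g{i:02d}" for i in range(20)],
                         columns=[f"s{i}" for i in range(10)])
        r = G.s2n_rank(m, list(range(5)), list(range(5, 10)))
        assert (np.diff(r["score"].to_numpy()) <= 1e-15).all()

    def test_empty_class_errors(self):
        m = pd.DataFrame([[1.0, 2.0]], index=["g"], columns=["a", "b"])
        with pytest.raises(ValueError, match="at least 2"):
            G.s2n_rank(m, [0], [1])


def brute_force_es(ranked, scores, members):
    """Independent running-sum implementation for the toy oracle."""
    hit_w = sum(abs(s) for g, s in zip(ranked, scores) if g in members)
    n_miss = sum(1 for g in ranked if g not in members)
    p_hit = p_miss = 0.0
    best = 0.0
    for g, s in zip(ranked, scores):
        if g in members:
            p_hit += abs(s) / hit_w
        else:
            p_miss += 1.0 / n_miss
        if abs(p_hit - p_miss) > abs(best):
            best = p_hit - p_miss
    return best


class TestGsea:
    def test_toy_running_sum(self):
        ranked = ["g1", "g2", "g3", "g4", "g5"]
        scores = np.array([3.0, 2.0, 1.0, 0.5, 0.1])
        members = {"g1", "g4"}
        es = G.enrichment_score(ranked, scores, members)
        assert es == pytest.approx(brute_force_es(ranked, scores, members))
        assert es == pytest.approx(3.0 / 3.5)  # peak right after the top hit

    def test_es_bounded(self, rng):
        ranked = [f"g{i}" for i in range(30)]
        scores = rng.normal(size=30)
        for _ in range(10):
            members = set(rng.choice(ranked, size=8, replace=False))
            es = G.enrichment_score(ranked, np.abs(scores), members)
            assert -1.0 <= es <= 1.0

    def test_small_set_dropped_by_size_filter(self, expression_cohort):
        expr, _, truth = expression_cohort
        y = truth.true_cluster.map(lambda c: "Mc1" if c == "Mc1" else "rest")
        sets = {"tiny": list(expr.index[:10]), "ok": list(expr.index[:20])}
        res = G.gsea(expr, y, "Mc1", "rest", sets, n_perm=10, seed=0)
        assert "tiny" in res.dropped and res.dropped["tiny"] == 10
        assert list(res.table.index) == ["ok"]

    def test_no_surviving_sets_errors(self, expression_cohort):
        expr, _, truth = expression_cohort
        y = truth.true_cluster.map(lambda c: "Mc1" if c == "Mc1" else "rest")
        with pytest.raises(ValueError, match="survive"):
            G.gsea(expr, y, "Mc1", "rest", {"tiny": list(expr.index[:5])}, n_perm=5)

    def test_planted_set_enriched(self, expression_cohort):
        """The designated ECM set clears the published FDR cutoff of 25 %."""
        expr, gene_sets, truth = expression_cohort
        y = truth.true_cluster.map(lambda c: "Mc1" if c == "Mc1" else "rest")
        res = G.gsea(expr, y, "Mc1", "rest", gene_sets, n_perm=200, seed=3)
        assert res.table.loc["ECM_ORGANIZATION", "q"] < 0.25
        assert abs(res.table.loc["ECM_ORGANIZATION", "NES"]) > 1.5

    def test_seed_determinism(self, expression_cohort):
        expr, gene_sets, truth = expression_cohort
        y = truth.true_cluster.map(lambda c: "Mc1" if c == "Mc1" else "rest")
        small = {k: v for k, v in list(gene_sets.items())[:5]}
        a = G.gsea(expr, y, "Mc1", "rest", small, n_perm=20, seed=4).table
        b = G.gsea(expr, y, "Mc1", "rest", small, n_perm=20, seed=4).table
        pd.testing.assert_frame_equal(a, b)

    def test_label_permutation_yields_no_discoveries(self, expression_cohort):
        """With cluster labels shuffled the planted structure is destroyed and
        no set clears the FDR cutoff (median over seeds is zero)."""
        expr, gene_sets, truth = expression_cohort
        counts = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            y = pd.Series(
                rng.permutation(
                    truth.true_cluster.map(
                        lambda c: "Mc1" if c == "Mc1" else "rest"
                    ).to_numpy()
                ),
                index=truth.true_cluster.index,
            )
            res = G.gsea(expr, y, "Mc1", "rest", gene_sets, n_perm=50, seed=seed)
            counts.append(int((res.table.q < 0.25).sum()))
        assert np.median(counts) == 0
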