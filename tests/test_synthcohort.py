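import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metaboclust import reference
from metaboclust import synthcohort as sc
from metaboclust.preprocess import preprocess
from metaboclust.quant import MetaboliteSpec, integrate_windows


def quantify(config, spectra):
    pp = preprocess(spectra)
    return integrate_windows(pp, config.specs, area_unit=config.area_unit)


class TestDefaults:
    def test_metabolite_spec_invariants(self):
        specs = sc.default_metabolite_specs()
        assert len(specs) == 18
        sc.validate_metabolite_specs(specs)  # centers/windows invariants

    def test_overlapping_windows_rejected(self):
        bad = [
            MetaboliteSpec("a", ((3.0, 1.0),), window=(2.98, 3.02)),
            MetaboliteSpec("b", ((3.01, 1.0),), window=(3.00, 3.04)),
        ]
        with pytest.raises(ValueError, match="overlap"):
            sc.validate_metabolite_specs(bad, excluded=())

    def test_config_validation(self):
        with pytest.raises(ValueError, match="grid"):
            sc.CohortConfig(grid=(2.0, 5.0, 0.001))
        with pytest.raises(ValueError, match="positive"):
            sc.CohortConfig(n_per_cluster=(0, 58, 112))
        with pytest.raises(ValueError, match="dispersion"):
            sc.CohortConfig(dispersion="variance")

    def test_se_dispersion_scales_with_cluster_size(self):
        sd_cfg = sc.CohortConfig(dispersion="sd")
        se_cfg = sc.CohortConfig(dispersion="se")
        ratio = se_cfg.cluster_sds()["Mc1"] / sd_cfg.cluster_sds()["Mc1"]
        assert np.allclose(ratio, np.sqrt(58))


class TestCalibration:
    def test_single_metabolite_recovers_mean(self):
        spec = MetaboliteSpec("solo", ((3.0, 1.0),), window=(2.985, 3.015))
        table = pd.DataFrame(
            {f"{c.lower()}_{k}": [v]
             for c in reference.CLUSTERS for k, v in (("mean", 100.0), ("sd", 10.0))},
            index=pd.Index(["solo"], name="metabolite"),
        )
        config = sc.CohortConfig(level_table=table, specs=[spec], noise_sd=0, gain_sd=0)
        scales = sc.calibrate_scales([spec], np.array([100.0]), config)
        model = sc._SpectralModel(config)
        rec = model.quantify(model.compose(scales * np.array([100.0])), ["m"]).iloc[0, 0]
        assert rec == pytest.approx(100.0, rel=1e-3)

    def test_default_table_converges_within_tolerance(self):
        config = sc.CohortConfig()
        targets = config.cluster_means().to_numpy() @ np.array([58, 58, 112]) / 228
        scales = sc.calibrate_scales(config.specs, targets, config)
        model = sc._SpectralModel(config)
        rec = model.quantify(model.compose(scales * targets, strict=True),
                             ["m"]).iloc[:, 0].to_numpy()
        assert np.abs(rec / targets - 1).max() < 1e-3

    def test_zero_target_gets_zero_scale(self):
        config = sc.CohortConfig()
        targets = config.cluster_means().to_numpy() @ np.array([58, 58, 112]) / 228
        targets[0] = 0.0
        scales = sc.calibrate_scales(config.specs, targets, config)
        assert scales[0] == 0.0


class TestGenSpectra:
    def test_default_cohort_shape_and_sizes(self, default_cohort):
        config, spectra, truth = default_cohort
        assert spectra.n_samples == 228
        counts = truth.true_cluster.value_counts()
        assert counts["Mc1"] == 58 and counts["Mc2"] == 58 and counts["Mc3"] == 112

    def test_intensities_finite_and_nonnegative_before_noise(self):
        config = sc.CohortConfig(seed=4, noise_sd=0.0, gain_sd=0.0)
        spectra, _ = sc.gen_spectra(config)
        assert np.isfinite(spectra.intensities).all()
        assert (spectra.intensities >= 0).all()

    def test_same_seed_bit_identical(self):
        a, _ = sc.gen_spectra(sc.CohortConfig(seed=9))
        b, _ = sc.gen_spectra(sc.CohortConfig(seed=9))
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_noiseless_per_sample_recovery(self):
        """Without noise and gain, quantification returns each sample's
        planted levels to within 0.5 % of the larger of the level and the
        metabolite's cohort-mean scale (cross-window leak is bounded)."""
        config = sc.CohortConfig(seed=2, noise_sd=0.0, gain_sd=0.0)
        spectra, truth = sc.gen_spectra(config)
        q = quantify(config, spectra)
        truth_levels = truth.true_levels.loc[q.index, q.columns]
        scale = np.maximum(
            truth_levels.to_numpy(),
            truth_levels.mean(axis=1).to_numpy()[:, None],
        )
        rel = np.abs(q.to_numpy() - truth_levels.to_numpy()) / scale
        assert rel.max() < 0.005

    def test_lipid_peaks_vanish_after_preprocessing(self, default_cohort):
        """Lipid amplitudes up to 20x the tallest peak sit inside the excluded
        windows and cannot reach the preprocessed matrix."""
        config, spectra, _ = default_cohort
        quiet, _ = sc.gen_spectra(
            sc.CohortConfig(seed=config.seed, lipid_amp_max=0.0)
        )
        np.testing.assert_allclose(
            preprocess(spectra).intensities, preprocess(quiet).intensities,
            rtol=0, atol=1e-9,
        )

    def test_cluster_means_within_three_se(self, default_cohort):
        config, spectra, truth = default_cohort
        q = quantify(config, spectra)
        means = config.cluster_means()
        sds = config.cluster_sds()
        for cluster, n in zip(reference.CLUSTERS, config.n_per_cluster):
            cols = truth.true_cluster.index[truth.true_cluster == cluster]
            rec = q[cols].mean(axis=1)
            se = sds[cluster] / np.sqrt(n)
            assert (np.abs(rec - means[cluster]) <= 3 * se + 0.01 * means[cluster]).all()


class TestGenExpression:
    def test_no_planted_effects_when_n_de_zero(self, default_cohort):
        _, _, truth = default_cohort
        t = sc.SyntheticTruth(truth.true_cluster, truth.true_levels)
        _, _sets = sc.gen_expression(t, n_de=0, seed=0)
        assert all(len(v) == 0 for v in t.de_genes.values())

    def test_mc2_vs_mc3_contrast_empty(self, expression_cohort):
        _, _, truth = expression_cohort
        assert truth.de_genes["Mc2_vs_Mc3"] == []

    def test_planted_gene_detectable_by_t_test(self, expression_cohort):
        """Power oracle: a planted |delta| >= 1 shift at n = 228 gives a
        two-sample t p-value far below 1e-6."""
        expr, _, truth = expression_cohort
        in_mc1 = truth.true_cluster == "Mc1"
        strong = [g for g, d in truth.de_genes["Mc1_vs_rest"] if abs(d) >= 1.0]
        assert strong
        gene = strong[0]
        a = expr.loc[gene, in_mc1[expr.columns]]
        b = expr.loc[gene, ~in_mc1[expr.columns]]
        assert stats.ttest_ind(a, b).pvalue < 1e-6

    def test_n_de_exceeding_n_genes_errors(self, default_cohort):
        _, _, truth = default_cohort
        t = sc.SyntheticTruth(truth.true_cluster, truth.true_levels)
        with pytest.raises(ValueError, match="n_de"):
            sc.gen_expression(t, n_genes=10, n_de=11)

    def test_gene_sets_sizes(self, expression_cohort):
        _, gene_sets, _ = expression_cohort
        assert len(gene_sets["ECM_ORGANIZATION"]) == 50
        null_sizes = [len(v) for k, v in gene_sets.items() if k.startswith("NULL")]
        assert len(null_sizes) >= 30
        assert all(15 <= s <= 500 for s in null_sizes)


class TestGenLabels:
    def test_degenerate_multinomial(self, default_cohort):
        _, _, truth = default_cohort
        probs = pd.DataFrame(
            {c: [1.0, 0.0] for c in reference.CLUSTERS}, index=["only", "never"]
        )
        t = sc.SyntheticTruth(truth.true_cluster, truth.true_levels)
        labels = sc.gen_labels(t, {"toy": probs}, seed=0)
        assert (labels["toy"] == "only").all()

    def test_unnormalized_probabilities_rejected(self, default_cohort):
        _, _, truth = default_cohort
        probs = pd.DataFrame({c: [0.5, 0.4] for c in reference.CLUSTERS}, index=["a", "b"])
        t = sc.SyntheticTruth(truth.true_cluster, truth.true_levels)
        with pytest.raises(ValueError, match="sum to 1"):
            sc.gen_labels(t, {"toy": probs}, seed=0)

    def test_seed_determinism(self, default_cohort):
        _, _, truth = default_cohort
        t1 = sc.SyntheticTruth(truth.true_cluster, truth.true_levels)
        t2 = sc.SyntheticTruth(truth.true_cluster, truth.true_levels)
        a = sc.gen_labels(t1, seed=5)
        b = sc.gen_labels(t2, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_mc2_reactive_one_fraction_matches_published(self):
        """Among RPPA-typed Mc2 samples the reactive I fraction converges to
        the published 24/55 (binomial error at large n)."""
        big = sc.CohortConfig(n_per_cluster=(100, 5000, 100), seed=3)
        cluster = pd.Series(
            np.repeat(list(reference.CLUSTERS), big.n_per_cluster),
            index=[f"S{i}" for i in range(sum(big.n_per_cluster))],
        )
        t = sc.SyntheticTruth(cluster, pd.DataFrame())
        labels = sc.gen_labels(t, sc.default_label_probs(big), seed=21)
        mc2 = labels.loc[cluster == "Mc2", "rppa"]
        typed = mc2[mc2 != "NA"]
        frac = (typed == "Reactive I").mean()
        p = 24 / 55
        se = np.sqrt(p * (1 - p) / len(typed))
        assert abs(frac - p) < 4 * se

    def test_label_marginals_chi_square_consistent(self):
        """Goodness of fit of generated PAM50 labels to the configured
        multinomial at n = 10,000 (chi-square p > 0.01)."""
        big = sc.CohortConfig(n_per_cluster=(10000, 10, 10), seed=3)
        cluster = pd.Series(
            np.repeat(list(reference.CLUSTERS), big.n_per_cluster),
            index=[f"S{i}" for i in range(sum(big.n_per_cluster))],
        )
        t = sc.SyntheticTruth(cluster, pd.DataFrame())
        probs = sc.default_label_probs(big)
        labels = sc.gen_labels(t, probs, seed=8)
        mc1 = labels.loc[cluster == "Mc1", "pam50"]
        expected = probs["pam50"]["Mc1"] * len(mc1)
        observed = mc1.value_counts().reindex(probs["pam50"].index).fillna(0)
        p = stats.chisquare(observed, expected).pvalue
        assert p > 0.01


class TestGenPathways:
    def test_planted_pathway_members(self, expression_cohort):
        expr, _, truth = expression_cohort
        pw = sc.gen_pathways(truth, universe_genes=list(expr.index), seed=2)
        planted = pw[0]
        de = {g for g, _ in truth.de_genes["Mc1_vs_rest"]}
        assert set(planted["genes"]) <= de
        assert "Phosphocholine" in planted["metabolites"]
        assert len(pw) == 11
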