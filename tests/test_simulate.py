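"""Synthetic cohort generator: determinism, marginal moments, truth recovery."""

import numpy as np
import pandas as pd
import pytest

from devgsem.simulate import (SimulationSpec, apply_missingness, full_spec,
                              simulate_cohort, simulate_genotypes,
                              simulate_phenotypes, stage1_spec, stage2_spec)


class TestGenotypes:
    def test_deterministic_under_seed(self):
        spec = stage1_spec(n_individuals=50, n_snps=100, seed=7)
        g1 = simulate_genotypes(spec)
        g2 = simulate_genotypes(spec)
        np.testing.assert_array_equal(g1.dosages, g2.dosages)

    def test_fixed_maf_half_gives_mean_dosage_one(self):
        spec = SimulationSpec(n_individuals=4000, n_snps=50,
                              maf_range=(0.5, 0.5),
                              truth_gamma=np.array([[0.3]]),
                              truth_epsilon=np.array([[np.sqrt(0.91)]]),
                              trait_labels=["t"], seed=1)
        g = simulate_genotypes(spec)
        means = g.dosages.mean(axis=0)
        # binomial(2, 0.5): sd of the mean = sqrt(0.5)/sqrt(n)
        mc_se = np.sqrt(0.5 / 4000)
        assert np.all(np.abs(means - 1.0) < 3 * mc_se + 1e-12)

    @pytest.mark.parametrize("bad", [(0.0, 0.5), (0.1, 0.6), (-0.1, 0.2)])
    def test_invalid_maf_range_rejected(self, bad):
        with pytest.raises(ValueError, match="maf_range"):
            SimulationSpec(n_individuals=10, n_snps=5, maf_range=bad,
                           truth_gamma=np.array([[0.3]]),
                           truth_epsilon=np.array([[np.sqrt(0.91)]]),
                           trait_labels=["t"])

    def test_zero_snps_rejected(self):
        spec = stage1_spec(n_individuals=10, n_snps=0)
        with pytest.raises(ValueError, match="SNP"):
            simulate_genotypes(spec)


class TestPhenotypes:
    def test_deterministic_under_seed(self):
        spec = stage1_spec(n_individuals=60, n_snps=80, seed=3)
        g = simulate_genotypes(spec)
        t1 = simulate_phenotypes(g, spec)
        t2 = simulate_phenotypes(g, spec)
        pd.testing.assert_frame_equal(t1.values, t2.values)

    def test_zero_gamma_gives_pure_residual_covariance(self):
        eps = np.linalg.cholesky(np.array([[1.0, 0.4], [0.4, 1.0]]))
        spec = SimulationSpec(n_individuals=4000, n_snps=50, seed=9,
                              truth_gamma=np.zeros((2, 2)),
                              truth_epsilon=eps, trait_labels=["u", "v"],
                              standardized=True, covariate_effects=None)
        table = simulate_phenotypes(simulate_genotypes(spec), spec)
        emp = np.cov(table.values.to_numpy().T)
        target = eps @ eps.T
        # MC-SE of a covariance entry ~ sqrt((v_ii v_jj + v_ij^2)/n)
        se = np.sqrt((np.outer(np.diag(target), np.diag(target))
                      + target ** 2) / 4000)
        assert np.all(np.abs(emp - target) < 3 * se)

    def test_genetic_value_covariance_matches_gamma(self):
        gamma = np.array([[0.6, 0.0], [0.3, 0.4]])
        eps = np.linalg.cholesky(np.eye(2) - gamma @ gamma.T)
        spec = SimulationSpec(n_individuals=2000, n_snps=5000, seed=11,
                              truth_gamma=gamma, truth_epsilon=eps,
                              trait_labels=["u", "v"], covariate_effects=None)
        g = simulate_genotypes(spec)
        _, comps = simulate_phenotypes(g, spec, return_components=True)
        emp = np.cov(comps["genetic"].to_numpy().T)
        target = gamma @ gamma.T
        # sampling error from both individuals (1/n) and SNP effects (2/M)
        scale = np.sqrt(np.outer(np.diag(target), np.diag(target)) + target ** 2)
        se = scale * np.sqrt(1 / 2000 + 2 / 5000)
        assert np.all(np.abs(emp - target) < 3 * se)

    def test_trait_count_mismatch_rejected(self):
        spec = stage1_spec(n_individuals=30, n_snps=40)
        other = stage1_spec(n_individuals=20, n_snps=40)
        with pytest.raises(ValueError):
            simulate_phenotypes(simulate_genotypes(other), spec)

    def test_standardized_rows_enforced(self):
        with pytest.raises(ValueError, match="standardized"):
            SimulationSpec(n_individuals=10, n_snps=5,
                           truth_gamma=np.array([[0.9]]),
                           truth_epsilon=np.array([[0.9]]),
                           trait_labels=["t"], standardized=True)


class TestMissingness:
    def test_wave_specific_observed_counts(self):
        # emulated design: N = 6524 with per-wave loss of 0 / 8% / 7% / 7%
        spec = stage1_spec(n_individuals=6524, n_snps=10, seed=5,
                           missingness=True)
        table = simulate_phenotypes(simulate_genotypes(spec), spec)
        masked = apply_missingness(table, spec)
        counts = masked.values.notna().sum()
        expected = {"exp15": 6524, "exp24": 6014, "exp38": 6092, "rec38": 6092}
        for t, exp in expected.items():
            frac = spec.missing_fraction[t]
            se = np.sqrt(6524 * frac * (1 - frac))
            assert abs(counts[t] - exp) <= 3 * se + 1e-9

    def test_zero_fraction_leaves_table_unchanged(self):
        spec = stage1_spec(n_individuals=100, n_snps=10, seed=2)
        spec.missing_fraction = {t: 0.0 for t in spec.trait_labels}
        table = simulate_phenotypes(simulate_genotypes(spec), spec)
        masked = apply_missingness(table, spec)
        pd.testing.assert_frame_equal(masked.values, table.values)

    def test_half_missing_reproducible(self):
        spec = stage1_spec(n_individuals=1000, n_snps=10, seed=8)
        spec.missing_fraction = {"exp15": 0.5}
        table = simulate_phenotypes(simulate_genotypes(spec), spec)
        m1 = apply_missingness(table, spec)
        m2 = apply_missingness(table, spec)
        n_obs = int(m1.values["exp15"].notna().sum())
        assert abs(n_obs - 500) < 3 * np.sqrt(1000 * 0.25)
        pd.testing.assert_frame_equal(m1.values, m2.values)

    def test_monotone_dropout_nested(self):
        spec = stage1_spec(n_individuals=500, n_snps=10, seed=4)
        spec.missing_fraction = {"exp15": 0.0, "exp24": 0.1,
                                 "exp38": 0.2, "rec38": 0.2}
        table = simulate_phenotypes(simulate_genotypes(spec), spec)
        masked = apply_missingness(table, spec, monotone=True)
        na = masked.values.isna()
        assert (na["exp24"] <= na["exp38"]).all()  # dropout never returns


class TestCohortStructure:
    def test_phenotypic_correlation_converges_to_truth(self):
        spec = stage1_spec(n_individuals=5000, n_snps=2000, seed=13)
        spec.covariate_effects = None
        co = simulate_cohort(spec)
        emp = np.corrcoef(co.phenotypes_complete.values.to_numpy().T)
        target = (spec.truth_gamma @ spec.truth_gamma.T
                  + spec.truth_epsilon @ spec.truth_epsilon.T)
        # MC-SE of a correlation ~ (1-r^2)/sqrt(n) plus SNP-effect sampling
        se = (1 - target ** 2) / np.sqrt(5000) + 0.15 * np.sqrt(2 / 2000)
        off = ~np.eye(4, dtype=bool)
        assert np.max(np.abs(emp - target)[off] / se[off]) < 3

    def test_largest_correlation_pair_matches_design(self):
        # expressive/receptive vocabulary at the last wave are designed to be
        # the most correlated pair (r_p = 0.63)
        spec = stage1_spec(n_individuals=5000, n_snps=500, seed=17)
        spec.covariate_effects = None
        co = simulate_cohort(spec)
        r = co.phenotypes_complete.values.corr()
        assert abs(r.loc["exp38", "rec38"] - 0.63) < 0.05
        np.fill_diagonal(r.values, 0)
        assert r.abs().to_numpy().max() == pytest.approx(
            abs(r.loc["exp38", "rec38"]))

    def test_full_spec_seven_traits_standardized(self):
        spec = full_spec(n_individuals=10, n_snps=5)
        assert spec.trait_labels[-3:] == ["reading", "viq", "piq"]
        total = (spec.truth_gamma ** 2).sum(1) + (spec.truth_epsilon ** 2).sum(1)
        np.testing.assert_allclose(total, 1.0, atol=1e-9)

    def test_stage2_outcome_appended_last(self):
        spec = stage2_spec("viq", n_individuals=10, n_snps=5)
        assert spec.trait_labels[-1] == "viq"
        assert spec.truth_gamma[4, 3] == pytest.approx(0.60)
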