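"""Derived statistics: formulas, identities, and uncertainty propagation."""

import numpy as np
import pandas as pd
import pytest

from devgsem import derived
from devgsem.derived import (bivariate_heritability, delta_se, draws_se,
                             factorial_coheritability, genetic_correlation,
                             residual_correlation, snp_h2, summarize,
                             variance_explained)
from devgsem.grm import compute_grm
from devgsem.gsem import CholeskyModel, fit
from devgsem.phenotypes import PhenotypeTable
from devgsem.simulate import SimulationSpec, simulate_cohort

from conftest import standardize


def _model(gamma, epsilon=None):
    gamma = np.asarray(gamma, dtype=float)
    m = gamma.shape[0]
    if epsilon is None:
        resid = 1.0 - (gamma ** 2).sum(axis=1)
        epsilon = np.diag(np.sqrt(resid))
    return CholeskyModel(gamma=gamma, epsilon=np.asarray(epsilon, dtype=float))


class TestVarianceExplained:
    def test_square_of_standardized_path(self):
        m = _model([[0.6]])
        assert variance_explained(m)[0, 0] == pytest.approx(0.36)

    def test_zero_and_full_loading(self):
        m0 = _model([[0.0]], [[1.0]])
        assert variance_explained(m0)[0, 0] == 0.0
        m1 = _model([[1.0]], [[0.0]])
        assert variance_explained(m1)[0, 0] == pytest.approx(1.0)

    def test_negative_path_squares_in(self):
        m = _model([[0.5, 0.0], [-0.3, 0.4]])
        assert variance_explained(m)[1, 0] == pytest.approx(0.09)


class TestSnpH2:
    def test_first_trait_is_squared_first_path(self):
        m = _model([[0.33, 0.0], [0.21, 0.32]])
        assert snp_h2(m)[0] == pytest.approx(0.33 ** 2)

    def test_row_sum_identity(self):
        m = _model([[0.33, 0.0], [0.21, 0.32]])
        ve = variance_explained(m)
        np.testing.assert_allclose(snp_h2(m), ve.sum(axis=1), atol=1e-12)

    def test_no_residual_gives_unit_h2(self):
        m = _model([[0.6, 0.0], [0.3, np.sqrt(1 - 0.09)]],
                   np.zeros((2, 2)))
        np.testing.assert_allclose(snp_h2(m), [1.0, 1.0])


class TestCorrelations:
    def test_worked_example(self):
        # loading rows (0.3, 0.4) and (0.5, 0): cov 0.15, variances 0.25 each
        gamma = np.array([[0.2, 0.0, 0.0],
                          [0.3, 0.4, 0.0],
                          [0.5, 0.0, 0.0]])
        m = CholeskyModel(gamma=gamma, epsilon=np.eye(3) * 0.5)
        assert genetic_correlation(m)[1, 2] == pytest.approx(0.6)

    def test_matches_brute_force_covariance(self):
        rng = np.random.default_rng(0)
        gamma = np.tril(rng.normal(scale=0.3, size=(4, 4)))
        np.fill_diagonal(gamma, np.abs(np.diag(gamma)) + 0.1)
        m = CholeskyModel(gamma=gamma, epsilon=np.eye(4) * 0.5)
        rg = genetic_correlation(m)
        cov = gamma @ gamma.T
        oracle = cov / np.sqrt(np.outer(np.diag(cov), np.diag(cov)))
        np.testing.assert_allclose(rg, oracle, atol=1e-14)

    def test_identical_and_orthogonal_rows(self):
        gamma = np.array([[0.4, 0.0], [0.4, 0.0]])
        m = CholeskyModel(gamma=gamma, epsilon=np.eye(2) * 0.5)
        assert genetic_correlation(m)[0, 1] == pytest.approx(1.0)
        gamma2 = np.array([[0.4, 0.0], [0.0, 0.3]])
        m2 = CholeskyModel(gamma=gamma2, epsilon=np.eye(2) * 0.5)
        assert genetic_correlation(m2)[0, 1] == pytest.approx(0.0)

    def test_zero_genetic_variance_flagged(self):
        gamma = np.array([[0.0, 0.0], [0.2, 0.3]])
        m = CholeskyModel(gamma=gamma, epsilon=np.eye(2) * 0.5)
        rg = genetic_correlation(m)
        assert np.isnan(rg[0, 1])
        assert rg[1, 1] == pytest.approx(1.0)

    def test_residual_analogue(self):
        eps = np.array([[0.8, 0.0], [0.4, 0.6]])
        m = CholeskyModel(gamma=np.eye(2) * 0.3, epsilon=eps)
        re = residual_correlation(m)
        cov = eps @ eps.T
        assert re[0, 1] == pytest.approx(cov[0, 1] /
                                         np.sqrt(cov[0, 0] * cov[1, 1]))


class TestFactorialCoheritability:
    def test_printed_share_split(self):
        # per-factor contributions 4.6% and 10.1% of phenotypic variance
        row = np.array([[np.sqrt(0.046), 0.0],
                        [np.sqrt(0.046), np.sqrt(0.101)]])
        m = CholeskyModel(gamma=row, epsilon=np.eye(2) * 0.5)
        fc = factorial_coheritability(m)[1]
        assert fc[0] == pytest.approx(0.046 / 0.147, abs=1e-9)
        assert fc[1] == pytest.approx(0.101 / 0.147, abs=1e-9)

    def test_single_factor_and_equal_loadings(self):
        m = CholeskyModel(gamma=np.array([[0.5, 0.0, 0.0],
                                          [0.0, 0.3, 0.0],
                                          [0.2, 0.2, 0.2]]),
                          epsilon=np.eye(3) * 0.5)
        fc = factorial_coheritability(m)
        assert fc[0, 0] == pytest.approx(1.0)
        np.testing.assert_allclose(fc[2], [1 / 3, 1 / 3, 1 / 3])

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        gamma = np.tril(rng.normal(size=(5, 5)))
        m = CholeskyModel(gamma=gamma, epsilon=np.eye(5))
        np.testing.assert_allclose(factorial_coheritability(m).sum(axis=1),
                                   1.0, atol=1e-9)


class TestBivariateHeritability:
    def test_direct_evaluation(self):
        gamma = np.array([[0.6, 0.0], [0.3, 0.0]])  # genetic cov 0.18
        m = CholeskyModel(gamma=gamma, epsilon=np.eye(2) * 0.5)
        rp = np.array([[1.0, 0.5], [0.5, 1.0]])
        b = bivariate_heritability(m, rp)
        assert b[0, 1] == pytest.approx(0.36)

    def test_pure_genetic_correlation_gives_one(self):
        gamma = np.array([[0.6, 0.0], [0.3, 0.0]])
        m = CholeskyModel(gamma=gamma, epsilon=np.eye(2) * 0.5)
        rp = np.array([[1.0, 0.18], [0.18, 1.0]])  # r_p equals genetic cov
        assert bivariate_heritability(m, rp)[0, 1] == pytest.approx(1.0)

    def test_zero_rp_flagged_not_infinite(self):
        m = CholeskyModel(gamma=np.eye(2) * 0.3, epsilon=np.eye(2) * 0.9)
        rp = np.array([[1.0, 0.0], [0.0, 1.0]])
        b = bivariate_heritability(m, rp)
        assert np.isnan(b[0, 1])

    def test_product_identity(self):
        rng = np.random.default_rng(2)
        gamma = np.tril(rng.normal(scale=0.3, size=(3, 3)))
        m = CholeskyModel(gamma=gamma, epsilon=np.eye(3) * 0.5)
        rp = np.array([[1.0, 0.4, 0.2], [0.4, 1.0, 0.5], [0.2, 0.5, 1.0]])
        b = bivariate_heritability(m, rp)
        np.testing.assert_allclose(b * rp, gamma @ gamma.T, atol=1e-12)


@pytest.fixture(scope="module")
def two_trait_fit():
    gamma = np.array([[0.5, 0.0], [0.25, 0.45]])
    eps = np.linalg.cholesky(np.eye(2) - gamma @ gamma.T
                             + 0.25 * (1 - np.eye(2)))
    spec = SimulationSpec(n_individuals=600, n_snps=1000, seed=77,
                          truth_gamma=gamma, truth_epsilon=eps,
                          trait_labels=["u", "v"], covariate_effects=None)
    co = simulate_cohort(spec)
    g = compute_grm(co.genotypes)
    ph = PhenotypeTable(values=standardize(co.phenotypes_complete.values))
    return fit(g, ph)


class TestUncertainty:
    def test_zero_gradient_quantity_has_zero_se(self, two_trait_fit):
        # a constant derived quantity has zero gradient, hence zero SE
        assert delta_se(two_trait_fit, lambda m: 1.0) == 0.0

    def test_delta_vs_monte_carlo_draws(self, two_trait_fit):
        f = lambda m: float(snp_h2(m)[1])
        d = delta_se(two_trait_fit, f)
        s = draws_se(two_trait_fit, f, n_draws=500, seed=3)
        assert abs(d - s) / d < 0.15

    def test_h2_se_matches_greml_delta_se(self, grm, std_phenotypes):
        from devgsem.greml import fit_univariate
        ph1 = PhenotypeTable(values=std_phenotypes.values[["exp24"]])
        res = fit(grm, ph1)
        se_gsem = delta_se(res, lambda m: float(snp_h2(m)[0]))
        uni = fit_univariate(grm, std_phenotypes.values["exp24"])
        assert abs(se_gsem - uni.se_h2) / uni.se_h2 < 0.2

    def test_summary_tables_consistent(self, two_trait_fit):
        summary = summarize(two_trait_fit)
        np.testing.assert_allclose(
            summary.factorial_coherit.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(
            summary.snp_h2.to_numpy(),
            summary.var_explained.sum(axis=1).to_numpy(), atol=1e-12)
        assert set(summary.tables()) >= {"snp_h2", "genetic_correlation",
                                         "factorial_coheritability"}
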