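"""Cholesky GSEM likelihood oracles, fitting, and stage-2 extensions."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from devgsem import derived
from devgsem.grm import GRM, compute_grm
from devgsem.greml import fit_univariate
from devgsem.gsem import CholeskyModel, fit, loglik, stage2_extend
from devgsem.phenotypes import PhenotypeTable
from devgsem.simulate import simulate_cohort, stage1_spec

from conftest import standardize


def _brute_force_loglik(model, a, values):
    """Independent dense oracle: stack observed entries, one big Gaussian."""
    y = values.to_numpy(dtype=float)
    m = y.shape[1]
    g = model.gamma @ model.gamma.T
    e = model.epsilon @ model.epsilon.T
    obs = [np.flatnonzero(~np.isnan(y[:, t])) for t in range(m)]
    yo = np.concatenate([y[obs[t], t] for t in range(m)])
    nblk = [len(o) for o in obs]
    starts = np.cumsum([0] + nblk)
    v = np.zeros((len(yo), len(yo)))
    for s in range(m):
        for t in range(m):
            blk = g[s, t] * a[np.ix_(obs[s], obs[t])] \
                + e[s, t] * (obs[s][:, None] == obs[t][None, :])
            v[starts[s]:starts[s + 1], starts[t]:starts[t + 1]] = blk
    return multivariate_normal.logpdf(yo, mean=np.zeros(len(yo)), cov=v)


@pytest.fixture(scope="module")
def small(grm, std_phenotypes):
    idx = np.arange(180)
    sub_grm = grm.subset(idx)
    sub_ph = PhenotypeTable(values=std_phenotypes.values.iloc[:180])
    return sub_grm, sub_ph


class TestLoglik:
    def test_univariate_matches_dense_oracle(self, small):
        sub_grm, sub_ph = small
        ph1 = PhenotypeTable(values=sub_ph.values[["exp24"]])
        model = CholeskyModel(gamma=[[0.4]], epsilon=[[0.9]],
                              trait_labels=["exp24"])
        ll = loglik(model, sub_grm, ph1)
        oracle = _brute_force_loglik(model, sub_grm.values, ph1.values)
        assert abs(ll - oracle) < 1e-8

    def test_zero_gamma_factorizes_over_individuals(self, small):
        sub_grm, sub_ph = small
        eps = np.linalg.cholesky(np.array([[1.0, 0.3], [0.3, 1.0]]))
        model = CholeskyModel(gamma=np.zeros((2, 2)), epsilon=eps,
                              trait_labels=["exp15", "exp24"])
        ph2 = PhenotypeTable(values=sub_ph.values[["exp15", "exp24"]])
        ll = loglik(model, sub_grm, ph2)
        # iid oracle: independent bivariate normals per individual
        cov = eps @ eps.T
        ll_iid = multivariate_normal.logpdf(
            ph2.values.to_numpy(), mean=np.zeros(2), cov=cov).sum()
        assert abs(ll - ll_iid) < 1e-8

    def test_permutation_invariance(self, small):
        sub_grm, sub_ph = small
        model = CholeskyModel(gamma=0.3 * np.tril(np.ones((4, 4))) / 2,
                              epsilon=0.8 * np.eye(4),
                              trait_labels=sub_ph.trait_labels)
        ll = loglik(model, sub_grm, sub_ph)
        rng = np.random.default_rng(1)
        perm = rng.permutation(sub_grm.n)
        grm_p = sub_grm.subset(perm)
        ph_p = PhenotypeTable(values=sub_ph.values.iloc[perm])
        assert abs(loglik(model, grm_p, ph_p) - ll) < 1e-8

    def test_missing_data_matches_dense_oracle(self, small):
        sub_grm, sub_ph = small
        vals = sub_ph.values.copy()
        rng = np.random.default_rng(2)
        vals.iloc[rng.choice(180, 30, replace=False), 1] = np.nan
        vals.iloc[rng.choice(180, 20, replace=False), 3] = np.nan
        ph = PhenotypeTable(values=vals)
        model = CholeskyModel(
            gamma=np.tril(0.25 * np.ones((4, 4))),
            epsilon=np.linalg.cholesky(
                0.6 * np.eye(4) + 0.2 * np.ones((4, 4))),
            trait_labels=sub_ph.trait_labels)
        ll = loglik(model, sub_grm, ph)
        oracle = _brute_force_loglik(model, sub_grm.values, vals)
        assert abs(ll - oracle) < 1e-8

    def test_column_sign_flip_invariance(self, small):
        sub_grm, sub_ph = small
        gamma = np.tril(0.25 * np.ones((4, 4)))
        eps = np.linalg.cholesky(0.6 * np.eye(4) + 0.2 * np.ones((4, 4)))
        base = CholeskyModel(gamma=gamma, epsilon=eps,
                             trait_labels=sub_ph.trait_labels)
        flipped_g = gamma.copy()
        flipped_g[:, 1] = -flipped_g[:, 1]
        flipped = CholeskyModel(gamma=flipped_g, epsilon=eps,
                                trait_labels=sub_ph.trait_labels)
        assert abs(loglik(base, sub_grm, sub_ph)
                   - loglik(flipped, sub_grm, sub_ph)) < 1e-8

    def test_non_pd_point_returns_minus_inf(self, small):
        sub_grm, sub_ph = small
        model = CholeskyModel(gamma=np.zeros((4, 4)),
                              epsilon=np.zeros((4, 4)),
                              trait_labels=sub_ph.trait_labels)
        assert loglik(model, sub_grm, sub_ph) == -np.inf


class TestFit:
    def test_univariate_gsem_agrees_with_greml(self, grm, std_phenotypes):
        for trait in ("exp24", "rec38"):
            ph1 = PhenotypeTable(values=std_phenotypes.values[[trait]])
            res = fit(grm, ph1)
            h2_gsem = derived.snp_h2(res.model)[0]
            h2_greml = fit_univariate(grm, std_phenotypes.values[trait]).h2
            assert abs(h2_gsem - h2_greml) < 0.02

    def test_four_trait_fit_recovers_truth_within_3se(self, grm,
                                                      std_phenotypes, cohort):
        res = fit(grm, std_phenotypes)
        assert res.converged
        truth = cohort.spec.truth_gamma
        tl = np.tril_indices(4)
        resid = np.abs(res.model.gamma - truth)[tl] / res.se_gamma[tl]
        assert np.all(resid < 3.5)
        # diagonals reported non-negative (sign identification)
        assert np.all(np.diag(res.model.gamma) >= 0)
        assert np.all(np.diag(res.model.epsilon) >= 0)

    def test_free_parameter_count(self, grm, std_phenotypes):
        res = fit(grm, std_phenotypes, compute_se=False)
        assert res.model.n_free == 4 * 5
        table = res.paths_table()
        assert len(table) == 2 * 10

    def test_identity_grm_flags_degeneracy(self):
        rng = np.random.default_rng(3)
        n = 150
        g = GRM(values=np.eye(n), pair_marker_counts=np.full((n, n), 10),
                individual_ids=np.array([f"i{k}" for k in range(n)]))
        vals = pd.DataFrame(rng.standard_normal((n, 2)),
                            index=g.individual_ids, columns=["u", "v"])
        with pytest.warns(UserWarning, match="flat"):
            res = fit(g, PhenotypeTable(values=vals), compute_se=False)
        assert not res.identifiable

    def test_implied_covariances_track_greml(self, grm, std_phenotypes):
        # saturated-model property: per-trait genetic variance from the
        # fitted model stays close to the univariate GREML estimate
        res = fit(grm, std_phenotypes, compute_se=False)
        h2_gsem = derived.snp_h2(res.model)
        for k, trait in enumerate(std_phenotypes.trait_labels):
            h2_greml = fit_univariate(grm, std_phenotypes.values[trait]).h2
            # joint 4-trait ML vs per-trait REML on the same data: well
            # within one SE (~0.07 at n=800) of each other
            assert abs(h2_gsem[k] - h2_greml) < 0.1


class TestStage2:
    def test_noise_outcome_has_no_genetic_paths(self, grm, std_phenotypes):
        rng = np.random.default_rng(4)
        noise = pd.Series(rng.standard_normal(grm.n),
                          index=std_phenotypes.values.index)
        res = stage2_extend(grm, std_phenotypes, noise, "noise")
        assert res.model.trait_labels[-1] == "noise"
        z = np.abs(res.model.gamma[4, :]) / res.se_gamma[4, :]
        assert np.all(z[np.isfinite(z)] < 3.5)

    def test_outcome_loading_recovered(self):
        from devgsem.simulate import stage2_spec
        spec = stage2_spec("viq", n_individuals=900, n_snps=1500, seed=53)
        spec.covariate_effects = None
        co = simulate_cohort(spec)
        g = compute_grm(co.genotypes)
        vals = standardize(co.phenotypes_complete.values)
        base = PhenotypeTable(values=vals[spec.trait_labels[:4]])
        res = stage2_extend(g, base, vals["viq"], "viq")
        a54, se = res.model.gamma[4, 3], res.se_gamma[4, 3]
        assert abs(a54 - 0.60) < 3 * se

    def test_extensions_share_stage1_substructure(self, grm, std_phenotypes):
        rng = np.random.default_rng(5)
        base3 = PhenotypeTable(values=std_phenotypes.values.iloc[:, :3])
        o1 = pd.Series(rng.standard_normal(grm.n),
                       index=std_phenotypes.values.index)
        o2 = std_phenotypes.values.iloc[:, 3]
        r1 = stage2_extend(grm, base3, o1, "o1", compute_se=False)
        r2 = stage2_extend(grm, base3, o2, "o2")
        sub1 = r1.model.gamma[:3, :3]
        sub2 = r2.model.gamma[:3, :3]
        tol = 2 * np.nan_to_num(r2.se_gamma[:3, :3], nan=0.0) + 1e-6
        assert np.all(np.abs(sub1 - sub2) <= np.maximum(tol, 0.05))

    def test_duplicate_outcome_label_rejected(self, grm, std_phenotypes):
        with pytest.raises(ValueError, match="already present"):
            stage2_extend(grm, std_phenotypes,
                          std_phenotypes.values["exp15"], "exp15")
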