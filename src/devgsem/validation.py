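"""Validation studies: oracle comparisons, parameter recovery, calibration.

These are the package's own correctness studies, run both by the test suite
and by ``scripts/acceptance.py``.  Each returns plain numbers computed from
scratch at call time.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import multivariate_normal

from . import derived, greml, gsem
from .grm import compute_grm
from .phenotypes import PhenotypeTable
from .simulate import (STAGE1_GAMMA, simulate_cohort, simulate_genotypes,
                       stage1_spec)

__all__ = [
    "printed_value_identities", "loglik_oracle_maxdiff", "rg_oracle_maxdiff",
    "gsem_greml_h2_gaps", "path_recovery_study", "lrt_null_calibration",
]


def printed_value_identities() -> dict[str, float]:
    """Arithmetic identities among derived statistics, on percentage scale.

    Reconstructs derived statistics from path coefficients alone: the split
    of per-factor variance contributions of 4.6% and 10.1% into factorial
    co-heritabilities, and the variance explained by standardized paths of
    0.60 and 0.33.
    """
    # two-factor trait with per-factor phenotypic variance 4.6% and 10.1%
    row = np.array([[np.sqrt(0.046), 0.0],
                    [np.sqrt(0.046), np.sqrt(0.101)]])
    m2 = gsem.CholeskyModel(gamma=row, epsilon=np.eye(2) * 0.5)
    fc = derived.factorial_coheritability(m2)[1]

    def ve_of(a: float) -> float:
        model = gsem.CholeskyModel(gamma=np.array([[a]]),
                                   epsilon=np.array([[np.sqrt(1 - a * a)]]))
        return float(derived.variance_explained(model)[0, 0])

    return {
        "factorial_coherit_factor1_pct": float(100 * fc[0]),
        "factorial_coherit_factor2_pct": float(100 * fc[1]),
        "var_explained_path060_pct": 100 * ve_of(0.60),
        "var_explained_path033_pct": 100 * ve_of(0.33),
    }


def loglik_oracle_maxdiff(seed: int, n: int = 200) -> float:
    """|GSEM m=1 log-likelihood - dense Gaussian oracle| on one dataset."""
    spec = stage1_spec(n_individuals=max(n, 60), n_snps=400, seed=seed)
    spec.covariate_effects = None
    co = simulate_cohort(spec)
    grm = compute_grm(co.genotypes).subset(np.arange(n))
    y = co.phenotypes_complete.values["exp24"].iloc[:n]
    y = (y - y.mean()) / y.std()
    ph = PhenotypeTable(values=y.to_frame())
    diffs = []
    for a, e in ((0.4, 0.9), (0.1, 1.0), (0.6, 0.7)):
        model = gsem.CholeskyModel(gamma=np.array([[a]]),
                                   epsilon=np.array([[e]]),
                                   trait_labels=["exp24"])
        ll = gsem.loglik(model, grm, ph)
        cov = a * a * grm.values + e * e * np.eye(n)
        oracle = multivariate_normal.logpdf(y.to_numpy(), np.zeros(n), cov)
        diffs.append(abs(ll - oracle))
    return float(max(diffs))


def rg_oracle_maxdiff(seed: int) -> float:
    """Genetic correlations from gamma vs brute-force corr of gamma gamma'."""
    rng = np.random.default_rng(seed)
    gamma = np.tril(rng.normal(scale=0.3, size=(5, 5)))
    np.fill_diagonal(gamma, np.abs(np.diag(gamma)) + 0.1)
    model = gsem.CholeskyModel(gamma=gamma, epsilon=np.eye(5) * 0.5)
    rg = derived.genetic_correlation(model)
    cov = gamma @ gamma.T
    d = np.sqrt(np.diag(cov))
    oracle = cov / np.outer(d, d)
    return float(np.max(np.abs(rg - oracle)))


def gsem_greml_h2_gaps(seed: int, n: int = 1000, n_snps: int = 2000
                       ) -> dict[str, float]:
    """Univariate GSEM vs GREML heritability on identical simulated data."""
    spec = stage1_spec(n_individuals=n, n_snps=n_snps, seed=seed)
    spec.covariate_effects = None
    co = simulate_cohort(spec)
    grm = compute_grm(co.genotypes)
    gaps = {}
    for trait in spec.trait_labels:
        y = co.phenotypes_complete.values[trait]
        y = (y - y.mean()) / y.std()
        h2_greml = greml.fit_univariate(grm, y, trait=trait).h2
        res = gsem.fit(grm, PhenotypeTable(values=y.to_frame()),
                       compute_se=False)
        h2_gsem = float(derived.snp_h2(res.model)[0])
        gaps[trait] = abs(h2_gsem - h2_greml)
    return gaps


#: the significant stage-1 genetic paths (truth of the recovery study)
RECOVERY_PATHS = {
    "a11": (0, 0), "a21": (1, 0), "a22": (1, 1),
    "a32": (2, 1), "a33": (2, 2), "a42": (3, 1),
}
NULL_PATH = ("a43", (3, 2))


def path_recovery_study(seed: int, n_reps: int = 50, n: int = 2000,
                        n_snps: int = 2000) -> dict:
    """Repeated 4-trait fits against the study-like truth paths.

    Returns per-path 2-SE coverage over replicates and the Wald rejection
    rate of the true-zero path a43 at alpha = 0.05.
    """
    within = {k: 0 for k in RECOVERY_PATHS}
    total = 0
    null_reject = 0
    for rep in range(n_reps):
        spec = stage1_spec(n_individuals=n, n_snps=n_snps, seed=seed + rep)
        spec.covariate_effects = None
        co = simulate_cohort(spec)
        grm = compute_grm(co.genotypes)
        vals = co.phenotypes_complete.values.apply(
            lambda c: (c - c.mean()) / c.std())
        res = gsem.fit(grm, PhenotypeTable(values=vals))
        if not np.all(np.isfinite(res.se_gamma[np.tril_indices(4)])):
            continue
        total += 1
        for key, (i, j) in RECOVERY_PATHS.items():
            truth = STAGE1_GAMMA[i, j]
            if abs(res.model.gamma[i, j] - truth) <= 2 * res.se_gamma[i, j]:
                within[key] += 1
        i, j = NULL_PATH[1]
        if res.wald_p_gamma[i, j] < 0.05:
            null_reject += 1
    coverage = {k: within[k] / total for k in within}
    return {
        "n_reps": total,
        "coverage": coverage,
        "min_coverage": min(coverage.values()),
        "null_rejection_rate": null_reject / total,
    }


def lrt_null_calibration(seed: int, n_reps: int = 500, n: int = 1000,
                         n_snps: int = 2000, alpha: float = 0.05) -> dict:
    """Type-I error of the boundary heritability LRT under h2 = 0.

    One genotype panel and GRM are shared across replicates (the null
    phenotype carries no genetic signal); phenotypes are fresh iid draws.
    """
    spec = stage1_spec(n_individuals=n, n_snps=n_snps, seed=seed)
    geno = simulate_genotypes(spec)
    grm = compute_grm(geno)
    grm.eigh()  # cache once
    rng = np.random.default_rng(seed + 1)
    rejections = 0
    for _ in range(n_reps):
        y = rng.standard_normal(n)
        res = greml.fit_univariate(grm, (y - y.mean()) / y.std())
        if res.lrt_p < alpha:
            rejections += 1
    return {"n_reps": n_reps, "type1_error": rejections / n_reps}
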