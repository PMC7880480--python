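"""Derived statistics from a fitted Cholesky model.

All quantities follow from the standardized path matrices: the square of a
path is the phenotypic variance a factor contributes to a trait; per-trait
SNP heritability is the genetic share of the implied total variance; genetic
and residual correlations come from the implied covariances gamma gamma' and
epsilon epsilon'; factorial co-heritability is the within-trait split of
genetic variance over factors; and bivariate heritability is the genetic
covariance as a share of the observed phenotypic correlation.

Standard errors are first-order delta-method propagations of the
path-parameter covariance (numerical gradients); a Monte-Carlo propagation
(draws from the asymptotic normal of the paths, re-evaluating the statistic)
is available as an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .gsem import CholeskyModel, FitResult

__all__ = [
    "variance_explained", "snp_h2", "genetic_correlation",
    "residual_correlation", "factorial_coheritability",
    "bivariate_heritability", "delta_se", "draws_se", "DerivedSummary",
    "summarize",
]


def _total_variance(model: CholeskyModel) -> np.ndarray:
    return (model.gamma ** 2).sum(axis=1) + (model.epsilon ** 2).sum(axis=1)


def variance_explained(model: CholeskyModel) -> np.ndarray:
    """Trait x factor matrix of squared standardized genetic paths.

    Entry (i, j) is a_ij^2 expressed as a fraction of the trait's implied
    total variance (the two coincide when standardization is exact).
    """
    return model.gamma ** 2 / _total_variance(model)[:, None]


def snp_h2(model: CholeskyModel) -> np.ndarray:
    """Per-trait SNP heritability: genetic share of implied total variance."""
    total = _total_variance(model)
    if np.any(total <= 0):
        raise ValueError("trait with zero implied total variance")
    return (model.gamma ** 2).sum(axis=1) / total


def _corr_from_cov(cov: np.ndarray) -> np.ndarray:
    v = np.diag(cov).copy()
    out = np.full_like(cov, np.nan)
    ok = v > 0
    denom = np.sqrt(np.outer(v, v))
    with np.errstate(invalid="ignore", divide="ignore"):
        out[np.ix_(ok, ok)] = (cov / denom)[np.ix_(ok, ok)]
    return out


def genetic_correlation(model: CholeskyModel) -> np.ndarray:
    """m x m genetic correlation matrix from the implied gamma gamma'.

    Entries involving a trait with zero genetic variance are NaN (undefined).
    """
    return _corr_from_cov(model.implied_genetic_cov())


def residual_correlation(model: CholeskyModel) -> np.ndarray:
    return _corr_from_cov(model.implied_residual_cov())


def factorial_coheritability(model: CholeskyModel) -> np.ndarray:
    """Trait x factor proportions of each trait's total genetic variance.

    Row i is a_ij^2 / sum_j' a_ij'^2; NaN for traits without genetic
    variance.  Rows sum to one.
    """
    g2 = model.gamma ** 2
    tot = g2.sum(axis=1)
    out = np.full_like(g2, np.nan)
    ok = tot > 0
    out[ok] = g2[ok] / tot[ok, None]
    return out


def bivariate_heritability(model: CholeskyModel, r_p: np.ndarray) -> np.ndarray:
    """Genetic contribution to each observed phenotypic correlation.

    b(i, k) = (gamma gamma')_ik / r_p(i, k) for standardized traits; entries
    with r_p = 0 (or missing) are NaN rather than infinite.  The diagonal is
    the per-trait SNP heritability (r_p = 1).
    """
    r_p = np.asarray(r_p, dtype=float)
    gcov = model.implied_genetic_cov()
    out = np.full_like(gcov, np.nan)
    ok = np.isfinite(r_p) & (r_p != 0)
    out[ok] = gcov[ok] / r_p[ok]
    return out


# -- uncertainty propagation ----------------------------------------------

def _check_cov(fit: FitResult) -> np.ndarray:
    if fit.param_cov is None:
        raise ValueError("parameter covariance unavailable (Hessian was not "
                         "positive definite); cannot propagate uncertainty")
    return fit.param_cov


def delta_se(fit: FitResult, func: Callable[[CholeskyModel], float],
             rel_step: float = 1e-6) -> float:
    """First-order delta-method SE of ``func`` of the fitted model.

    ``func`` maps a :class:`CholeskyModel` to a scalar; its gradient over the
    free paths is taken by central differences.
    """
    cov = _check_cov(fit)
    x0 = fit.model.pack()
    m = fit.model.m
    labels = fit.model.trait_labels
    h = rel_step * np.maximum(1.0, np.abs(x0))
    grad = np.empty(len(x0))
    for a in range(len(x0)):
        xp, xm = x0.copy(), x0.copy()
        xp[a] += h[a]
        xm[a] -= h[a]
        grad[a] = (func(CholeskyModel.unpack(xp, m, labels))
                   - func(CholeskyModel.unpack(xm, m, labels))) / (2 * h[a])
    return float(np.sqrt(max(grad @ cov @ grad, 0.0)))


def draws_se(fit: FitResult, func: Callable[[CholeskyModel], float],
             n_draws: int = 500, seed: int = 0) -> float:
    """Monte-Carlo SE: draw paths from N(theta-hat, Cov), re-evaluate func."""
    cov = _check_cov(fit)
    rng = np.random.default_rng(seed)
    x0 = fit.model.pack()
    draws = rng.multivariate_normal(x0, cov, size=n_draws,
                                    method="eigh")
    m = fit.model.m
    labels = fit.model.trait_labels
    vals = np.array([func(CholeskyModel.unpack(xi, m, labels))
                     for xi in draws])
    return float(np.std(vals, ddof=1))


@dataclass
class DerivedSummary:
    """All derived statistics of one fitted model, with SEs where defined."""

    trait_labels: list[str]
    var_explained: pd.DataFrame
    var_explained_se: pd.DataFrame
    snp_h2: pd.Series
    snp_h2_se: pd.Series
    r_g: pd.DataFrame
    r_g_se: pd.DataFrame
    r_e: pd.DataFrame
    factorial_coherit: pd.DataFrame
    factorial_coherit_se: pd.DataFrame
    bivariate_h2: pd.DataFrame | None = None

    def tables(self) -> dict[str, pd.DataFrame]:
        out = {
            "variance_explained": self.var_explained,
            "variance_explained_se": self.var_explained_se,
            "snp_h2": self.snp_h2.to_frame("h2").assign(se=self.snp_h2_se),
            "genetic_correlation": self.r_g,
            "genetic_correlation_se": self.r_g_se,
            "residual_correlation": self.r_e,
            "factorial_coheritability": self.factorial_coherit,
            "factorial_coheritability_se": self.factorial_coherit_se,
        }
        if self.bivariate_h2 is not None:
            out["bivariate_heritability"] = self.bivariate_h2
        return out


def summarize(fit: FitResult, r_p: pd.DataFrame | None = None,
              with_se: bool = True) -> DerivedSummary:
    """Compute every derived statistic (and delta-method SEs) from a fit."""
    model = fit.model
    m = model.m
    labels = list(model.trait_labels)
    factors = [f"A{j+1}" for j in range(m)]

    ve = variance_explained(model)
    h2 = snp_h2(model)
    rg = genetic_correlation(model)
    re_ = residual_correlation(model)
    fc = factorial_coheritability(model)

    ve_se = np.full((m, m), np.nan)
    h2_se = np.full(m, np.nan)
    rg_se = np.full((m, m), np.nan)
    fc_se = np.full((m, m), np.nan)
    can_se = with_se and fit.param_cov is not None
    if can_se:
        for i in range(m):
            h2_se[i] = delta_se(fit, lambda mo, i=i: float(snp_h2(mo)[i]))
            for j in range(i + 1):
                ve_se[i, j] = delta_se(
                    fit, lambda mo, i=i, j=j: float(variance_explained(mo)[i, j]))
                if model.gamma[i, :].any():
                    fc_se[i, j] = delta_se(
                        fit, lambda mo, i=i, j=j:
                        float(factorial_coheritability(mo)[i, j]))
            for k2 in range(i):
                if np.isfinite(rg[i, k2]):
                    rg_se[i, k2] = rg_se[k2, i] = delta_se(
                        fit, lambda mo, i=i, k2=k2:
                        float(genetic_correlation(mo)[i, k2]))

    biv = None
    if r_p is not None:
        rp_arr = r_p.loc[labels, labels].to_numpy()
        biv = pd.DataFrame(bivariate_heritability(model, rp_arr),
                           index=labels, columns=labels)

    return DerivedSummary(
        trait_labels=labels,
        var_explained=pd.DataFrame(ve, index=labels, columns=factors),
        var_explained_se=pd.DataFrame(ve_se, index=labels, columns=factors),
        snp_h2=pd.Series(h2, index=labels),
        snp_h2_se=pd.Series(h2_se, index=labels),
        r_g=pd.DataFrame(rg, index=labels, columns=labels),
        r_g_se=pd.DataFrame(rg_se, index=labels, columns=labels),
        r_e=pd.DataFrame(re_, index=labels, columns=labels),
        factorial_coherit=pd.DataFrame(fc, index=labels, columns=factors),
        factorial_coherit_se=pd.DataFrame(fc_se, index=labels, columns=factors),
        bivariate_h2=biv,
    )
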