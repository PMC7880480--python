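"""Multivariate Cholesky GSEM: maximum-likelihood factor paths on a GRM.

The model decomposes the covariance of m standardized traits over n
genotyped individuals into as many lower-triangular latent genetic factors
as traits (loadings gamma, identified through the GRM ``A``) and as many
residual factors (loadings epsilon, identified through the identity):

    Cov(vec Y) = (gamma gamma') (x) A  +  (epsilon epsilon') (x) I_n,

with a zero mean for pre-standardized residual phenotypes, fitted by full
maximum likelihood on the observed entries only (missing trait values drop
the corresponding rows/columns of the big covariance; no casewise deletion).

Two likelihood evaluation routes:

* fast path - when every trait is observed on the same individuals, the GRM
  eigendecomposition A = U diag(d) U' turns the problem into n independent
  m-dimensional Gaussians with covariance ``d_i * gamma gamma' + epsilon
  epsilon'`` (batched Cholesky, O(n m^3) per evaluation);
* dense path - otherwise the observed-block covariance is assembled and
  factorized directly (desk scale, total observations <= ~10,000).

Standard errors come from the inverse numerical Hessian (central
differences, relative step 1e-4) of the negative log-likelihood at the
optimum; Wald p-values are two-sided normal.  A whole-column sign flip of
any factor leaves the likelihood unchanged, so fitted results are reported
with non-negative diagonal paths.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .grm import GRM
from .phenotypes import PhenotypeTable

logger = logging.getLogger(__name__)

__all__ = ["CholeskyModel", "FitResult", "loglik", "fit", "stage2_extend"]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class CholeskyModel:
    """Lower-triangular genetic (gamma) and residual (epsilon) path matrices."""

    gamma: np.ndarray
    epsilon: np.ndarray
    trait_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        m = self.gamma.shape[0]
        if self.gamma.shape != (m, m) or self.epsilon.shape != (m, m):
            raise ValueError("gamma and epsilon must be square of equal size")
        if not np.allclose(self.gamma, np.tril(self.gamma)) or \
                not np.allclose(self.epsilon, np.tril(self.epsilon)):
            raise ValueError("path matrices must be lower-triangular")
        if self.trait_labels is None:
            self.trait_labels = [f"trait{i+1}" for i in range(m)]
        if len(self.trait_labels) != m:
            raise ValueError("trait_labels length must equal trait count")

    @property
    def m(self) -> int:
        return self.gamma.shape[0]

    @property
    def n_free(self) -> int:
        return self.m * (self.m + 1)

    # -- packing of free parameters (row-major lower triangles) ----------
    def pack(self) -> np.ndarray:
        i, j = np.tril_indices(self.m)
        return np.concatenate([self.gamma[i, j], self.epsilon[i, j]])

    @classmethod
    def unpack(cls, params: np.ndarray, m: int,
               trait_labels: list[str] | None = None) -> "CholeskyModel":
        i, j = np.tril_indices(m)
        k = len(i)
        gamma = np.zeros((m, m))
        epsilon = np.zeros((m, m))
        gamma[i, j] = params[:k]
        epsilon[i, j] = params[k:]
        return cls(gamma=gamma, epsilon=epsilon, trait_labels=trait_labels)

    def implied_genetic_cov(self) -> np.ndarray:
        return self.gamma @ self.gamma.T

    def implied_residual_cov(self) -> np.ndarray:
        return self.epsilon @ self.epsilon.T

    def implied_phenotypic_cov(self) -> np.ndarray:
        return self.implied_genetic_cov() + self.implied_residual_cov()

    def sign_fixed(self) -> "CholeskyModel":
        """Flip factor columns so all diagonal paths are non-negative."""
        g = self.gamma.copy()
        e = self.epsilon.copy()
        for j in range(self.m):
            if g[j, j] < 0:
                g[:, j] = -g[:, j]
            if e[j, j] < 0:
                e[:, j] = -e[:, j]
        return CholeskyModel(gamma=g, epsilon=e, trait_labels=self.trait_labels)


@dataclass
class FitResult:
    """A fitted Cholesky GSEM with uncertainty and diagnostics."""

    model: CholeskyModel
    se_gamma: np.ndarray
    se_epsilon: np.ndarray
    wald_p_gamma: np.ndarray
    wald_p_epsilon: np.ndarray
    loglik: float
    n_obs: pd.Series
    converged: bool
    n_iter: int
    param_cov: np.ndarray | None
    hessian_condition: float
    identifiable: bool = True

    def paths_table(self) -> pd.DataFrame:
        """Long-format per-path estimates, SEs and Wald p-values."""
        rows = []
        m = self.model.m
        labels = self.model.trait_labels
        for kind, est, se, p in (
                ("a", self.model.gamma, self.se_gamma, self.wald_p_gamma),
                ("e", self.model.epsilon, self.se_epsilon, self.wald_p_epsilon)):
            for i in range(m):
                for j in range(i + 1):
                    rows.append({
                        "path": f"{kind}{i+1}{j+1}",
                        "trait": labels[i],
                        "factor": f"{'A' if kind == 'a' else 'E'}{j+1}",
                        "estimate": est[i, j],
                        "se": se[i, j],
                        "wald_p": p[i, j],
                    })
        return pd.DataFrame(rows)


# -- observed-data layout -------------------------------------------------

def _obs_layout(phenotypes: PhenotypeTable, grm: GRM):
    vals = phenotypes.values
    if not np.array_equal(vals.index.to_numpy().astype(str),
                          grm.individual_ids.astype(str)):
        reindexed = vals.reindex(pd.Index(grm.individual_ids, name="iid"))
        if reindexed.notna().sum().sum() != vals.notna().sum().sum():
            raise ValueError("phenotype IDs do not match the GRM")
        vals = reindexed
    y = vals.to_numpy(dtype=float)
    masks = [~np.isnan(y[:, t]) for t in range(y.shape[1])]
    shared = all(np.array_equal(masks[0], mk) for mk in masks[1:])
    return y, masks, shared


def _loglik_fast(gamma, epsilon, d, yt) -> float:
    """Complete-data likelihood via batched per-eigenvalue m x m blocks."""
    g = gamma @ gamma.T
    e = epsilon @ epsilon.T
    s = d[:, None, None] * g + e  # (n, m, m)
    try:
        c = np.linalg.cholesky(s)
    except np.linalg.LinAlgError:
        return -np.inf
    logdet = 2.0 * np.sum(np.log(np.einsum("nii->ni", c)))
    z = np.linalg.solve(c, yt[:, :, None])[:, :, 0]  # c z = y per block
    quad = float(np.sum(z * z))
    n, m = yt.shape
    return -0.5 * (n * m * _LOG2PI + logdet + quad)


def _loglik_dense(gamma, epsilon, a, y, masks) -> float:
    g = gamma @ gamma.T
    e = epsilon @ epsilon.T
    idx = [np.flatnonzero(mk) for mk in masks]
    m = len(masks)
    blocks = []
    for ti in range(m):
        row = []
        for tj in range(m):
            blk = g[ti, tj] * a[np.ix_(idx[ti], idx[tj])]
            if e[ti, tj] != 0.0:
                blk = blk + e[ti, tj] * (
                    idx[ti][:, None] == idx[tj][None, :])
            row.append(blk)
        blocks.append(row)
    v = np.block(blocks)
    yo = np.concatenate([y[idx[t], t] for t in range(m)])
    try:
        c = np.linalg.cholesky(v)
    except np.linalg.LinAlgError:
        return -np.inf
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    z = np.linalg.solve(c, yo)
    return -0.5 * (len(yo) * _LOG2PI + logdet + float(z @ z))


def loglik(model: CholeskyModel, grm: GRM, phenotypes: PhenotypeTable) -> float:
    """Gaussian log-likelihood of the observed stacked phenotype vector."""
    if model.m != len(phenotypes.trait_labels):
        raise ValueError("model trait count does not match phenotype table")
    y, masks, shared = _obs_layout(phenotypes, grm)
    if shared:
        idx = np.flatnonzero(masks[0])
        if len(idx) == grm.n:
            d, u = grm.eigh()
        else:
            d, u = np.linalg.eigh(grm.values[np.ix_(idx, idx)])
        yt = u.T @ y[idx, :]
        return _loglik_fast(model.gamma, model.epsilon, d, yt)
    return _loglik_dense(model.gamma, model.epsilon, grm.values, y, masks)


# -- fitting ---------------------------------------------------------------

def _default_start(m: int, h2: np.ndarray | None, off: float = 0.05
                   ) -> np.ndarray:
    if h2 is None:
        h2 = np.full(m, 0.15)
    h2 = np.clip(np.asarray(h2, dtype=float), 0.01, 0.9)
    gamma = np.full((m, m), off)
    epsilon = np.full((m, m), off)
    np.fill_diagonal(gamma, np.sqrt(h2))
    np.fill_diagonal(epsilon, np.sqrt(1.0 - h2))
    i, j = np.tril_indices(m)
    return np.concatenate([np.tril(gamma)[i, j], np.tril(epsilon)[i, j]])


def _num_hessian(f, x0: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of scalar ``f`` at ``x0``."""
    p = len(x0)
    h = rel_step * np.maximum(1.0, np.abs(x0))
    hess = np.empty((p, p))
    for a in range(p):
        ea = np.zeros(p)
        ea[a] = h[a]
        for b in range(a, p):
            eb = np.zeros(p)
            eb[b] = h[b]
            if a == b:
                f0 = f(x0)
                val = (f(x0 + ea) - 2.0 * f0 + f(x0 - ea)) / h[a] ** 2
            else:
                val = (f(x0 + ea + eb) - f(x0 + ea - eb)
                       - f(x0 - ea + eb) + f(x0 - ea - eb)) / (4 * h[a] * h[b])
            hess[a, b] = hess[b, a] = val
    return hess


def fit(grm: GRM, phenotypes: PhenotypeTable,
        start: CholeskyModel | np.ndarray | None = None,
        compute_se: bool = True, h2_start: np.ndarray | None = None,
        maxiter: int = 2000) -> FitResult:
    """Fit the saturated Cholesky GSEM by quasi-Newton ML."""
    labels = phenotypes.trait_labels
    m = len(labels)
    if m < 1:
        raise ValueError("need at least one trait")
    y, masks, shared = _obs_layout(phenotypes, grm)
    n_obs = phenotypes.values.notna().sum()

    d_all, _ = grm.eigh()
    identifiable = bool(d_all.max() - d_all.min()
                        > 1e-8 * max(1.0, abs(d_all.max())))
    if not identifiable:
        warnings.warn(
            "GRM spectrum is flat: only the total trait covariance "
            "gamma gamma' + epsilon epsilon' is identified; the genetic/"
            "residual split is arbitrary", stacklevel=2)

    # cache the expensive pieces of the likelihood once
    if shared:
        idx = np.flatnonzero(masks[0])
        if len(idx) == grm.n:
            d, u = grm.eigh()
        else:
            d, u = np.linalg.eigh(grm.values[np.ix_(idx, idx)])
        yt = u.T @ y[idx, :]

        def negll(params: np.ndarray) -> float:
            mod_g = np.zeros((m, m))
            mod_e = np.zeros((m, m))
            i, j = np.tril_indices(m)
            k = len(i)
            mod_g[i, j] = params[:k]
            mod_e[i, j] = params[k:]
            ll = _loglik_fast(mod_g, mod_e, d, yt)
            return -ll if np.isfinite(ll) else 1e12
    else:
        def negll(params: np.ndarray) -> float:
            mod_g = np.zeros((m, m))
            mod_e = np.zeros((m, m))
            i, j = np.tril_indices(m)
            k = len(i)
            mod_g[i, j] = params[:k]
            mod_e[i, j] = params[k:]
            ll = _loglik_dense(mod_g, mod_e, grm.values, y, masks)
            return -ll if np.isfinite(ll) else 1e12

    if start is None:
        x0 = _default_start(m, h2_start)
    elif isinstance(start, CholeskyModel):
        x0 = start.pack()
    else:
        x0 = np.asarray(start, dtype=float)

    res = optimize.minimize(negll, x0, method="L-BFGS-B",
                            options={"maxiter": maxiter, "ftol": 1e-12,
                                     "gtol": 1e-8})
    if not res.success:
        logger.warning("GSEM optimizer did not report convergence: %s",
                       res.message)
    xhat = res.x
    model = CholeskyModel.unpack(xhat, m, labels)

    se_g = np.full((m, m), np.nan)
    se_e = np.full((m, m), np.nan)
    p_g = np.full((m, m), np.nan)
    p_e = np.full((m, m), np.nan)
    param_cov = None
    hess_cond = np.nan
    if compute_se:
        hess = _num_hessian(negll, xhat)
        try:
            hess_cond = float(np.linalg.cond(hess))
            # PD check via Cholesky; non-PD Hessian -> SEs suppressed
            np.linalg.cholesky(hess)
            param_cov = np.linalg.inv(hess)
            se = np.sqrt(np.diag(param_cov))
            i, j = np.tril_indices(m)
            k = len(i)
            se_g[i, j] = se[:k]
            se_e[i, j] = se[k:]
            with np.errstate(divide="ignore", invalid="ignore"):
                p_g = 2.0 * stats.norm.sf(np.abs(model.gamma) / se_g)
                p_e = 2.0 * stats.norm.sf(np.abs(model.epsilon) / se_e)
        except np.linalg.LinAlgError:
            warnings.warn("Hessian not positive definite at the optimum; "
                          "standard errors suppressed", stacklevel=2)
            param_cov = None

    # sign identification: report non-negative diagonals (likelihood and SEs
    # are invariant under whole-column sign flips)
    fixed = model.sign_fixed()
    flip_g = np.sign(np.diag(model.gamma)) < 0
    flip_e = np.sign(np.diag(model.epsilon)) < 0
    if param_cov is not None and (flip_g.any() or flip_e.any()):
        i, j = np.tril_indices(m)
        k = len(i)
        signs = np.ones(2 * k)
        signs[:k][flip_g[j]] = -1.0
        signs[k:][flip_e[j]] = -1.0
        param_cov = param_cov * np.outer(signs, signs)
    model = fixed

    return FitResult(
        model=model, se_gamma=se_g, se_epsilon=se_e,
        wald_p_gamma=p_g, wald_p_epsilon=p_e,
        loglik=float(-res.fun), n_obs=n_obs, converged=bool(res.success),
        n_iter=int(res.nit), param_cov=param_cov,
        hessian_condition=hess_cond, identifiable=identifiable,
    )


def stage2_extend(grm: GRM, base_phenotypes: PhenotypeTable, outcome: pd.Series,
                  outcome_label: str, **fit_kwargs) -> FitResult:
    """Append a later-life outcome as the last trait and refit from scratch.

    The outcome enters the Cholesky ordering last (chronological order), and
    the returned result is a full fresh (m+1)-variate fit, not a constrained
    update of the base model.
    """
    vals = base_phenotypes.values.copy()
    if outcome_label in vals.columns:
        raise ValueError(f"outcome label {outcome_label!r} already present")
    vals[outcome_label] = outcome.reindex(vals.index)
    extended = PhenotypeTable(values=vals)
    return fit(grm, extended, **fit_kwargs)
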