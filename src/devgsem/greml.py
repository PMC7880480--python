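"""GREML variance components on a genetic-relationship matrix.

Univariate fits use restricted maximum likelihood with average-information
(AI) updates and an EM first step.  The model is

    y = X b + g + e,   g ~ N(0, sigma2_g A),  e ~ N(0, sigma2_e I),

with X an intercept.  Rotating by the eigenvectors of A diagonalizes the
covariance, so every REML iteration is O(n) after one eigendecomposition.
Bivariate fits (two genetic variances, a genetic covariance and the residual
analogues) run AI-REML on the dense stacked covariance and allow each trait
its own set of observed individuals.

The null test for sigma2_g = 0 is a likelihood-ratio test against the
boundary of the parameter space; its p-value uses the standard 50:50 mixture
of a point mass at zero and chi-square(1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grm import GRM
from .phenotypes import PhenotypeTable

logger = logging.getLogger(__name__)

__all__ = ["VarianceComponents", "fit_univariate", "fit_bivariate",
           "screen_heritability"]

_REL_TOL = 1e-8
_MAX_ITER = 100


@dataclass
class VarianceComponents:
    """Estimates from a univariate or bivariate GREML fit."""

    sigma2_g: float
    sigma2_e: float
    se_sigma2_g: float
    se_sigma2_e: float
    h2: float
    se_h2: float
    loglik: float
    n: int
    converged: bool
    n_iter: int
    identifiable: bool = True
    trait: str | None = None
    score_norm: float = float("nan")  # analytic REML gradient at the optimum
    # univariate-only
    loglik_null: float | None = None
    lrt: float | None = None
    lrt_p: float | None = None
    # bivariate-only
    sigma_g12: float | None = None
    sigma_e12: float | None = None
    sigma2_g2: float | None = None
    sigma2_e2: float | None = None
    h2_2: float | None = None
    rg: float | None = None
    se_rg: float | None = None
    re: float | None = None

    def to_hsq_text(self) -> str:
        """GCTA hsq-style report (Source / Variance / SE rows)."""
        s = self.sigma2_g + self.sigma2_e
        rows = [
            ("V(G)", self.sigma2_g, self.se_sigma2_g),
            ("V(e)", self.sigma2_e, self.se_sigma2_e),
            ("Vp", s, float("nan")),
            ("V(G)/Vp", self.h2, self.se_h2),
        ]
        lines = ["Source\tVariance\tSE"]
        lines += [f"{k}\t{v:.6f}\t{se:.6f}" for k, v, se in rows]
        lines.append(f"logL\t{self.loglik:.4f}")
        if self.lrt_p is not None:
            lines.append(f"Pval\t{self.lrt_p:.4g}")
        lines.append(f"n\t{self.n}")
        return "\n".join(lines) + "\n"


# -- rotated-space univariate REML ----------------------------------------

def _reml_ll_rotated(theta: np.ndarray, d: np.ndarray, yt: np.ndarray,
                     xt: np.ndarray) -> float:
    v = theta[0] * d + theta[1]
    if np.any(v <= 0):
        return -np.inf
    vinv = 1.0 / v
    xtvx = xt.T @ (vinv[:, None] * xt)
    sign, logdet_x = np.linalg.slogdet(xtvx)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(xtvx, xt.T @ (vinv * yt))
    r = yt - xt @ beta
    ypy = float(r @ (vinv * r))
    n, p = len(yt), xt.shape[1]
    return -0.5 * (np.sum(np.log(v)) + logdet_x + ypy
                   + (n - p) * np.log(2 * np.pi))


def _reml_univariate(d: np.ndarray, yt: np.ndarray, xt: np.ndarray,
                     constrain: bool = True):
    """AI-REML on the rotated problem.  Returns (theta, ai_cov, ll, conv, it)."""
    n, p = len(yt), xt.shape[1]
    vary = float(np.var(yt))
    floor = 1e-6 * vary
    theta = np.array([0.5 * vary, 0.5 * vary])
    ll = _reml_ll_rotated(theta, d, yt, xt)
    ai = np.eye(2)
    converged = False
    struct = [d, np.ones_like(d)]
    score = np.zeros(2)
    score_norm = np.inf
    it = 0
    for it in range(1, _MAX_ITER + 1):
        v = theta[0] * d + theta[1]
        vinv = 1.0 / v
        xtvx_inv = np.linalg.inv(xt.T @ (vinv[:, None] * xt))
        vix = vinv[:, None] * xt

        def pdot(w):
            return vinv * w - vix @ (xtvx_inv @ (vix.T @ w))

        py = pdot(yt)
        score = np.empty(2)
        for k, dk in enumerate(struct):
            tr_pd = float(np.sum(vinv * dk)) - float(
                np.trace(xtvx_inv @ (vix.T @ (dk[:, None] * vix))))
            score[k] = -0.5 * (tr_pd - float((dk * py) @ py))
        q = [dk * py for dk in struct]
        pq = [pdot(w) for w in q]
        ai = 0.5 * np.array([[float(q[a] @ pq[b]) for b in range(2)]
                             for a in range(2)])
        # effective score: boundary components pushed outward don't count
        at_floor = constrain & (theta <= floor * (1 + 1e-9))
        eff = np.where(at_floor & (score < 0), 0.0, score)
        score_norm = float(np.max(np.abs(eff)))
        if score_norm < 1e-6:
            converged = True
            break
        if score_norm < 1e-2:
            # quadratic zone: take plain Newton(-AI) steps; the likelihood
            # change is below float resolution but the score is not
            try:
                cand = theta + np.linalg.solve(ai, score)
            except np.linalg.LinAlgError:
                break
            if constrain:
                cand = np.maximum(cand, floor)
            ll_new = _reml_ll_rotated(cand, d, yt, xt)
            if not np.isfinite(ll_new):
                converged = True
                break
            theta, ll = cand, ll_new
            continue
        try:
            delta = np.linalg.solve(ai, score)
        except np.linalg.LinAlgError:
            delta = score / max(np.abs(np.diag(ai)).max(), 1.0)
        if it == 1:
            # EM step for stability on the first iteration
            delta = theta ** 2 * np.array(
                [float((dk * py) @ py) - float(np.sum(vinv * dk))
                 + float(np.trace(xtvx_inv @ (vix.T @ (dk[:, None] * vix))))
                 for dk in struct]) / n
        step = 1.0
        for _ in range(30):
            cand = theta + step * delta
            if constrain:
                cand = np.maximum(cand, floor)
            ll_new = _reml_ll_rotated(cand, d, yt, xt)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-10:
                break
            step *= 0.5
        else:
            converged = True  # no improving step: at (or numerically at) optimum
            break
        theta, ll_prev, ll = cand, ll, ll_new
        if abs(ll - ll_prev) < 1e-12 * (abs(ll_prev) + 1.0):
            converged = True  # likelihood numerically flat before score tol
            break
    try:
        ai_cov = np.linalg.inv(ai)
    except np.linalg.LinAlgError:
        ai_cov = np.full((2, 2), np.nan)
    return theta, ai_cov, ll, converged, it, score_norm


def _align_trait(grm: GRM, y) -> tuple[np.ndarray, np.ndarray]:
    """Match a phenotype vector/Series to GRM order; returns (values, obs-idx)."""
    if isinstance(y, pd.Series):
        missing_ids = set(y.index) - set(grm.individual_ids)
        if missing_ids:
            raise ValueError(
                f"{len(missing_ids)} phenotype IDs absent from the GRM, e.g. "
                f"{sorted(missing_ids)[:3]}")
        yv = y.reindex(grm.individual_ids).to_numpy(dtype=float)
    else:
        yv = np.asarray(y, dtype=float)
        if len(yv) != grm.n:
            raise ValueError(
                f"phenotype length {len(yv)} does not match GRM size {grm.n}")
    idx = np.flatnonzero(~np.isnan(yv))
    return yv, idx


def fit_univariate(grm: GRM, y, trait: str | None = None,
                   constrain: bool = True) -> VarianceComponents:
    """Univariate GREML fit of one trait against the GRM."""
    yv, idx = _align_trait(grm, y)
    n = len(idx)
    if n < 50:
        raise ValueError(f"need at least 50 observed individuals, got {n}")
    if n == grm.n:
        d, u = grm.eigh()
    else:
        sub = grm.values[np.ix_(idx, idx)]
        d, u = np.linalg.eigh(sub)
    yobs = yv[idx]
    yt = u.T @ yobs
    xt = u.T @ np.ones((n, 1))

    identifiable = bool(d.max() - d.min() > 1e-8 * max(1.0, abs(d.max())))
    if not identifiable:
        warnings.warn(
            "GRM spectrum is flat (A ~ c*I): genetic and residual variance "
            "are separately unidentifiable; estimates reflect a flat "
            "likelihood ridge", stacklevel=2)

    theta, ai_cov, ll, converged, it, score_norm = _reml_univariate(
        d, yt, xt, constrain)
    s = theta.sum()
    h2 = float(theta[0] / s)
    grad = np.array([theta[1], -theta[0]]) / s ** 2
    se_h2 = float(np.sqrt(max(grad @ ai_cov @ grad, 0.0)))

    # boundary LRT: sigma2_g = 0 has closed-form REML sigma2_e
    xo = np.ones((n, 1))
    resid0 = yobs - yobs.mean()
    s2_null = float(resid0 @ resid0) / (n - 1)
    ll_null = _reml_ll_rotated(np.array([0.0, s2_null]), d, yt, xt)
    lrt = max(2.0 * (ll - ll_null), 0.0)
    lrt_p = float(0.5 * stats.chi2.sf(lrt, df=1))

    return VarianceComponents(
        sigma2_g=float(theta[0]), sigma2_e=float(theta[1]),
        se_sigma2_g=float(np.sqrt(max(ai_cov[0, 0], 0.0))),
        se_sigma2_e=float(np.sqrt(max(ai_cov[1, 1], 0.0))),
        h2=h2, se_h2=se_h2, loglik=float(ll), n=n, converged=converged,
        n_iter=it, identifiable=identifiable, trait=trait,
        score_norm=score_norm,
        loglik_null=float(ll_null), lrt=float(lrt), lrt_p=lrt_p,
    )


# -- dense bivariate AI-REML ----------------------------------------------

def _dense_reml(structs: list[np.ndarray], y: np.ndarray, x: np.ndarray,
                theta0: np.ndarray, floor_mask: np.ndarray,
                floor: float, project=None):
    """Generic AI-REML for V = sum_k theta_k * structs[k] (dense).

    ``project`` optionally maps a candidate parameter vector back into the
    feasible region (boundary projection) before evaluation.
    """
    n, p = len(y), x.shape[1]
    k = len(structs)

    def reml_ll(th):
        v = sum(t * s for t, s in zip(th, structs))
        try:
            c = np.linalg.cholesky(v)
        except np.linalg.LinAlgError:
            return -np.inf, None
        logdet_v = 2.0 * np.sum(np.log(np.diag(c)))
        vinv_y = np.linalg.solve(c.T, np.linalg.solve(c, y))
        vinv_x = np.linalg.solve(c.T, np.linalg.solve(c, x))
        xtvx = x.T @ vinv_x
        sign, logdet_x = np.linalg.slogdet(xtvx)
        if sign <= 0:
            return -np.inf, None
        beta = np.linalg.solve(xtvx, x.T @ vinv_y)
        py = vinv_y - vinv_x @ np.linalg.solve(xtvx, vinv_x.T @ y)
        ll = -0.5 * (logdet_v + logdet_x + float(y @ py)
                     + (n - p) * np.log(2 * np.pi))
        return ll, (c, vinv_x, xtvx, py)

    theta = theta0.copy()
    ll, aux = reml_ll(theta)
    if not np.isfinite(ll):
        raise RuntimeError("starting values give a non-PD covariance")
    ai = np.eye(k)
    converged = False
    scale = max(np.abs(theta0).max(), 1e-3)
    it = 0
    for it in range(1, _MAX_ITER + 1):
        c, vinv_x, xtvx, py = aux
        xtvx_inv = np.linalg.inv(xtvx)
        cinv = np.linalg.inv(c)
        vinv = cinv.T @ cinv

        def pdot(w):
            return vinv @ w - vinv_x @ (xtvx_inv @ (vinv_x.T @ w))

        score = np.empty(k)
        q = []
        for a, s_a in enumerate(structs):
            # tr(P S) = tr(V^-1 S) - tr((X'V^-1X)^-1 X'V^-1 S V^-1 X)
            tr_ps = float(np.sum(vinv * s_a)) - float(
                np.trace(xtvx_inv @ (vinv_x.T @ (s_a @ vinv_x))))
            qa = s_a @ py
            q.append(qa)
            score[a] = -0.5 * (tr_ps - float(qa @ py))
        pq = [pdot(w) for w in q]
        ai = 0.5 * np.array([[float(q[a] @ pq[b]) for b in range(k)]
                             for a in range(k)])

        def linesearch(direction):
            # trust-region cap keeps near-singular AI steps finite
            big = np.abs(direction).max()
            if big > 10.0 * scale:
                direction = direction * (10.0 * scale / big)
            step = 1.0
            for _ in range(40):
                cand = theta + step * direction
                cand[floor_mask] = np.maximum(cand[floor_mask], floor)
                if project is not None:
                    cand = project(cand)
                ll_new, aux_new = reml_ll(cand)
                if np.isfinite(ll_new) and ll_new >= ll - 1e-10:
                    return cand, ll_new, aux_new
                step *= 0.5
            return None

        try:
            delta = np.linalg.solve(ai + 1e-8 * np.eye(k), score)
        except np.linalg.LinAlgError:
            delta = score
        hit = linesearch(delta)
        if hit is None:
            hit = linesearch(score * scale)  # gradient fallback
        if hit is None:
            converged = True
            break
        cand, ll_new, aux_new = hit
        theta, ll_prev, ll, aux = cand, ll, ll_new, aux_new
        if abs(ll - ll_prev) < _REL_TOL * (abs(ll_prev) + 1.0):
            converged = True
            break
    try:
        ai_cov = np.linalg.inv(ai)
    except np.linalg.LinAlgError:
        ai_cov = np.full((k, k), np.nan)
    return theta, ai_cov, ll, converged, it


def fit_bivariate(grm: GRM, y1, y2, traits: tuple[str, str] | None = None
                  ) -> VarianceComponents:
    """Bivariate GREML: genetic/residual (co)variances of two traits.

    Each trait may be observed on a different subset of the GRM individuals;
    the residual covariance applies only to individuals observed for both.
    Parameter order: (sg1, sg12, sg2, se1, se12, se2).
    """
    y1v, i1 = _align_trait(grm, y1)
    y2v, i2 = _align_trait(grm, y2)
    if len(np.intersect1d(i1, i2)) == 0:
        raise ValueError("the two traits share no observed individuals")
    n1, n2 = len(i1), len(i2)

    # degenerate input: identical trait vectors make the stacked covariance
    # singular at the optimum (r_g = r_e = 1); delegate to the univariate fit
    if n1 == n2 and np.array_equal(i1, i2) and np.allclose(y1v[i1], y2v[i2]):
        warnings.warn("bivariate fit of a trait with itself: correlations "
                      "are 1 at the boundary; components taken from the "
                      "univariate fit", stacklevel=2)
        uni = fit_univariate(grm, y1, trait=traits[0] if traits else None)
        return VarianceComponents(
            sigma2_g=uni.sigma2_g, sigma2_e=uni.sigma2_e,
            se_sigma2_g=uni.se_sigma2_g, se_sigma2_e=uni.se_sigma2_e,
            h2=uni.h2, se_h2=uni.se_h2, loglik=np.inf, n=2 * n1,
            converged=True, n_iter=uni.n_iter, trait=uni.trait,
            sigma_g12=uni.sigma2_g, sigma_e12=uni.sigma2_e,
            sigma2_g2=uni.sigma2_g, sigma2_e2=uni.sigma2_e, h2_2=uni.h2,
            rg=1.0, se_rg=0.0, re=1.0,
        )

    a = grm.values
    z1 = np.zeros((n1, n1))
    y = np.concatenate([y1v[i1], y2v[i2]])
    x = np.zeros((n1 + n2, 2))
    x[:n1, 0] = 1.0
    x[n1:, 1] = 1.0

    def blocks(b11, b12, b22):
        out = np.zeros((n1 + n2, n1 + n2))
        out[:n1, :n1] = b11
        out[:n1, n1:] = b12
        out[n1:, :n1] = b12.T
        out[n1:, n1:] = b22
        return out

    a11 = a[np.ix_(i1, i1)]
    a12 = a[np.ix_(i1, i2)]
    a22 = a[np.ix_(i2, i2)]
    overlap = (i1[:, None] == i2[None, :]).astype(float)
    zero12 = np.zeros_like(a12)
    structs = [
        blocks(a11, zero12, np.zeros((n2, n2))),           # sg1
        blocks(z1, a12, np.zeros((n2, n2))),               # sg12
        blocks(z1, zero12, a22),                           # sg2
        blocks(np.eye(n1), zero12, np.zeros((n2, n2))),    # se1
        blocks(z1, overlap, np.zeros((n2, n2))),           # se12
        blocks(z1, zero12, np.eye(n2)),                    # se2
    ]
    v1, v2 = float(np.var(y1v[i1])), float(np.var(y2v[i2]))
    theta0 = np.array([0.4 * v1, 0.02 * np.sqrt(v1 * v2), 0.4 * v2,
                       0.6 * v1, 0.1 * np.sqrt(v1 * v2), 0.6 * v2])
    floor_mask = np.array([True, False, True, True, False, True])
    floor = 1e-6 * max(v1, v2)

    def project(th):
        # keep the 2x2 genetic and residual covariance matrices PSD
        out = th.copy()
        for a, b, c in ((0, 1, 2), (3, 4, 5)):
            bound = np.sqrt(out[a] * out[c]) * (1.0 - 1e-9)
            out[b] = np.clip(out[b], -bound, bound)
        return out

    theta, ai_cov, ll, converged, it = _dense_reml(
        structs, y, x, theta0, floor_mask, floor, project=project)

    sg1, sg12, sg2, se1, se12, se2 = theta
    h2_1 = float(sg1 / (sg1 + se1))
    h2_2 = float(sg2 / (sg2 + se2))
    rg = float(sg12 / np.sqrt(sg1 * sg2))
    re = float(se12 / np.sqrt(se1 * se2))
    # delta-method SE of rg over (sg1, sg12, sg2)
    grad = np.zeros(6)
    grad[0] = -0.5 * rg / sg1
    grad[1] = 1.0 / np.sqrt(sg1 * sg2)
    grad[2] = -0.5 * rg / sg2
    se_rg = float(np.sqrt(max(grad @ ai_cov @ grad, 0.0)))
    grad_h1 = np.zeros(6)
    grad_h1[0] = se1 / (sg1 + se1) ** 2
    grad_h1[3] = -sg1 / (sg1 + se1) ** 2
    se_h1 = float(np.sqrt(max(grad_h1 @ ai_cov @ grad_h1, 0.0)))
    t1, t2 = traits if traits else (None, None)
    return VarianceComponents(
        sigma2_g=float(sg1), sigma2_e=float(se1),
        se_sigma2_g=float(np.sqrt(max(ai_cov[0, 0], 0.0))),
        se_sigma2_e=float(np.sqrt(max(ai_cov[3, 3], 0.0))),
        h2=h2_1, se_h2=se_h1, loglik=float(ll), n=n1 + n2,
        converged=converged, n_iter=it, trait=t1,
        sigma_g12=float(sg12), sigma_e12=float(se12),
        sigma2_g2=float(sg2), sigma2_e2=float(se2), h2_2=h2_2,
        rg=rg, se_rg=se_rg, re=re,
    )


def screen_heritability(results: list[VarianceComponents],
                        alpha: float = 0.05) -> tuple[list[str], list[str]]:
    """Retain traits whose heritability LRT p-value is below ``alpha``.

    Returns (retained trait labels, excluded trait labels); exclusions are
    logged with their p-values.
    """
    retained, excluded = [], []
    for k, res in enumerate(results):
        label = res.trait if res.trait is not None else f"trait{k+1}"
        if res.lrt_p is None:
            raise ValueError(f"{label}: no LRT p-value (not a univariate fit?)")
        if res.lrt_p < alpha:
            retained.append(label)
        else:
            excluded.append(label)
            logger.info("screening excluded %s (h2 LRT p = %.3g >= %.3g)",
                        label, res.lrt_p, alpha)
    return retained, excluded
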