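"""Synthetic cohort generator with known Cholesky genetic/residual structure.

Genotypes are simulated as independent biallelic SNPs; multivariate
phenotypes are built from explicit per-SNP effects so that the same genotype
matrix feeds GRM construction and variance-component estimation downstream
(genotype -> GRM -> phenotype causal chain).  For each latent genetic factor
j the factor score is f_j = Z beta_j with Z the standardized dosages and
beta_j ~ N(0, 1/M); trait i receives sum_j gamma[i, j] * f_j.  Residual
factors are iid standard normal scaled by the lower-triangular epsilon.
With standardized rows (sum of squared gamma and epsilon loadings = 1) the
population trait covariance is gamma gamma' + epsilon epsilon'.

The default truth matrices emulate a longitudinal vocabulary design:
four early-life traits (expressive vocabulary at 15, 24, 38 months and
receptive vocabulary at 38 months, in chronological model order) with modest
SNP heritabilities (~0.11-0.16) and an optional fifth mid-childhood outcome
(reading, verbal IQ or performance IQ) appended last.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .phenotypes import CovariateTable, PhenotypeTable

__all__ = [
    "SimulationSpec", "Cohort", "simulate_genotypes", "simulate_covariates",
    "simulate_phenotypes", "apply_missingness", "simulate_cohort",
    "stage1_spec", "stage2_spec", "full_spec", "STAGE1_GAMMA", "STAGE1_TRAITS",
]

# -- study-like truth -----------------------------------------------------

STAGE1_TRAITS = ["exp15", "exp24", "exp38", "rec38"]

#: genetic loadings for the four early-life vocabulary traits; the non-zero
#: entries follow the magnitudes of the emulated study design
STAGE1_GAMMA = np.array([
    [0.33, 0.00, 0.00, 0.00],
    [0.21, 0.32, 0.00, 0.00],
    [0.00, 0.27, 0.29, 0.00],
    [0.00, 0.33, 0.00, 0.15],
])

#: phenotypic correlations the default cohort aims at (residual loadings are
#: solved from these minus the genetic covariance implied by STAGE1_GAMMA)
_STAGE1_RP = {
    (0, 1): 0.53, (0, 2): 0.33, (0, 3): 0.29,
    (1, 2): 0.50, (1, 3): 0.45, (2, 3): 0.63,
}

#: mid-childhood outcome rows (loadings on factors A1..A4 and the outcome's
#: own factor A5) and their residual covariance with the four early traits
_OUTCOMES = {
    "reading": (np.array([0.00, 0.25, 0.00, 0.57, 0.00]),
                np.array([0.05, 0.115, 0.10, 0.03])),
    "viq": (np.array([0.00, 0.42, 0.00, 0.60, 0.00]),
            np.array([0.05, 0.115, 0.10, 0.03])),
    "piq": (np.array([0.00, -0.03, 0.00, 0.50, 0.00]),
            np.array([0.05, 0.115, 0.10, 0.03])),
}

#: per-trait assessment age mean/SD in months
TRAIT_AGES = {
    "exp15": (15.41, 0.97), "exp24": (24.39, 1.03), "exp38": (38.48, 1.17),
    "rec15": (15.41, 0.97), "rec38": (38.48, 1.17),
    "reading": (84.0, 3.0), "viq": (96.0, 3.0), "piq": (96.0, 3.0),
}

#: wave-specific missingness matching the emulated Ns (6524/6014/6092 of 6524)
STAGE1_MISSING = {"exp15": 0.0, "exp24": 0.08, "exp38": 0.07, "rec38": 0.07}
_OUTCOME_MISSING = 0.19  # mid-childhood N <= 5296 of 6524

_DEFAULT_COVARIATE_EFFECTS = {
    "early_life": {"sex": 0.2, "age": 0.1, "age2": -0.02},
    "reading": {"sex": 0.15, "age": 0.05},
    "iq": {"sex": 0.1},
}


@dataclass
class SimulationSpec:
    """Everything needed to draw one synthetic cohort reproducibly."""

    n_individuals: int = 1000
    n_snps: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    truth_gamma: np.ndarray = field(default_factory=lambda: STAGE1_GAMMA.copy())
    truth_epsilon: np.ndarray | None = None
    trait_labels: list[str] = field(default_factory=lambda: list(STAGE1_TRAITS))
    trait_ages: dict[str, tuple[float, float]] | None = None
    missing_fraction: dict[str, float] | None = None
    covariate_effects: dict[str, dict[str, float]] | None = None
    standardized: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(
                f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        self.truth_gamma = np.asarray(self.truth_gamma, dtype=float)
        m = self.truth_gamma.shape[0]
        if self.truth_gamma.shape != (m, m):
            raise ValueError("truth_gamma must be square")
        if len(self.trait_labels) != m:
            raise ValueError("trait_labels length must equal trait count")
        if self.truth_epsilon is None:
            self.truth_epsilon = _default_epsilon(self.trait_labels,
                                                  self.truth_gamma)
        self.truth_epsilon = np.asarray(self.truth_epsilon, dtype=float)
        for name, mat in (("truth_gamma", self.truth_gamma),
                          ("truth_epsilon", self.truth_epsilon)):
            if not np.allclose(mat, np.tril(mat)):
                raise ValueError(f"{name} must be lower-triangular")
            if np.any(np.diag(mat) < 0):
                raise ValueError(f"{name} diagonal must be non-negative")
        if self.standardized:
            total = (self.truth_gamma ** 2).sum(axis=1) + \
                    (self.truth_epsilon ** 2).sum(axis=1)
            if not np.allclose(total, 1.0, atol=1e-9):
                raise ValueError(
                    "standardized spec requires per-trait squared loadings "
                    f"to sum to 1, got {total}")
        if self.missing_fraction is not None:
            for t, f in self.missing_fraction.items():
                if not (0.0 <= f < 1.0):
                    raise ValueError(
                        f"missing_fraction[{t!r}] must lie in [0, 1), got {f}")

    @property
    def n_traits(self) -> int:
        return self.truth_gamma.shape[0]


def _default_epsilon(labels: list[str], gamma: np.ndarray) -> np.ndarray:
    """Residual loadings from the target phenotypic correlations.

    Residual covariance = target r_p minus the genetic covariance implied by
    gamma; its Cholesky factor gives a lower-triangular epsilon that
    standardizes each trait.  Works for the built-in stage-1/stage-2 labels;
    custom specs should pass ``truth_epsilon`` explicitly.
    """
    m = gamma.shape[0]
    gcov = gamma @ gamma.T
    rcov = np.eye(m) - np.diag(np.diag(gcov))
    known = set(STAGE1_TRAITS)
    for i in range(m):
        for j in range(i):
            li, lj = labels[i], labels[j]
            if li in known and lj in known:
                a, b = sorted((STAGE1_TRAITS.index(lj), STAGE1_TRAITS.index(li)))
                rp = _STAGE1_RP[(a, b)]
            elif li in _OUTCOMES and lj in known:
                rcov_row = _OUTCOMES[li][1]
                rcov[i, j] = rcov[j, i] = rcov_row[STAGE1_TRAITS.index(lj)]
                continue
            elif li in _OUTCOMES and lj in _OUTCOMES:
                rcov[i, j] = rcov[j, i] = 0.15  # modest shared residual
                continue
            else:
                rp = 0.3  # generic modest phenotypic correlation
            rcov[i, j] = rcov[j, i] = rp - gcov[i, j]
    try:
        eps = np.linalg.cholesky(rcov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("implied residual covariance is not positive "
                         "definite; supply truth_epsilon explicitly") from exc
    return eps


def stage1_spec(n_individuals: int = 1000, n_snps: int = 2000,
                seed: int = 0, missingness: bool = False) -> SimulationSpec:
    """Four early-life vocabulary traits with the study-like truth paths."""
    return SimulationSpec(
        n_individuals=n_individuals, n_snps=n_snps, seed=seed,
        truth_gamma=STAGE1_GAMMA.copy(),
        trait_labels=list(STAGE1_TRAITS),
        trait_ages={t: TRAIT_AGES[t] for t in STAGE1_TRAITS},
        missing_fraction=dict(STAGE1_MISSING) if missingness else None,
        covariate_effects={t: dict(_DEFAULT_COVARIATE_EFFECTS["early_life"])
                           for t in STAGE1_TRAITS},
    )


def stage2_spec(outcome: str, n_individuals: int = 1000, n_snps: int = 2000,
                seed: int = 0, missingness: bool = False) -> SimulationSpec:
    """Stage-1 traits plus one mid-childhood outcome appended last."""
    if outcome not in _OUTCOMES:
        raise ValueError(f"outcome must be one of {sorted(_OUTCOMES)}")
    row, _ = _OUTCOMES[outcome]
    gamma = np.zeros((5, 5))
    gamma[:4, :4] = STAGE1_GAMMA
    gamma[4, :] = row
    labels = STAGE1_TRAITS + [outcome]
    miss = dict(STAGE1_MISSING, **{outcome: _OUTCOME_MISSING})
    cov_eff = {t: dict(_DEFAULT_COVARIATE_EFFECTS["early_life"])
               for t in STAGE1_TRAITS}
    cov_eff[outcome] = dict(_DEFAULT_COVARIATE_EFFECTS[
        "reading" if outcome == "reading" else "iq"])
    return SimulationSpec(
        n_individuals=n_individuals, n_snps=n_snps, seed=seed,
        truth_gamma=gamma, trait_labels=labels,
        trait_ages={t: TRAIT_AGES[t] for t in labels},
        missing_fraction=miss if missingness else None,
        covariate_effects=cov_eff,
    )


def full_spec(n_individuals: int = 1000, n_snps: int = 2000, seed: int = 0,
              missingness: bool = False) -> SimulationSpec:
    """All seven traits: four early-life plus reading, verbal IQ and
    performance IQ, in chronological order, for staged analyses over one
    cohort."""
    outcomes = ["reading", "viq", "piq"]
    labels = STAGE1_TRAITS + outcomes
    gamma = np.zeros((7, 7))
    gamma[:4, :4] = STAGE1_GAMMA
    for k, out in enumerate(outcomes):
        row = _OUTCOMES[out][0]
        gamma[4 + k, :4] = row[:4]
        gamma[4 + k, 4 + k] = row[4]  # the outcome's own factor
    miss = dict(STAGE1_MISSING, **{o: _OUTCOME_MISSING for o in outcomes})
    cov_eff = {t: dict(_DEFAULT_COVARIATE_EFFECTS["early_life"])
               for t in STAGE1_TRAITS}
    cov_eff["reading"] = dict(_DEFAULT_COVARIATE_EFFECTS["reading"])
    cov_eff["viq"] = dict(_DEFAULT_COVARIATE_EFFECTS["iq"])
    cov_eff["piq"] = dict(_DEFAULT_COVARIATE_EFFECTS["iq"])
    return SimulationSpec(
        n_individuals=n_individuals, n_snps=n_snps, seed=seed,
        truth_gamma=gamma, trait_labels=labels,
        trait_ages={t: TRAIT_AGES[t] for t in labels},
        missing_fraction=miss if missingness else None,
        covariate_effects=cov_eff,
    )


# -- generators -----------------------------------------------------------

def _streams(spec: SimulationSpec) -> dict[str, np.random.Generator]:
    names = ("genotypes", "covariates", "phenotypes", "missingness")
    children = np.random.SeedSequence(spec.seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def simulate_genotypes(spec: SimulationSpec) -> GenotypeMatrix:
    """Independent biallelic SNPs: dosage ~ Binomial(2, p), p ~ U(maf_range)."""
    if spec.n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    if spec.n_snps < 1:
        raise ValueError("need at least 1 SNP")
    rng = _streams(spec)["genotypes"]
    p = rng.uniform(spec.maf_range[0], spec.maf_range[1], size=spec.n_snps)
    dosages = rng.binomial(2, p, size=(spec.n_individuals, spec.n_snps)).astype(float)
    ids = np.array([f"id{i:06d}" for i in range(spec.n_individuals)])
    snps = np.array([f"snp{j:06d}" for j in range(spec.n_snps)])
    return GenotypeMatrix(dosages=dosages, snp_ids=snps, individual_ids=ids)


def simulate_covariates(spec: SimulationSpec) -> tuple[CovariateTable, pd.DataFrame]:
    """Sex (0/1, ~51% male) and per-trait assessment ages."""
    rng = _streams(spec)["covariates"]
    n = spec.n_individuals
    ids = pd.Index([f"id{i:06d}" for i in range(n)], name="iid")
    sex = rng.binomial(1, 0.511, size=n)
    ages = {}
    for t in spec.trait_labels:
        mu, sd = (spec.trait_ages or {}).get(t, TRAIT_AGES.get(t, (0.0, 0.0)))
        ages[t] = mu + sd * rng.standard_normal(n) if sd > 0 else np.full(n, mu)
    cov = CovariateTable(values=pd.DataFrame({"sex": sex}, index=ids))
    return cov, pd.DataFrame(ages, index=ids)


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    spec: SimulationSpec,
    covariates: CovariateTable | None = None,
    ages: pd.DataFrame | None = None,
    return_components: bool = False,
):
    """Multivariate phenotypes with the spec's Cholesky truth structure."""
    m = spec.n_traits
    if genotypes.n_individuals != spec.n_individuals:
        raise ValueError("genotype matrix does not match spec.n_individuals")
    rng = _streams(spec)["phenotypes"]
    x = genotypes.dosages
    p = np.nanmean(x, axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    z = np.zeros_like(x)
    z[:, poly] = (x[:, poly] - 2 * p[poly]) / np.sqrt(2 * p[poly] * (1 - p[poly]))
    m_eff = int(poly.sum())
    if m_eff == 0:
        raise ValueError("no polymorphic SNPs to carry genetic effects")

    beta = rng.normal(0.0, np.sqrt(1.0 / m_eff), size=(m_eff, m))
    f = z[:, poly] @ beta                     # n x m factor scores, var ~ 1
    genetic = f @ spec.truth_gamma.T
    u = rng.standard_normal(size=(spec.n_individuals, m))
    resid = u @ spec.truth_epsilon.T
    y = genetic + resid

    if covariates is None or ages is None:
        covariates, ages = simulate_covariates(spec)
    if spec.covariate_effects:
        for i, t in enumerate(spec.trait_labels):
            eff = spec.covariate_effects.get(t, {})
            if "sex" in eff:
                y[:, i] += eff["sex"] * covariates.values["sex"].to_numpy()
            agec = ages[t].to_numpy() - ages[t].mean()
            if "age" in eff:
                y[:, i] += eff["age"] * agec
            if "age2" in eff:
                y[:, i] += eff["age2"] * (agec ** 2 - np.mean(agec ** 2))

    ids = pd.Index(genotypes.individual_ids, name="iid")
    table = PhenotypeTable(
        values=pd.DataFrame(y, index=ids, columns=spec.trait_labels),
        ages=ages.set_axis(ids, axis=0))
    if return_components:
        comps = {
            "genetic": pd.DataFrame(genetic, index=ids, columns=spec.trait_labels),
            "factor_scores": pd.DataFrame(
                f, index=ids, columns=[f"A{j+1}" for j in range(m)]),
        }
        return table, comps
    return table


def apply_missingness(phenotypes: PhenotypeTable, spec: SimulationSpec,
                      monotone: bool = False) -> PhenotypeTable:
    """Mask phenotype entries completely at random at the per-trait rates.

    With ``monotone=True`` a single uniform draw per individual produces
    longitudinal dropout (missing from some wave onward); this requires
    non-decreasing per-trait fractions in column order.
    """
    if not spec.missing_fraction:
        return phenotypes
    rng = _streams(spec)["missingness"]
    vals = phenotypes.values.copy()
    n = len(vals)
    if monotone:
        fracs = [spec.missing_fraction.get(t, 0.0) for t in vals.columns]
        if any(b < a - 1e-12 for a, b in zip(fracs, fracs[1:])):
            raise ValueError("monotone dropout needs non-decreasing fractions")
        u = rng.uniform(size=n)
        for t, fr in zip(vals.columns, fracs):
            vals.loc[u < fr, t] = np.nan
    else:
        for t in vals.columns:
            fr = spec.missing_fraction.get(t, 0.0)
            if fr > 0:
                mask = rng.uniform(size=n) < fr
                vals.loc[mask, t] = np.nan
    return PhenotypeTable(values=vals, ages=phenotypes.ages)


@dataclass
class Cohort:
    """One simulated cohort with its ground truth components."""

    spec: SimulationSpec
    genotypes: GenotypeMatrix
    covariates: CovariateTable
    phenotypes: PhenotypeTable            # after missingness
    phenotypes_complete: PhenotypeTable
    genetic_values: pd.DataFrame
    factor_scores: pd.DataFrame


def simulate_cohort(spec: SimulationSpec) -> Cohort:
    genotypes = simulate_genotypes(spec)
    covariates, ages = simulate_covariates(spec)
    complete, comps = simulate_phenotypes(
        genotypes, spec, covariates=covariates, ages=ages,
        return_components=True)
    observed = apply_missingness(complete, spec)
    return Cohort(spec=spec, genotypes=genotypes, covariates=covariates,
                  phenotypes=observed, phenotypes_complete=complete,
                  genetic_values=comps["genetic"],
                  factor_scores=comps["factor_scores"])
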