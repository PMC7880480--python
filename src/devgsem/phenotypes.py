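"""Phenotype preparation: covariate adjustment, rank-based inverse normal
transformation, and phenotypic correlation matrices.

Trait columns are kept in model (chronological) order throughout; downstream
Cholesky models inherit that order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PhenotypeTable", "CovariateTable", "adjust_covariates",
    "rank_inverse_normal", "transform_table", "phenotypic_correlations",
    "read_phen", "write_phen",
]

#: per-trait covariate recipes used in the staged analysis; "age"/"age2" are
#: resolved from the table's per-trait assessment ages
DEFAULT_RECIPES = {
    "early_life": ["sex", "age", "age2", "PC1", "PC2"],
    "reading": ["sex", "age", "PC1", "PC2"],
    "iq": ["sex", "PC1", "PC2"],  # IQ scores come age-normed
}


@dataclass
class PhenotypeTable:
    """n x m trait values (rows = individuals, columns = traits, NaN = missing).

    ``ages`` optionally holds per-individual assessment ages aligned with
    ``values`` (same index/columns), used when a covariate recipe asks for
    "age" or "age2".
    """

    values: pd.DataFrame
    ages: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.ages is not None:
            if not self.ages.index.equals(self.values.index) or \
                    list(self.ages.columns) != list(self.values.columns):
                raise ValueError("ages must be aligned with values")

    @property
    def trait_labels(self) -> list[str]:
        return list(self.values.columns)

    @property
    def individual_ids(self) -> np.ndarray:
        return self.values.index.to_numpy()

    def observed_counts(self) -> pd.Series:
        return self.values.notna().sum()


@dataclass
class CovariateTable:
    """Individual-level covariates (sex, ancestry PCs, ...) row-aligned by ID."""

    values: pd.DataFrame

    @property
    def columns(self) -> list[str]:
        return list(self.values.columns)


def rank_inverse_normal(values: np.ndarray, offset: str = "vdw") -> np.ndarray:
    """Rank-based inverse normal transform of one trait vector.

    The van der Waerden convention scores observation with rank r (average
    ranks for ties) as Phi^-1(r / (n + 1)); ``offset="blom"`` uses
    Phi^-1((r - 3/8) / (n + 1/4)).  NaNs are preserved in place.
    """
    x = np.asarray(values, dtype=float)
    out = np.full_like(x, np.nan)
    obs = ~np.isnan(x)
    v = x[obs]
    n = len(v)
    if n < 2:
        raise ValueError("rank transform needs at least 2 observed values")
    if np.all(v == v[0]):
        raise ValueError("rank transform undefined for all-identical input")
    r = stats.rankdata(v, method="average")
    if offset == "vdw":
        u = r / (n + 1.0)
    elif offset == "blom":
        u = (r - 0.375) / (n + 0.25)
    else:
        raise ValueError(f"unknown offset convention {offset!r}")
    out[obs] = stats.norm.ppf(u)
    return out


def transform_table(phenotypes: PhenotypeTable, offset: str = "vdw") -> PhenotypeTable:
    """Apply the rank-based INT to every trait column."""
    vals = phenotypes.values.apply(
        lambda col: pd.Series(rank_inverse_normal(col.to_numpy(), offset=offset),
                              index=col.index))
    return PhenotypeTable(values=vals, ages=phenotypes.ages)


def _design_matrix(trait: str, recipe: list[str], phenotypes: PhenotypeTable,
                   covariates: CovariateTable) -> pd.DataFrame:
    cols = {}
    for name in recipe:
        if name in ("age", "age2"):
            if phenotypes.ages is None or trait not in phenotypes.ages:
                raise ValueError(
                    f"trait {trait!r}: recipe asks for {name!r} but no "
                    "assessment ages are available")
            age = phenotypes.ages[trait]
            cols[name] = age if name == "age" else age ** 2
        elif name in covariates.values.columns:
            cols[name] = covariates.values[name]
        else:
            raise ValueError(
                f"trait {trait!r}: covariate {name!r} not found in the "
                f"covariate table (available: {covariates.columns})")
    return pd.DataFrame(cols, index=phenotypes.values.index)


def adjust_covariates(
    phenotypes: PhenotypeTable,
    covariates: CovariateTable,
    recipes: dict[str, list[str]],
) -> PhenotypeTable:
    """Per-trait OLS residuals after regressing out the recipe covariates.

    Each trait is adjusted complete-case: rows with a missing phenotype or any
    missing covariate stay NaN.  Residuals are exactly orthogonal to the
    design columns used.
    """
    out = {}
    for trait in phenotypes.trait_labels:
        y = phenotypes.values[trait]
        recipe = recipes.get(trait, [])
        if not recipe:
            out[trait] = y - y.mean()
            continue
        design = _design_matrix(trait, recipe, phenotypes, covariates)
        x = np.column_stack([np.ones(len(design)), design.to_numpy()])
        yv = y.to_numpy(dtype=float)
        ok = ~np.isnan(yv) & ~np.isnan(x).any(axis=1)
        resid = np.full(len(yv), np.nan)
        beta, *_ = np.linalg.lstsq(x[ok], yv[ok], rcond=None)
        resid[ok] = yv[ok] - x[ok] @ beta
        out[trait] = pd.Series(resid, index=y.index)
    return PhenotypeTable(values=pd.DataFrame(out)[phenotypes.trait_labels],
                          ages=phenotypes.ages)


def phenotypic_correlations(
    phenotypes: PhenotypeTable, method: str = "pearson", min_periods: int = 3
) -> pd.DataFrame:
    """Pairwise-complete trait correlation matrix (Pearson or Spearman).

    Pairs with fewer than ``min_periods`` shared observations come back NaN
    rather than a fabricated value.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    corr = phenotypes.values.corr(method=method, min_periods=min_periods)
    return corr


# -- GCTA-style whitespace files ------------------------------------------

def write_phen(phenotypes: PhenotypeTable, path: str | Path) -> None:
    """Write FID IID value... whitespace table (NA for missing)."""
    df = phenotypes.values.copy()
    df.insert(0, "IID", df.index.to_numpy())
    df.insert(0, "FID", df.index.to_numpy())
    df.to_csv(path, sep=" ", index=False, header=False, na_rep="NA",
              float_format="%.6f")


def read_phen(path: str | Path, trait_labels: list[str] | None = None) -> PhenotypeTable:
    df = pd.read_csv(path, sep=r"\s+", header=None, na_values=["NA", "-9"])
    df = df.astype({0: str, 1: str})
    m = df.shape[1] - 2
    labels = trait_labels if trait_labels is not None else [f"trait{i+1}" for i in range(m)]
    values = df.iloc[:, 2:].set_axis(labels, axis=1)
    values.index = pd.Index(df[1], name="iid")
    return PhenotypeTable(values=values.astype(float))
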