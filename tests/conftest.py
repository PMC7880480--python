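"""Shared fixtures: one small simulated cohort reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from devgsem.grm import GRM, compute_grm
from devgsem.phenotypes import PhenotypeTable
from devgsem.simulate import simulate_cohort, stage1_spec


def standardize(df: pd.DataFrame) -> pd.DataFrame:
    return df.apply(lambda c: (c - c.mean()) / c.std())


@pytest.fixture(scope="session")
def cohort():
    """Stage-1 cohort, complete data, no covariate effects (raw structure)."""
    spec = stage1_spec(n_individuals=800, n_snps=1500, seed=42)
    spec.covariate_effects = None
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def grm(cohort):
    return compute_grm(cohort.genotypes)


@pytest.fixture(scope="session")
def std_phenotypes(cohort):
    """Standardized complete phenotypes for model fitting."""
    return PhenotypeTable(values=standardize(cohort.phenotypes_complete.values))


@pytest.fixture()
def toy_grm():
    """Hand-made 4-individual GRM for rule-level tests."""
    vals = np.eye(4)
    ids = np.array(["a", "b", "c", "d"])
    return GRM(values=vals, pair_marker_counts=np.full((4, 4), 100),
               individual_ids=ids)
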