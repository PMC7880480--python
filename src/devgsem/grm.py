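"""Genetic-relationship matrix construction, pruning, PCs and GCTA file I/O.

The GRM entry for individuals j, k is the average over SNPs of the product of
their standardized dosages,

    A_jk = (1/M_jk) * sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i)),

with missing dosages excluded pairwise: ``M_jk`` counts the SNPs non-missing
in both individuals (the .grm.N.bin convention).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GRM", "compute_grm", "prune_related", "grm_principal_components",
    "read_grm", "write_grm", "PCResult",
]


@dataclass
class GRM:
    """Symmetric realized-relationship matrix with per-pair marker counts."""

    values: np.ndarray
    pair_marker_counts: np.ndarray
    individual_ids: np.ndarray
    _eig: tuple[np.ndarray, np.ndarray] | None = field(
        default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.pair_marker_counts = np.asarray(self.pair_marker_counts)
        self.individual_ids = np.asarray(self.individual_ids)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("GRM values must be square")
        if self.pair_marker_counts.shape != (n, n):
            raise ValueError("pair_marker_counts shape does not match values")
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length does not match GRM size")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("GRM is not symmetric")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("GRM contains non-finite entries")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def eigh(self) -> tuple[np.ndarray, np.ndarray]:
        """Cached eigendecomposition (ascending eigenvalues d, vectors U)."""
        if self._eig is None:
            d, u = np.linalg.eigh(self.values)
            self._eig = (d, u)
        return self._eig

    def subset(self, idx: np.ndarray) -> "GRM":
        idx = np.asarray(idx)
        return GRM(
            values=self.values[np.ix_(idx, idx)],
            pair_marker_counts=self.pair_marker_counts[np.ix_(idx, idx)],
            individual_ids=self.individual_ids[idx],
        )


def compute_grm(genotypes: GenotypeMatrix) -> GRM:
    if genotypes.n_snps < 1:
        raise ValueError("need at least one SNP to build a GRM")
    p = np.asarray(genotypes.allele_freqs, dtype=float)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        bad = np.asarray(genotypes.snp_ids)[(p <= 0) | (p >= 1)]
        raise ValueError(
            f"monomorphic SNPs present (should have been QC-filtered): "
            f"{bad[:5].tolist()}{'...' if len(bad) > 5 else ''}"
        )
    x = genotypes.dosages
    obs = ~np.isnan(x)
    w = (x - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    w = np.where(obs, w, 0.0)
    counts = obs.astype(np.float64) @ obs.astype(np.float64).T
    if np.any(counts == 0):
        raise ValueError("some individual pairs share no non-missing SNPs")
    values = (w @ w.T) / counts
    values = (values + values.T) / 2.0  # enforce exact symmetry
    return GRM(values=values, pair_marker_counts=counts.astype(np.int64),
               individual_ids=genotypes.individual_ids)


def prune_related(grm: GRM, cutoff: float = 0.05) -> tuple[GRM, list]:
    """Drop individuals until all off-diagonal relatedness is below ``cutoff``.

    Greedy: repeatedly remove the individual involved in the most pairs at or
    above the cutoff, breaking ties by input order (earliest removed first).
    Returns the pruned GRM and the removed IDs in removal order.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = grm.n
    viol = (grm.values >= cutoff)
    np.fill_diagonal(viol, False)
    active = np.ones(n, dtype=bool)
    removed_idx: list[int] = []
    while True:
        deg = viol[np.ix_(active, active)].sum(axis=1)
        if deg.size == 0 or deg.max() == 0:
            break
        local = int(np.argmax(deg))  # argmax takes first max -> input order
        victim = np.flatnonzero(active)[local]
        active[victim] = False
        removed_idx.append(victim)
    removed_ids = [grm.individual_ids[i] for i in removed_idx]
    if removed_ids:
        logger.info("relatedness pruning removed %d of %d individuals",
                    len(removed_ids), n)
    keep = np.flatnonzero(active)
    return grm.subset(keep), removed_ids


@dataclass
class PCResult:
    """Top-k GRM eigenvectors as per-individual ancestry scores."""

    scores: np.ndarray          # n x k, unit-norm eigenvector columns
    eigenvalues: np.ndarray     # length k, descending
    individual_ids: np.ndarray
    informative: bool           # False when the spectrum is (near-)flat


def grm_principal_components(grm: GRM, k: int) -> PCResult:
    """Leading eigenvectors of the GRM, sign-fixed (largest loading positive)."""
    if k <= 0:
        raise ValueError("k must be a positive integer")
    if k > grm.n:
        raise ValueError(f"k={k} exceeds the number of individuals n={grm.n}")
    d, u = grm.eigh()
    order = np.argsort(d)[::-1][:k]
    vals = d[order]
    vecs = u[:, order]
    for j in range(vecs.shape[1]):
        i = np.argmax(np.abs(vecs[:, j]))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    spread = d.max() - d.min()
    informative = bool(spread > 1e-8 * max(1.0, abs(d.max())))
    if not informative:
        warnings.warn("GRM spectrum is flat; principal components are "
                      "uninformative", stacklevel=2)
    return PCResult(scores=vecs, eigenvalues=vals,
                    individual_ids=grm.individual_ids, informative=informative)


# -- GCTA binary triplet I/O ---------------------------------------------

def _tri_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    # row-major lower triangle including diagonal: pairs (i, j), j <= i
    return np.tril_indices(n)


def write_grm(grm: GRM, prefix: str | Path) -> None:
    """Write GCTA .grm.bin / .grm.N.bin / .grm.id triplet."""
    prefix = Path(prefix)
    i, j = _tri_indices(grm.n)
    grm.values[i, j].astype("<f4").tofile(f"{prefix}.grm.bin")
    grm.pair_marker_counts[i, j].astype("<f4").tofile(f"{prefix}.grm.N.bin")
    pd.DataFrame({"fid": grm.individual_ids, "iid": grm.individual_ids}).to_csv(
        f"{prefix}.grm.id", sep="\t", header=False, index=False)


def read_grm(prefix: str | Path) -> GRM:
    """Read a GCTA GRM triplet written by :func:`write_grm` (or GCTA)."""
    prefix = Path(prefix)
    ids = pd.read_csv(f"{prefix}.grm.id", sep=r"\s+", header=None,
                      names=["fid", "iid"], dtype=str)
    n = len(ids)
    n_tri = n * (n + 1) // 2
    tri = np.fromfile(f"{prefix}.grm.bin", dtype="<f4")
    if len(tri) != n_tri:
        raise ValueError(
            f"{prefix}.grm.bin holds {len(tri)} float32 records but "
            f"{prefix}.grm.id lists {n} individuals "
            f"(expected n(n+1)/2 = {n_tri})"
        )
    counts = np.fromfile(f"{prefix}.grm.N.bin", dtype="<f4")
    if len(counts) != n_tri:
        raise ValueError(
            f"{prefix}.grm.N.bin holds {len(counts)} records, expected {n_tri}"
        )
    i, j = _tri_indices(n)
    values = np.zeros((n, n))
    values[i, j] = tri
    values[j, i] = tri
    nmat = np.zeros((n, n))
    nmat[i, j] = counts
    nmat[j, i] = counts
    return GRM(values=values, pair_marker_counts=nmat,
               individual_ids=ids["iid"].to_numpy())
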