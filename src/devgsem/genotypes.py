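"""Genotype container and SNP-level quality control.

Dosages are stored as counts of the A1 (by convention minor) allele in
{0, 1, 2}, with ``numpy.nan`` marking missing calls.  Allele frequencies are
estimated from the non-missing calls of the sample itself unless supplied
explicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["GenotypeMatrix", "qc_filter", "hwe_chi2_p"]


@dataclass
class GenotypeMatrix:
    """An n x M dosage matrix with SNP and individual metadata."""

    dosages: np.ndarray
    snp_ids: np.ndarray
    individual_ids: np.ndarray
    allele_freqs: np.ndarray | None = None
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-d (individuals x SNPs) array")
        n, m = self.dosages.shape
        self.snp_ids = np.asarray(self.snp_ids)
        self.individual_ids = np.asarray(self.individual_ids)
        if len(self.snp_ids) != m:
            raise ValueError(
                f"snp_ids length {len(self.snp_ids)} != number of SNP columns {m}"
            )
        if len(self.individual_ids) != n:
            raise ValueError(
                f"individual_ids length {len(self.individual_ids)} != rows {n}"
            )
        if self.allele_freqs is None:
            self.allele_freqs = self.empirical_allele_freqs()
        else:
            self.allele_freqs = np.asarray(self.allele_freqs, dtype=float)
            if len(self.allele_freqs) != m:
                raise ValueError("allele_freqs length does not match SNP count")
        if self.positions is None:
            self.positions = np.arange(1, m + 1)

    # -- basic properties -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def empirical_allele_freqs(self) -> np.ndarray:
        """A1 allele frequency per SNP from non-missing dosages."""
        with np.errstate(invalid="ignore"):
            p = np.nanmean(self.dosages, axis=0) / 2.0
        return p

    def call_rates(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.dosages), axis=0)

    def subset_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            dosages=self.dosages[:, mask],
            snp_ids=self.snp_ids[mask],
            individual_ids=self.individual_ids,
            allele_freqs=np.asarray(self.allele_freqs)[mask],
            positions=np.asarray(self.positions)[mask],
        )

    def subset_individuals(self, mask_or_idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            dosages=self.dosages[mask_or_idx, :],
            snp_ids=self.snp_ids,
            individual_ids=self.individual_ids[mask_or_idx],
            allele_freqs=self.allele_freqs,
            positions=self.positions,
        )


def hwe_chi2_p(dosages_1snp: np.ndarray) -> float:
    """Hardy-Weinberg 1-df chi-square p-value for one SNP's dosage column.

    Observed genotype counts (0/1/2 copies of A1) are compared with the
    counts expected under HWE at the sample allele frequency.
    """
    x = dosages_1snp[~np.isnan(dosages_1snp)]
    n = len(x)
    if n == 0:
        return np.nan
    obs = np.array([np.sum(x == 0), np.sum(x == 1), np.sum(x == 2)], dtype=float)
    p = (obs[1] + 2 * obs[2]) / (2 * n)
    q = 1.0 - p
    if p <= 0 or q <= 0:
        return 1.0  # monomorphic: nothing to test; caught by the MAF filter
    exp = n * np.array([q * q, 2 * p * q, p * p])
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    return float(stats.chi2.sf(chi2, df=1))


def qc_filter(
    genotypes: GenotypeMatrix,
    maf_min: float = 0.01,
    call_rate_min: float = 0.99,
    hwe_p_min: float = 5e-7,
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Remove SNPs failing MAF, call-rate or Hardy-Weinberg thresholds.

    A SNP is kept when MAF >= ``maf_min``, call rate >= ``call_rate_min`` and
    the HWE test p-value >= ``hwe_p_min``.  Returns the filtered genotypes and
    per-criterion removal counts (a SNP may be counted under several criteria).
    """
    for name, v in (("maf_min", maf_min), ("call_rate_min", call_rate_min),
                    ("hwe_p_min", hwe_p_min)):
        if not (0.0 < v < 1.0):
            raise ValueError(f"{name} must lie in (0, 1), got {v}")

    p = genotypes.empirical_allele_freqs()
    maf = np.minimum(p, 1.0 - p)
    call = genotypes.call_rates()
    hwe_p = np.array([hwe_chi2_p(genotypes.dosages[:, j])
                      for j in range(genotypes.n_snps)])

    fail_maf = ~(maf >= maf_min)
    fail_call = ~(call >= call_rate_min)
    fail_hwe = ~(hwe_p >= hwe_p_min)
    keep = ~(fail_maf | fail_call | fail_hwe)

    counts = {
        "maf": int(fail_maf.sum()),
        "call_rate": int(fail_call.sum()),
        "hwe": int(fail_hwe.sum()),
        "removed": int((~keep).sum()),
        "kept": int(keep.sum()),
    }
    logger.info(
        "QC: removed %d/%d SNPs (MAF %d, call rate %d, HWE %d)",
        counts["removed"], genotypes.n_snps,
        counts["maf"], counts["call_rate"], counts["hwe"],
    )
    if counts["kept"] == 0:
        raise ValueError(
            "QC removed all SNPs "
            f"(MAF<{maf_min}: {counts['maf']}, call rate<{call_rate_min}: "
            f"{counts['call_rate']}, HWE p<{hwe_p_min}: {counts['hwe']})"
        )
    out = genotypes.subset_snps(keep)
    # frequencies are re-estimated on the post-QC data
    out.allele_freqs = out.empirical_allele_freqs()
    return out, counts
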