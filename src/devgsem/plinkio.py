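"""PLINK 1 bed/bim/fam reading and writing.

Implements the SNP-major bed v1.00 layout: magic bytes ``0x6c 0x1b`` then
``0x01``, followed by ceil(n/4) bytes per SNP.  Each byte packs four samples,
two bits each, least-significant pair first:

    00  homozygous A1      (dosage 2)
    01  missing            (dosage nan)
    10  heterozygous       (dosage 1)
    11  homozygous A2      (dosage 0)

Dosages count A1 alleles, matching :class:`devgsem.genotypes.GenotypeMatrix`.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit code -> dosage; index by code
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


def write_plink(genotypes: GenotypeMatrix, prefix: str | Path) -> None:
    """Write bed/bim/fam triplet for ``prefix``."""
    prefix = Path(prefix)
    n, m = genotypes.dosages.shape

    # fam: FID IID PID MID sex phenotype
    fam = pd.DataFrame({
        "fid": genotypes.individual_ids,
        "iid": genotypes.individual_ids,
        "pid": 0, "mid": 0, "sex": 0, "pheno": -9,
    })
    fam.to_csv(prefix.with_suffix(".fam"), sep=" ", header=False, index=False)

    bim = pd.DataFrame({
        "chrom": 1,
        "snp": genotypes.snp_ids,
        "cm": 0,
        "pos": np.asarray(genotypes.positions, dtype=int),
        "a1": "A", "a2": "G",
    })
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    d = genotypes.dosages
    codes = np.full((m, n), 1, dtype=np.uint8)  # default missing
    codes[(d == 2).T] = 0
    codes[(d == 1).T] = 2
    codes[(d == 0).T] = 3

    n_bytes = (n + 3) // 4
    padded = np.zeros((m, 4 * n_bytes), dtype=np.uint8)
    padded[:, :n] = codes
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = np.zeros((m, n_bytes), dtype=np.uint8)
    for k in range(4):
        packed |= padded[:, k::4] << shifts[k]

    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_MAGIC)
        packed.tofile(fh)


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a bed/bim/fam triplet into a :class:`GenotypeMatrix`."""
    prefix = Path(prefix)
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None,
                      names=["fid", "iid", "pid", "mid", "sex", "pheno"],
                      dtype={"fid": str, "iid": str})
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None,
                      names=["chrom", "snp", "cm", "pos", "a1", "a2"],
                      dtype={"snp": str})
    n, m = len(fam), len(bim)
    n_bytes = (n + 3) // 4

    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _MAGIC:
        raise ValueError(f"{prefix}.bed is not a SNP-major PLINK bed v1.00 file")
    body = raw[3:]
    if len(body) != m * n_bytes:
        raise ValueError(
            f"{prefix}.bed has {len(body)} data bytes but bim/fam imply "
            f"{m} SNPs x {n_bytes} bytes = {m * n_bytes}"
        )
    packed = body.reshape(m, n_bytes)
    codes = np.zeros((m, 4 * n_bytes), dtype=np.uint8)
    for k, shift in enumerate((0, 2, 4, 6)):
        codes[:, k::4] = (packed >> shift) & 0b11
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T  # n x m

    return GenotypeMatrix(
        dosages=dosages,
        snp_ids=bim["snp"].to_numpy(),
        individual_ids=fam["iid"].to_numpy(),
        positions=bim["pos"].to_numpy(),
    )
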