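"""Simulate the synthetic longitudinal cohort and write it to disk.

Seven traits in chronological order — expressive vocabulary at 15, 24 and 38
months, receptive vocabulary at 38 months, then mid-childhood reading,
verbal IQ and performance IQ — with a known lower-triangular genetic/residual
factor structure, sex/age covariate effects, and n = 2000 unrelated
individuals typed at 2000 independent SNPs.  Outputs PLINK bed/bim/fam plus
whitespace phenotype/covariate files under scratch/cohort_data/ (small derived tables go to results/).
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from devgsem import plinkio
from devgsem.phenotypes import write_phen
from devgsem.simulate import full_spec, simulate_cohort

OUT = Path(__file__).resolve().parents[1] / "scratch" / "cohort_data"
SEED = 7

def main() -> None:
    spec = full_spec(n_individuals=2000, n_snps=2000, seed=SEED)
    cohort = simulate_cohort(spec)
    OUT.mkdir(parents=True, exist_ok=True)
    plinkio.write_plink(cohort.genotypes, OUT / "cohort")
    write_phen(cohort.phenotypes, OUT / "cohort.phen")
    cov = cohort.covariates.values.copy()
    cov.insert(0, "IID", cov.index.to_numpy())
    cov.insert(0, "FID", cov.index.to_numpy())
    cov.to_csv(OUT / "cohort.covar", sep=" ", index=False, header=False)
    ages = cohort.phenotypes.ages.round(4)
    ages.to_csv(OUT / "cohort.ages.tsv", sep="\t")
    (OUT / "trait_order.txt").write_text("\n".join(spec.trait_labels) + "\n")

    h2 = (spec.truth_gamma ** 2).sum(axis=1)
    print(f"wrote cohort (n={spec.n_individuals}, M={spec.n_snps}) "
          f"to {OUT}")
    print("traits (chronological):", ", ".join(spec.trait_labels))
    print("truth SNP-h2 per trait:",
          ", ".join(f"{t}={v:.3f}" for t, v in zip(spec.trait_labels, h2)))


if __name__ == "__main__":
    main()
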