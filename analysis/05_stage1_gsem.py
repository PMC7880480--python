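"""Stage 1: saturated Cholesky model of the early-life vocabulary traits.

Fits as many genetic (GRM-identified) and residual (identity-identified)
lower-triangular factors as screened-in traits, by full maximum likelihood
on the standardized rank-transformed residuals, and derives SNP-h2,
genetic/residual correlations, per-factor variance shares, factorial
co-heritability and bivariate heritability.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from devgsem import derived, gsem
from devgsem.grm import read_grm
from devgsem.phenotypes import (PhenotypeTable, phenotypic_correlations,
                                read_phen)

ROOT = Path(__file__).resolve().parents[1] / "results"
DATA = Path(__file__).resolve().parents[1] / "scratch" / "cohort_data"


def main() -> None:
    data = DATA
    traits = (data / "trait_order.txt").read_text().split()
    grm = read_grm(data / "cohort")
    table = read_phen(data / "cohort.prepared.phen", trait_labels=traits)
    screen = pd.read_csv(ROOT / "greml_h2.tsv", sep="\t")
    retained = screen.loc[screen["retained_stage1"], "trait"].tolist()
    if len(retained) < 2:
        raise SystemExit("fewer than 2 traits passed screening; "
                         "rerun 01-04 at a larger sample size")
    print("stage-1 traits:", ", ".join(retained))

    ph = PhenotypeTable(values=table.values[retained])
    h2_start = screen.set_index("trait").loc[retained, "h2"].to_numpy()
    res = gsem.fit(grm, ph, h2_start=h2_start)
    print(f"fit: logL = {res.loglik:.2f}, converged = {res.converged}, "
          f"Hessian condition = {res.hessian_condition:.2e}")

    r_p = phenotypic_correlations(ph)
    summary = derived.summarize(res, r_p=r_p)

    out = ROOT / "stage1"
    out.mkdir(parents=True, exist_ok=True)
    res.paths_table().to_csv(out / "paths.tsv", sep="\t", index=False,
                             float_format="%.6g")
    for name, tab in summary.tables().items():
        tab.to_csv(out / f"{name}.tsv", sep="\t", float_format="%.6g")

    print("estimated genetic paths (rows = traits, cols = factors):")
    print(np.array_str(res.model.gamma, precision=3, suppress_small=True))
    print("SNP-h2 (GSEM):",
          ", ".join(f"{t}={h:.3f}" for t, h in summary.snp_h2.items()))
    print(f"reports under {out}")


if __name__ == "__main__":
    main()
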