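"""Stage 2: extend the early-life model with each mid-childhood outcome.

Each of reading, verbal IQ and performance IQ is appended (in turn) as the
last trait of a fresh 5-variate Cholesky fit, after passing the same
heritability screen.  The comparative table shows each outcome's loadings
on the early-life genetic factors A1..A4 and on its own factor A5 — the
developmental question is which early factors carry forward.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from devgsem import derived, gsem
from devgsem.greml import fit_univariate
from devgsem.grm import read_grm
from devgsem.phenotypes import (PhenotypeTable, phenotypic_correlations,
                                read_phen)

ROOT = Path(__file__).resolve().parents[1] / "results"
DATA = Path(__file__).resolve().parents[1] / "scratch" / "cohort_data"
OUTCOMES = ["reading", "viq", "piq"]


def main() -> None:
    data = DATA
    traits = (data / "trait_order.txt").read_text().split()
    grm = read_grm(data / "cohort")
    table = read_phen(data / "cohort.prepared.phen", trait_labels=traits)
    screen = pd.read_csv(ROOT / "greml_h2.tsv", sep="\t")
    retained = screen.loc[screen["retained_stage1"], "trait"].tolist()
    base = PhenotypeTable(values=table.values[retained])
    h2 = screen.set_index("trait")["h2"]

    comparison = []
    for outcome in OUTCOMES:
        uni = fit_univariate(grm, table.values[outcome], trait=outcome)
        if uni.lrt_p >= 0.05:
            print(f"{outcome}: failed heritability screen "
                  f"(p = {uni.lrt_p:.3f}); skipped")
            continue
        res = gsem.stage2_extend(
            grm, base, table.values[outcome], outcome,
            h2_start=list(h2.loc[retained]) + [uni.h2])
        labels = retained + [outcome]
        r_p = phenotypic_correlations(
            PhenotypeTable(values=table.values[labels]))
        summary = derived.summarize(res, r_p=r_p)
        out = ROOT / "stage2" / outcome
        out.mkdir(parents=True, exist_ok=True)
        res.paths_table().to_csv(out / "paths.tsv", sep="\t", index=False,
                                 float_format="%.6g")
        for name, tab in summary.tables().items():
            tab.to_csv(out / f"{name}.tsv", sep="\t", float_format="%.6g")
        m = res.model.m
        row = {"outcome": outcome, "h2_gsem": summary.snp_h2[outcome]}
        for j in range(m):
            row[f"A{j+1}"] = res.model.gamma[m - 1, j]
            row[f"A{j+1}_se"] = res.se_gamma[m - 1, j]
        comparison.append(row)
        loads = ", ".join(f"A{j+1}={res.model.gamma[m-1, j]:+.3f}"
                          for j in range(m))
        print(f"{outcome}: logL = {res.loglik:.2f}; loadings {loads}")

    if comparison:
        comp = pd.DataFrame(comparison)
        comp.to_csv(ROOT / "stage2" / "outcome_loadings.tsv", sep="\t",
                    index=False, float_format="%.6g")
        print(f"comparative loadings in {ROOT / 'stage2' / 'outcome_loadings.tsv'}")


if __name__ == "__main__":
    main()
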