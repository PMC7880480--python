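"""End-to-end two-stage analysis orchestration.

Stage 1: simulate (or load) a cohort, QC the genotypes, build and prune the
GRM, compute ancestry PCs, covariate-adjust and rank-transform phenotypes,
screen traits by univariate GREML heritability, and fit the saturated
Cholesky model to the retained early-life traits.  Stage 2: extend the
Stage-1 model with each mid-childhood outcome in turn (outcome last) as a
fresh 5-variate fit.

Every run writes machine-readable TSV reports, a JSON config snapshot and a
per-stage counts log; report tables are byte-identical under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import derived, greml, gsem
from .genotypes import qc_filter
from .grm import GRM, compute_grm, grm_principal_components, prune_related
from .phenotypes import (CovariateTable, PhenotypeTable, adjust_covariates,
                         phenotypic_correlations, transform_table)
from .simulate import STAGE1_TRAITS, full_spec, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineContext", "prepare", "run_stage1",
           "run_stage2"]

_FLOAT_FMT = "%.6g"


@dataclass
class PipelineConfig:
    """All knobs of the staged analysis, serialized with every run."""

    n_individuals: int = 1000
    n_snps: int = 2000
    seed: int = 0
    maf_min: float = 0.01
    call_rate_min: float = 0.99
    hwe_p_min: float = 5e-7
    relatedness_cutoff: float = 0.05
    #: with few iid simulated SNPs the null GRM off-diagonal SD (1/sqrt(M))
    #: can swallow the cutoff; the floor keeps pruning aimed at genuine
    #: relatedness (cutoff_eff = max(cutoff, 4.5/sqrt(M))), mirroring the
    #: ~10-SD margin the cutoff has at real marker densities
    auto_relatedness_floor: bool = True
    n_pcs: int = 2
    alpha: float = 0.05
    stage1_traits: list[str] = field(default_factory=lambda: list(STAGE1_TRAITS))
    outcomes: list[str] = field(default_factory=lambda: ["reading", "viq", "piq"])
    missingness: bool = False
    rg_comparison: bool = False
    maxiter: int = 2000
    out_dir: str = "results/pipeline"

    def __post_init__(self) -> None:
        for name, v in (("maf_min", self.maf_min),
                        ("call_rate_min", self.call_rate_min),
                        ("hwe_p_min", self.hwe_p_min),
                        ("alpha", self.alpha)):
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.relatedness_cutoff <= 0:
            raise ValueError("relatedness_cutoff must be positive")

    def snapshot(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                   sort_keys=True) + "\n")


@dataclass
class PipelineContext:
    """Prepared inputs shared between Stage 1 and Stage 2."""

    config: PipelineConfig
    grm: GRM
    phenotypes: PhenotypeTable        # adjusted + rank-transformed, all traits
    covariates: CovariateTable
    univariate: dict[str, greml.VarianceComponents]
    retained: list[str]
    excluded: list[str]
    counts: dict[str, int]
    r_p: pd.DataFrame


def _recipe_for(trait: str) -> list[str]:
    if trait in ("viq", "piq"):
        return ["sex", "PC1", "PC2"]
    if trait == "reading":
        return ["sex", "age", "PC1", "PC2"]
    return ["sex", "age", "age2", "PC1", "PC2"]


def prepare(config: PipelineConfig) -> PipelineContext:
    """Simulate the cohort and run QC / GRM / phenotype prep / screening."""
    spec = full_spec(n_individuals=config.n_individuals,
                     n_snps=config.n_snps, seed=config.seed,
                     missingness=config.missingness)
    cohort = simulate_cohort(spec)
    counts = {"individuals_in": spec.n_individuals, "snps_in": spec.n_snps}

    genotypes, qc_counts = qc_filter(cohort.genotypes, config.maf_min,
                                     config.call_rate_min, config.hwe_p_min)
    counts["snps_post_qc"] = qc_counts["kept"]

    grm_full = compute_grm(genotypes)
    cutoff = config.relatedness_cutoff
    if config.auto_relatedness_floor:
        cutoff = max(cutoff, 4.5 / np.sqrt(qc_counts["kept"]))
    counts["relatedness_cutoff_effective"] = cutoff
    grm, removed = prune_related(grm_full, cutoff)
    counts["individuals_pruned"] = len(removed)
    counts["individuals_post_prune"] = grm.n
    logger.info("pruning removed %d individuals; %d remain",
                len(removed), grm.n)

    pcs = grm_principal_components(grm, config.n_pcs)
    keep = pd.Index(grm.individual_ids, name="iid")
    cov_vals = cohort.covariates.values.loc[keep].copy()
    for k in range(config.n_pcs):
        cov_vals[f"PC{k+1}"] = pcs.scores[:, k]
    covariates = CovariateTable(values=cov_vals)

    pheno = PhenotypeTable(values=cohort.phenotypes.values.loc[keep],
                           ages=cohort.phenotypes.ages.loc[keep])
    recipes = {t: _recipe_for(t) for t in pheno.trait_labels}
    adjusted = adjust_covariates(pheno, covariates, recipes)
    transformed = transform_table(adjusted)
    r_p = phenotypic_correlations(transformed, method="pearson")

    univariate: dict[str, greml.VarianceComponents] = {}
    stage1 = [t for t in config.stage1_traits if t in transformed.trait_labels]
    for t in stage1:
        univariate[t] = greml.fit_univariate(grm, transformed.values[t], trait=t)
    retained, excluded = greml.screen_heritability(
        [univariate[t] for t in stage1], alpha=config.alpha)
    counts["traits_in"] = len(stage1)
    counts["traits_retained"] = len(retained)

    return PipelineContext(config=config, grm=grm, phenotypes=transformed,
                           covariates=covariates, univariate=univariate,
                           retained=retained, excluded=excluded,
                           counts=counts, r_p=r_p)


def _write_tables(out: Path, fitres: gsem.FitResult,
                  summary: derived.DerivedSummary) -> None:
    out.mkdir(parents=True, exist_ok=True)
    paths = fitres.paths_table()
    paths.to_csv(out / "paths.tsv", sep="\t", index=False,
                 float_format=_FLOAT_FMT)
    sig = paths[paths["wald_p"] < 0.05]
    sig.to_csv(out / "paths_significant.tsv", sep="\t", index=False,
               float_format=_FLOAT_FMT)
    for name, tab in summary.tables().items():
        tab.to_csv(out / f"{name}.tsv", sep="\t", float_format=_FLOAT_FMT)
    meta = {
        "loglik": fitres.loglik,
        "converged": bool(fitres.converged),
        "n_iter": fitres.n_iter,
        "n_obs": {k: int(v) for k, v in fitres.n_obs.items()},
        "hessian_condition": fitres.hessian_condition,
    }
    (out / "fit.json").write_text(json.dumps(meta, indent=2, sort_keys=True)
                                  + "\n")


def _path_diagram(fitres: gsem.FitResult) -> str:
    """Plain-text path diagram keyed A1..Am / E1..Em."""
    model = fitres.model
    lines = []
    for kind, mat in (("A", model.gamma), ("E", model.epsilon)):
        for j in range(model.m):
            loads = [f"{model.trait_labels[i]} ({mat[i, j]:+.3f})"
                     for i in range(j, model.m) if abs(mat[i, j]) > 1e-12]
            lines.append(f"{kind}{j+1} -> " + (", ".join(loads) or "(none)"))
    return "\n".join(lines) + "\n"


def run_stage1(config: PipelineConfig,
               context: PipelineContext | None = None
               ) -> tuple[gsem.FitResult, derived.DerivedSummary]:
    """Fit the m-variate Cholesky to the screened early-life traits."""
    ctx = context if context is not None else prepare(config)
    if len(ctx.retained) < 2:
        raise RuntimeError(
            f"only {len(ctx.retained)} trait(s) passed heritability "
            f"screening (need >= 2); excluded: {ctx.excluded}")
    sub = PhenotypeTable(values=ctx.phenotypes.values[ctx.retained])
    h2_start = np.array([ctx.univariate[t].h2 for t in ctx.retained])
    fitres = gsem.fit(ctx.grm, sub, h2_start=h2_start, maxiter=config.maxiter)
    summary = derived.summarize(fitres, r_p=ctx.r_p.loc[ctx.retained,
                                                        ctx.retained])
    out = Path(config.out_dir) / "stage1"
    _write_tables(out, fitres, summary)
    (out / "path_diagram.txt").write_text(_path_diagram(fitres))
    config.snapshot(out / "config.json")
    screening = pd.DataFrame(
        [{"trait": t, "h2": r.h2, "se": r.se_h2, "lrt_p": r.lrt_p,
          "retained": t in ctx.retained}
         for t, r in ctx.univariate.items()])
    screening.to_csv(out / "screening.tsv", sep="\t", index=False,
                     float_format=_FLOAT_FMT)
    (out / "counts.json").write_text(
        json.dumps(ctx.counts, indent=2, sort_keys=True) + "\n")
    if config.rg_comparison:
        _rg_comparison(ctx, fitres).to_csv(
            out / "rg_gsem_vs_greml.tsv", sep="\t", index=False,
            float_format=_FLOAT_FMT)
    return fitres, summary


def _rg_comparison(ctx: PipelineContext, fitres: gsem.FitResult) -> pd.DataFrame:
    """GSEM vs bivariate-GREML genetic correlations with CI-overlap flag."""
    summary = derived.summarize(fitres, with_se=True)
    rows = []
    labels = fitres.model.trait_labels
    for a in range(len(labels)):
        for b in range(a):
            t1, t2 = labels[b], labels[a]
            biv = greml.fit_bivariate(ctx.grm, ctx.phenotypes.values[t1],
                                      ctx.phenotypes.values[t2],
                                      traits=(t1, t2))
            g_rg = summary.r_g.loc[t1, t2]
            g_se = summary.r_g_se.loc[t1, t2]
            lo1, hi1 = g_rg - 1.96 * g_se, g_rg + 1.96 * g_se
            lo2, hi2 = biv.rg - 1.96 * biv.se_rg, biv.rg + 1.96 * biv.se_rg
            rows.append({"trait1": t1, "trait2": t2,
                         "rg_gsem": g_rg, "se_gsem": g_se,
                         "rg_greml": biv.rg, "se_greml": biv.se_rg,
                         "ci_overlap": bool(max(lo1, lo2) <= min(hi1, hi2))})
    return pd.DataFrame(rows)


def run_stage2(config: PipelineConfig, outcomes: list[str] | None = None,
               context: PipelineContext | None = None
               ) -> dict[str, tuple[gsem.FitResult, derived.DerivedSummary]]:
    """Extend the Stage-1 model with each mid-childhood outcome in turn."""
    ctx = context if context is not None else prepare(config)
    if len(ctx.retained) < 2:
        raise RuntimeError(
            f"only {len(ctx.retained)} trait(s) passed heritability "
            f"screening (need >= 2); excluded: {ctx.excluded}")
    outcomes = outcomes if outcomes is not None else config.outcomes
    base = PhenotypeTable(values=ctx.phenotypes.values[ctx.retained])
    results = {}
    comparison = []
    for out_trait in outcomes:
        uni = greml.fit_univariate(ctx.grm, ctx.phenotypes.values[out_trait],
                                   trait=out_trait)
        if uni.lrt_p >= config.alpha:
            logger.info("stage 2: outcome %s failed heritability screening "
                        "(p = %.3g); skipped", out_trait, uni.lrt_p)
            continue
        h2_start = np.array([ctx.univariate[t].h2 for t in ctx.retained]
                            + [uni.h2])
        fitres = gsem.stage2_extend(ctx.grm, base,
                                    ctx.phenotypes.values[out_trait],
                                    out_trait, h2_start=h2_start,
                                    maxiter=config.maxiter)
        labels = ctx.retained + [out_trait]
        summary = derived.summarize(fitres,
                                    r_p=ctx.r_p.loc[labels, labels])
        out = Path(config.out_dir) / "stage2" / out_trait
        _write_tables(out, fitres, summary)
        (out / "path_diagram.txt").write_text(_path_diagram(fitres))
        config.snapshot(out / "config.json")
        results[out_trait] = (fitres, summary)
        m = fitres.model.m
        row = {"outcome": out_trait}
        for j in range(m):
            row[f"A{j+1}"] = fitres.model.gamma[m - 1, j]
            row[f"A{j+1}_se"] = fitres.se_gamma[m - 1, j]
        comparison.append(row)
    if comparison:
        comp_dir = Path(config.out_dir) / "stage2"
        pd.DataFrame(comparison).to_csv(
            comp_dir / "outcome_loadings.tsv", sep="\t", index=False,
            float_format=_FLOAT_FMT)
    return results
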