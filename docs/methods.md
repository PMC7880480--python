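# Methods

`devgsem` estimates how much of the variation and covariation of a set of
developmental traits is tagged by common genotyped variants, in a sample of
nominally unrelated individuals, and how that genetic variance is organised
across developmental time.  This note documents the models, the numerical
choices, and what the synthetic cohort does and does not emulate.

## Models

### GREML variance components

For one standardized trait `y` on `n` individuals with genetic-relationship
matrix `A`,

    y = Xb + g + e,    g ~ N(0, σ²_g A),    e ~ N(0, σ²_e I),

with `X` an intercept.  `A` is the realized-relationship estimator on
standardized dosages,

    A_jk = (1/M_jk) Σ_i (x_ij − 2p_i)(x_ik − 2p_i) / (2 p_i (1 − p_i)),

with missing dosages removed pairwise (`M_jk` = SNPs observed in both
individuals, the `.grm.N.bin` convention).  The same cross-product form is
used on the diagonal.  Allele frequencies are estimated from the analysis
sample itself.

Estimation is restricted maximum likelihood with average-information (AI)
updates, an EM first step, and step-halving whenever a step fails to improve
the likelihood.  Because `A = U diag(d) U'` can be computed once, the whole
univariate iteration runs in the rotated basis where the covariance is
diagonal, making each iteration O(n); near the optimum, where likelihood
changes fall below float resolution, plain Newton–AI steps drive the
analytic score below 1e-6 (the convergence criterion, with a cap of 100
iterations).  Variance components are constrained non-negative by boundary
projection (floor 1e-6 × var(y)); an unconstrained option exists.  SNP
heritability is `h² = σ²_g/(σ²_g+σ²_e)` with a delta-method SE from the
inverse AI matrix.

The test of `h² = 0` is a likelihood-ratio test against a boundary null, so
the p-value uses the standard 50:50 mixture of a point mass at zero and
χ²(1).  The null REML fit has a closed form (`σ̂²_e` = residual mean square
about the intercept).

The bivariate model adds a genetic and a residual covariance (six
components); it runs the same AI-REML scheme on the dense stacked
covariance, allows each trait its own observed subset (the residual
covariance applies only to individuals observed for both), and keeps each
2×2 covariance block positive semi-definite by projecting line-search
candidates onto the cone (so `|r_g| ≤ 1`, matching constrained-GCTA-style
behaviour).  Two degenerate inputs are handled explicitly: a flat GRM
spectrum (`A ≈ cI`) flags the genetic/residual split as unidentifiable, and
a trait paired with itself — where the stacked covariance is exactly
singular at the optimum — is delegated to the univariate fit with
`r_g = r_e = 1`.

### Cholesky GSEM

For `m` traits in chronological order, the saturated model has as many
lower-triangular latent genetic factors (loadings Γ, identified through the
GRM) and residual factors (loadings Ε, identified through the identity):

    Cov(vec Y) = (ΓΓ') ⊗ A + (ΕΕ') ⊗ I.

The chronological ordering gives the factors their developmental reading:
factor `A_j` is the genetic variance newly appearing with trait `j` that was
not already captured by factors `1..j−1`.

Estimation is full maximum likelihood with mean zero on pre-standardized,
rank-transformed residuals (the `m(m+1)` free paths are the two lower
triangles), by L-BFGS-B with finite-difference gradients.  Missing trait
values select the observed rows/columns of the big covariance — every
available observation contributes, with no casewise deletion.  Two
evaluation routes:

* **fast path** (all traits share one missingness pattern): with
  `A = U diag(d) U'`, the rotated data decompose into `n` independent
  m-dimensional Gaussians with covariance `d_i ΓΓ' + ΕΕ'`; a batched
  Cholesky makes one likelihood evaluation O(n·m³);
* **dense path** (trait-specific missingness): the observed-block covariance
  is assembled and factorized directly.  This is exact but cubic in the
  total observation count, so it is intended for n·m up to ~10,000;
  the tests exercise it at n ≤ 200.

Starting values put `√h²` (from univariate GREML when available, 0.15
otherwise) on the genetic diagonal, `√(1−h²)` on the residual diagonal, and
0.05 on all off-diagonals (avoiding the saddle at exactly zero).  A
whole-column sign flip of either loading matrix leaves the likelihood
invariant; fitted models are reported with non-negative diagonals (the
parameter covariance is sign-adjusted consistently).  Non-positive-definite
evaluation points return −inf to the optimizer rather than raising.

Standard errors come from the inverse numerical Hessian of the negative
log-likelihood (central differences, relative step 1e-4); if the Hessian is
not positive definite the SEs are suppressed and the condition number
reported.  Wald p-values are two-sided normal.  Confidence intervals, where
reported, are Wald intervals assuming normality.

Stage-2 models append one later-life outcome as the last trait and refit the
full (m+1)-variate model from scratch — no stage-1 estimates are fixed.

### Derived statistics

All from the standardized path matrices:

* variance explained by factor `j` on trait `i`: `a_ij²` (as a fraction of
  the implied total variance; negative estimates square in unmodified);
* SNP-h² per trait: `Σ_j a_ij² / (Σ_j a_ij² + Σ_j e_ij²)`;
* genetic (residual) correlations: correlation matrix of ΓΓ' (ΕΕ');
  undefined entries (zero genetic variance) are NaN, never fabricated;
* factorial co-heritability: `a_ij² / Σ_j' a_ij'²` — the share of a trait's
  genetic variance owed to one factor; rows sum to 1;
* bivariate heritability: `(ΓΓ')_ik / r_p(i,k)` with the *observed*
  phenotypic correlation in the denominator (undefined at `r_p = 0`).

Internally everything is a proportion; report tables print percentages to
one decimal.  SEs propagate the path covariance by a first-order delta
method (numerical gradients); `draws_se` provides an independent Monte-Carlo
cross-check (sampling paths from their asymptotic normal and re-evaluating —
the Krinsky–Robb method).  Whether published SEs for such quantities come
from the delta method or resampling is generally unstated; the delta method
is the default here.

## Phenotype preparation

Per-trait covariate adjustment is ordinary least squares on complete cases
(rows missing the phenotype or any covariate stay missing): early-life
traits on sex + age + age² + PC1 + PC2, reading on sex + age + PC1 + PC2,
IQ scores (already age-normed) on sex + PC1 + PC2.  PCs are eigenvectors of
the pruned GRM (whether to take PCs from the GRM or raw genotypes is an
open choice; the GRM route is used, and for these data the two coincide up
to scaling).  Adjustment precedes transformation.  The rank-based inverse
normal transform scores rank `r` of `n` observed values as `Φ⁻¹(r/(n+1))`
(van der Waerden; average ranks for ties; a Blom offset is available).
All-constant input is rejected rather than transformed.

## Genotype QC and pruning

SNPs are dropped for MAF < 1%, call rate < 99%, or a 1-df chi-square HWE
test p < 5e-7 (a PLINK-like default; the chi-square is the test used at
these thresholds).  Individuals are greedily removed until no pair's
relatedness reaches the cutoff (0.05 by default): repeatedly drop the
individual in the most violating pairs, ties broken by input order.  The
selection heuristic is a documented choice; the contract is the
post-condition (no remaining pair at or above the cutoff).

A scale caveat: at real marker densities the 0.05 cutoff sits roughly 10
noise-SDs above the null GRM off-diagonal spread, so it removes genuine
relatives only.  With `M` iid simulated SNPs the null spread is `1/√M`
(≈ 0.022 at M = 2000), and a literal 0.05 cutoff would discard most of a
perfectly unrelated cohort.  The pipeline therefore floors its effective
cutoff at `4.5/√M` (on by default, logged); the pruning operation itself is
unchanged.

## The synthetic cohort

The generator emulates a longitudinal vocabulary design: four early-life
traits (expressive vocabulary at 15, 24, 38 months; receptive at 38 months)
with SNP-h² of 0.109–0.157 from a lower-triangular truth Γ whose non-zero
entries are `a11 = 0.33, a21 = 0.21, a22 = 0.32, a32 = 0.27, a33 = 0.29,
a42 = 0.33, a44 = 0.15`, and optionally mid-childhood outcomes (reading,
verbal IQ, performance IQ) loading mainly on factors A2 and A4 with no
unique genetic variance of their own.  Residual loadings are the Cholesky
factor of the residual covariance implied by target phenotypic correlations
(0.53 for the 15/24-month expressive pair, 0.63 for the 38-month
expressive/receptive pair, intermediate values elsewhere), standardizing
every trait to unit variance.

Genetic values are built from explicit per-SNP effects — `β_j ~ N(0, 1/M)`
on standardized dosages, factor score `f_j = Zβ_j`, trait genetic value
`Σ_j a_ij f_j` — so the *same* genotypes feed GRM construction and model
fitting; heritability is a property of the generated data, not an assumed
parameter.  Covariate effects (sex ≈ 0.2 SD, age 0.1/month, age² −0.02,
smaller for the outcomes), assessment-age distributions (e.g. 15.41 ± 0.97
months), and wave-specific completely-at-random missingness (0 / 8% / 7% /
7% across the early waves, 19% for outcomes) mirror the emulated design;
a monotone-dropout option exists but longitudinal attrition is otherwise
not modelled, and the missingness mechanism of any real cohort is an
assumption of this harness, not a claim about it.  Not emulated at all:
linkage disequilibrium, population structure, assortative mating, indirect
(parental) genetic effects, instrument ceiling effects.  Passing tests
therefore demonstrate correctness of the estimators under an idealized
architecture, not robustness to those features of real data.

Default problem sizes (n = 1000–2000 individuals, M = 2000 SNPs) were
chosen so that h² standard errors (~0.03–0.06) match the emulated study's,
giving recovery checks realistic power at desk scale.  Note that with iid
markers `SE(h²) ≈ √(2M)/n`, so marker count and sample size trade off
differently than in LD-structured real data.

## Validation studies

`scripts/acceptance.py --seed S --out results/acceptance.json` recomputes,
from scratch: the arithmetic identities among derived statistics evaluated
at published-scale path values (e.g. per-factor variance shares of 4.6% and
10.1% split into factorial co-heritabilities of ≈31.3%/68.7%); the
equivalence of the structured GSEM likelihood with a dense Gaussian oracle
and of the implied genetic correlations with brute-force covariance
correlations; the univariate GSEM-vs-GREML h² gap on one simulated cohort
(n = 1000); 2-SE coverage of each non-zero truth path and the Wald
rejection rate of the true-zero path a43 over 50 four-trait fits at
n = 2000; the type-I error of the boundary LRT over 500 null replicates at
n = 1000; and pipeline invariants (pruning post-condition, factorial
co-heritability row sums, byte-identical reports under a fixed seed).  The
same studies back `tests/test_acceptance.py`.

## Known limitations

* The dense missing-data likelihood is cubic in total observations; large
  cohorts with trait-specific missingness are out of desk-scale reach.
* GSEM uses ML (not REML); the univariate ML/REML gap is below 0.02 in h²
  at n = 1000 and shrinks with n, but is nonzero.
* Bivariate r_g estimates at small n and M are noisy and may sit at the
  |r_g| = 1 constraint; the covariance component is the stabler scale.
* No multi-GRM models, gene–environment interaction, dominance, or
  non-Cholesky (common/independent pathway) structures.
* Wald inference throughout; no profile-likelihood intervals.
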