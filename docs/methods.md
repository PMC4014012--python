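# Methods

## The problem

A combinatorial growth screen crosses single transgenic Arabidopsis
lines, each of which enlarges leaves on its own, and asks whether a
pairwise combination grows *more* (synergistic epistasis) or *less*
(negative epistasis) than the two single perturbations predict. The
unit of measurement is the area of each dissected leaf of a rosette at
21 days after stratification (DAS): cotyledons are trait L0, rosette
leaves L1..Ln, and the rosette area is the sum of all measured leaves
of one plant. Crosses are analyzed as heterozygous F1s, so the proper
single-perturbation baselines are the *heterozygous controls* — each
parental line crossed to wild type with the same maternal/paternal
direction as the combination cross, which cancels maternal effects by
construction.

## The null model and test

Gene effects on organ size are naturally multiplicative, so the
analysis works on log2-transformed areas, where "no interaction" is
additive. The expected-if-non-interacting value of a cross is

    log2(A_EXPni) = log2(A_c1) + log2(A_c2) - log2(A_wt)

equivalently `A_EXPni = (A_c1 * A_c2) / A_wt` on the natural scale.
The no-interaction null hypothesis is the LS-mean contrast

    log2(A_cross) - log2(A_c1) - log2(A_c2) + log2(A_wt) = 0

estimated from a linear mixed model and tested two-sided (Wald). The
same two-sided test yields both classes: a rejected null with a
positive estimate is *synergistic*, with a negative estimate
*negative*, otherwise *additive*. Across the screen's combinations the
rosette-level p-values are Benjamini–Hochberg corrected (FDR 0.05);
within each combination, a second BH family spans its traits (L0..L6
and the rosette) for the per-combination panels. Both families are
reported because the screen-wide claim and the per-combination panels
answer different questions; the rosette label is driven by the
screen-wide family.

Reported effect summaries are back-transformed percentages of
LS-means (geometric means): C/W, P1/W, P2/W (cross and controls vs
wild type) and C/E = 100·2^estimate (cross vs EXPni, an exact
identity). Two display flags follow the field's reporting
conventions: *bold* when the cross is at least 5% larger than each
heterozygous control, *strong* when C/E ≥ 120%.

## Mixed models

**Rosette level.** `log2(rosette area) ~ genotype` (fixed, cell-means
coding so coefficients are LS-means) with a random experiment
intercept; a genotype×experiment random intercept is added when a
likelihood-ratio test of that component is significant at p < 0.05
(ML fits, statistic clamped at zero, plain χ²₁ reference — the
boundary makes this conservative, which matches the decision rule's
intent). Final estimates are REML. With a single experiment the
random terms are dropped and the fit is ordinary least squares (the
fallback one combination in such a screen may need). This family is
fit with statsmodels `MixedLM`; when its gradient optimizer stalls or
diverges at a variance boundary the fit is retried with Powell, and
non-finite likelihoods are treated as failures.

**Leaf level (repeated measures).** `log2(leaf area) ~ genotype + leaf
+ genotype:leaf` for traits L0..L6, with a *structured residual
covariance* across the leaves of one plant: compound symmetry (CS),
AR(1), Toeplitz (TOEP) or unstructured (UN), plus the same random
experiment terms. No installed Python package fits mixed models with
structured within-subject residual covariance, so this fitter is
implemented here: the marginal covariance is assembled blockwise (per
plant when no random intercepts are present — grouping plants with
identical leaf-observation patterns to vectorize — or per experiment
when they are), fixed effects are profiled out by GLS, and the
covariance parameters are maximised numerically (L-BFGS-B with a
Nelder–Mead fallback). Parameterisations keep CS/AR1/UN inside the
positive-definite region by construction (expit/tanh bounds,
log-Cholesky); Toeplitz band correlations are tanh-mapped and a
non-PD proposal is treated as infeasible. Structures are compared by
AIC = −2·REML loglik + 2·(number of covariance parameters), valid
because all four candidates share one fixed-effects mean model; exact
ties break towards fewer parameters (CS < AR1 < TOEP < UN). Plants
with missing leaves contribute the leaves they have.

**Inference scale.** Contrast p-values use the normal approximation
(z) rather than a t with estimated degrees of freedom: at the screen's
scale (~48 plants per genotype, residual df ≈ 180 per fit) the
difference is below 2% relative. The LS-mean covariance is the
plug-in REML fixed-effects covariance.

**Repeatability.** Broad-sense heritability at the individual level
refits the rosette model with genotype, experiment and
genotype×experiment all random (crossed variance components, single
grouping) and reports h² = σ²_G / (σ²_G + σ²_GE + σ²_res). The pure
experiment (block) variance is excluded from the denominator:
experiment is a controlled block and individual-level repeatability
conventionally conditions on it. The component estimates are returned
so the alternative convention can be computed by the caller.

## Outlier rule

Germination failures produce severely undersized plants, so removal
is one-sided: within each genotype×experiment cell, a plant whose
log2 rosette area lies more than k = 3.5 robust scale units
(1.4826·MAD) below the cell median is removed. Cells with fewer than
3 plants or zero MAD are left untouched. The rule is a reproducible
stand-in for a manual "severe outlier" judgement; k is configurable.
With 16 plants per cell the MAD estimate is noisy, so the rule
occasionally trims a legitimate low plant (~1% of plants under a
clean null); the effect on inference is small and conservative
choices of k can eliminate it.

## Synthetic screens

The generator draws, for plant p of genotype g in experiment e, log2
leaf areas `mu + beta_g + gamma_g·[g is a cross] + b_e + c_ge + eps`
with `eps ~ MVN(0, Sigma)` across L0..L6 — the analysis model is
literally true under the null, so every stage has a recoverable
target. Defaults emulate the screen's design: 3 experiments × 16
plants per genotype; wild-type leaf means (28, 80, 95, 110, 95, 70,
45) mm² (a realistic 21-DAS Col-0 rosette of ≈ 520 mm²); single-line
effects drawn once per line, uniform in log2(1.05)–log2(1.25) (single
lines 5–25% above wild type); σ²_E = 0.01, σ²_GE = 0 and CS residual
covariance with variance 0.04 and correlation 0.6 on the log2 scale;
late leaves occasionally missing (emergence 0.97 for L5, 0.90 for
L6); 1% germination failures shrunk to 5% of their size. A cross's
mean effect is the sum of its two controls' effects plus its
interaction coefficient gamma (log2 scale, 0 = additive), so the
rosette-level contrast targets gamma exactly. An optional
maternal-line intercept exists solely to verify that the
matched-direction control design cancels it.

What the generator does **not** emulate: growth dynamics over time,
genotype-specific leaf-number differences, non-Gaussian residuals,
segregation within F1 families, or measurement error from image
processing. Passing tests therefore validate the statistical
machinery under its stated assumptions, not robustness to every
feature of real rosettes.

## Validation studies and problem sizes

The studies in `episcreen.studies` (run by `scripts/acceptance.py`
and the test suite) use these sizes, chosen to keep each study a few
minutes on one core while leaving Monte-Carlo error well below the
bands being checked: 50 balanced datasets for OLS-oracle equivalence
(agreement to 1e-6); 1,000 random inputs for the EXPni identities
(machine precision); 20 null screens of 60 combinations for type-I
error (pooled raw fraction, band [0.03, 0.07]); 50 screens with
gamma = log2(1.2) injected into 10 of 60 combinations (500 contrasts)
for recovery and 95%-interval coverage — contrasts within a screen
share control data, so the Monte-Carlo SE of the mean is computed
over independent screen means; 200 replicates per truth for
covariance-structure recovery (4 genotypes × 30 plants, single
experiment); 5 replicates of 100 genotypes × 3 experiments × 6 plants
for repeatability. The repeatability study simulates the rosette
table directly from the variance-components model (genotype effects
drawn from a population), because that is the exact generative model
of the estimand h².

## Known limitations

- The leaf fitter's Toeplitz parameterisation is not globally
  positive-definite; the optimizer treats non-PD proposals as
  infeasible, which can (rarely) stop at the boundary. The AIC table
  records any structure that fails to fit.
- Wald/z inference is mildly anticonservative at small per-genotype
  sample sizes; a Satterthwaite-style correction is a possible
  extension behind the same interface.
- The BH families assume the combinations' tests are positively
  dependent at worst (shared wild-type data induces positive
  correlation), which BH tolerates.
- LS-mean covariances condition on the estimated variance components
  (plug-in REML), as is standard.
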