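# Methods

This note documents the models behind `empoweranc`: what the synthetic
cohort generator assumes, how the indices and estimators are defined,
which defaults matter and why, and what the validation results do and do
not establish.

## Estimands

The exposure A is a three-level categorization (low / medium / high) of
a continuous empowerment score, cut at the sample 25th and 75th
percentiles (ties at a cutpoint go to the higher category; cutpoints are
linear-interpolation sample quantiles, computed once on the full
analysis sample and reused in all strata). The target parameters are the
three pairwise contrasts of counterfactual means E[Y(a₁) − Y(a₀)].

Four outcome specifications are analyzed. The three binary ones are
pairwise contrasts of the ANC category (none / 1–3 / ≥4 visits), each
run on the subsample its pair implies — e.g. "≥4 vs 1–3" is the
probability of attending ≥4 visits among women with at least one visit.
The fourth is the total visit count on the full sample. Identification
assumes no unmeasured confounding given the covariate set W,
positivity (protected by propensity truncation), and — for the
subsample outcomes — that subsample membership is not itself strongly
exposure-dependent (see Limitations).

## Synthetic cohort generator

`synthdata.generate_cohort` draws, in order:

1. **Covariates.** Independent draws matched to the field study's
   descriptive margins: age N(25.8, 5.5²) clipped to [15, 49]; CES-D
   depressive score N(13.8, 8.9²) clipped to [0, 60]; education years
   rounded N(6.6, 3.5²) in [0, 16]; spousal education differential
   rounded N(1.1, 3.8²); child age N(13.5, 5.3²) months in [6, 24];
   household size rounded N(5.2, 1.9²) ≥ 2; children under 15 rounded
   N(1.9, 0.8²) ≥ 1. Household wealth is a latent N(0, 1) that produces
   8 binary asset indicators via a logistic item model with spread
   difficulties; the **asset count** (analytic moments 4.0 / 1.95) is
   the wealth variable entering the structural equations, so that the
   analysis — which observes the assets and summarizes them by their
   first principal component — retains no unmeasured confounding.
2. **Villages.** Mothers are assigned uniformly to `n_villages`
   (default 109) villages; each village carries a shared random effect
   b_v ~ N(0, village_sd²), default village_sd = 0.15 on the log-mean
   scale, inducing positive within-village outcome correlation.
3. **Latent empowerment.** U = Σ_k γ_k z_k + ε, ε ~ N(0, 1), with z_k
   the standardized covariates and default weights γ: education 0.35,
   CES-D −0.30, asset count 0.30, age 0.25, household size −0.20,
   children −0.15, education differential 0.10. These make the exposure
   strongly confounded: the crude high-vs-low gap in P(≥4 | ≥1) is
   roughly double the causal contrast.
4. **Items.** Each of the 15 items is an ordinal cut of U plus item
   noise (SD 1.2) at equally spaced thresholds spanning ±1 SD of the
   item latent — the simplest model producing domain-correlated ordinal
   items. Default response scales: 3 levels for decision and asset
   items, 4 for movement items (the real instrument's per-item scales
   are not public, so the schema is configurable).
5. **Exposure.** The WEAI-style aggregate score of the generated items,
   categorized at the realized 25/75 quantiles — so the observational
   exposure is *derived*, while the structural outcome equation takes
   the category label directly, which keeps forced-assignment
   counterfactuals unambiguous.
6. **Outcome.** A zero-inflated Poisson count: with probability
   `zero_inflation` the visit count is a structural zero, otherwise
   Poisson with log-mean = intercept + Σ_k β_k z_k + effect(A) + b_v,
   capped at log 30. Default outcome weights β: education 0.10, asset
   count 0.10, CES-D −0.08, age 0.05, children −0.05, household size
   −0.03, education differential 0.03.

**Calibrated defaults.** Four parameters were fixed once by forward
simulation (bisection against large-sample cohorts and 10⁶-draw
counterfactual simulation) so the default generator reproduces the
study margins and a known effect size: intercept = 1.0965 and
zero_inflation = 0.0985 (observed mean 3.11 visits, 13.9% zeros, vs
targets 3.1 / 14%), effect_high = 0.2310 (true high-vs-low contrast on
P(≥4 | ≥1) of 0.1501) and effect_medium = 0.0956 (medium-vs-low
contrast 0.060). Effects are additive on the log-mean.

**Truth oracle.** `true_ate` forces the exposure level in the
structural equation for fresh Monte-Carlo draws and averages; for the
subsample outcomes it conditions each arm on the counterfactual
subsample event. Village effects are drawn i.i.d. per simulated mother
here, since the estimand marginalizes over their distribution; reusing
a finite set of village draws would leave cluster-level noise in the
reported truth. Truth for binary specs is validated to lie in (0, 1);
effect parameters violating this are rejected.

**Missingness** is injected MCAR at configurable per-covariate rates
(defaults mirror the study: 17/1609 on the education differential,
1/1609 on CES-D). Median imputation is only defensible near MCAR, and
the package tests the mechanics, not MNAR sensitivity.

What the generator does *not* emulate: multistage sampling weights (the
analysis uses none), item-level dependence beyond the single latent,
informative missingness, and any misreporting of visit counts. Passing
tests therefore demonstrate the estimation machinery is correct under
the stated model, not that the field study's substantive estimates are
right.

## Indices

- **Aggregate score:** domain score = (domain item sum − domain min) /
  (domain max − domain min); aggregate = 100 × mean of the three domain
  scores. Items are equally weighted *within* a domain (the construction
  fixes only equal domain weights; equal item weights is the simplest
  completion). Subscales are the raw per-domain sums.
- **PCA (SWPER-style) indices:** items standardized, correlation-matrix
  eigendecomposition, first three components retained, each matched to
  the subscale with which it correlates most strongly and sign-flipped
  to correlate positively (PCA is sign-ambiguous; the data decide the
  orientation). Zero-variance items are dropped with a warning.
  Correlation rather than covariance PCA because item scales differ.
- **WAMI:** four components, 8 points each on the published 0–32 scale:
  improved water (4) + sanitation (4); eight assets (1 each); education
  and monthly income banded by ordered cutpoints (defaults: education
  years at 1,3,…,15; income at 30–300 USD/month), all exposed as a
  configurable weight table since the exact allocation is not restated
  in the source material. Terciles use the published fixed cut-offs
  (≥21 / ≥17 / <17), not sample terciles.
- **Asset-wealth PC:** leading component of the standardized asset
  matrix, zero-centered, oriented so more assets ⇒ higher score.

## Nuisance estimation

The Super Learner is a V-fold cross-validated convex stack: out-of-fold
predictions per learner, meta-weights minimizing the cross-validated
loss (binary negative log-likelihood or squared error) over the
probability simplex via SLSQP, with an explicit vertex comparison so
the ensemble can never report a worse CV loss than its best member.
Base learners that fail on any fold are dropped with a warning. Defaults:
10 folds (stratified on binary targets), predictions bounded away from
{0, 1} by 10⁻⁶. The "spline-basis LASSO" learner is an L1-penalized
logistic/linear model on a zero-order indicator basis (quantile knots,
capped total basis size) — a deliberately small-scale stand-in for the
highly adaptive LASSO idea.

The three-level propensity is built from two nested binary stacks —
P(low | W), then P(high | W, not low) — which multiply into a row-
stochastic matrix and let every binary learner be reused unchanged.
Levels with fewer than 10 observations abort with advice to collapse.
Propensities are truncated to [0.025, 0.975] and renormalized; the
truncated-cell fraction is reported as a positivity diagnostic. No
outer cross-fitting is applied by default, matching common practice for
this design; the simulation harness shows the default behaves well at
the study's n.

## Targeting, variance, G-computation

One intercept-only logistic fluctuation per exposure level, with the
clever covariate used as a *weight* (better behaved near positivity
violations than the covariate-in-regression form). The fluctuation is
solved by Newton iteration to |step| < 10⁻¹³, which drives each level's
empirical mean EIC below 10⁻⁸; a residual score above 10⁻⁶ raises an
error. The three level means are targeted jointly from one nuisance
fit, so pairwise contrasts telescope exactly. Count outcomes are
min–max scaled to [0, 1] with the observed range, targeted with the
same machinery, and back-transformed. Constant outcomes short-circuit
to the constant with zero EIC (flagged degenerate).

Standard errors: se² = n⁻² Σ_c (Σ_{i∈c} EIC_i)² over villages; with
singleton clusters this is exactly the unclustered influence-curve SE.
A single cluster is an error.

Parametric G-computation fits one outcome GLM (main-terms logistic or
linear; optionally saturated in discrete covariates × exposure, in
which case the identity link is used because a saturated linear model
reproduces stratum means exactly without separation issues), predicts
under forced exposure, and differences the means. Its CI is a
percentile interval over resamples of whole villages with replacement
(default 1000).

## Pipeline conventions

Median imputation appends a 0/1 indicator column per listed covariate
(all-zero when nothing is missing); models include only indicators with
nonzero sum. Outcome and exposure items are never imputed. Subsample
analyses refit nuisances within the subsample; stratified analyses
refit within each stratum but reuse full-sample exposure cutpoints.
Strata smaller than 100 records are skipped with a logged reason.
Risk subgroups: age at birth (age − child age) < 20; more than one
child under 15; any adult beyond the woman and her husband; CES-D > 18
(a fixed default, with the option to recompute the quartile). A
biological-mother filter applies when a caregiver-type column exists.

## Simulation harness and problem sizes

Experiments derive per-replicate seeds from a master seed via seed-
sequence spawning, so results are reproducible and replicates
independent. The harness defaults to a plain-logistic learner library
with 2-fold cross-validation: at the generator's defaults both
nuisances are essentially correctly specified by main-terms logistic
models, richer libraries change the estimates negligibly, and the lean
library keeps 500-replicate experiments at desk scale. The full library
remains one flag away.

Headline validation numbers (computed by `tests/test_acceptance.py` at
n = 2000, 500 replicates, and n = 5000, 200 replicates): recovery bias
below 0.01 on the 0.15 contrast with 95% CI coverage inside
[0.92, 0.98]; with the strongest confounder (education) omitted from
the outcome regression, the naive plug-in is biased by more than 0.03
while TMLE stays below 0.01; TMLE, G-computation and direct
standardization agree to 10⁻⁶ on the discrete toy cohort.

## Numerical choices and edge cases

- Quantile categorization requires ≥4 distinct values; constant score
  vectors are an error, heavy ties legitimately distort the 25/50/25
  shares.
- Logit transforms clip at 10⁻¹² (tighter than the nuisance bound)
  only to guard exact 0/1 from saturated nuisances.
- The λ-weight simplex solution is polished against all vertices, so
  Super Learner dominance is an invariant, not a hope.
- G-computation returns a degenerate CI at 0 for an (a, a) comparison
  and short-circuits constant outcomes.
- The ANC category boundary is exactly 4 visits (0 / 1–3 / ≥4).

## Limitations

- The subsample estimands condition on factual subsample membership;
  the generator's truth conditions per arm on counterfactual
  membership. These coincide here because subsample selection for the
  primary contrast is dominated by the exposure-independent structural
  zero, but for DGPs where selection depends strongly on exposure the
  two readings diverge and neither is "the" causal effect among
  attenders.
- MCAR missingness and median imputation only; no MNAR sensitivity.
- The spline-basis LASSO is a small-basis surrogate, not full HAL.
- Village effects are additive on the log-mean; no cross-classified or
  spatial structure.
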