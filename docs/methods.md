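# Methods

## The problem and the bias rules

The estimand throughout is the exposure coefficient of a main analysis —
a linear or logistic regression of an outcome Y on an exposure X and
confounders C — fitted to data with missing values. Write S = 1 for a
complete case (all analysis variables observed). The engine encodes the
selection-model results for regression:

- If S ⟂ Y | (X, C) — completeness does not depend on the outcome once
  the covariates are conditioned on — then the complete cases have the
  correct outcome-conditional f(Y | X, C) and CCA is unbiased for *all*
  regression coefficients. This covers MCAR, covariate-driven MAR, and
  MNAR mechanisms confined to the exposure and confounders.
- If completeness depends on Y, linear-regression CCA is biased in
  general; the single exception is a truly zero exposure effect with
  dependence on Y only.
- Logistic regression adds three exemptions, all consequences of the
  disease odds ratio equalling the exposure odds ratio: completeness may
  depend on (i) Y only, (ii) Y and C, or (iii) Y and X *independently*
  (the completeness probability factorizes f(Y)·g(X), so the factor in X
  cancels from the conditional odds), and the exposure log-OR survives.
  None of the three hold when the binary outcome is a dichotomized
  continuous score Y\* and missingness tracks Y\* itself: selection then
  uses finer information than Y, and within each level of Y it still
  co-varies with X through the residual distribution of Y\*.

`decision.cca_bias_verdict` implements this as a pure function of the
dependence set {outcome, exposure, confounders, self} × model × flags; an
exhaustive golden table (256 rows) is committed with the tests.

## Synthetic cohorts

Two generators provide complete data with known truth; all coefficients
are dataclass fields and overridable.

**Adolescent cohort.** sex ~ Bernoulli(0.5); maternal substance use ~
Bernoulli(0.3); cannabis use (none / less-than-weekly / weekly) from a
proportional-odds model on sex and maternal substance use (baseline mix
≈ 0.60/0.25/0.15); depression score at 21 = 2.0 + 0.5·less + 1.0·weekly +
0.3·sex + 0.5·maternal + N(0, 1); self-harm = 1(Y\* > 0) where Y\* is a
latent score with standard-logistic noise around a linear predictor with
log-ORs (0.5, 1.0, 0.3, 0.7) — thresholding logistic noise at zero makes
the logistic analysis model for self-harm *exactly* correctly specified
with the same coefficients, and Y\* is retained as a hidden `latent`
column for score-driven missingness mechanisms. Auxiliaries: a childhood
depression score generated as a correlation-0.7 proxy of the outcome, and
conduct disorder as a logistic function of cannabis use.

The weekly-use effect of 1.0 outcome-SD is deliberately strong. The
reason is quantitative: the one genuinely weak signal in the study design
is the bias of MAR-based MI when the exposure's missingness depends on its
own value. With the outcome fully observed and a flexible (multinomial)
conditional model, the imputation distribution is the *selection-tilted*
observed conditional, and a tilt that does not involve Y distorts the
imputed-row joint only through the non-log-linearity ("curvature") of the
selection function — an effect that is exactly zero for exponential
tilting and grows with the sharpness of the selection and with the spread
of the outcome means across exposure levels. Asymptotic quadrature of the
MAR functional puts the weekly-coefficient bias at about +0.06 under the
default mechanism; a 0.5-SD effect would halve it below practical
detectability. This analysis was done, and the defaults frozen, before
the verification suite was written.

**Growth cohort.** Birth weight ~ N(3.4, 0.5) kg; maternal / paternal
weight ~ N(62, 10) / N(78, 11) kg; gestational age (<39 / 39–40 / >41
weeks) and parental social class (I/II / III / IV/V) from fixed
probabilities; weight at 5 structurally linear in birth weight, sex and
parental weights (SD 1.8 kg); adult BMI linear in all of them with the
multiply-imputed published estimates as generating coefficients
(weight-at-5 slope 0.458 kg/m² per kg, maternal weight 0.0835, birth
weight −0.788, class IV/V +1.20, …; residual SD 3 kg/m², mean ≈ 25).
Auxiliaries: childhood weight at 4.5 y (ρ = 0.7 to the exposure) and
height at 5 y (ρ = 0.5). The covariate marginals are realistic
anthropometry, not estimates of any real cohort.

## Missingness mechanisms

A `MechanismSpec` is a per-variable logistic model: parents (column
names, `SELF`, or a latent score), log-odds coefficients, and a target
marginal rate; the intercept is calibrated by bracketed root-finding on
the empirical mean probability (tolerance 1e-8). Classification is purely
structural: no parents → MCAR; SELF or a latent parent → MNAR; otherwise
MAR. Amputation draws independent Bernoulli cells against the
pre-missingness data, so multiple specs compose without order effects and
observed values are never altered.

Catalog defaults (cannabis example, rate 0.35 unless noted): b maternal
1.2; c maternal 1.0 + SELF 2.0 per use level at rate 0.40 (weekly users
mostly conceal — the sharp self-dependence is what makes the MNAR-MI bias
first-order, see above); d outcome 0.9 (1.4 on binary self-harm) +
maternal 1.2; e outcome + SELF; f outcome only; g two *separate*
mechanisms — outcome missing depending on its own value, exposure missing
depending on its own value — so completeness factorizes exactly as the
independence exemption requires; h latent-score dependence 2.0 at rate
0.30.

The growth mechanism is row-level: a logistic completeness model with the
published odds ratios (weight-at-5 0.913, birth weight 1.19, sex 0.721,
maternal weight 0.950, adult BMI 1.06) selects incomplete rows at the
published marginal rate (404/951), and each incomplete row loses a block
pattern drawn from the published pattern mix (210:125:61:7:1 across
outcome-only, confounders-only, outcome+confounders, exposure-only,
outcome+exposure). Within a multi-variable block each member is deleted
with probability 1/2, at least one. Because the pattern draw is
independent of the covariates, restricting the completeness regression to
rows with observed predictors shifts only its intercept — which is why
the diagnostic model recovers the generating odds ratios.

## Estimators

`fit_ols` solves weighted least squares by QR with an explicit rank check
(rank deficiency is an error, never silently dropped); classical variance
unweighted, HC0 sandwich when weighted. `fit_logistic` is IRLS with
convergence at max coefficient change < 1e-8 and explicit separation
detection (diverging coefficients raise, never return). Both are
cross-checked against statsmodels in the tests. Linear CIs use t
quantiles on residual df; logistic CIs are Wald. IPW fits the
completeness model on rows with observed weight predictors, weights
complete cases by 1/p̂ (floor 0.01 with trimming warning), and reports
sandwich SEs treating the weights as fixed — conservative, and stated in
the output.

## Multiple imputation

Chained equations in fixed left-to-right column order (reproducibility;
configurable), initialized from observed marginals, default 10 cycles.
Conditionals: Bayesian linear regression for continuous targets (σ² from
its scaled inverse-χ² posterior, β from the conditional normal);
logistic / multinomial fits with a multivariate-normal coefficient
perturbation (large-sample posterior draw) for binary / categorical
targets; type-1 predictive mean matching (donor pool 5, ties broken by
rng) as both an option and the automatic fallback when a conditional
model fails by separation or rank deficiency. Declared product terms can
be imputed passively. Every imputation model includes the analysis
outcome by default (predictor matrix = all other non-latent columns,
configurable per variable).

Pooling is exact Rubin: T = W + (1+1/m)B with the large-sample df; B = 0
yields infinite df and normal quantiles. The Barnard–Rubin small-sample
df adjustment and a bootstrap-then-fit alternative for the parameter draw
are not implemented — the package targets the simulation scales where the
large-sample formulas are adequate.

## The verification grid

Each cell runs generate → ampute → estimate for R replicates and compares
the mean bias of the weekly-use coefficient (log-OR for logistic cells)
with its rule-based verdict: "unbiased" requires |bias| ≤ max(3·MCSE,
2% of the true effect); "biased" requires the bias-test p < 0.001. The
default grid is n = 2000, R = 200 — 20 cells covering the five dependence
rows × both models for CCA, the three special cases, MI under mechanisms
a/b/d/f (valid) and c/e (invalid), and IPW with a correctly specified
weight model under d. Two cells run at n = 4000 (`n_scale = 2`): the
dichotomized-latent cell, whose bias (≈ −0.09) sits against an inflated
logistic SE, and that choice plus the mechanism strengths above came from
the pre-freeze power analysis targeting ≥ 90% power for every "biased"
cell. Grid MI cells use 2 FCS iterations: with a single incomplete
variable the first cycle already draws from the target conditional, so
further cycles only re-randomize.

Efficiency comparisons use the growth cohort at n = 500: "scattered"
missingness (outcome 15%, exposure 25%, parental weights 15%) with and
without the auxiliary proxies in the imputation model, versus CCA; and an
outcome-only scenario (40% missing, no auxiliaries, m = 3) where imputing
an uninformative outcome can only add Monte-Carlo noise — small m is the
regime where that inflation (measured ≈ 4–5%) is visible above the
ratio's sampling error.

## What the synthetic studies do and do not show

The generators match the *structure* the methods arguments need — correct
conditional models, known truth, mechanisms with exact parent sets — not
the joint distribution of any real cohort: covariate dependence beyond
the stated structural equations is absent, measurement error is not
modelled, and the auxiliary proxies are exactly linear. Passing the grid
therefore demonstrates that the estimators and decision rules behave as
the theory predicts *under their stated assumptions*; it does not certify
performance under model misspecification, clustering, or longitudinal
dropout. The MNAR-MI bias magnitude in particular is design-dependent:
gentler self-selection than the catalog default makes MAR-MI practically
unbiased for the exposure coefficient even though the mechanism is MNAR —
a point the curvature analysis above makes precise.

## Numerical choices and degenerate inputs

Intercept calibration: Brent root-finding on [−40, 40], |achieved −
target| ≤ 1e-8. IRLS: linear predictors clipped at ±30; coefficients
beyond 30 in absolute value raise separation. Multinomial Newton uses the
full block Hessian. Pattern tables order the complete pattern first, then
by descending count with a deterministic tie-break. Empty datasets
generate with full schema; zero residual SDs produce exact linear
predictors; n = 0 or one-class outcomes raise typed errors. All
randomness descends from a single seed through `numpy` `SeedSequence`
spawning: generation, amputation and imputation each get independent
streams, and identical configuration reproduces identical output bit for
bit.
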