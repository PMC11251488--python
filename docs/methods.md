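# Methods

`hdprog` re-implements, as a tested pipeline on synthetic data, an analysis of
modifiable factors in presymptomatic Huntington's disease (HD): composite
UHDRS (cUHDRS) scoring, control-calibrated staging, mixed-effects random
forest (MERF) trajectory modelling, and Shapley/partial-dependence
explanation. This note records the models, the generator, the numerical
choices, and the limitations — including two estimation phenomena that the
package deliberately documents rather than hides.

## The cUHDRS composite

Each annual visit contributes four domain scores: Total Functional Capacity
(TFC, 0–13), Total Motor Score (TMS, 0–124, higher = worse), Symbol Digit
Modalities Test (SDMT) and Stroop Word Reading (SWR). The composite is

    cUHDRS = (TFC − 10.4)/1.9 − (TMS − 29.7)/14.9
           + (SDMT − 28.4)/11.3 + (SWR − 66.1)/20.1 + 10,

lower = more advanced disease. Missing components yield a missing score
(never imputed). Progression per participant is summarised as
ΔcUHDRS/time = (last − first score)/(elapsed years); the slow/fast decliner
split uses the threshold T = |mean(ΔcUHDRS/time)| recomputed from the
analysed cohort. We use the *signed* convention (slow iff Δ/time ≥ −T), so
an improving participant is a slow decliner; the literal absolute-value
reading of the published rule is available via
`classify_decliners(..., convention="absolute")`. The boundary case
Δ/time = −T is slow (the published rule is `<=`).

## Synthetic cohort generator

The real cohort (an access-gated international observational study) cannot
ship with the package; every stage is exercised on cohorts from an explicit
generative model with known ground truth. Latent cUHDRS for subject *i* at
visit *j*:

    y_ij = mu(age_ij, CAG_i, x_i) + b0_i + b1_i (age_ij − 40) + eps_ij

* `mu` = baseline level 18.5, minus for carriers a logistic decline
  `6 / (1 + exp(−(age − m(CAG))/8))` with midpoint `m(CAG) = 110 − 1.5·CAG`
  (longer expansions → earlier decline; this builds a real age×CAG
  interaction), minus for controls a mild ageing slope (−0.02/yr past 40);
  plus additive covariate terms whose signs and magnitudes follow the
  per-factor effect sizes reported for this population (education
  +0.45/ISCED level, female +0.18, tobacco −0.30, antidepressant exposure
  −0.34, current coffee +0.06, alcohol protective to ~16 units/week with a
  +0.25 peak, BMI < 23 bonus +0.14, psychiatric history −0.20, smaller terms
  for the rest).
* Random effects: intercept SD 0.8, slope SD 0.05/yr, correlation −0.1;
  residual SD 0.5. These defaults reproduce the observed overall score SD
  (~1.4) and a ΔcUHDRS/time distribution with mean ≈ −0.15 and SD ≈ 0.7 on
  the staged cohort.
* Covariate marginals are calibrated to the published cohort description
  (57.5% female, age ~N(40.16, 12.6²) truncated to [18, 80], education
  ISCED ~N(3.92, 1.16) on 0–6, BMI ~N(26.01, 5.36²), carrier CAG a
  discretised normal around 42 on [36, 55], controls a normal-range allele,
  zero-inflated exponential alcohol, and the published binary frequencies).
  Truncation bounds are wide enough that realized means stay close to the
  targets (BMI within ~0.1; baseline age sits ~1 year above 40.16 because of
  the [18, 80] truncation).
* Components are generated by inverse construction: TFC/TMS/SDMT are drawn
  around their observed means, each carrying a share of the latent deviation,
  and SWR is solved from the composite identity (re-solving through SDMT and
  TMS when a clip is needed), so `compute_cuhdrs` recovers the latent score
  to < 1e−9 on every visit.

What the generator does **not** emulate: item-level UHDRS, informative
dropout, the real covariance structure among covariates, practice effects,
or any site/rater structure. Passing tests show the pipeline's estimators
recover *this* generative model; they are not evidence about effect sizes in
real data.

## Control-calibrated staging

A linear mixed model is fitted to family controls by REML
(statsmodels `MixedLM`): fixed effects {intercept, age, sex, education,
marital status, alcohol, tobacco, coffee, drugs, BMI, comorbidity count
(sum of 5 history flags)}, random intercept + age slope per control. The
random-effect timescale is age − 40 (reference near the cohort mean age):
with follow-ups of a few years at ages 18–80, a raw-age random intercept is
an extrapolation to age 0 and is numerically unidentifiable.

A carrier is presymptomatic when its baseline cUHDRS exceeds the lower bound
of the 95% *prediction* interval for a new individual:

    bound = x'beta − 1.959964 · sqrt(x' Cov(beta) x + z D_c z' + sigma²_c),

z = [1, age−40]. This includes random-effect and residual variance (the
interval for a new person, not the mean), uses the normal quantile (the
t correction is immaterial at control n in the thousands), and uses the
lower endpoint of the two-sided 95% interval. On held-out synthetic
controls ~2.5% of baseline scores fall below their own bound.

The selection flowchart excludes, in order: incomplete core data, baseline
score below the bound, incomplete health-behaviour data, off-norm
trajectories, and absence of follow-up (<2 visits). The verbal off-norm rule
is made explicit and configurable: CAG above 55 with a per-subject OLS slope
steeper than −2 cUHDRS/yr (very rapid early decline), or a positive slope
despite baseline age above 60 (no decline at advanced age).

## Mixed-effects random forest

The trajectory model is `y = f(x) + b0 + b1 (age−40) + eps` with a random
forest as `f` over 18 fixed-effect features (age, CAG, sociodemographics,
health behaviours, comorbidity and treatment history; ordinal features enter
as integers — tree splits handle ordinality). Fitting alternates:

1. refit the forest on the de-trended responses `y − Z b`;
2. BLUP update `b_i = D Z_i' V_i^{-1} (y_i − f(X_i))`,
   `V_i = Z_i D Z_i' + σ² I`;
3. `σ² ← N^{-1} Σ_i [e_i'e_i + σ² (n_i − σ² tr V_i^{-1})]`;
4. `D ← m^{-1} Σ_i [b_i b_i' + (D − D Z_i' V_i^{-1} Z_i D)]`,

monitoring `GLL = Σ_i [e_i'e_i/σ² + b_i'D^{-1}b_i + ln|D| + n_i ln σ²]`
until its relative change is < 1e−4 or 30 iterations. Initialisation
b = 0, D = 0.1·I, σ² = var(y)/2; D is floored to the PSD cone (eigenvalue
≥ 1e−8). Forest defaults: 300 trees, unlimited depth, ⌈p/3⌉ features per
split, min leaf 5, all seeded. The updates are implemented in per-subject
2×2 sufficient statistics (Woodbury form), so they are exact and cheap.
Train/validation splits are by subject, never by visit.

### Identifiability of subject effects vs. forest error (a documented limit)

In this design every covariate except age is constant within subject, so all
of a subject's visits sit at essentially one point of feature space. Two
consequences, measured extensively during development:

* **A subject's random intercept is confounded with the forest's pointwise
  error at that subject's covariate point.** Any honest (out-of-bag)
  residual attributes the forest's pointwise generalization error
  (~0.25 cUHDRS² at n≈1500, p=18) to `D̂`; any in-sample residual lets the
  forest partially memorise subject effects instead.
* **The plug-in GLL is not monotone.** The first forest (fit at b = 0)
  absorbs part of the subject effects; subsequent iterations slowly hand
  them back to the random effects. Because GLL rewards small |D|, the trace
  *rises* during this redistribution (typically from iteration ~3 onward) as
  the variance components converge. The trace is recorded and violations are
  logged; treat it as a diagnostic, not an objective with guaranteed
  descent. For the same reason, with truly zero random effects the
  alternation slowly moves fittable structure from `f` into `b` rather than
  pinning `b` at zero, so the MERF forest and a plain forest are *not*
  interchangeable after many iterations even when no random effects exist.

Under the recovery conditions used in the acceptance suite (300 subjects ×
5 visits, intercept SD 1.0, residual SD 0.5), the fitted values land at
D̂₀₀ ≈ 1.15–1.26 and σ̂² ≈ 0.23–0.25 for truth 1.0 / 0.25.

## Explanation

* **Shapley values** use the permutation estimator against a background
  sample: features of a background row are replaced by the explained row's
  values in permutation order; the contribution of a feature is the
  prediction change at its insertion. Contributions telescope to
  `f(x) − f(r)` for every (row, permutation), so
  `base_value + Σ φ = f(x)` holds *exactly* at any permutation count —
  sampling only redistributes credit among features. Permutations are drawn
  in antithetic pairs (a permutation and its reverse), which is exact for
  purely pairwise-interaction functions and halves variance generally.
  Defaults: 200-row background, 64 antithetic pairs; SHAP is computed on
  population predictions `f(X)` (random effects are subject identity, not
  explanatory factors). Importance = mean(|φ|) per feature, ties broken by
  column order.
* **Interaction values** are Monte-Carlo Shapley interaction indices: for a
  pair (j,k), random coalitions S of the remaining features (size uniform,
  members uniform) are completed from background rows and the second
  difference `f(S∪jk) − f(S∪j) − f(S∪k) + f(S)` is averaged. Symmetric by
  construction; deterministic given the seed.
* **Partial dependence** sweeps one feature over a 40-point quantile grid
  (all observed levels for ordinals/binaries), averaging predictions with
  other features at observed values; optional strata (CAG < 42 vs ≥ 42, BMI
  tertiles, education < 4 vs ≥ 4) yield one curve each.

## Problem sizes used by the shipped analyses and test suite

The `analysis/` drivers simulate 2,600 carriers + 2,300 controls with 1–8
annual visits; the staged cohort retains ~1,000 presymptomatic carriers.
Explanation uses 200 explained visits, a 150-row background, 12 antithetic
pairs and 48 interaction draws. The acceptance tests use the stated
recovery conditions (300 × 5 for MERF; 2,000 held-out controls for staging
coverage) and, for the explanation-recovery reruns, 20 seeded replicates of
a 200-carrier cohort with a widened CAG distribution (uniform 36–52) and a
steeper midpoint shift (2.0 yr/repeat) so that age and CAG are planted as
dominant — the staging filter is deliberately skipped there because it
truncates exactly the signal whose recovery is being tested. Monte-Carlo
budgets in tests (6 permutation pairs, 12 interaction draws) are sized for
stable rankings, not for publication-quality attribution values.

## Known limitations

* The decliner threshold, staging bound and all explanation outputs are
  conditional on the synthetic generative model; absolute numbers are not
  comparable to real-cohort publications beyond qualitative shape.
* Staging truncation attenuates the CAG effect in the retained cohort (by
  construction it removes carriers whose decline has begun), so CAG ranks
  lower in the shipped analysis' importance table than in the full-cohort
  recovery tests.
* The MERF variance decomposition inherits the identifiability limit above;
  D̂ carries a positive bias of roughly the forest's pointwise error
  variance.
* The propensity-score sensitivity analysis and per-component composite
  sensitivity analyses of the original study are out of scope.
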