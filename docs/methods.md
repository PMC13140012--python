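# Methods

This note records the statistical model, the estimators, the synthetic
data-generating process and the numerical choices behind `kpmediation`,
at the level of detail a maintainer or reviewer needs to judge what the
package's tests do and do not demonstrate.

## Data model

A cohort is a long-format table, one record per participant-visit, with
three visit rounds (T1/T2/T3 at nominally 6, 26 and 52 weeks after the
end of treatment). Columns carry roles (exposure, mediator, outcome,
covariate, id, time) declared in a schema file; validation enforces the
uniqueness of (subject, visit), the fixed visit label set, categorical
level sets, and any declared value bounds (0–100 for HRQoL scales,
non-negativity for metabolite concentrations, when the schema declares
them). Missing values are empty CSV fields; each model deletes its own
incomplete rows listwise and reports the count — no imputation is
performed anywhere.

The analysis-set rule keeps every subject with at least one visit on
which all required variables (exposure, mediators, outcome, covariates)
are observed, and keeps *all* records of retained subjects.

## Derived variables

* **Energy conversion.** Nutrient grams/day × fixed factors
  (protein 4, carbohydrate 4, fat 9, alcohol 7, fiber 2 kcal/g).
* **KP ratios.** KTR = 1000·Kyn/Trp (the factor bridges Kyn in µmol/L
  to the nmol/L numerator convention), HKr = HK/(KA+XA+AA+HAA),
  KA/QA = KA/QA. Ratios require strictly positive denominators; HKr and
  KA/QA are invariant to common rescaling of all concentrations.
* **Per-SD standardization.** For an exposure, compute the sample SD
  (n−1 denominator) at each visit with ≥ 2 non-missing values, then
  average those SDs with equal weight; divide the exposure by this
  pooled scale. No centering — location is absorbed by the model
  intercept and slopes are what matter. On the published summary
  statistics this reproduces the familiar per-SD labels (alcohol
  131 kcal/day, total protein 69, mono-/disaccharides 137).
* **Energy-adjustment schemes.** All models share a base covariate set
  (age, sex, chemotherapy, creatinine, comorbidities, stoma, weeks
  since end of treatment, BMI, MVPA, smoking, education, prolonged
  sedentary time). Macronutrient exposures add the kcal of all energy
  components *except their own*: a subtype exposure (e.g. saturated
  fat) drops its parent component's kcal total, because entering both
  the subtype and its parent total would be collinear by construction.
  Plant protein adds animal-protein kcal plus the four non-protein
  components. Micronutrients add alcohol kcal and total energy kcal;
  pattern scores add total energy kcal.
* **EORTC scoring.** Functioning scales: (1 − (m−1)/r)·100; symptom
  scales: ((m−1)/r)·100, with m the raw item mean and r the item range.
  The summary score is the unweighted mean of 13 subscales (five
  functioning, eight symptom scales reversed as 100 − s); global QoL
  and financial difficulties are excluded, and a missing constituent is
  an error rather than being prorated.

## Path models: random-intercept REML

Every path is a linear mixed model with a single per-subject random
intercept and no random slopes:

    y_ij = x_ij' β + u_i + e_ij,  u_i ~ N(0, τ²),  e_ij ~ N(0, σ²).

Repeated measurements enter cross-sectionally; time since treatment end
is a fixed covariate. Categorical covariates are reference-coded
(references: male, no chemotherapy, no stoma, 0 comorbidities, never
smoked, low education).

Estimation is restricted maximum likelihood, computed by profiling:
for fixed variance ratio λ = τ²/σ² the cluster precision is the
rank-one update W_i = I − λ/(1+λn_i)·J, so the GLS coefficients, σ̂²(λ)
and the restricted likelihood are closed-form in the sufficient
statistics (XᵀX, Xᵀy, per-cluster column sums). The scalar criterion is
minimized by bounded search over log λ ∈ [−25, 25] (tolerance 1e-8,
max 200 iterations); the boundary λ = 0 is always evaluated explicitly
and the estimate is clamped there when it wins, at which point the fit
*is* ordinary least squares exactly. A unit test verifies agreement of
coefficients, standard errors and variance components with an
independent general-purpose mixed-model implementation (statsmodels
MixedLM) on an interior-variance dataset.

Rank-deficient designs are rejected up front with the aliased columns
named (QR with pivoting). Fixed-effect inference is Wald/normal with
the REML covariance σ̂²(XᵀŴX)⁻¹; no Satterthwaite or Kenward–Roger
small-sample correction is applied, consistent with the Monte Carlo
step, which samples coefficients from normal distributions.

## Mediation decomposition

For exposure X (per-SD), mediators M₁…M_K and outcome Y:

* a-paths: K separate models M_k ~ X + C (coefficient a_k);
* outcome model: Y ~ X + M₁ + … + M_K + C (coefficients c′, b₁…b_K and
  their joint covariance);
* indirect_k = a_k·b_k, total indirect = Σ_k a_k·b_k, direct = c′,
  total = c′ + Σ_k a_k·b_k.

The identities `total = direct + total_indirect` and
`total_indirect = Σ indirect_k` are asserted to machine precision on
every fit. The indirect effects are labelled *interventional*: because
the mediators are measured simultaneously in plasma, no causal ordering
among them is imposed, and a_k·b_k is interpreted as the effect through
M_k together with anything causally upstream of it. Mediators enter on
their measured concentration scale (no log transform). Serial
(causally ordered) mediator models, exposure–mediator interactions and
random slopes are out of scope.

## Monte Carlo intervals

Indirect-effect CIs are percentile intervals of the simulated
distribution of the product(s): draw a_k* ~ N(â_k, SE²) independently
across mediators (they come from separate models, so their sampling
covariance is not estimated), and draw the outcome-model block
(c′*, b₁*…b_K*) jointly from a multivariate normal at the fitted REML
covariance; each draw contributes Σ_k a_k*·b_k* (or a single product).
Defaults: 20 000 draws, 95% level, seed required and logged. The point
estimate is always the plain product/sum — never the draw mean, which
carries the product-of-estimators bias. Percentile (not bias-corrected)
intervals are used.

Direct effects use normal (Wald) intervals. The total effect uses a
normal interval whose SE is the Monte Carlo SD of the composite draw
c′* + Σ a_k*·b_k*, which automatically includes the c′–b covariance of
the outcome model; an exact product-moment formula for
Var(Σ a_k* b_k*) serves as the analytic oracle in tests. Significance
is "the interval excludes zero", with an interval touching zero
counting as covering it. Fixed seeds give bit-identical intervals.

## Synthetic cohort generator

The generator emulates the structure of the motivating three-visit
survivor cohort without attempting to reproduce its joint dependence
or its estimates:

* **Design (defaults).** 209 subjects at T1; monotone dropout via a
  single uniform per subject thresholded at retention 174/209 (T2) and
  143/209 (T3), so visit counts are binomial around 209/174/143;
  covariate marginals match the published descriptives (age
  N(66.1, 9.1²); 67.5% male; 36.4% chemotherapy; comorbidity classes
  0.19/0.26/0.55; per-visit stoma 0.30/0.18/0.14; BMI N(27.7, 4.4²);
  sedentary time N(4.8, 2.4²); MVPA and creatinine lognormal with
  medians 7.5 h/week and 82 µmol/L).
* **Diet.** Subcomponent grams (animal/plant protein, mono-/di- and
  polysaccharides, saturated/unsaturated fat, alcohol, fiber) are drawn
  around published per-visit means and SDs, scaled by a shared
  "appetite" factor (subject-stable, sex-dependent — males ~1.08×,
  females ~0.85×) that induces realistic correlation among intakes and
  with total energy; totals and kcal columns are exact sums/conversions,
  so energy_kcal is internally consistent. The subject-habit/visit-noise
  SD split (0.745/0.667) preserves marginal SDs; values are floored at
  zero, which truncates alcohol's left tail noticeably (its realized SD
  runs below the published one) — the other intakes are barely affected.
* **Mediators.** M_k = mean_k + a_k·X_std + τ_m u_ik + ε_ijk with
  equicorrelated residuals (default ρ = 0.3), Gaussian by default so
  linear-model recovery is exact; a lognormal re-expression is
  available as a realism toggle. Concentrations are floored at 1% of
  their typical level (a ~1e-4-probability truncation) so ratios stay
  defined. Typical levels approximate the published medians (checked
  within 10% for Trp and QA in tests).
* **Outcome.** Y = intercept + c′·X_std + Σ b_k M_k + τ_y u_i + ε, with
  the intercept re-centred by −Σ b_k·mean_k so the marginal outcome
  mean stays near its target whatever b is. X_std uses the *realized*
  mean-of-per-visit-SDs scale of the designated exposure, making
  truth.a and truth.c_prime exactly the per-SD quantities the pipeline
  estimates. Other HRQoL columns are noise around their published
  means. Outcomes are unbounded Gaussians by default ("none" mode);
  "clip" truncates to [0, 100] for realism at the cost of a small
  attenuation bias.
* **Dropout** is covariate-independent (MCAR) by default; an
  informative-dropout coefficient (retention decreasing with poor
  current outcome) exists for robustness experiments only.
* **Not emulated:** the real cohort's joint dependence structure,
  zero-inflation of alcohol, item-level EORTC responses, stoma/comorbidity
  trajectories as Markov chains (they are redrawn per visit), or any of
  the published effect estimates. Passing recovery tests therefore
  demonstrates correctness of the estimators under the generating
  model, not agreement with the original cohort.

## Verification strategy and problem sizes

* Worked-example arithmetic (energy factors, per-SD labels, ratio
  values, effect-decomposition sums) is checked exactly against
  hand-computable values.
* The REML engine is checked against closed-form OLS at the variance
  boundary (agreement < 1e-6) and against statsmodels MixedLM in the
  interior; slope recovery and equivariance (response shifts, affine
  covariate recoding, record order) are property-tested.
* Monte Carlo intervals are checked against an independent brute-force
  sampler on a separate RNG stream (2×10⁷ draws, endpoint agreement
  1e-3), against the exact product-moment variance (10⁶ draws, 5%), and
  against the normal approximation in the high-precision regime.
* Coverage: with a true null indirect effect (a = 0, b ≠ 0), the 95%
  interval covers zero in 400 replicates of 200-subject cohorts within
  [0.92, 0.98].
* Recovery: with K = 3 mediators, n = 500 subjects and fixed seeds,
  each path and the total effect land within 3 SEs of truth in ≥ 95% of
  100 replicates. Three mediators exercise the parallel-multiple
  structure while keeping the suite fast; the estimators are dimension-
  agnostic and the nine-metabolite configuration is exercised end to
  end elsewhere (and in `scripts/acceptance.py`, which averages a
  100-replicate nine-metabolite recovery run on the full default
  design).

## Known limitations

* Wald/normal inference throughout; no small-sample df corrections, so
  intervals can be slightly anticonservative in very small cohorts.
* The a-path draws ignore cross-model sampling covariance between
  a-paths and the outcome model fitted to the same data; this is the
  standard distribution-of-product setup. The exact product-moment
  variance (`product_sum_variance`) is exposed as the delta-style
  analytic counterpart, and the Monte Carlo composite SD is verified
  against it in the tests.
* Complete-case deletion per model means different cells of an analysis
  grid may use slightly different records when missingness is present.
* The bounded ("clip") outcome mode attenuates path coefficients near
  the scale limits; recovery guarantees are stated for the Gaussian
  mode only.
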