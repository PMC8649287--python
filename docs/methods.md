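# Methods

## The estimation problem

A subject seen quarterly for two years contributes 4–9 SBP readings.
The sample SD of so few readings estimates the subject's underlying
visit-to-visit variability with large error (with ν degrees of freedom,
Var(log s) ≈ 1/(2ν); at the cohort's mean 4.5 readings and a linear
detrend, ν ≈ 2.5). When such an error-laden quantity is used as a Cox
covariate, the coefficient is attenuated by roughly the exposure's
reliability — here ω²/(ω² + 1/(2ν)) ≈ 0.14 — so a true hazard ratio of
1.30 per 5 mm Hg appears as ≈ 1.03. The package's central move is to
replace the raw statistic with the posterior mean of the subject's
residual SD under a hierarchical model, which is a regression-calibration
estimate: to first order, a regression on E[σ_i | data] is unbiased for
the coefficient on σ_i.

## Hierarchical model and priors

    y_ij = α_i + β_i t_ij + ε_ij,   ε_ij ~ N(0, σ_i²)
    (α_i, β_i) ~ BVN(μ, Σ),         log σ_i ~ N(θ, ω²)

Subjects with fewer than 4 readings are excluded before fitting
(configurable; 2 and 7 are the sensitivity cutoffs). The slope enters
as both fixed and random effect; no covariates enter the longitudinal
model. "Usual SBP" is the posterior mean of α_i — the intercept at the
first reading; the slope is deliberately not folded in.

Priors (weakly informative; all scales configurable in
`MixedModelSpec`): μ components N(0, 10⁶); Σ through independent
half-Cauchy(5) SDs with a uniform(−1, 1) correlation; θ ~ N(log 12, 1);
ω ~ half-Normal(1). With thousands of subjects the posterior is
dominated by the likelihood; the priors' role is to keep the sampler
proper in degenerate regimes (e.g. homogeneous variances, ω → 0).

## Sampler

A naive Gibbs scheme (effects | hypers, hypers | effects) mixes very
slowly here for two reasons: the slope-related components of Σ are
weakly identified (a 2-year window with ~4.5 readings gives per-subject
slope SEs near 10 mm Hg/yr against a population SD of 2), and (θ, ω)
are funnel-coupled to the 3000-dimensional block of subject log-SDs —
their full conditionals are orders of magnitude tighter than their
marginal posteriors. The implemented sampler therefore collapses the
latent blocks analytically wherever a hyperparameter is updated:

* **μ** — conjugate normal draw with the random effects integrated out
  (Woodbury identities reduce everything to per-subject 2×2 sufficient
  statistics; each sweep is O(n)).
* **Σ** — component-wise random-walk Metropolis on
  (log s_α, log s_β, atanh ρ) against the effects-marginal likelihood;
  six scans per sweep; proposal scales adapted only during burn-in.
* **(θ, ω)** — random-walk Metropolis against the likelihood with the
  random effects integrated analytically *and* every subject log-SD
  integrated numerically by 20-node Gauss–Hermite quadrature, adapted
  per subject around a Laplace mode (Newton on the concave 1-d
  conditional). Because the quadrature value is a deterministic
  function of (θ, ω) and the data, the move is an exact MH update.
* **log σ_i** — vectorized random-walk Metropolis against the
  effects-marginal likelihood plus the lognormal prior (two refreshes
  per sweep; one global step size adapted during burn-in).
* **(α_i, β_i)** — exact conjugate bivariate-normal draws, needed only
  for the posterior summaries.

Two chains (more allowed) with over-dispersed data-based starts; split-R̂
and effective sample sizes (via `arviz`) are computed for all seven
hyperparameters, and the fit **fails loudly** when any split-R̂ exceeds
1.05 (threshold configurable). Default length 1500 iterations with 500
burn-in; the recovery studies use 900/300, at which all R̂ ≤ 1.05 with
margin in every replicate examined (the recovery wrapper refits once
with doubled length should a replicate ever trip the check). Identical
seed, chain count and data give byte-identical summaries.

## Regression-dilution comparators

* **Naive route** — per-subject OLS line; residual SD with the n−2
  denominator (an n−1 no-slope variant is available).
* **Rosner route** — readings split at month 12; subjects with ≥2
  readings in both windows contribute paired window SDs (about the
  window mean, n−1); b is the least-squares slope of the second-window
  on the first-window estimate; the dilution ratio λ = 1/b multiplies
  the log HR estimated on the first-window exposure. Both b and λ are
  reported, so either convention of "dilution ratio" is recoverable.

A caution established by the package's own recovery experiments: with
only ~2 readings per window, the between-window covariance that
determines b is extremely noisy at desk scale (thousands of subjects),
so λ is unstable (median ≈ 15, long right tail) and the corrected
estimate, while centred near the truth, has several times the spread of
the model-based route. The Rosner route should be read as a sensitivity
direction check at these problem sizes, not as a competitive estimator.

## Survival analysis

Follow-up enters in counting-process form (entry, exit] on the
time-on-study scale. Each subject's follow-up is Lexis-split at 5-year
attained-age boundaries; the 10-year age-at-risk band (45–54 … 75–84,
attained age above 84 stays in the top band) enters as a time-varying
categorical covariate and baseline age as a linear term. Person-time
and events are conserved exactly by construction of the split.

The partial likelihood (Efron ties by default, Breslow optional) is
maximized by Newton–Raphson with step-halving to an infinity-norm
gradient below 10⁻⁹; risk-set sums are assembled from suffix cumulative
sums over exit- and entry-sorted rows, so one evaluation is O(n·p²).
The covariance matrix is the inverse observed information. Constant
covariates are rejected; separation is detected heuristically
(|coefficient| × covariate SD > 20) and reported as a warning rather
than an error. The implementation is cross-checked in the test suite
against a grid-search oracle, hand-expanded tied-case likelihoods and
`lifelines` (left truncation included).

Exposure parameterizations: linear per 5 mm Hg (HR = exp(5β̂)); the
five study groups with **floating absolute risks** — the reference is
augmented with β = 0, all pairwise contrast variances Var(β̂_k − β̂_l)
are formed from the fitted covariance, and per-group variances v_k ≥ 0
are obtained by non-negative least squares over all pairs, with the
worst pairwise reproduction residual reported (< 0.2% of the mean
contrast variance on the cohorts examined); a restricted cubic spline
with 3 knots at the 10th/50th/90th percentiles of the exposure
(Harrell's truncated-power basis, linear beyond the boundary knots);
and per-half-decade exposure terms whose decade-level HR is the
geometric mean, log HR = (b₁+b₂)/2 with delta-method variance
(v₁+v₂+2c₁₂)/4.

By default both baseline SBP and usual SBP are in the adjustment set
(`adjust_baseline_sbp=False` drops the former), alongside sex, smoking,
BMI, HbA1c, LDL-C, eGFR, Charlson index and the drug-class flags.

## Incidence and imputation

Rates are first events per 1000 person-years, person-time censored at
that outcome's first event or censoring (death censors non-fatal
outcomes in the generator). Intervals are exact Garwood intervals,
lower = χ²(α/2, 2k)/2 and upper = χ²(1−α/2, 2k+2)/2 — the conservative
reading of "Poisson-distribution CIs"; a normal-on-log variant sits
behind a flag.

Missing baseline covariates (never blood pressure) are imputed m = 5
times by chained equations: proper Bayesian linear-regression draws for
continuous variables (σ² from the scaled inverse-χ², then β | σ²),
logistic draws from the asymptotic posterior for binary ones, cycled 10
times (5 in the scaled-down studies) from random-draw initialization,
with the event indicator and log follow-up time among the predictors.
Analyses are pooled by Rubin's rules, T = W̄ + (1 + 1/m)B, with the
standard small-m degrees of freedom. Predictive-mean matching is off by
default; the conditional-model forms are declared choices, not inferred
ones.

## Synthetic cohort

The generator emulates the target study's structure: ages 45–84
(truncated normal 63.9 ± 10), 45.2% male, usual SBP 137.1 ± 10.7 mm Hg,
true σ_i lognormal with natural-scale mean 12.7 and SD 2.3, slopes
N(0, 2²) mm Hg/yr, quarterly visits over 24 months with the first visit
always observed and later visits retained i.i.d. with probability 0.28,
redrawing subjects below 4 readings — this rejection-sampled retention
reproduces the target mean of ~4.5 readings (a 0.44 retention matches
4.5 only without the minimum-4 floor). Outcomes (CVD and death, shares
0.56/0.44 of a 0.025/person-year composite baseline) are exponential
proportional-hazards draws whose log hazard is linear in
(σ_i − 12.7)/5, with configurable covariate coefficients and an
optional age-by-variability interaction; administrative censoring at 10
years minus a truncated-exponential staggered-entry offset (mean 0.35
y) yields a median follow-up of ≈ 9.7 years. Covariates are drawn from
simple parametric families with the target cohort's marginal moments;
eGFR follows the Chinese-recalibrated abbreviated MDRD formula from
lognormal creatinine. MCAR deletion is the default missingness
mechanism; MAR-on-age (logistic in standardized age, intercept solved
for the requested marginal rate) is available.

What the generator does **not** emulate: within-visit duplicate
readings (assumed pre-averaged), diagnosis-code event adjudication,
informative visit schedules, medication changes over follow-up,
non-Gaussian reading noise, and competing-risk dependence beyond
death censoring non-fatal outcomes. Passing recovery tests therefore
demonstrate the statistical machinery under the assumed data-generating
law, not robustness to these real-data features.

## Problem sizes and numerical choices

The replicated recovery study uses 20 cohorts of n = 3000 subjects at
true HR 1.30 per 5 mm Hg with the reduced 900/300 MCMC length; the
Rubin coverage study uses 200 cohorts of n = 150 with a Cox estimate on
the true σ_i (no MCMC inside the 200-replicate loop). Smaller unit
fixtures (n = 150–200) exercise dense (9-reading) and sparse (4-reading)
designs. SSE and variance quantities are clipped at tiny positive
floors before logs; Cox covariates are centered internally for
numerical stability (coefficients are unaffected).

A structural finding from the recovery study, worth restating: with
4.5 readings per subject the *sampling noise* of even the best
de-attenuated estimator (SE ≈ 0.2 on the per-5 log HR at ~770 events)
is comparable to the naive estimator's *bias* (≈ 0.23). The corrected
routes are essentially unbiased — the naive route is not — but on any
single replicate the corrected estimate is not guaranteed to land
closer to the truth than the naive one; that comparison favours the
correction reliably only in expectation or at larger event counts.

On the shrinkage geometry: the posterior mean of σ_i is not literally
sandwiched between the subject's raw SD and the population central
value exp(θ + ω²/2) — the raw SD is biased low by the c4 factor and the
posterior corrects this, so for subjects whose raw SD already sits near
the center the posterior mean can land just outside that (nearly empty)
interval. The property that does hold, and is tested, is contraction:
|usual_sd − center| ≤ |naive_sd/c4 − center| for ≥95% of subjects.

## Known limitations

* The Cox model treats the estimated exposure as fixed; posterior
  uncertainty in usual_sd is not propagated into the hazard-ratio CI
  (regression calibration; CIs are mildly optimistic in principle,
  though coverage was nominal in the recovery study).
* The Rosner λ is reported without a delta-method SE; its instability
  at small reading counts is documented above.
* Fine–Gray competing-risk models, proportionality diagnostics and
  covariate-adjusted variability models are out of scope.
* One composite outcome generator with independent cause labels stands
  in for a full multi-state model.
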