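# Methods

## Scope and data model

The package analyses a person-level cohort: sociodemographic covariates
(age, gender, education, marital status, smoking, drinking, BMI class,
rural/urban location), a continuous economic measure (per-capita
expenditure, PCE, in currency units), a sampling weight, a binary pain
indicator with severity (mild/moderate/severe) and 15 body-site indicators
among pain cases, and 3-year vital status with follow-up time. Economic
status enters twice, deliberately: the continuous PCE drives the SES
ranking, while expenditure tertiles enter the regressions as categorical
indicators (the middle tertile sits at the centre of the ranking, so its
category concentration index is ~0 by construction).

## Inequality estimators

Fractional ranks are midpoint positions in the weighted PCE ordering; tied
values receive the average over tie orders, which keeps results invariant to
input order and the weighted mean of ranks exactly ½. The concentration
index is computed three equivalent ways — the covariance formula
2·cov_w(y,R)/μ, twice the signed area between the concentration curve and
the diagonal (with one curve vertex per distinct PCE value so the trapezoid
area matches the covariance form to machine precision), and the slope of the
convenient regression — and the test suite enforces pairwise agreement to
1e-8. Weights default to 1; a weighted mode applies the sampling-weight
column to ranks, means and regressions throughout. Because the variance
estimator behind published concentration-index intervals is rarely stated,
we use the standard default: heteroskedasticity-robust (HC0) standard error
of the convenient-regression slope, with a normal 95% interval. The plain
(uncorrected) index is reported; Wagstaff (C/(1−μ)) and Erreygers (4μC)
normalizations for bounded outcomes are available as explicit post-hoc
transforms and never applied silently.

The decomposition uses a weighted linear probability model because it is the
only specification under which C = Σ η_k C_k + GC_ε/μ holds exactly (checked
to 1e-8 on every input). A logit marginal-effects mode is provided for
sensitivity analysis; its identity gap is folded into the residual term.
Contribution rates divide by the sum of factor contributions *excluding* the
residual, so rates across rows always total 100%; this is the convention
that makes published decomposition tables internally consistent, and it is
the one place where the denominator choice materially changes the headline
percentages. Empty factor categories are dropped with a warning; a factor
with a single observed category is skipped (its indicator would be collinear
with the intercept); rank-deficient designs are reported with the offending
columns rather than silently pseudo-inverted.

## Survival estimators

Kaplan–Meier, the two-group log-rank test and Cox proportional hazards are
implemented from their defining statistics. The Cox partial likelihood is
maximised by Newton–Raphson with step-halving; the ascent check uses a
tolerance relative to |log L| because near the optimum the difference
between successive log-likelihood values falls below the floating-point
resolution of the log-likelihood itself. Convergence requires max|gradient|
< 1e-8 within 50 iterations; standard errors come from the inverse observed
information and intervals are Wald on the hazard-ratio scale. Breslow is the
default tie-handling (matching the common default of survey-analysis
software); Efron is available, and the two coincide exactly when event times
are distinct. A coefficient exceeding |β| > 15 is treated as monotone
likelihood (separation) and raised as an error, never returned as an
estimate.

The adjusted fit enters age in bands (45–60, 60–75, ≥75) for symmetry with
the decomposition table; a continuous-age fit is a one-line change via
`CoxPH` directly. Design matrices for the adjusted fits are event-aware: a
covariate category whose members experienced no events cannot support a
finite hazard ratio, so it is merged into the reference with a warning, and
if the nominal reference itself has no events the largest-event category
becomes the reference. Stratified fits adjust for every factor except the
stratum variable and skip strata with fewer than 100 records or 5 events
(configurable), logging the reason — mirroring the reporting convention of
omitting subgroups too small to support the model. Site- and severity-
specific fits compare one indicator at a time against the pain-free
reference (no mutual adjustment between sites).

## Synthetic cohort generator

The generator emulates the 2011/2013 CHARLS pain cohort's statistical
structure at n = 16,747:

- **Age**: normal truncated to [45, 100]; the latent mean/SD are solved
  numerically so the truncated distribution has mean 59.57 and SD 9.82
  years. Age bands derive from the continuous draw.
- **Categorical covariates**: drawn at the published marginal frequencies
  (stored as raw integer counts and normalised, so no rounding is baked in).
- **PCE**: log-normal with meanlog 9.2 and sdlog 0.9 (annual per-capita
  expenditure in yuan; right-skewed and positive). Only the ranks matter for
  the concentration index, so these two parameters are free.
- **SES coupling**: education follows a proportional-odds model in the
  expenditure percentile (slope 2.0 log-odds per unit rank) and urban
  residence a logistic model (slope 3.4), with thresholds re-solved at
  generation time so the marginals stay at their targets. The slopes were
  chosen once so the education and location category indices have roughly
  the magnitudes seen in published decompositions (≈ −0.2 for illiteracy,
  ≈ −0.13 for rural residence).
- **Pain**: logistic in the rank plus covariate indicators. The intercept
  (−0.692) and rank slope (−0.145) are frozen outputs of the calibration
  routines, run at n = 400,000, targeting prevalence 32.54% and a pain
  concentration index of −0.066 jointly. Calibration root-finds on the
  *expected* prevalence and expected index (mean of fitted probabilities and
  2·cov(p,R)/mean(p) over a large simulated covariate sample), which is the
  large-n limit of the empirical quantities and makes the routines smooth,
  monotone and deterministic.
- **Severity and sites**: drawn only for pain cases at the published
  conditional mixes; 23/5449 of pain cases receive a missing severity grade,
  mirroring the severity denominator (5426) of the emulated survey. Site
  indicators are independent given pain by default; optional per-site rank
  slopes let sites carry their own SES gradients.
- **Survival**: exponential proportional hazards — the minimal model
  consistent with a single 3-year hazard ratio — with rate λ₀·exp(η), pain
  log-HR log 1.30 (or severity-graded log-HRs when supplied), age-band and
  gender effects on mortality, and administrative censoring at 3 years. λ₀
  (0.0038/year) is the frozen output of the baseline-hazard calibration
  targeting 2.35% cumulative 3-year mortality.

Randomness is organised as one substream per field, derived from the single
seed, so adding a generated field never perturbs the fields drawn before it;
the same seed yields a bit-identical table.

What the generator does *not* emulate: multistage cluster sampling and
survey weights (the weight column is constant unless supplied), household
structure, item nonresponse outside severity, reporting heterogeneity in
self-reported pain, and non-proportional or time-varying hazards. Passing
tests therefore demonstrate that the estimators recover known parameters
under the assumed structure — not that the substantive findings would
replicate in the real survey.

## Problem sizes and tolerances

Deterministic identities are asserted at 1e-8 (1e-10 where exact algebra
applies). Stochastic checks use the study-condition sizes: single-cohort
calibration checks at n = 16,747; parameter-recovery means over 200
replicate cohorts (pain HR within 0.03, severity HRs within 0.05); log-rank
size over 1,000 null replicates of n = 200 (rejection rate inside the
3-SE binomial band around 0.05); marginal-frequency checks within 3 binomial
SEs. Calibration routines default to n = 200,000 evaluation samples.

## Known limitations

- Concentration-index inference ignores the survey design (no cluster-robust
  or multistage variance); with the default unit weights this matches the
  apparent convention of published analyses but understates variance for
  genuinely clustered samples.
- The LPM can fit probabilities outside [0,1]; this is inherent to the exact
  decomposition and is why the marginal-effects mode exists for sensitivity.
- No dominance tests between concentration curves, no Oaxaca-style change
  decomposition across waves, no competing risks or mediation analysis.
- Proportional-hazards diagnostics are limited to comparing stratified and
  pooled fits; Schoenfeld-residual machinery is not included.
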