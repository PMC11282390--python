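# painequity

Socioeconomic inequality in pain and its mortality consequences, as studied
in ageing cohorts such as CHARLS (the China Health and Retirement
Longitudinal Study): who bears the burden of pain across the economic
gradient, which factors drive that inequality, and whether pain carries an
excess risk of all-cause death.

The package is for epidemiologists and health economists who want the full
analysis chain as tested, reusable code: weighted fractional SES ranking,
the concentration curve and concentration index with robust uncertainty, the
regression-based (Wagstaff-style) decomposition of the index into factor
contributions, and first-principles survival machinery (Kaplan–Meier,
log-rank, Cox proportional hazards with Breslow/Efron ties and stratified
fits). A calibrated synthetic cohort generator reproduces the statistical
structure of the 2011/2013 CHARLS pain cohort, so the whole pipeline runs
and is validated without access to restricted microdata.

## The statistics at the core

**Concentration index.** Rank individuals from poorest to richest by a
continuous economic measure (per-capita expenditure) with weighted
fractional ranks R_i ∈ (0,1) (weighted mean exactly ½; ties averaged). For
an outcome y with mean μ,

C = 2 · cov_w(y, R) / μ,

equivalently twice the signed area between the concentration curve and the
45° diagonal; C < 0 means the outcome is concentrated among the poor. The
standard error comes from the "convenient regression"
2σ²_R · y_i/μ = α + C·R_i + ε_i with a heteroskedasticity-robust slope
variance.

**Decomposition.** With a linear probability model y = β₀ + Σ_k β_k x_k + ε,

C = Σ_k η_k C_k + GC_ε/μ,  η_k = β_k x̄_k / μ,

where C_k is the concentration index of regressor x_k over the same ranks,
η_k its elasticity, η_k·C_k its contribution, and GC_ε/μ the residual term.
The identity is exact, and contribution rates are percentages of the
explained (residual-excluded) total.

**Survival.** Cox proportional hazards fitted by Newton–Raphson on the
partial likelihood (Breslow default, Efron optional), Wald CIs from the
inverse observed information, plus the Kaplan–Meier product-limit estimator
and the two-group log-rank test — all implemented directly and cross-checked
against independent oracles in the test suite.

## Worked example

Simulate a CHARLS-like cohort at the default calibrated conditions and run
the full analysis:

```bash
painequity analyze --generate --seed 0 --out demo
```

prints

```
Concentration index of pain
============================================
n                        16747
mean outcome            0.3192
index C                -0.0661
robust SE               0.0065
95% CI            [-0.0788, -0.0534]

adjusted pain HR 1.347 (95% CI 1.091-1.663); log-rank p = 0.01784
```

Read: roughly a third of the simulated cohort reports pain; the negative
index says pain is concentrated among the poor (the concentration curve lies
above the diagonal); and after adjusting for age band, gender, education,
marital status, smoking, drinking, BMI class, economic tertile and
rural/urban location, pain carries a ~35% higher hazard of death over the
3-year follow-up in this particular replicate (the generating hazard ratio
is 1.30). `demo/` then holds the descriptive table, concentration curve and
index, decomposition table, Kaplan–Meier curves with the log-rank test, the
adjusted and stratified Cox fits, per-site and per-severity analyses, and a
`manifest.json` from which any output can be regenerated.

The same objects are available as a library, statsmodels-style:

```python
from painequity import (GeneratorParams, generate_cohort,
                        ConcentrationIndex, ConcentrationDecomposition,
                        adjusted_pain_hr)

cohort = generate_cohort(GeneratorParams(seed=0))
res = ConcentrationIndex.from_dataframe(cohort, "pain").fit()
print(res.summary())
decomp = ConcentrationDecomposition.from_dataframe(cohort).fit()
print(decomp.contribution_rates())
cox = adjusted_pain_hr(cohort)
print(cox.summary())
```

Real cohort CSVs run through `painequity analyze --input cohort.csv --out dir`
with the same schema the generator writes (one row per person, 0/1 site
indicator columns); standard exclusions (missing core fields, age < 45) are
applied and counted in the manifest.

## Layout

- `src/painequity/ranking.py`, `concentration.py` — fractional ranks, curve, index
- `src/painequity/decomposition.py` — design building, LPM fit, decomposition
- `src/painequity/survival.py` — KM, log-rank, Cox, stratified fits
- `src/painequity/cohort.py` — synthetic cohort generator and calibration
- `src/painequity/stats.py` — descriptive table, weighted prevalence, logistic correlates, per-site/per-severity analyses
- `src/painequity/pipeline.py`, `cli.py` — end-to-end runner and CLI
- `docs/methods.md` — model assumptions, calibration and design choices
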