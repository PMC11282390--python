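"""Descriptive and supplementary cohort analyses.

Covers the descriptive layer of the analysis: the baseline characteristics
table by pain status (chi-square tests for categorical rows, a two-sample t
test for age), the weighted pain-prevalence estimate, a logistic model of
pain correlates, and the per-site / per-severity concentration indices and
Cox fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import reference
from .cohort import SITE_COLUMNS
from .concentration import ConcentrationIndex
from .decomposition import build_design, default_factor_specs
from .survival import CoxPH, SeparationError, _ensure_design_columns

__all__ = [
    "DescriptiveTable",
    "descriptive_table",
    "weighted_prevalence",
    "pain_correlates_logistic",
    "site_severity_inequality",
    "site_severity_mortality",
]

_CATEGORICAL_VARS = (
    "age_group", "gender", "education", "marital", "smoking",
    "drinking", "bmi_class", "econ", "location",
)


@dataclass
class DescriptiveTable:
    """Counts/percentages by pain status with group-comparison tests."""

    table: pd.DataFrame
    n_total: int
    n_pain: int
    n_no_pain: int

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_markdown(self) -> str:
        return self.table.to_markdown(index=False)


def _chi2_table(cohort: pd.DataFrame, var: str) -> tuple[float, float]:
    ct = pd.crosstab(cohort[var], cohort["pain"])
    chi2, p, _, expected = stats.chi2_contingency(ct, correction=False)
    if (expected < 1).any():
        warnings.warn(f"expected cell count < 1 in chi-square table for {var!r}", UserWarning)
    return float(chi2), float(p)


def descriptive_table(cohort: pd.DataFrame, t_test: str = "welch") -> DescriptiveTable:
    """Baseline characteristics by pain status.

    Categorical variables get a Pearson chi-square test (no continuity
    correction); age gets a two-sided two-sample t test (Welch by default,
    ``t_test='student'`` for the pooled-variance variant).  Percentages are
    column percentages within pain status.
    """
    if "pain" not in cohort.columns:
        raise ValueError("cohort must contain the pain column")
    cohort = _ensure_design_columns(cohort)
    pain = cohort["pain"].astype(int)
    g0, g1 = cohort[pain == 0], cohort[pain == 1]
    rows = []

    a0, a1 = g0["age"].to_numpy(), g1["age"].to_numpy()
    tstat, tp = stats.ttest_ind(a0, a1, equal_var=(t_test == "student"))
    rows.append({
        "variable": "age", "category": "mean (SD)",
        "total": f"{cohort['age'].mean():.2f} ({cohort['age'].std(ddof=1):.2f})",
        "no_pain": f"{a0.mean():.2f} ({a0.std(ddof=1):.2f})",
        "pain": f"{a1.mean():.2f} ({a1.std(ddof=1):.2f})",
        "statistic": float(tstat), "pvalue": float(tp), "test": f"t ({t_test})",
    })

    for var in _CATEGORICAL_VARS:
        chi2, p = _chi2_table(cohort, var)
        first = True
        for cat, n_tot in cohort[var].value_counts(sort=False).items():
            n0 = int((g0[var] == cat).sum())
            n1 = int((g1[var] == cat).sum())
            rows.append({
                "variable": var, "category": str(cat),
                "total": f"{n_tot} ({100 * n_tot / len(cohort):.2f})",
                "no_pain": f"{n0} ({100 * n0 / len(g0):.2f})",
                "pain": f"{n1} ({100 * n1 / len(g1):.2f})",
                "statistic": chi2 if first else np.nan,
                "pvalue": p if first else np.nan,
                "test": "chi-square" if first else "",
            })
            first = False

    # severity and site rows are defined among pain cases only
    sev = g1["severity"].dropna()
    for grade in ("mild", "moderate", "severe"):
        k = int((sev == grade).sum())
        rows.append({
            "variable": "severity", "category": grade, "total": "",
            "no_pain": "", "pain": f"{k} ({100 * k / len(sev):.2f})" if len(sev) else "0",
            "statistic": np.nan, "pvalue": np.nan, "test": "",
        })
    for site, col in zip(reference.SITES, SITE_COLUMNS):
        if col in cohort.columns:
            k = int((g1[col] == 1).sum())
            rows.append({
                "variable": "pain_site", "category": site, "total": "",
                "no_pain": "", "pain": f"{k} ({100 * k / len(cohort):.2f})",
                "statistic": np.nan, "pvalue": np.nan, "test": "",
            })

    return DescriptiveTable(table=pd.DataFrame(rows), n_total=len(cohort),
                            n_pain=int(pain.sum()), n_no_pain=int((1 - pain).sum()))


def weighted_prevalence(y, weights=None, alpha: float = 0.05):
    """Weighted proportion with a normal-approximation confidence interval.

    Horvitz-Thompson-style estimate p = sum(w y) / sum(w) with variance
    sum(w_i^2 (y_i - p)^2) / (sum w)^2.
    """
    y = np.asarray(y, dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive total")
    p = float(np.sum(w * y) / np.sum(w))
    var = float(np.sum(w ** 2 * (y - p) ** 2) / np.sum(w) ** 2)
    se = np.sqrt(var)
    z = stats.norm.ppf(1 - alpha / 2)
    return p, se, (p - z * se, p + z * se)


def pain_correlates_logistic(cohort: pd.DataFrame, weights=None,
                             separation_bound: float = 15.0) -> pd.DataFrame:
    """Odds ratios of pain on the sociodemographic factors (logistic fit).

    Maximum-likelihood logit via iteratively reweighted least squares
    (statsmodels GLM); Wald 95% CIs on the odds-ratio scale.  A diverging
    coefficient raises :class:`SeparationError`.
    """
    cohort = _ensure_design_columns(cohort)
    X, _ = build_design(cohort, default_factor_specs(), weights)
    exog = sm.add_constant(X.to_numpy(float))
    y = cohort["pain"].to_numpy(float)
    kw = {} if weights is None else {"freq_weights": np.asarray(weights, dtype=float)}
    fit = sm.GLM(y, exog, family=sm.families.Binomial(), **kw).fit()
    params = fit.params[1:]
    if np.max(np.abs(params)) > separation_bound:
        bad = X.columns[int(np.argmax(np.abs(params)))]
        raise SeparationError(f"logistic coefficient for {bad!r} diverged; separation suspected")
    se = fit.bse[1:]
    return pd.DataFrame({
        "term": X.columns,
        "odds_ratio": np.exp(params),
        "or_low": np.exp(params - 1.96 * se),
        "or_high": np.exp(params + 1.96 * se),
        "pvalue": fit.pvalues[1:],
    }).set_index("term")


def _binary_outcomes(cohort: pd.DataFrame) -> dict[str, np.ndarray]:
    """Site and severity indicators over the full cohort (pain-free -> 0)."""
    out = {}
    pain = cohort["pain"].to_numpy()
    for site, col in zip(reference.SITES, SITE_COLUMNS):
        if col in cohort.columns:
            out[site] = np.where(pain == 1, cohort[col].fillna(0).to_numpy(float), 0.0)
    sev = cohort["severity"].astype(object)
    for grade in ("mild", "moderate", "severe"):
        out[f"severity:{grade}"] = ((sev == grade) & (pain == 1)).to_numpy(float)
    return out


def site_severity_inequality(cohort: pd.DataFrame, weights=None) -> pd.DataFrame:
    """Concentration index of each pain site and severity grade over the
    same SES ranks as the overall pain index."""
    rows = []
    for name, y in _binary_outcomes(cohort).items():
        if y.sum() == 0:
            warnings.warn(f"no cases for {name!r}; skipped", UserWarning)
            continue
        res = ConcentrationIndex(y, cohort["pce"].to_numpy(float), weights,
                                 outcome_name=name).fit()
        rows.append({"outcome": name, "n_cases": int(y.sum()), "index": res.index,
                     "se": res.se, "ci_low": res.conf_int[0], "ci_high": res.conf_int[1]})
    return pd.DataFrame(rows).set_index("outcome")


def site_severity_mortality(cohort: pd.DataFrame, ties: str = "breslow",
                            min_events: int = 5):
    """Adjusted Cox fit of each site / severity indicator versus the
    no-pain reference.

    Each fit restricts the sample to pain-free individuals plus the pain
    cases carrying that indicator; sites are modelled one at a time (no
    mutual adjustment between sites).  Returns (fits, skipped).
    """
    from .survival import survival_design

    cohort = _ensure_design_columns(cohort)
    fits, skipped = {}, {}
    pain = cohort["pain"].to_numpy()
    for name, y in _binary_outcomes(cohort).items():
        mask = (pain == 0) | (y == 1)
        sub = cohort[mask].copy()
        sub["exposure"] = y[mask]
        exposed_deaths = int(sub.loc[sub["exposure"] == 1, "dead"].sum())
        if exposed_deaths == 0:
            skipped[name] = "no deaths among exposed"
            continue
        if int(sub["dead"].sum()) < min_events:
            skipped[name] = f"fewer than {min_events} events"
            continue
        try:
            X = survival_design(sub, exposure="exposure")
            fits[name] = CoxPH(sub["time"], sub["dead"], X, ties=ties).fit()
        except (SeparationError, ValueError) as exc:
            skipped[name] = str(exc)
    return fits, skipped
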