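"""Survival analysis: Kaplan-Meier, log-rank and Cox proportional hazards.

All three estimators are implemented directly from their defining
statistics rather than delegated, since they are the analytical core of the
pain-mortality association:

* Kaplan-Meier product-limit estimator over distinct event times, with
  individuals censored exactly at an event time counted as still at risk.
* Two-group log-rank test with the hypergeometric variance.
* Cox partial likelihood maximised by Newton-Raphson with Breslow (default)
  or Efron handling of tied event times, standard errors from the inverse
  observed information, Wald confidence intervals on the hazard-ratio scale.

Monotone-likelihood (separation) is detected by a diverging coefficient and
reported as an exception rather than returned as a spurious estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .decomposition import FactorSpec, default_factor_specs, economic_tertiles

__all__ = [
    "KMCurve",
    "km_estimator",
    "LogRankResult",
    "logrank_test",
    "CoxPH",
    "CoxPHResults",
    "SeparationError",
    "ConvergenceError",
    "adjusted_pain_hr",
    "stratified_fits",
    "forest_frame",
]


class SeparationError(RuntimeError):
    """Monotone partial likelihood: a coefficient diverges."""


class ConvergenceError(RuntimeError):
    """Newton-Raphson failed to converge within the iteration budget."""


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit estimate at the distinct event times."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    nobs: int

    def survival_at(self, t) -> np.ndarray:
        """Step-function value S(t) (right-continuous)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, t, side="right")
        s = np.r_[1.0, self.survival]
        return s[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.times, "survival": self.survival,
            "at_risk": self.at_risk, "events": self.events,
        })


def _check_surv(time, event):
    t = np.asarray(time, dtype=float)
    d = np.asarray(event)
    if t.ndim != 1 or t.shape != d.shape or t.size == 0:
        raise ValueError("time and event must be equal-length nonempty 1-d arrays")
    if np.any(t < 0) or not np.all(np.isfinite(t)):
        raise ValueError("times must be finite and nonnegative")
    if not np.all(np.isin(d, (0, 1))):
        raise ValueError("event must be binary")
    return t, d.astype(int)


def km_estimator(time, event, group=None):
    """Kaplan-Meier curve, or one curve per group label.

    Returns a :class:`KMCurve`, or a dict label -> KMCurve when `group` is
    given.
    """
    t, d = _check_surv(time, event)
    if group is not None:
        g = np.asarray(group)
        return {lab: km_estimator(t[g == lab], d[g == lab]) for lab in pd.unique(g)}
    order = np.argsort(t, kind="stable")
    t, d = t[order], d[order]
    n = t.size
    ev_times = np.unique(t[d == 1])
    at_risk = n - np.searchsorted(t, ev_times, side="left")
    n_events = np.array([int(d[t == tau].sum()) for tau in ev_times])
    surv = np.cumprod(1.0 - n_events / at_risk)
    return KMCurve(times=ev_times, survival=surv, at_risk=at_risk, events=n_events, nobs=n)


@dataclass
class LogRankResult:
    statistic: float
    df: int
    pvalue: float
    observed: np.ndarray
    expected: np.ndarray

    def __repr__(self):
        return f"LogRankResult(chi2={self.statistic:.4f}, df={self.df}, p={self.pvalue:.4g})"


def logrank_test(time, event, group) -> LogRankResult:
    """Two-group log-rank test (O-E with hypergeometric variance)."""
    t, d = _check_surv(time, event)
    g = np.asarray(group)
    labels = pd.unique(g)
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {len(labels)}")
    if d.sum() == 0:
        raise ValueError("no events; log-rank statistic undefined")
    in1 = g == labels[0]
    ev_times = np.unique(t[d == 1])
    o1 = e1 = v = 0.0
    for tau in ev_times:
        at_risk = t >= tau
        n_tau = at_risk.sum()
        n1 = (at_risk & in1).sum()
        d_tau = int(d[(t == tau)].sum())
        d1 = int(d[(t == tau) & in1].sum())
        o1 += d1
        e1 += d_tau * n1 / n_tau
        if n_tau > 1:
            v += d_tau * (n1 / n_tau) * (1 - n1 / n_tau) * (n_tau - d_tau) / (n_tau - 1)
    if v == 0:
        raise ValueError("zero log-rank variance")
    chi2 = (o1 - e1) ** 2 / v
    p = float(stats.chi2.sf(chi2, 1))
    return LogRankResult(statistic=float(chi2), df=1, pvalue=p,
                         observed=np.array([o1, d.sum() - o1]),
                         expected=np.array([e1, d.sum() - e1]))


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class CoxPHResults:
    """Maximum partial-likelihood estimates with Wald inference."""

    params: pd.Series
    bse: pd.Series
    loglik: float
    loglik_trace: list[float] = field(repr=False)
    niter: int = 0
    converged: bool = False
    ties: str = "breslow"
    nobs: int = 0
    nevents: int = 0

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.params).rename("HR")

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        lo = np.exp(self.params - z * self.bse)
        hi = np.exp(self.params + z * self.bse)
        return pd.DataFrame({"hr_low": lo, "hr_high": hi})

    @property
    def pvalues(self) -> pd.Series:
        z = self.params / self.bse
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=self.params.index)

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            f"Cox proportional hazards ({self.ties} ties)",
            f"n = {self.nobs}, events = {self.nevents}, "
            f"log partial likelihood = {self.loglik:.4f}, iterations = {self.niter}",
            "=" * 78,
            f"{'covariate':<28}{'coef':>9}{'HR':>8}{'SE':>8}{'95% CI':>19}{'p':>8}",
            "-" * 78,
        ]
        for name in self.params.index:
            lines.append(
                f"{name:<28}{self.params[name]:>9.4f}{np.exp(self.params[name]):>8.3f}"
                f"{self.bse[name]:>8.4f}"
                f"{'[' + format(ci.loc[name, 'hr_low'], '.3f') + ', ' + format(ci.loc[name, 'hr_high'], '.3f') + ']':>19}"
                f"{self.pvalues[name]:>8.4f}"
            )
        return "\n".join(lines)


class CoxPH:
    """Cox proportional-hazards model fit by Newton-Raphson.

    Parameters
    ----------
    time, event : array-like
        Follow-up times (> 0) and binary event indicators.
    X : DataFrame or 2-d array
        Covariates; column names label the coefficients.
    ties : {'breslow', 'efron'}
        Partial-likelihood approximation for tied event times.  The two
        coincide when all event times are distinct.
    """

    def __init__(self, time, event, X, ties: str = "breslow"):
        if ties not in ("breslow", "efron"):
            raise ValueError("ties must be 'breslow' or 'efron'")
        t, d = _check_surv(time, event)
        if d.sum() == 0:
            raise ValueError("at least one event is required")
        if isinstance(X, pd.DataFrame):
            self.names = list(X.columns)
            Xm = X.to_numpy(float)
        else:
            Xm = np.asarray(X, dtype=float)
            if Xm.ndim == 1:
                Xm = Xm[:, None]
            self.names = [f"x{j}" for j in range(Xm.shape[1])]
        if Xm.shape[0] != t.size:
            raise ValueError("covariate rows must match number of observations")
        order = np.argsort(t, kind="stable")
        self.time = t[order]
        self.event = d[order]
        self.X = Xm[order]
        self.ties = ties
        # unique event times, their first index in the sorted arrays, multiplicity
        ev = self.time[self.event == 1]
        self.ev_times = np.unique(ev)
        self.ev_start = np.searchsorted(self.time, self.ev_times, side="left")
        self.ev_d = np.array([int(self.event[self.time == tau].sum()) for tau in self.ev_times])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, duration_col: str = "time",
                       event_col: str = "dead", covariates: list[str] | None = None,
                       ties: str = "breslow") -> "CoxPH":
        cols = covariates or [c for c in df.columns if c not in (duration_col, event_col)]
        return cls(df[duration_col], df[event_col], df[cols], ties=ties)

    # -- partial likelihood machinery ------------------------------------

    def _tied_members(self, k):
        tau = self.ev_times[k]
        return np.flatnonzero((self.time == tau) & (self.event == 1))

    def _quantities(self, beta):
        """(log partial likelihood, gradient, observed information)."""
        X, d_marks = self.X, self.event
        n, p = X.shape
        eta = X @ beta
        eta = np.clip(eta, -500, 500)
        r = np.exp(eta)
        # reverse cumulative sums give the risk-set aggregates S0, S1
        S0_all = np.cumsum(r[::-1])[::-1]
        S1_all = np.cumsum((X * r[:, None])[::-1], axis=0)[::-1]
        S0 = S0_all[self.ev_start]
        S1 = S1_all[self.ev_start]
        d = self.ev_d.astype(float)
        tied = d > 1
        efron = self.ties == "efron"

        ll = float(eta[d_marks == 1].sum())
        grad = X[d_marks == 1].sum(axis=0)
        info = np.zeros((p, p))

        # Breslow aggregates for all times handled in closed vector form;
        # Efron-corrected tied times are excluded here and added explicitly.
        plain = ~(tied & efron)
        m = S1 / S0[:, None]
        ll -= float((d[plain] * np.log(S0[plain])).sum())
        grad -= (d[plain, None] * m[plain]).sum(axis=0)
        # sum_tau d*S2/S0 == sum_j r_j * A_j * x_j x_j^T with A the cumulative
        # hazard increments d/S0 accrued at event times <= t_j
        inc = np.zeros(n)
        np.add.at(inc, self.ev_start[plain], d[plain] / S0[plain])
        A = np.cumsum(inc)
        info += np.einsum("i,ij,ik->jk", r * A, X, X)
        info -= np.einsum("t,tj,tk->jk", d[plain], m[plain], m[plain])

        if efron and tied.any():
            for k in np.flatnonzero(tied):
                members = self._tied_members(k)
                dk = int(d[k])
                T0 = r[members].sum()
                T1 = (X[members] * r[members, None]).sum(axis=0)
                at_risk = slice(self.ev_start[k], n)
                S2 = np.einsum("i,ij,ik->jk", r[at_risk], X[at_risk], X[at_risk])
                T2 = np.einsum("i,ij,ik->jk", r[members], X[members], X[members])
                for j in range(dk):
                    f = j / dk
                    D = S0[k] - f * T0
                    g = (S1[k] - f * T1) / D
                    ll -= np.log(D)
                    grad -= g
                    info += (S2 - f * T2) / D - np.outer(g, g)
        return ll, grad, info

    def partial_loglik(self, beta) -> float:
        """Log partial likelihood at an arbitrary coefficient vector."""
        return self._quantities(np.asarray(beta, dtype=float))[0]

    def fit(self, tol: float = 1e-8, maxiter: int = 50,
            separation_bound: float = 15.0) -> CoxPHResults:
        p = self.X.shape[1]
        beta = np.zeros(p)
        ll, grad, info = self._quantities(beta)
        trace = [ll]
        converged = False
        it = 0
        for it in range(1, maxiter + 1):
            try:
                step = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError as exc:
                raise ValueError("singular information matrix; collinear covariates?") from exc
            # step-halving safeguards the ascent; tolerance is relative to
            # |ll| since near the optimum differences fall below float
            # resolution of the log-likelihood itself
            for _ in range(30):
                cand = beta + step
                ll_new, grad_new, info_new = self._quantities(cand)
                if ll_new >= ll - 1e-9 * (abs(ll) + 1.0):
                    break
                step = step / 2.0
            beta, ll, grad, info = cand, ll_new, grad_new, info_new
            trace.append(ll)
            if np.max(np.abs(beta)) > separation_bound:
                bad = self.names[int(np.argmax(np.abs(beta)))]
                raise SeparationError(
                    f"coefficient for {bad!r} diverged beyond |beta| > {separation_bound}; "
                    "monotone partial likelihood (separation) suspected"
                )
            if np.max(np.abs(grad)) < tol:
                converged = True
                break
        if not converged:
            raise ConvergenceError(f"no convergence in {maxiter} Newton iterations")
        cov = np.linalg.inv(info)
        se = np.sqrt(np.diag(cov))
        return CoxPHResults(
            params=pd.Series(beta, index=self.names, name="coef"),
            bse=pd.Series(se, index=self.names, name="se"),
            loglik=ll, loglik_trace=trace, niter=it, converged=converged,
            ties=self.ties, nobs=self.time.size, nevents=int(self.event.sum()),
        )


# ---------------------------------------------------------------------------
# Cohort-level fits
# ---------------------------------------------------------------------------

def _ensure_design_columns(cohort: pd.DataFrame) -> pd.DataFrame:
    cohort = cohort.copy()
    if "age_group" not in cohort.columns:
        bins = pd.cut(cohort["age"], [-np.inf, 60, 75, np.inf],
                      right=False, labels=["45-60", "60-75", ">=75"])
        cohort["age_group"] = bins.astype(str)
    if "econ" not in cohort.columns:
        w = cohort["weight"].to_numpy(float) if "weight" in cohort.columns else None
        cohort["econ"] = economic_tertiles(cohort["pce"].to_numpy(float), w)
    return cohort


def survival_design(cohort: pd.DataFrame, exposure: str = "pain",
                    exclude: str | None = None, event_col: str = "dead") -> pd.DataFrame:
    """Design matrix for the adjusted Cox fits: exposure first, then
    reference-coded adjuster indicators.

    Coding is event-aware: a covariate category whose members experienced no
    events cannot support a finite hazard-ratio estimate (the partial
    likelihood becomes monotone), so it is merged into the reference with a
    warning; if the nominal reference itself has no events, the category
    with the most events becomes the reference instead.  `exclude` drops one
    factor (used when stratifying on it).
    """
    import warnings

    cohort = _ensure_design_columns(cohort)
    ev = cohort[event_col].to_numpy()
    specs = [s for s in default_factor_specs() if s.variable != exclude]
    cols: dict[str, np.ndarray] = {exposure: cohort[exposure].to_numpy(float)}
    for spec in specs:
        values = cohort[spec.variable].astype(str)
        events = {c: int(ev[(values == c).to_numpy()].sum()) for c in spec.categories}
        ref = spec.reference
        if events[ref] == 0:
            ref = max(events, key=events.get)
            warnings.warn(
                f"reference {spec.reference!r} of {spec.variable!r} has no events; "
                f"re-referenced to {ref!r}", UserWarning, stacklevel=2)
        for cat in spec.categories:
            if cat == ref:
                continue
            members = (values == cat).to_numpy()
            if members.sum() == 0:
                continue
            if events[cat] == 0:
                warnings.warn(
                    f"category {cat!r} of {spec.variable!r} has no events; "
                    f"merged into reference {ref!r}", UserWarning, stacklevel=2)
                continue
            cols[f"{spec.variable}[{cat}]"] = members.astype(float)
    return pd.DataFrame(cols, index=cohort.index)


def adjusted_pain_hr(cohort: pd.DataFrame, ties: str = "breslow") -> CoxPHResults:
    """Cox fit of pain on all-cause mortality, adjusted for the nine
    sociodemographic factors (age band, gender, education, marital status,
    smoking, drinking, BMI class, economic tertile, location)."""
    X = survival_design(cohort)
    return CoxPH(cohort["time"], cohort["dead"], X, ties=ties).fit()


def stratified_fits(cohort: pd.DataFrame, stratum_variable: str,
                    min_records: int = 100, min_events: int = 5,
                    ties: str = "breslow"):
    """Per-stratum adjusted Cox fits of pain, adjusting for every factor
    except the stratum variable.

    Returns (fits, skipped): dicts keyed by stratum label; `skipped` maps a
    label to the reason it was not fitted (mirroring the reporting rule of
    dropping strata too small to support the model).
    """
    cohort = _ensure_design_columns(cohort)
    fits: dict[str, CoxPHResults] = {}
    skipped: dict[str, str] = {}
    for label, sub in cohort.groupby(stratum_variable, sort=False):
        n, ev = len(sub), int(sub["dead"].sum())
        if n < min_records or ev < min_events:
            skipped[str(label)] = f"n={n}, events={ev} below thresholds ({min_records}, {min_events})"
            continue
        try:
            X = survival_design(sub, exclude=stratum_variable)
            fits[str(label)] = CoxPH(sub["time"], sub["dead"], X, ties=ties).fit()
        except (SeparationError, ValueError) as exc:
            skipped[str(label)] = str(exc)
    if not fits:
        raise ValueError(f"all strata of {stratum_variable!r} were skipped: {skipped}")
    return fits, skipped


def forest_frame(fits: dict[str, CoxPHResults], term: str = "pain") -> pd.DataFrame:
    """Forest-plot-ready table (stratum, HR, CI bounds, n, events)."""
    rows = []
    for label, res in fits.items():
        ci = res.conf_int().loc[term]
        rows.append({
            "stratum": label, "hr": float(np.exp(res.params[term])),
            "hr_low": float(ci["hr_low"]), "hr_high": float(ci["hr_high"]),
            "n": res.nobs, "events": res.nevents,
        })
    return pd.DataFrame(rows)
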