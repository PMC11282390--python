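"""Concentration curve and concentration index of a health outcome.

The concentration index C summarises socioeconomic inequality in an outcome
y over a population ranked from poorest to richest.  Equivalently it is

* twice the weighted covariance between y and the fractional SES rank R,
  divided by the outcome mean mu, and
* twice the signed area between the concentration curve (cumulative outcome
  share vs cumulative population share) and the 45-degree diagonal.

Negative C means the outcome is concentrated among the poor (curve above the
diagonal).  The standard error comes from the "convenient regression"

    2 * var_w(R) * y_i / mu = a + C * R_i + e_i

fitted by weighted least squares with a heteroskedasticity-robust (HC0)
sandwich variance on the slope; the slope reproduces the covariance-form C
exactly, so the regression adds only the uncertainty estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from numpy.typing import ArrayLike
from scipy import stats

from .ranking import weighted_fractional_rank

__all__ = [
    "ConcentrationIndex",
    "ConcentrationIndexResults",
    "concentration_index",
    "concentration_curve",
    "curve_area_index",
    "ci_uncertainty",
]


def _validate(y, ranks, weights):
    y = np.asarray(y, dtype=float)
    r = np.asarray(ranks, dtype=float)
    if weights is None:
        w = np.ones_like(y)
    else:
        w = np.asarray(weights, dtype=float)
    if not (y.shape == r.shape == w.shape) or y.ndim != 1 or y.size == 0:
        raise ValueError("y, ranks and weights must be equal-length 1-d arrays")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive total")
    if np.any(r <= 0) or np.any(r >= 1):
        raise ValueError("ranks must lie strictly inside (0, 1)")
    return y, r, w


def _wcov(a, b, w):
    wt = w / w.sum()
    return np.sum(wt * (a - np.sum(wt * a)) * (b - np.sum(wt * b)))


def concentration_index(y: ArrayLike, ranks: ArrayLike, weights: ArrayLike | None = None) -> float:
    """Point estimate C = 2 cov_w(y, R) / mu.

    Raises ValueError when the weighted mean of y is zero (index undefined).
    """
    y, r, w = _validate(y, ranks, weights)
    mu = np.average(y, weights=w)
    if mu == 0:
        raise ValueError("outcome mean is zero; concentration index undefined")
    return float(2.0 * _wcov(y, r, w) / mu)


def concentration_curve(y: ArrayLike, ranks: ArrayLike, weights: ArrayLike | None = None) -> pd.DataFrame:
    """Concentration curve vertices, one per distinct SES rank.

    Returns a DataFrame with columns ``pop_share`` (cumulative weighted
    population share) and ``outcome_share`` (cumulative weighted outcome
    share), beginning at (0, 0) and ending at (1, 1).  Tie groups (equal
    ranks) collapse to a single vertex so the trapezoid-area index agrees
    with the covariance form to machine precision.
    """
    y, r, w = _validate(y, ranks, weights)
    mu = np.average(y, weights=w)
    if mu == 0:
        raise ValueError("outcome mean is zero; curve undefined")
    order = np.argsort(r, kind="stable")
    r_s, y_s, w_s = r[order], y[order], w[order]
    start = np.r_[True, r_s[1:] != r_s[:-1]]
    gid = np.cumsum(start) - 1
    gw = np.bincount(gid, weights=w_s)
    gyw = np.bincount(gid, weights=w_s * y_s)
    pop = np.r_[0.0, np.cumsum(gw)] / w_s.sum()
    out = np.r_[0.0, np.cumsum(gyw)] / gyw.sum()
    return pd.DataFrame({"pop_share": pop, "outcome_share": out})


def curve_area_index(curve: pd.DataFrame | ArrayLike) -> float:
    """Index from curve geometry: twice the area between diagonal and curve.

    ``C = 1 - 2 * (trapezoid area under the curve)``; a curve above the
    diagonal (pro-poor concentration) yields a negative index.
    """
    if isinstance(curve, pd.DataFrame):
        x = curve["pop_share"].to_numpy(float)
        f = curve["outcome_share"].to_numpy(float)
    else:
        arr = np.asarray(curve, dtype=float)
        x, f = arr[:, 0], arr[:, 1]
    if np.any(np.diff(x) < 0) or np.any(np.diff(f) < -1e-12):
        raise ValueError("curve points must be sorted with nondecreasing ordinates")
    if not (abs(x[0]) < 1e-12 and abs(f[0]) < 1e-12 and abs(x[-1] - 1) < 1e-12 and abs(f[-1] - 1) < 1e-12):
        raise ValueError("curve must start at (0,0) and end at (1,1)")
    area = np.trapezoid(f, x)
    return float(1.0 - 2.0 * area)


def ci_uncertainty(y: ArrayLike, ranks: ArrayLike, weights: ArrayLike | None = None,
                   alpha: float = 0.05) -> tuple[float, float, tuple[float, float]]:
    """(C, robust SE, (lower, upper)) via the convenient regression."""
    y, r, w = _validate(y, ranks, weights)
    if y.size < 3:
        raise ValueError("at least 3 observations required for a standard error")
    mu = np.average(y, weights=w)
    if mu == 0:
        raise ValueError("outcome mean is zero; concentration index undefined")
    var_r = _wcov(r, r, w)
    if var_r <= 0:
        raise ValueError("degenerate rank variance")
    lhs = 2.0 * var_r * y / mu
    exog = sm.add_constant(r)
    fit = sm.WLS(lhs, exog, weights=w).fit(cov_type="HC0")
    c = float(fit.params[1])
    se = float(fit.bse[1])
    z = stats.norm.ppf(1 - alpha / 2)
    return c, se, (c - z * se, c + z * se)


@dataclass
class ConcentrationIndexResults:
    """Fitted concentration index with uncertainty and curve ordinates."""

    index: float
    se: float
    conf_int: tuple[float, float]
    mean: float
    nobs: int
    curve: pd.DataFrame = field(repr=False)
    outcome_name: str = "y"

    def normalized(self, method: str = "wagstaff") -> float:
        """Bounded-outcome correction of the plain index (optional post hoc).

        ``wagstaff``: C / (1 - mu); ``erreygers``: 4 * mu * C, both for an
        outcome bounded in [0, 1].  The plain index is what is reported by
        default.
        """
        if method == "wagstaff":
            if self.mean >= 1:
                raise ValueError("Wagstaff normalization undefined for mu >= 1")
            return self.index / (1.0 - self.mean)
        if method == "erreygers":
            return 4.0 * self.mean * self.index
        raise ValueError(f"unknown normalization {method!r}")

    def summary(self) -> str:
        lo, hi = self.conf_int
        return (
            f"Concentration index of {self.outcome_name}\n"
            f"{'=' * 44}\n"
            f"n                 {self.nobs:>12d}\n"
            f"mean outcome      {self.mean:>12.4f}\n"
            f"index C           {self.index:>12.4f}\n"
            f"robust SE         {self.se:>12.4f}\n"
            f"95% CI            [{lo:.4f}, {hi:.4f}]\n"
        )

    def to_frame(self) -> pd.DataFrame:
        lo, hi = self.conf_int
        return pd.DataFrame(
            {"outcome": [self.outcome_name], "n": [self.nobs], "mean": [self.mean],
             "index": [self.index], "se": [self.se], "ci_low": [lo], "ci_high": [hi]}
        )

    def plot(self, ax=None, shade_ci: bool = True):
        """Concentration curve against the equality diagonal."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        x = self.curve["pop_share"]
        f = self.curve["outcome_share"]
        ax.plot([0, 1], [0, 1], "k--", lw=1, label="equality")
        ax.plot(x, f, lw=1.5, label="concentration curve")
        if shade_ci and self.se > 0:
            # first-order band: shift proportional to the index CI half-width
            half = 1.96 * self.se / 2.0
            ax.fill_between(x, f - half * 4 * x * (1 - x), f + half * 4 * x * (1 - x), alpha=0.2)
        ax.set_xlabel("cumulative population share (poorest first)")
        ax.set_ylabel(f"cumulative share of {self.outcome_name}")
        ax.set_xlim(0, 1)
        ax.set_ylim(0, 1)
        ax.legend(loc="lower right", frameon=False)
        return ax


class ConcentrationIndex:
    """Concentration-index model for an outcome ranked by an SES measure.

    Parameters
    ----------
    y : array-like
        Outcome (binary indicator or nonnegative quantity).
    ses : array-like
        Continuous SES measure used for ranking (e.g. per-capita expenditure).
    weights : array-like, optional
        Sampling weights; default unweighted.
    """

    def __init__(self, y, ses, weights=None, outcome_name: str = "y"):
        self.y = np.asarray(y, dtype=float)
        self.ranks = weighted_fractional_rank(ses, weights)
        self.weights = None if weights is None else np.asarray(weights, dtype=float)
        self.outcome_name = outcome_name

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, outcome: str, ses: str = "pce",
                       weights: str | None = None) -> "ConcentrationIndex":
        w = df[weights].to_numpy(float) if weights else None
        return cls(df[outcome].to_numpy(float), df[ses].to_numpy(float), w, outcome_name=outcome)

    def fit(self) -> ConcentrationIndexResults:
        c, se, ci = ci_uncertainty(self.y, self.ranks, self.weights)
        w = self.weights if self.weights is not None else np.ones_like(self.y)
        mu = float(np.average(self.y, weights=w))
        curve = concentration_curve(self.y, self.ranks, self.weights)
        return ConcentrationIndexResults(
            index=c, se=se, conf_int=ci, mean=mu, nobs=self.y.size,
            curve=curve, outcome_name=self.outcome_name,
        )
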