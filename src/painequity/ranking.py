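"""Weighted fractional ranks for socioeconomic ordering.

The fractional rank R_i places each individual at the weighted midpoint of
their position in the SES ordering: sort ascending by the SES measure and set

    R_i = (cumulative weight of strictly poorer individuals + w_i / 2) / W.

Individuals tied on the SES measure receive the average rank over all tie
orders, which equals (weight before the tie group + half the group's total
weight) / W for every member.  The weighted mean of R is exactly 0.5, a
property the concentration index relies on.
"""

from __future__ import annotations

import numpy as np
from numpy.typing import ArrayLike


def weighted_fractional_rank(ses: ArrayLike, weights: ArrayLike | None = None) -> np.ndarray:
    """Midpoint fractional ranks in (0, 1) of `ses` under sampling `weights`.

    Parameters
    ----------
    ses : array-like of float
        Socioeconomic measure (e.g. per-capita expenditure). Only the ordering
        matters; ties are averaged.
    weights : array-like of float, optional
        Nonnegative sampling weights; default all ones.

    Returns
    -------
    ndarray
        Ranks aligned with the input order, weighted mean exactly 0.5.
    """
    ses = np.asarray(ses, dtype=float)
    if ses.ndim != 1 or ses.size == 0:
        raise ValueError("ses must be a nonempty 1-d array")
    if not np.all(np.isfinite(ses)):
        raise ValueError("ses contains non-finite values")
    if weights is None:
        w = np.ones_like(ses)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != ses.shape:
            raise ValueError("weights must match ses in length")
        if np.any(w < 0) or not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite and nonnegative")
    total = w.sum()
    if total <= 0:
        raise ValueError("total weight must be positive")

    order = np.argsort(ses, kind="stable")
    s_sorted = ses[order]
    w_sorted = w[order]

    # tie groups share the rank (weight below group + group weight / 2) / W
    group_start = np.r_[True, s_sorted[1:] != s_sorted[:-1]]
    group_id = np.cumsum(group_start) - 1
    group_w = np.bincount(group_id, weights=w_sorted)
    cum_before = np.r_[0.0, np.cumsum(group_w)[:-1]]
    rank_sorted = (cum_before[group_id] + group_w[group_id] / 2.0) / total

    ranks = np.empty_like(rank_sorted)
    ranks[order] = rank_sorted
    return ranks
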