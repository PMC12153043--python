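"""Cultivation-study statistics and the two-regime piecewise regression.

Operates on long-format colony records (one row per colony per observation
day) with columns ``colony_id, phi, day, n_cells, n_viable, alive, l_um,
l0_um``.  A colony counts as alive while at least one of its cells shows a
fluorescent (chlorophyll) signal, i.e. ``n_viable >= 1``; averages are taken
over living colonies only, dead colonies staying frozen at their last size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "SegmentFit",
    "TwoRegimeFit",
    "TwoRegimeRegression",
    "living_fraction",
    "mean_cells_per_colony",
    "normalized_colony_size",
    "colony_size_ratio",
    "cell_number_histogram",
    "viable_cell_fraction",
    "cells_variance",
    "two_regime_fit",
]


def _at_day(records: pd.DataFrame, day: float) -> pd.DataFrame:
    sub = records[records["day"] == day]
    if sub.empty:
        raise ValueError(f"no records at day {day}")
    return sub


def living_fraction(records: pd.DataFrame, day: float) -> float:
    """Fraction of colonies alive (>= 1 fluorescent cell) at a given day."""
    sub = _at_day(records, day)
    return float(sub["alive"].mean())


def mean_cells_per_colony(records: pd.DataFrame, day: float,
                          living_only: bool = True) -> tuple[float, float]:
    """Mean cell count per colony and its standard error (sd / sqrt(n))."""
    sub = _at_day(records, day)
    if living_only:
        sub = sub[sub["alive"]]
    if sub.empty:
        raise ValueError(f"no living colonies at day {day}")
    n = sub["n_cells"].to_numpy(dtype=float)
    se = n.std(ddof=1) / math.sqrt(n.size) if n.size > 1 else 0.0
    return float(n.mean()), float(se)


def normalized_colony_size(records: pd.DataFrame, day: float,
                           living_only: bool = True) -> float:
    """Mean colony size l relative to the founder size l0 at a given day."""
    sub = _at_day(records, day)
    if living_only:
        sub = sub[sub["alive"]]
    if sub.empty:
        raise ValueError(f"no living colonies at day {day}")
    l0 = sub["l0_um"].to_numpy(dtype=float)
    if np.any(l0 <= 0):
        raise ValueError("l0 must be > 0")
    return float((sub["l_um"].to_numpy() / l0).mean())


def colony_size_ratio(n_cells, p: float):
    """Geometry rule for synthetic colonies: l/l0 = n_cells**p, with p = 1 a
    cell chain and p = 1/3 a close-packed sphere."""
    return np.asarray(n_cells, dtype=float) ** p


def cell_number_histogram(records: pd.DataFrame, day: float, bin_edges):
    """Fraction of living colonies per cell-count bin (sums to 1).

    Bins follow :func:`numpy.histogram` conventions (right-open, last bin
    closed); edges must cover all observed counts.
    """
    sub = _at_day(records, day)
    sub = sub[sub["alive"]]
    if sub.empty:
        raise ValueError(f"no living colonies at day {day}")
    counts = sub["n_cells"].to_numpy(dtype=float)
    edges = np.asarray(bin_edges, dtype=float)
    if counts.min() < edges[0] or counts.max() > edges[-1]:
        raise ValueError("bin edges do not cover the observed cell counts")
    hist, _ = np.histogram(counts, bins=edges)
    return hist / hist.sum()


def viable_cell_fraction(records: pd.DataFrame, day: float) -> float:
    """Fraction of viable cells among all cells of living colonies."""
    sub = _at_day(records, day)
    sub = sub[sub["alive"]]
    if sub.empty:
        raise ValueError(f"no living colonies at day {day}")
    return float(sub["n_viable"].sum() / sub["n_cells"].sum())


def cells_variance(records: pd.DataFrame, day: float) -> float:
    """Unbiased sample variance of cell counts across living colonies."""
    sub = _at_day(records, day)
    sub = sub[sub["alive"]]
    if len(sub) < 2:
        raise ValueError("need >= 2 living colonies for a variance")
    return float(sub["n_cells"].to_numpy(dtype=float).var(ddof=1))


# -- two-regime piecewise regression ------------------------------------------

@dataclass
class SegmentFit:
    """OLS line y = intercept + slope * phi on one side of the breakpoint."""

    slope: float
    intercept: float
    se_slope: float
    p_value: float
    n: int


@dataclass
class TwoRegimeFit:
    breakpoint: float
    below: SegmentFit
    above: SegmentFit


def _ols_segment(x: np.ndarray, y: np.ndarray) -> SegmentFit:
    if x.size < 3:
        raise ValueError("each segment needs >= 3 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate segment: all phi values equal")
    res = stats.linregress(x, y)
    p = res.pvalue
    if not np.isfinite(p):
        # zero-residual data: an exactly flat segment carries no evidence
        # against slope = 0 (p = 1); an exact nonzero slope is certain (p = 0)
        p = 1.0 if np.isclose(res.slope, 0.0) else 0.0
    return SegmentFit(slope=float(res.slope), intercept=float(res.intercept),
                      se_slope=float(res.stderr), p_value=float(p), n=int(x.size))


class TwoRegimeRegression(BaseEstimator, RegressorMixin):
    """Piecewise linear regression with a fixed breakpoint.

    Separate ordinary least-squares lines are fitted below and above the
    breakpoint, with the boundary point included in both segments (matching
    ranges quoted as, e.g., 0-2% and 2-7%).  Each slope carries a two-sided
    t-test p-value against slope = 0 with n - 2 degrees of freedom.

    Fitted attributes: ``below_`` and ``above_`` (:class:`SegmentFit`) and
    ``result_`` (:class:`TwoRegimeFit`).
    """

    def __init__(self, breakpoint: float = 2.0):
        self.breakpoint = breakpoint

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if x.size != y.size:
            raise ValueError("x and y must have equal length")
        lo = x <= self.breakpoint
        hi = x >= self.breakpoint
        self.below_ = _ols_segment(x[lo], y[lo])
        self.above_ = _ols_segment(x[hi], y[hi])
        self.result_ = TwoRegimeFit(self.breakpoint, self.below_, self.above_)
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).ravel()
        seg = np.where(x <= self.breakpoint, 0, 1)
        out = np.empty_like(x)
        for s, fit in ((0, self.below_), (1, self.above_)):
            m = seg == s
            out[m] = fit.intercept + fit.slope * x[m]
        return out


def two_regime_fit(x, y, breakpoint: float = 2.0) -> TwoRegimeFit:
    """Two-segment OLS split at ``breakpoint`` (boundary point in both)."""
    return TwoRegimeRegression(breakpoint=breakpoint).fit(x, y).result_
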