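"""Precision drift over time and log-normal concentration structure.

Long-deployment sensor performance is tracked two ways:

* **drift**: ordinary least squares of pair precision on time of operation
  (days since the first observation).  The slope is a per-day change in
  precision; expressed relative to the fitted starting precision and
  annualised (×365) it becomes a relative annual change in percent, the
  quantity that is invariant to the choice of time origin.
* **distribution**: ambient and indoor PM concentrations are approximately
  log-normal, so log-concentration against normal scores (a probability
  plot) is nearly straight.  The least-squares line of log10(value) on
  normal score gives the geometric mean (10^intercept) and geometric
  standard deviation (10^slope); the fit R² quantifies departure from
  log-normality, e.g. wildfire-inflated upper tails.

Zeros (produced by vendor thresholding, never by the ALT conversion) cannot
be log-transformed; they must be excluded upstream and accounted for with
:func:`zero_exclusion_report`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "TrendResult",
    "QQResult",
    "precision_trend",
    "relative_annual_change",
    "lognormal_probability_stats",
    "zero_exclusion_report",
    "PrecisionTrend",
    "LognormalQQ",
]

DAYS_PER_YEAR = 365.0


@dataclass(frozen=True)
class TrendResult:
    """Summary of a precision-on-time OLS fit (one drift-table column)."""

    n: int
    intercept: float
    intercept_se: float
    slope_per_day: float
    slope_se: float
    r2_adj: float
    se_of_estimate: float
    f_value: float
    z: float  # slope / SE(slope)
    p_value: float
    starting_precision: float  # fitted value at the first timestamp
    ending_precision: float  # fitted value at the last timestamp
    span_days: float

    @property
    def relative_annual_change_pct(self) -> float:
        """100 × slope × 365 / starting precision."""
        return 100.0 * self.slope_per_day * DAYS_PER_YEAR / self.starting_precision

    def to_dict(self) -> dict:
        d = asdict(self)
        d["relative_annual_change_pct"] = self.relative_annual_change_pct
        return d


def relative_annual_change(slope_per_day: float, starting_precision: float) -> float:
    """Annualised drift relative to the starting precision, in percent."""
    if starting_precision <= 0:
        raise ValueError("starting precision must be > 0")
    return 100.0 * slope_per_day * DAYS_PER_YEAR / starting_precision


def _to_days(times) -> np.ndarray:
    """Timestamps (or numeric day values) -> float days since the first."""
    arr = np.asarray(times)
    if np.issubdtype(arr.dtype, np.number):
        t = arr.astype(float)
    else:
        t = pd.to_datetime(arr).astype("int64").to_numpy() / (86400.0 * 1e9)
    return t - t[0]


def precision_trend(times, precisions) -> TrendResult:
    """OLS of precision on days-since-start; see :class:`TrendResult`.

    Times may be timestamps or already-numeric day offsets.  Requires at
    least three observations spanning a positive time interval.
    """
    days = _to_days(times)
    y = np.asarray(precisions, dtype=float)
    if days.size != y.size:
        raise ValueError("times and precisions must align")
    if days.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(days) <= 0:
        raise ValueError("times are degenerate (zero span)")
    model = sm.OLS(y, sm.add_constant(days)).fit()
    intercept, slope = model.params
    se_int, se_slope = model.bse
    start = float(intercept)  # fitted value at day 0
    end = float(intercept + slope * days.max())
    return TrendResult(
        n=int(days.size),
        intercept=float(intercept),
        intercept_se=float(se_int),
        slope_per_day=float(slope),
        slope_se=float(se_slope),
        r2_adj=float(model.rsquared_adj),
        se_of_estimate=float(np.sqrt(model.mse_resid)),
        f_value=float(model.fvalue),
        z=float(slope / se_slope) if se_slope > 0 else math.copysign(math.inf, slope),
        p_value=float(model.pvalues[1]),
        starting_precision=start,
        ending_precision=end,
        span_days=float(np.ptp(days)),
    )


@dataclass(frozen=True)
class QQResult:
    """Log-normal probability-plot fit: GM, GSD and linearity."""

    n: int
    gm: float
    gsd: float
    r2: float
    positions_rule: str

    def __post_init__(self) -> None:
        if self.gsd < 1 - 1e-12:
            raise ValueError("GSD must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


_POSITION_RULES = {
    "blom": lambda i, n: (i - 0.375) / (n + 0.25),
    "hazen": lambda i, n: (i - 0.5) / n,
}


def lognormal_probability_stats(values, positions_rule: str = "blom") -> QQResult:
    """Fit log10(value) against normal scores from plotting positions.

    All values must be strictly positive; zeros must be excluded (and
    counted) upstream with :func:`zero_exclusion_report`.  The Blom rule
    (i − 0.375)/(n + 0.25) is the default for normal scores; Hazen
    (i − 0.5)/n is available and the rule used is echoed in the result.
    """
    arr = np.sort(np.asarray(values, dtype=float))
    if arr.size < 3:
        raise ValueError("need at least 3 values")
    if np.any(arr <= 0):
        raise ValueError(
            "values must be > 0 for a logarithmic probability plot; "
            "exclude zeros upstream (see zero_exclusion_report)"
        )
    try:
        rule = _POSITION_RULES[positions_rule]
    except KeyError:
        raise ValueError(f"unknown positions_rule {positions_rule!r}") from None
    i = np.arange(1, arr.size + 1, dtype=float)
    scores = stats.norm.ppf(rule(i, arr.size))
    logv = np.log10(arr)
    if np.ptp(logv) == 0:  # degenerate: all values equal
        return QQResult(n=arr.size, gm=float(arr[0]), gsd=1.0, r2=0.0, positions_rule=positions_rule)
    fit = stats.linregress(scores, logv)
    return QQResult(
        n=int(arr.size),
        gm=float(10.0**fit.intercept),
        gsd=float(10.0**fit.slope),
        r2=float(fit.rvalue**2),
        positions_rule=positions_rule,
    )


def zero_exclusion_report(values) -> tuple[np.ndarray, int, float]:
    """Partition a non-negative series into (positive subset, n zeros, fraction).

    The fraction is exact; round to two decimals only for display.
    """
    arr = np.asarray(values, dtype=float)
    if np.any(arr < 0):
        raise ValueError("values must be >= 0")
    positive = arr[arr > 0]
    n_excluded = int(arr.size - positive.size)
    fraction = n_excluded / arr.size if arr.size else float("nan")
    return positive, n_excluded, fraction


class PrecisionTrend(BaseEstimator, RegressorMixin):
    """Estimator form of :func:`precision_trend`.

    ``fit(times, precisions)`` exposes ``slope_per_day_``, ``result_`` and
    supports ``predict(times)`` of fitted precision (times on the same
    clock as the training data).
    """

    def fit(self, X, y) -> "PrecisionTrend":
        self._t0 = np.asarray(X)[0]
        self.result_ = precision_trend(X, y)
        self.slope_per_day_ = self.result_.slope_per_day
        self.intercept_ = self.result_.intercept
        return self

    def predict(self, X) -> np.ndarray:
        days = _to_days(np.concatenate([[self._t0], np.asarray(X)]))[1:]
        return self.intercept_ + self.slope_per_day_ * days


class LognormalQQ(BaseEstimator):
    """Estimator form of :func:`lognormal_probability_stats`.

    ``fit(values)`` exposes ``gm_``, ``gsd_``, ``r2_`` and ``result_``.
    """

    def __init__(self, positions_rule: str = "blom"):
        self.positions_rule = positions_rule

    def fit(self, X, y=None) -> "LognormalQQ":
        self.result_ = lognormal_probability_stats(np.ravel(X), self.positions_rule)
        self.gm_ = self.result_.gm
        self.gsd_ = self.result_.gsd
        self.r2_ = self.result_.r2
        return self
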