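"""Duplicate-channel precision statistics, filtering, data-loss and bias accounting.

A PurpleAir-style monitor carries two independent sensors (*a* and *b*)
sampling the same air.  Pair precision is ``|a - b| / (a + b)``: 0 for
identical readings, 1 when one channel reads zero, undefined (NaN) when both
do.  Records are conventionally accepted when precision is strictly below a
cutoff (0.2, i.e. better than 20%).  Because precision is scale-invariant it
is unchanged by any calibration factor applied to both channels.

For a duplicate pair the mean is µ = (a+b)/2 and the two-point sample
standard deviation is σ = |a-b|/√2, giving the exact identity
µ/σ = 1 / (√2 · precision) that links the precision cutoff to
signal-to-noise criteria (precision < 1/(3√2) ≈ 0.2357 iff µ/σ > 3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "pair_precision",
    "PrecisionSummary",
    "LossReport",
    "BiasResult",
    "apply_precision_filter",
    "precision_summary",
    "relative_bias",
    "data_loss_comparison",
    "PrecisionFilter",
]


def pair_precision(a, b):
    """``|a - b| / (a + b)`` elementwise; NaN where ``a + b == 0``.

    Inputs must be >= 0.  Returns a float scalar for scalar input.
    """
    a_arr = np.asarray(a, dtype=float)
    b_arr = np.asarray(b, dtype=float)
    if np.any(a_arr < 0) or np.any(b_arr < 0):
        raise ValueError("pair precision requires non-negative readings")
    total = a_arr + b_arr
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(total > 0, np.abs(a_arr - b_arr) / total, np.nan)
    if np.isscalar(a) and np.isscalar(b):
        return float(p)
    return p


@dataclass(frozen=True)
class PrecisionSummary:
    """Distributional summary of a precision sample (one Table-style row)."""

    algorithm: str
    filter_description: str
    valid_n: int
    mean: float
    std_err: float
    lower_quartile: float
    median: float
    upper_quartile: float
    p90: float
    max: float

    def __post_init__(self) -> None:
        q = (self.lower_quartile, self.median, self.upper_quartile, self.p90, self.max)
        if any(x > y + 1e-12 for x, y in zip(q, q[1:])):
            raise ValueError("quantiles must be ordered")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class LossReport:
    """Conservation ledger for one filtered stream.

    total_obs = lost_to_zero + lost_to_precision + remaining, always.
    ``lost_to_zero`` counts pairs whose precision is undefined because both
    channels reported zero (only possible for vendor algorithms; the ALT
    conversion is strictly positive).  ``lost_to_precision`` counts pairs
    removed by the precision cutoff.
    """

    total_obs: int
    lost_to_zero: int
    lost_to_precision: int
    remaining: int

    def __post_init__(self) -> None:
        if self.total_obs != self.lost_to_zero + self.lost_to_precision + self.remaining:
            raise ValueError("loss report does not conserve observations")
        if min(self.total_obs, self.lost_to_zero, self.lost_to_precision, self.remaining) < 0:
            raise ValueError("loss report counts must be >= 0")

    @property
    def fraction_lost(self) -> float:
        if self.total_obs == 0:
            return float("nan")
        return (self.lost_to_zero + self.lost_to_precision) / self.total_obs

    @property
    def fraction_remaining(self) -> float:
        return 1.0 - self.fraction_lost if self.total_obs else float("nan")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fraction_lost"] = self.fraction_lost
        return d

    @classmethod
    def from_counts(cls, total_obs: int, remaining: int, lost_to_zero: int = 0) -> "LossReport":
        """Build a report from headline counts (precision loss is the residual)."""
        return cls(
            total_obs=total_obs,
            lost_to_zero=lost_to_zero,
            lost_to_precision=total_obs - remaining - lost_to_zero,
            remaining=remaining,
        )


def apply_precision_filter(
    paired: pd.DataFrame,
    cutoff: float = 0.2,
    precision_source: str = "self",
    companion: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, LossReport]:
    """Retain paired observations with precision strictly below ``cutoff``.

    ``paired`` is a paired-observation frame (columns ``timestamp, a_value,
    b_value, mu, sigma, precision``).  With ``precision_source="self"`` each
    observation is judged by its own precision; with ``"alt"`` the precision
    is taken from the ``companion`` frame (typically the ALT-converted pairs
    of the same monitor) matched on timestamp — this reproduces the
    "vendor values gated by ALT precision" accounting variant.

    Undefined-precision pairs (both channels zero) are counted as
    ``lost_to_zero``; a pair with one zero and one positive channel has
    precision 1 and is a valid (if poor) pair, removed by the cutoff rather
    than the zero ledger.  Filtering is idempotent.
    """
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must be in (0, 1]")
    total = len(paired)
    if precision_source == "self":
        prec = paired["precision"].to_numpy(dtype=float)
    elif precision_source == "alt":
        if companion is None:
            raise ValueError("precision_source='alt' requires a companion paired series")
        comp = companion.set_index("timestamp")["precision"]
        prec = paired["timestamp"].map(comp).to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown precision_source {precision_source!r}")

    own = paired["precision"].to_numpy(dtype=float)
    zero_mask = np.isnan(own)  # both channels zero -> undefined precision
    keep = (~zero_mask) & ~np.isnan(prec) & (prec < cutoff)
    filtered = paired.loc[keep].reset_index(drop=True)
    report = LossReport(
        total_obs=total,
        lost_to_zero=int(zero_mask.sum()),
        lost_to_precision=int(total - zero_mask.sum() - keep.sum()),
        remaining=int(keep.sum()),
    )
    return filtered, report


def precision_summary(
    precisions,
    algorithm: str = "ALT_CF3",
    filter_description: str = "",
) -> PrecisionSummary:
    """Mean, SE (sd/√n) and empirical quantiles of a precision sample.

    Quantiles use linear interpolation between order statistics (the numpy
    default); the rule is fixed so published-style tables are reproducible.
    """
    arr = np.asarray(pd.Series(precisions).dropna(), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarise an empty precision sample")
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    q25, q50, q75, q90 = np.quantile(arr, [0.25, 0.5, 0.75, 0.9])
    return PrecisionSummary(
        algorithm=algorithm,
        filter_description=filter_description,
        valid_n=int(arr.size),
        mean=float(arr.mean()),
        std_err=sd / math.sqrt(arr.size),
        lower_quartile=float(q25),
        median=float(q50),
        upper_quartile=float(q75),
        p90=float(q90),
        max=float(arr.max()),
    )


@dataclass(frozen=True)
class BiasResult:
    """Per-sensor relative bias against the ensemble grand mean."""

    sensor_means: dict
    grand_mean: float
    per_sensor_bias_pct: dict
    overall_mean_abs_bias_pct: float
    overall_se_pct: float

    def to_dict(self) -> dict:
        return asdict(self)


def relative_bias(sensor_means: Mapping[str, float] | np.ndarray) -> BiasResult:
    """Relative bias of each sensor's mean PM against the mean of all sensors.

    bias_i = 100 · (mean_i − grand) / grand with grand the unweighted mean of
    the per-sensor means; the overall figure is the mean of |bias_i| with its
    standard error across sensors (all-positive magnitudes, matching how
    multi-sensor bias envelopes are conventionally quoted).
    """
    if isinstance(sensor_means, Mapping):
        labels = list(sensor_means)
        means = np.asarray([sensor_means[k] for k in labels], dtype=float)
    else:
        means = np.asarray(sensor_means, dtype=float)
        labels = [str(i) for i in range(means.size)]
    if means.size < 2:
        raise ValueError("need at least two sensors")
    if np.any(means < 0):
        raise ValueError("sensor means must be >= 0")
    grand = float(means.mean())
    if grand <= 0:
        raise ValueError("grand mean must be > 0")
    bias = 100.0 * (means - grand) / grand
    abs_bias = np.abs(bias)
    se = float(np.std(abs_bias, ddof=1) / math.sqrt(abs_bias.size)) if abs_bias.size > 1 else 0.0
    return BiasResult(
        sensor_means=dict(zip(labels, means.tolist())),
        grand_mean=grand,
        per_sensor_bias_pct=dict(zip(labels, bias.tolist())),
        overall_mean_abs_bias_pct=float(abs_bias.mean()),
        overall_se_pct=se,
    )


def data_loss_comparison(alt_report: LossReport, cf1_report: LossReport) -> pd.DataFrame:
    """Side-by-side retention comparison of two algorithms on the same stream.

    Raises if the totals differ (the reports must describe the same
    underlying observations) or if the ALT report claims zero-losses, which
    the strictly-positive ALT conversion cannot produce.
    """
    if alt_report.total_obs != cf1_report.total_obs:
        raise ValueError("loss reports describe different observation totals")
    if alt_report.lost_to_zero > 0:
        raise ValueError("ALT conversion never yields zeros; inconsistent report")
    rows = []
    for name, rep in (("ALT_CF3", alt_report), ("CF1", cf1_report)):
        rows.append(
            {
                "algorithm": name,
                "total_obs": rep.total_obs,
                "lost_to_zero": rep.lost_to_zero,
                "lost_to_precision": rep.lost_to_precision,
                "remaining": rep.remaining,
                "fraction_remaining": rep.fraction_remaining,
            }
        )
    return pd.DataFrame(rows)


class PrecisionFilter(BaseEstimator, TransformerMixin):
    """Estimator wrapper around :func:`apply_precision_filter`.

    ``transform(X)`` filters a paired-observation frame and stores the
    conservation ledger as ``loss_report_``.
    """

    def __init__(self, cutoff: float = 0.2, precision_source: str = "self", companion=None):
        self.cutoff = cutoff
        self.precision_source = precision_source
        self.companion = companion

    def fit(self, X=None, y=None) -> "PrecisionFilter":
        if not 0 < self.cutoff <= 1:
            raise ValueError("cutoff must be in (0, 1]")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        filtered, report = apply_precision_filter(
            X, cutoff=self.cutoff, precision_source=self.precision_source, companion=self.companion
        )
        self.loss_report_ = report
        return filtered
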