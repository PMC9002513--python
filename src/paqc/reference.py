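"""Ratios of sensor PM2.5 to a co-located reference monitor, per source experiment.

For each particle-source experiment (cooking oils, meats, matches, ...)
the sensor and reference series are matched in time and summarised by their
arithmetic means; the comparison statistic is the ratio of means with the
first-order propagated standard error

    SE(ratio) = ratio · sqrt((SE_s/mean_s)² + (SE_r/mean_r)²),

assuming independence of the two mean errors.  When the particle density is
the controlling optical difference, the expected ratio is simply the ratio
of the assumed sensor aerosol density to the reference instrument's
calibrant density (e.g. 1 g/cm³ water vs 2.6 g/cm³ Arizona Road Dust gives
≈ 0.4).  Experiments in which any sensor record reaches the saturation
limit (~1 mg/m³) are flagged: their ratios are biased low and are not
comparable to unsaturated sources.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "RatioResult",
    "ratio_with_propagated_se",
    "expected_density_ratio",
    "experiment_table",
]


@dataclass(frozen=True)
class RatioResult:
    """Ratio of sensor-to-reference means for one source experiment."""

    source: str
    algorithm: str
    n: int
    sensor_mean: float
    sensor_se: float
    reference_mean: float
    reference_se: float
    saturated: bool

    @property
    def ratio(self) -> float:
        return self.sensor_mean / self.reference_mean

    @property
    def ratio_se(self) -> float:
        rel = math.hypot(
            self.sensor_se / self.sensor_mean if self.sensor_mean else 0.0,
            self.reference_se / self.reference_mean,
        )
        return self.ratio * rel

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ratio"] = self.ratio
        d["ratio_se"] = self.ratio_se
        return d


def _mean_se(arr: np.ndarray) -> tuple[float, float]:
    se = float(np.std(arr, ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else 0.0
    return float(arr.mean()), se


def ratio_with_propagated_se(
    sensor,
    reference,
    source: str = "",
    algorithm: str = "ALT_CF3",
    saturation_limit: float | None = 1000.0,
) -> RatioResult:
    """Ratio of means of two matched series with propagated SE.

    ``sensor`` and ``reference`` must be equal-length, already time-matched
    series for one source experiment.  The saturation flag is set when any
    sensor record reaches ``saturation_limit`` (pass ``None`` to skip the
    check).
    """
    s = np.asarray(sensor, dtype=float)
    r = np.asarray(reference, dtype=float)
    if s.size != r.size:
        raise ValueError("sensor and reference series must be matched (equal length)")
    if s.size == 0:
        raise ValueError("empty experiment: no records after filtering")
    s_mean, s_se = _mean_se(s)
    r_mean, r_se = _mean_se(r)
    if r_mean <= 0:
        raise ValueError("reference mean must be > 0")
    saturated = bool(saturation_limit is not None and np.any(s >= saturation_limit))
    return RatioResult(
        source=source,
        algorithm=algorithm,
        n=int(s.size),
        sensor_mean=s_mean,
        sensor_se=s_se,
        reference_mean=r_mean,
        reference_se=r_se,
        saturated=saturated,
    )


def expected_density_ratio(sensor_density: float, reference_calibrant_density: float) -> float:
    """Sensor/reference ratio expected when particle density dominates response."""
    if sensor_density <= 0 or reference_calibrant_density <= 0:
        raise ValueError("densities must be > 0")
    return sensor_density / reference_calibrant_density


def experiment_table(results: Iterable[RatioResult]) -> pd.DataFrame:
    """One row per (source, algorithm): ratio, SE, n and the saturation flag.

    Raises on an empty collection — an experiment set that lost every record
    to filtering has no comparable ratios and should be reported upstream
    with its loss diagnostics.
    """
    rows = [r.to_dict() for r in results]
    if not rows:
        raise ValueError(
            "no ratio results to tabulate; all experiments were lost to filtering "
            "(check the precision-loss reports)"
        )
    df = pd.DataFrame(rows)
    cols = ["source", "algorithm", "n", "ratio", "ratio_se", "sensor_mean", "sensor_se",
            "reference_mean", "reference_se", "saturated"]
    return df[cols].sort_values(["source", "algorithm"], kind="stable").reset_index(drop=True)
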