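"""Size-bin particle counts to mass concentration (the ALT-CF3 algorithm).

Optical particle counters such as the Plantower PMS 5003 report *cumulative*
particle number concentrations per deciliter of air above a set of diameter
thresholds (>0.3, >0.5, >1.0, >2.5 µm).  Differencing adjacent thresholds
gives the number concentration in each size bin.  Treating every particle in
a bin as a sphere of a single representative diameter ``d`` (geometric mean
of the bin bounds by default), the particle volume is ``π d³ / 6``; summing
``N · π d³ / 6`` over bins, multiplying by an assumed particle density and a
calibration factor (CF) obtained against reference monitors yields a mass
concentration in µg/m³.  With the three bins below 2.5 µm this is a PM2.5
estimate; with the two smallest bins it is a PM1 estimate.

The default configuration — density 1 g/cm³ (water), CF = 3, geometric-mean
diameters — is the ALT-CF3 parameterisation.  The vendor's proprietary CF1 /
CF_ATM outputs are never computed here; they are carried through from input
files and only *accounted for* (zero counting, saturation flagging).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "BinScheme",
    "AlgorithmConfig",
    "ZeroReport",
    "cumulative_to_bins",
    "representative_diameters",
    "alt_pm",
    "flag_saturation",
    "count_reported_zeros",
    "AltMassConverter",
]

#: default size-bin bounds in µm (contiguous, strictly increasing)
DEFAULT_BOUNDS: tuple[tuple[float, float], ...] = ((0.3, 0.5), (0.5, 1.0), (1.0, 2.5))


@dataclass(frozen=True)
class BinScheme:
    """Diameter intervals and the rule mapping each to one representative diameter.

    Parameters
    ----------
    bounds
        Ordered ``(lo, hi)`` diameter intervals in µm.  Must be contiguous,
        strictly increasing and positive.
    diameter_rule
        ``"geometric"`` (``sqrt(lo*hi)``), ``"arithmetic"`` (``(lo+hi)/2``) or
        ``"explicit"`` (use ``explicit_diameters`` verbatim).  Diameters are
        always computed at full floating-point precision; the ``explicit``
        rule is the escape hatch for reproducing published rounded
        coefficient sets.
    explicit_diameters
        Required iff ``diameter_rule == "explicit"``; one diameter per bin.
    """

    bounds: tuple[tuple[float, float], ...] = DEFAULT_BOUNDS
    diameter_rule: str = "geometric"
    explicit_diameters: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not self.bounds:
            raise ValueError("bounds must contain at least one interval")
        prev_hi = None
        for lo, hi in self.bounds:
            if not (0 < lo < hi):
                raise ValueError(f"invalid interval ({lo}, {hi}): need 0 < lo < hi")
            if prev_hi is not None and not math.isclose(lo, prev_hi):
                raise ValueError("intervals must be contiguous")
            prev_hi = hi
        if self.diameter_rule not in ("geometric", "arithmetic", "explicit"):
            raise ValueError(f"unknown diameter_rule {self.diameter_rule!r}")
        if self.diameter_rule == "explicit":
            if self.explicit_diameters is None or len(self.explicit_diameters) != len(self.bounds):
                raise ValueError("explicit rule requires one diameter per interval")

    @property
    def thresholds(self) -> tuple[float, ...]:
        """Cumulative-count thresholds implied by the bounds (lo edges + final hi)."""
        return tuple(lo for lo, _ in self.bounds) + (self.bounds[-1][1],)

    @property
    def n_bins(self) -> int:
        return len(self.bounds)


def representative_diameters(scheme: BinScheme) -> np.ndarray:
    """Representative diameter (µm) of each bin under the scheme's rule."""
    if scheme.diameter_rule == "geometric":
        return np.array([math.sqrt(lo * hi) for lo, hi in scheme.bounds])
    if scheme.diameter_rule == "arithmetic":
        return np.array([(lo + hi) / 2.0 for lo, hi in scheme.bounds])
    return np.asarray(scheme.explicit_diameters, dtype=float)


@dataclass(frozen=True)
class AlgorithmConfig:
    """Parameters of the number-to-mass conversion.

    density is in g/cm³ (default 1, water); calibration_factor is the
    dimensionless CF against reference monitors (default 3, the ALT-CF3
    value); dl_to_m3 converts count concentrations from per-deciliter to
    per-m³ (10⁴ dL per m³); saturation_limit (µg/m³) is the concentration at
    and above which the sensor is considered out of range (~1 mg/m³).
    """

    density: float = 1.0
    calibration_factor: float = 3.0
    bin_scheme: BinScheme = field(default_factory=BinScheme)
    dl_to_m3: float = 1.0e4
    saturation_limit: float = 1000.0

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("density must be > 0")
        if self.calibration_factor <= 0:
            raise ValueError("calibration_factor must be > 0")
        if self.saturation_limit <= 0:
            raise ValueError("saturation_limit must be > 0")
        if self.dl_to_m3 <= 0:
            raise ValueError("dl_to_m3 must be > 0")

    def mass_coefficients(self) -> np.ndarray:
        """µg/m³ contributed by one count/dL in each bin.

        CF · ρ · (dL/m³ · 10⁻⁶ µg·cm³/(g·µm³)) · π d³ / 6 — with the default
        dl_to_m3 = 10⁴ the unit factor collapses to 10⁻².
        """
        d = representative_diameters(self.bin_scheme)
        unit = self.dl_to_m3 * 1.0e-6  # (counts/dL -> counts/m³) × (g·µm³/cm³ -> µg)
        return self.calibration_factor * self.density * unit * (math.pi / 6.0) * d**3


def cumulative_to_bins(counts_gt: Sequence[float] | np.ndarray, scheme: BinScheme | None = None) -> np.ndarray:
    """Difference cumulative ">threshold" counts into per-bin counts.

    ``counts_gt`` holds, for each record, the cumulative counts/dL above each
    ascending threshold (one more threshold than bins; the last threshold is
    the upper edge of the largest bin).  Accepts a 1-D array (one record) or a
    2-D array ``(n_records, n_thresholds)``.

    Raises ``ValueError`` if any cumulative sequence increases with the
    threshold or contains negative/non-finite values.
    """
    scheme = scheme or BinScheme()
    arr = np.asarray(counts_gt, dtype=float)
    squeeze = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if arr.shape[1] != scheme.n_bins + 1:
        raise ValueError(
            f"expected {scheme.n_bins + 1} cumulative thresholds, got {arr.shape[1]}"
        )
    if not np.all(np.isfinite(arr)) or np.any(arr < 0):
        raise ValueError("cumulative counts must be finite and >= 0")
    if np.any(np.diff(arr, axis=1) > 0):
        raise ValueError("cumulative counts must be non-increasing across ascending thresholds")
    bins = -np.diff(arr, axis=1)
    return bins[0] if squeeze else bins


def alt_pm(
    bins: Sequence[float] | np.ndarray,
    config: AlgorithmConfig | None = None,
    n_bins_used: int | None = None,
) -> np.ndarray | float:
    """Mass concentration (µg/m³) from per-bin counts/dL.

    ``n_bins_used`` restricts the sum to the smallest bins: with the default
    three-bin scheme, 2 gives PM1 and 3 (default) gives PM2.5.
    """
    config = config or AlgorithmConfig()
    arr = np.asarray(bins, dtype=float)
    squeeze = arr.ndim == 1
    arr = np.atleast_2d(arr)
    n_bins = config.bin_scheme.n_bins
    if arr.shape[1] != n_bins:
        raise ValueError(f"expected {n_bins} bins, got {arr.shape[1]}")
    if np.any(arr < 0):
        raise ValueError("bin counts must be >= 0")
    k = n_bins if n_bins_used is None else n_bins_used
    if not 1 <= k <= n_bins:
        raise ValueError(f"n_bins_used must be in [1, {n_bins}]")
    coef = config.mass_coefficients()[:k]
    out = arr[:, :k] @ coef
    return float(out[0]) if squeeze else out


def flag_saturation(value: np.ndarray | float, config: AlgorithmConfig | None = None) -> np.ndarray | bool:
    """True where ``value`` is at or above the saturation limit (inclusive).

    Saturation is an annotation: flagged records are interpretable but
    out-of-range, so callers should flag rather than drop them.
    """
    config = config or AlgorithmConfig()
    arr = np.asarray(value, dtype=float)
    out = arr >= config.saturation_limit
    return bool(out) if np.isscalar(value) or arr.ndim == 0 else out


@dataclass(frozen=True)
class ZeroReport:
    """Accounting of exact-zero values in a vendor-reported PM series."""

    sensor_id: str
    location: str
    n_obs: int
    n_zeros: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_zeros <= self.n_obs:
            raise ValueError("need 0 <= n_zeros <= n_obs")

    @property
    def fraction_zero(self) -> float:
        return self.n_zeros / self.n_obs if self.n_obs else float("nan")

    @property
    def fraction_zero_display(self) -> float:
        """Fraction rounded to two decimals for tabular display."""
        return round(self.fraction_zero, 2)

    @classmethod
    def from_counts(cls, n_obs: int, n_zeros: int, sensor_id: str = "", location: str = "") -> "ZeroReport":
        return cls(sensor_id=sensor_id, location=location, n_obs=n_obs, n_zeros=n_zeros)


def count_reported_zeros(values, sensor_id: str = "", location: str = "") -> ZeroReport:
    """Count exact zeros in a vendor PM2.5 series (values must be >= 0)."""
    arr = np.asarray(values, dtype=float)
    if np.any(arr < 0):
        raise ValueError("vendor PM values must be >= 0")
    return ZeroReport(
        sensor_id=sensor_id,
        location=location,
        n_obs=int(arr.size),
        n_zeros=int(np.count_nonzero(arr == 0)),
    )


class AltMassConverter(BaseEstimator, TransformerMixin):
    """Transformer from cumulative size-bin counts to mass concentration.

    ``transform(X)`` takes an ``(n_records, n_thresholds)`` array of
    cumulative counts/dL and returns a 1-D array of PM estimates in µg/m³.
    Stateless; ``fit`` only validates parameters.

    Parameters mirror :class:`AlgorithmConfig`; ``n_bins_used=3`` yields
    PM2.5 and ``n_bins_used=2`` PM1 under the default scheme.
    """

    def __init__(
        self,
        density: float = 1.0,
        calibration_factor: float = 3.0,
        diameter_rule: str = "geometric",
        explicit_diameters: tuple[float, ...] | None = None,
        saturation_limit: float = 1000.0,
        n_bins_used: int = 3,
    ):
        self.density = density
        self.calibration_factor = calibration_factor
        self.diameter_rule = diameter_rule
        self.explicit_diameters = explicit_diameters
        self.saturation_limit = saturation_limit
        self.n_bins_used = n_bins_used

    def _config(self) -> AlgorithmConfig:
        scheme = BinScheme(
            diameter_rule=self.diameter_rule,
            explicit_diameters=self.explicit_diameters,
        )
        return AlgorithmConfig(
            density=self.density,
            calibration_factor=self.calibration_factor,
            bin_scheme=scheme,
            saturation_limit=self.saturation_limit,
        )

    def fit(self, X=None, y=None) -> "AltMassConverter":
        self.config_ = self._config()
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "config_"):
            self.fit()
        bins = cumulative_to_bins(np.asarray(X, dtype=float), self.config_.bin_scheme)
        pm = alt_pm(np.atleast_2d(bins), self.config_, n_bins_used=self.n_bins_used)
        return np.asarray(pm, dtype=float)

    def saturated(self, pm) -> np.ndarray:
        """Saturation flags for already-converted PM values."""
        if not hasattr(self, "config_"):
            self.fit()
        return np.asarray(flag_saturation(np.asarray(pm, dtype=float), self.config_))
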