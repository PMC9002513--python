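"""Limit of detection for continuous duplicate-sensor streams.

For continuous collocated duplicates the detection limit is defined on the
pair statistics µ = (a+b)/2 and σ = |a-b|/√2: the LOD is the lowest mean
value above which more than 95% of observations satisfy µ/σ > 3.  Two
estimators are provided:

* a **block search** (the practical algorithm): sort by µ ascending, walk
  consecutive blocks of 100, and take the last block containing 5 or more
  failures (µ/σ < 3); the LOD is the largest failing µ in that block;
* an **exact tail scan** implementing the verbal definition directly: the
  smallest observed µ such that every evaluable tail above it passes the
  criterion.  It serves as the independent oracle for the block search.

Because µ/σ = 1/(√2·precision), an observation passes µ/σ > 3 exactly when
its pair precision is below 1/(3√2) ≈ 0.2357.  σ = 0 (identical channels)
counts as a pass: duplicate agreement is the strongest detection evidence.

The two estimators answer the same question with different resolution: the
block search is local (100-observation windows) while the tail scan is
cumulative, so they coincide only when the failure probability drops
sharply within about one block and most observations lie below the floor;
with smooth (e.g. Gaussian additive) noise the cumulative tail dilutes
failures and the exact scan settles systematically below the block answer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "LodResult",
    "lod_block_search",
    "lod_exact_oracle",
    "fraction_above_lod",
    "LodEstimator",
]


@dataclass(frozen=True)
class LodResult:
    """Detection limit plus method metadata and fraction-above accounting."""

    lod: float
    method: str  # "block" | "oracle"
    block_size: int | None
    ratio_threshold: float
    pass_fraction: float
    n_total: int
    n_above: int
    all_below: bool = False

    @property
    def fraction_above(self) -> float:
        """Percent of observations with µ strictly above the LOD."""
        return 100.0 * self.n_above / self.n_total if self.n_total else float("nan")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fraction_above"] = self.fraction_above
        return d


def _mu_sigma(paired, sigma=None) -> tuple[np.ndarray, np.ndarray]:
    """Accept a paired-observation DataFrame or explicit (mu, sigma) arrays."""
    if sigma is not None:
        return np.asarray(paired, dtype=float), np.asarray(sigma, dtype=float)
    if isinstance(paired, pd.DataFrame):
        return paired["mu"].to_numpy(dtype=float), paired["sigma"].to_numpy(dtype=float)
    raise TypeError("pass a paired DataFrame, or mu and sigma arrays")


def _pass_mask(mu: np.ndarray, sigma: np.ndarray, ratio_threshold: float) -> np.ndarray:
    # sigma == 0 means the duplicates agree exactly: µ/σ = +inf, a pass.
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(sigma > 0, mu / np.where(sigma > 0, sigma, 1.0), np.inf)
    return ratio > ratio_threshold


def lod_block_search(
    paired,
    sigma=None,
    block_size: int = 100,
    ratio_threshold: float = 3.0,
    max_fail_per_block: int | None = None,
) -> LodResult:
    """Blockwise LOD search on pair means sorted ascending.

    Observations are sorted by µ and partitioned into consecutive blocks of
    ``block_size``; a block *qualifies* when it contains at least
    ``max_fail_per_block`` failures (µ/σ < ratio_threshold; default 5 per
    100, i.e. a 95% criterion).  The final partial block uses the
    proportional threshold ``ceil(fail_rate × size)``.  The scan always runs
    to the end of the data, since higher qualifying blocks supersede lower
    ones; the LOD is the largest failing µ within the last qualifying block.

    If no block qualifies everything is detectable and the LOD is the
    smallest observed µ (reported with 100% above).  If every block
    qualifies the result carries ``all_below=True``.
    """
    mu, sig = _mu_sigma(paired, sigma)
    if mu.size == 0:
        raise ValueError("cannot estimate an LOD from an empty collection")
    if block_size < 10:
        raise ValueError("block_size must be >= 10")
    if max_fail_per_block is None:
        max_fail_per_block = max(1, math.ceil(0.05 * block_size))
    fail_rate = max_fail_per_block / block_size

    order = np.argsort(mu, kind="stable")
    mu_s = mu[order]
    ok = _pass_mask(mu, sig, ratio_threshold)[order]

    n = mu_s.size
    last_lod = None
    n_blocks = 0
    n_qualifying = 0
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        size = stop - start
        threshold = max_fail_per_block if size == block_size else max(1, math.ceil(fail_rate * size))
        fails = ~ok[start:stop]
        n_blocks += 1
        if fails.sum() >= threshold:
            n_qualifying += 1
            last_lod = float(mu_s[start:stop][fails].max())

    pass_fraction = 1.0 - fail_rate
    if last_lod is None:
        return LodResult(
            lod=float(mu_s[0]),
            method="block",
            block_size=block_size,
            ratio_threshold=ratio_threshold,
            pass_fraction=pass_fraction,
            n_total=n,
            n_above=n,  # everything detectable
        )
    n_above = int(np.count_nonzero(mu_s > last_lod))
    return LodResult(
        lod=last_lod,
        method="block",
        block_size=block_size,
        ratio_threshold=ratio_threshold,
        pass_fraction=pass_fraction,
        n_total=n,
        n_above=n_above,
        all_below=n_qualifying == n_blocks,
    )


def lod_exact_oracle(
    paired,
    sigma=None,
    ratio_threshold: float = 3.0,
    pass_fraction: float = 0.95,
    min_tail: int = 100,
) -> LodResult:
    """Exact tail-scan LOD: the direct reading of the verbal definition.

    Returns the smallest observed µ value ``t`` such that for *every*
    observed threshold ``s >= t`` whose strict tail ``{µ > s}`` holds at
    least ``min_tail`` observations, the fraction of that tail with
    µ/σ > ratio_threshold is strictly greater than ``pass_fraction``
    ("more than 95%").  Tails smaller than ``min_tail`` are not evaluable
    (a 95% criterion is meaningless on a handful of points) and never veto.

    The scan over sorted thresholds is O(n log n).  If no threshold
    satisfies the condition the result carries ``all_below=True`` with an
    infinite LOD.
    """
    mu, sig = _mu_sigma(paired, sigma)
    n = mu.size
    if n < min_tail:
        raise ValueError(f"need at least min_tail={min_tail} observations")
    order = np.argsort(mu, kind="stable")
    mu_s = mu[order]
    ok = _pass_mask(mu, sig, ratio_threshold)[order].astype(int)

    # suffix_pass[i] = passes among mu_s[i:]
    suffix_pass = np.concatenate([np.cumsum(ok[::-1])[::-1], [0]])

    # for each candidate threshold s = mu_s[k], its strict tail {mu > s}
    first_above = np.searchsorted(mu_s, mu_s, side="right")
    n_tail = n - first_above
    evaluable = n_tail >= min_tail
    with np.errstate(invalid="ignore", divide="ignore"):
        tail_frac = suffix_pass[first_above] / np.where(n_tail > 0, n_tail, 1)
    veto = evaluable & ~(tail_frac > pass_fraction)
    # smallest k such that no threshold at or above mu_s[k] is vetoed
    veto_at_or_above = np.maximum.accumulate(veto[::-1])[::-1]
    clean = np.flatnonzero(~veto_at_or_above)
    lod = float(mu_s[clean[0]]) if clean.size else None

    if lod is None:
        return LodResult(
            lod=float("inf"),
            method="oracle",
            block_size=None,
            ratio_threshold=ratio_threshold,
            pass_fraction=pass_fraction,
            n_total=n,
            n_above=0,
            all_below=True,
        )
    n_above = int(np.count_nonzero(mu_s > lod))
    if lod == mu_s[0] and n_above == n - np.count_nonzero(mu_s == mu_s[0]):
        # everything detectable: count the minimum itself as above-LOD
        n_above = n
    return LodResult(
        lod=lod,
        method="oracle",
        block_size=None,
        ratio_threshold=ratio_threshold,
        pass_fraction=pass_fraction,
        n_total=n,
        n_above=n_above,
    )


def fraction_above_lod(values, lod: float) -> float:
    """Percent of ``values`` strictly above ``lod``."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty series")
    if lod < 0:
        raise ValueError("lod must be >= 0")
    return 100.0 * float(np.count_nonzero(arr > lod)) / arr.size


class LodEstimator(BaseEstimator):
    """Detection-limit estimator over paired duplicate observations.

    ``fit(X)`` accepts a paired-observation DataFrame (or an ``(n, 2)``
    array of µ, σ columns) and exposes ``lod_``, ``fraction_above_`` and the
    full ``result_``.  ``method`` selects the block search (default) or the
    exact tail-scan oracle.
    """

    def __init__(
        self,
        method: str = "block",
        block_size: int = 100,
        ratio_threshold: float = 3.0,
        pass_fraction: float = 0.95,
        min_tail: int = 100,
    ):
        self.method = method
        self.block_size = block_size
        self.ratio_threshold = ratio_threshold
        self.pass_fraction = pass_fraction
        self.min_tail = min_tail

    def fit(self, X, y=None) -> "LodEstimator":
        if isinstance(X, pd.DataFrame):
            mu, sigma = X["mu"].to_numpy(float), X["sigma"].to_numpy(float)
        else:
            arr = np.asarray(X, dtype=float)
            mu, sigma = arr[:, 0], arr[:, 1]
        if self.method == "block":
            max_fail = max(1, math.ceil((1.0 - self.pass_fraction) * self.block_size))
            self.result_ = lod_block_search(
                mu,
                sigma,
                block_size=self.block_size,
                ratio_threshold=self.ratio_threshold,
                max_fail_per_block=max_fail,
            )
        elif self.method == "oracle":
            self.result_ = lod_exact_oracle(
                mu,
                sigma,
                ratio_threshold=self.ratio_threshold,
                pass_fraction=self.pass_fraction,
                min_tail=self.min_tail,
            )
        else:
            raise ValueError(f"unknown method {self.method!r}")
        self.lod_ = self.result_.lod
        self.fraction_above_ = self.result_.fraction_above
        return self
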