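"""Limit-of-detection estimators: worked cases, brute-force recheck, invariants."""

import numpy as np
import pytest

from paqc.lod import LodEstimator, fraction_above_lod, lod_block_search, lod_exact_oracle

from conftest import make_paired


def brute_force_oracle(mu, sigma, ratio=3.0, pass_fraction=0.95, min_tail=100):
    """Quadratic-time literal re-evaluation of the tail-scan definition."""
    mu = np.asarray(mu, float)
    sigma = np.asarray(sigma, float)
    passes = np.where(sigma > 0, mu / np.where(sigma > 0, sigma, 1), np.inf) > ratio
    candidates = np.sort(mu)
    for t in candidates:
        ok = True
        for s in candidates[candidates >= t]:
            tail = mu > s
            if tail.sum() >= min_tail and not (passes[tail].mean() > pass_fraction):
                ok = False
                break
        if ok:
            return float(t)
    return float("inf")


def sharp_floor_pairs(rng, n=10_000, lo=0.01, hi=10.0, floor_pct=0.85):
    """µ log-uniform over 3 decades; σ regime-switches at a detection floor
    sitting high in the sampled range (most observations below detection)."""
    mu = np.exp(rng.uniform(np.log(lo), np.log(hi), n))
    floor = np.quantile(mu, floor_pct)
    below = mu < floor
    sigma = np.where(below, mu / 1.5, mu / 10.0)
    flip = rng.random(n)
    swap_up = below & (flip < 0.02)
    swap_down = ~below & (flip < 0.002)
    sigma[swap_up] = mu[swap_up] / 10.0
    sigma[swap_down] = mu[swap_down] / 1.5
    return mu, sigma, floor


class TestBlockSearch:
    def test_all_exact_duplicates_fully_detectable(self):
        mu = np.linspace(1, 10, 300)
        res = lod_block_search(mu, np.zeros_like(mu))
        assert res.lod == 1.0
        assert res.fraction_above == 100.0

    def test_two_block_boundary_case(self):
        # first block all failing, second all passing: LOD = top of block 1
        mu = np.arange(1.0, 201.0)
        sigma = np.where(mu <= 100, mu, mu / 100.0)  # mu/sigma = 1 (fail) then 100
        res = lod_block_search(mu, sigma)
        assert res.lod == 100.0
        assert res.n_above == 100

    def test_all_blocks_failing_flagged(self):
        mu = np.linspace(1, 2, 250)
        res = lod_block_search(mu, mu)  # mu/sigma = 1 everywhere
        assert res.all_below

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            lod_block_search(np.array([]), np.array([]))

    def test_accepts_paired_frame(self):
        paired = make_paired(np.full(200, 5.0), np.full(200, 5.0))
        res = lod_block_search(paired)
        assert res.lod == 5.0


class TestExactOracle:
    def test_all_passing_lod_at_minimum(self):
        mu = np.linspace(1, 10, 300)
        res = lod_exact_oracle(mu, np.zeros_like(mu))
        assert res.lod == 1.0
        assert res.fraction_above == 100.0

    def test_single_failure_with_small_min_tail(self):
        # one failure at the top; evaluable 20-point tails contain it at
        # exactly the 19/20 = 95% rate, which "more than 95%" excludes
        mu = np.linspace(1, 2, 40)
        sigma = np.zeros_like(mu)
        sigma[-1] = mu[-1]  # mu/sigma = 1: the largest observation fails
        res = lod_exact_oracle(mu, sigma, min_tail=20)
        assert res.lod > mu[0]

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(10)
        for _ in range(8):
            mu = np.exp(rng.uniform(np.log(0.05), np.log(50), 500))
            sigma = np.abs(rng.normal(0.0, 0.3, 500))
            fast = lod_exact_oracle(mu, sigma)
            slow = brute_force_oracle(mu, sigma)
            assert fast.lod == pytest.approx(slow)

    def test_monotonicity_adding_clean_high_observations(self):
        rng = np.random.default_rng(11)
        mu, sigma, _ = sharp_floor_pairs(rng, n=2000)
        base = lod_exact_oracle(mu, sigma).lod
        extra_mu = np.full(500, mu.max() * 2)
        grown = lod_exact_oracle(
            np.concatenate([mu, extra_mu]), np.concatenate([sigma, extra_mu / 100])
        ).lod
        assert grown <= base + 1e-12


class TestSharedProperties:
    def test_scaling_equivariance(self):
        rng = np.random.default_rng(12)
        mu, sigma, _ = sharp_floor_pairs(rng, n=3000)
        for fn in (lod_block_search, lod_exact_oracle):
            base = fn(mu, sigma).lod
            scaled = fn(7.0 * mu, 7.0 * sigma).lod
            assert scaled == pytest.approx(7.0 * base, rel=1e-9)

    def test_block_and_oracle_agree_on_sharp_floor(self):
        agree = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            mu, sigma, _ = sharp_floor_pairs(rng)
            block = lod_block_search(mu, sigma)
            oracle = lod_exact_oracle(mu, sigma)
            mu_s = np.sort(mu)
            i = np.searchsorted(mu_s, block.lod)
            width = mu_s[min(i + 50, mu_s.size - 1)] - mu_s[max(i - 50, 0)]
            agree += abs(block.lod - oracle.lod) <= width
        assert agree >= 0.9 * n_seeds

    def test_pass_criterion_equals_precision_identity(self):
        # µ/σ > 3 iff pair precision < 1/(3√2) ≈ 0.2357
        rng = np.random.default_rng(13)
        a = rng.uniform(0.01, 10, 1000)
        b = rng.uniform(0.01, 10, 1000)
        paired = make_paired(a, b)
        with np.errstate(divide="ignore"):
            ratio = paired["mu"] / paired["sigma"]
        np.testing.assert_array_equal(ratio > 3, paired["precision"] < 1 / (3 * np.sqrt(2)))


class TestFractionAbove:
    @pytest.mark.parametrize(
        "values, lod, expected",
        [([1, 2, 3, 4], 0.5, 100.0), ([1, 2, 3, 4], 2.0, 50.0), ([2, 2, 2], 2.0, 0.0)],
    )
    def test_strict_inequality(self, values, lod, expected):
        assert fraction_above_lod(values, lod) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fraction_above_lod([], 1.0)


class TestLodEstimator:
    def test_fit_exposes_attributes(self):
        rng = np.random.default_rng(14)
        mu, sigma, floor = sharp_floor_pairs(rng, n=2000)
        est = LodEstimator(method="block").fit(np.column_stack([mu, sigma]))
        assert est.lod_ == pytest.approx(floor, rel=0.2)
        assert 0 <= est.fraction_above_ <= 100
        import pandas as pd

        oracle = LodEstimator(method="oracle").fit(pd.DataFrame({"mu": mu, "sigma": sigma}))
        assert oracle.result_.method == "oracle"
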