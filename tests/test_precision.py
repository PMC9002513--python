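"""Pair precision, the cutoff filter, loss accounting and ensemble bias."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from paqc.precision import (
    LossReport,
    PrecisionFilter,
    apply_precision_filter,
    data_loss_comparison,
    pair_precision,
    precision_summary,
    relative_bias,
)

from conftest import make_paired


class TestPairPrecision:
    @pytest.mark.parametrize("a, b, expected", [(5, 5, 0.0), (3, 1, 0.5), (0, 7, 1.0)])
    def test_direct_values(self, a, b, expected):
        assert pair_precision(a, b) == pytest.approx(expected)

    def test_undefined_for_double_zero(self):
        assert math.isnan(pair_precision(0.0, 0.0))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            pair_precision(-1.0, 2.0)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        a=st.floats(0, 1e6),
        b=st.floats(0, 1e6),
        k=st.floats(1e-6, 1e6),
    )
    def test_scale_invariance_and_range(self, a, b, k):
        p = pair_precision(a, b)
        if a + b > 0:
            assert 0 <= p <= 1
            if k * (a + b) > 0:
                assert pair_precision(k * a, k * b) == pytest.approx(p, rel=1e-9, abs=1e-12)

    def test_mu_sigma_precision_identity(self):
        # µ/σ · precision = 1/√2 exactly, for any pair with a+b > 0
        rng = np.random.default_rng(0)
        a = rng.uniform(0.01, 100, 500)
        b = rng.uniform(0.01, 100, 500)
        paired = make_paired(a, b)
        distinct = paired["sigma"] > 0
        lhs = (paired["mu"] / paired["sigma"])[distinct] * paired["precision"][distinct]
        np.testing.assert_allclose(lhs, 1 / np.sqrt(2), rtol=1e-12)


class TestPrecisionFilter:
    def test_strict_cutoff_boundary(self):
        # precisions 0.1, 0.19, 0.2, 0.3 with cutoff 0.2: strictly-below keeps 2
        paired = make_paired([11.0, 1.19, 3.0, 13.0], [9.0, 0.81, 2.0, 7.0])
        np.testing.assert_allclose(paired["precision"], [0.1, 0.19, 0.2, 0.3])
        filtered, report = apply_precision_filter(paired, cutoff=0.2)
        assert len(filtered) == 2
        assert report.lost_to_precision == 2 and report.lost_to_zero == 0

    def test_identical_channels_all_retained(self):
        paired = make_paired([5.0] * 10, [5.0] * 10)
        filtered, report = apply_precision_filter(paired)
        assert len(filtered) == 10 and report.fraction_lost == 0.0

    def test_double_zero_counted_as_zero_loss_and_mixed_pair_as_precision_loss(self):
        paired = make_paired([0.0, 0.0, 4.0], [0.0, 3.0, 4.1], algorithm="CF1")
        filtered, report = apply_precision_filter(paired)
        assert report.lost_to_zero == 1       # (0, 0): undefined precision
        assert report.lost_to_precision == 1  # (0, 3): precision 1, cut by the filter
        assert len(filtered) == 1

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        paired = make_paired(rng.uniform(0, 5, 200), rng.uniform(0, 5, 200))
        once, r1 = apply_precision_filter(paired)
        twice, r2 = apply_precision_filter(once)
        assert len(once) == len(twice)
        assert r2.fraction_lost == 0.0

    def test_loss_conservation_random_streams(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            a = rng.choice([0.0, 1.0, 2.0, 5.0], 300, p=[0.2, 0.3, 0.3, 0.2])
            b = rng.choice([0.0, 1.0, 2.0, 5.0], 300, p=[0.2, 0.3, 0.3, 0.2])
            _, rep = apply_precision_filter(make_paired(a, b))
            assert rep.total_obs == rep.lost_to_zero + rep.lost_to_precision + rep.remaining

    def test_constructed_retention_rate(self):
        # stream built with 8% of pairs above the cutoff retains ~92%
        rng = np.random.default_rng(3)
        n = 20_000
        above = rng.random(n) < 0.08
        prec = np.where(above, rng.uniform(0.25, 0.9, n), rng.uniform(0.0, 0.15, n))
        a = 1 + prec  # pair_precision((1+p)/(1-p) scaled) == p
        b = 1 - prec
        filtered, report = apply_precision_filter(make_paired(a, b))
        assert report.remaining / report.total_obs == pytest.approx(0.92, abs=0.01)

    def test_alt_precision_source_uses_companion(self):
        alt = make_paired([1.0, 1.0], [1.0, 3.0])          # precisions 0, 0.5
        cf1 = make_paired([10.0, 10.0], [10.0, 10.0], algorithm="CF1")  # own precision 0
        filtered, report = apply_precision_filter(cf1, precision_source="alt", companion=alt)
        assert len(filtered) == 1  # second pair gated out by companion precision 0.5
        with pytest.raises(ValueError, match="companion"):
            apply_precision_filter(cf1, precision_source="alt")

    def test_estimator_wrapper_exposes_loss_report(self):
        paired = make_paired([1.0, 1.5], [1.0, 0.5])
        est = PrecisionFilter(cutoff=0.2).fit()
        out = est.transform(paired)
        assert len(out) == 1
        assert est.loss_report_.remaining == 1


class TestPrecisionSummary:
    def test_constant_sample(self):
        s = precision_summary([0.05] * 100)
        assert s.mean == pytest.approx(0.05) and s.std_err == pytest.approx(0.0, abs=1e-12)
        assert s.lower_quartile == s.median == s.upper_quartile == s.p90 == s.max == 0.05

    def test_linear_interpolation_quantiles(self):
        s = precision_summary([0.1, 0.2, 0.3, 0.4])
        assert s.median == pytest.approx(0.25)
        assert s.lower_quartile == pytest.approx(0.175)

    def test_uniform_sample_mean(self):
        rng = np.random.default_rng(4)
        s = precision_summary(rng.uniform(0, 0.2, 100_000))
        assert s.mean == pytest.approx(0.1, abs=0.002)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            precision_summary([])


class TestRelativeBias:
    def test_equal_means_zero_bias(self):
        res = relative_bias([4.0, 4.0, 4.0])
        assert res.overall_mean_abs_bias_pct == 0.0

    def test_two_sensor_arithmetic(self):
        res = relative_bias({"a": 4.0, "b": 6.0})
        assert res.per_sensor_bias_pct["a"] == pytest.approx(-20.0)
        assert res.per_sensor_bias_pct["b"] == pytest.approx(20.0)
        assert res.overall_mean_abs_bias_pct == pytest.approx(20.0)
        assert res.overall_se_pct == 0.0

    def test_half_normal_oracle_for_gaussian_gains(self):
        # sensors with multiplicative gains ~ N(1, 0.03): |bias| is
        # half-normal with mean 3% · sqrt(2/π) ≈ 2.4%
        rng = np.random.default_rng(5)
        overall = [
            relative_bias(5.0 * rng.normal(1.0, 0.03, 8)).overall_mean_abs_bias_pct
            for _ in range(200)
        ]
        assert np.mean(overall) == pytest.approx(3.0 * math.sqrt(2 / math.pi), abs=0.5)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            relative_bias([4.0])
        with pytest.raises(ValueError):
            relative_bias([0.0, 0.0])


class TestDataLossComparison:
    def test_identical_reports_zero_difference(self):
        rep = LossReport(100, 0, 10, 90)
        table = data_loss_comparison(rep, rep)
        assert (table["remaining"] == 90).all()

    def test_mismatched_totals_rejected(self):
        with pytest.raises(ValueError, match="totals|different"):
            data_loss_comparison(LossReport(100, 0, 10, 90), LossReport(99, 9, 10, 80))

    def test_alt_zero_loss_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            data_loss_comparison(LossReport(100, 5, 5, 90), LossReport(100, 9, 10, 81))

    def test_conservation_violation_rejected_at_construction(self):
        with pytest.raises(ValueError):
            LossReport(100, 0, 10, 80)
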