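"""Count-to-mass conversion: worked values, invariants, accounting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from paqc.algorithms import (
    AlgorithmConfig,
    AltMassConverter,
    BinScheme,
    ZeroReport,
    alt_pm,
    count_reported_zeros,
    cumulative_to_bins,
    flag_saturation,
    representative_diameters,
)


class TestCumulativeToBins:
    @pytest.mark.parametrize(
        "cumulative, expected",
        [((1110, 110, 10, 0), (1000, 100, 10)), ((5, 5, 5, 5), (0, 0, 0))],
    )
    def test_differencing(self, cumulative, expected):
        np.testing.assert_allclose(cumulative_to_bins(cumulative), expected)

    def test_increasing_sequence_rejected(self):
        with pytest.raises(ValueError, match="non-increasing"):
            cumulative_to_bins((100, 90, 95, 0))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            cumulative_to_bins((100, -1, 0, 0))

    def test_bin_sum_telescopes(self):
        cum = np.array([[812.0, 400.0, 30.0, 2.0], [50.0, 10.0, 10.0, 0.0]])
        bins = cumulative_to_bins(cum)
        np.testing.assert_allclose(bins.sum(axis=1), cum[:, 0] - cum[:, -1])


class TestRepresentativeDiameters:
    def test_geometric_full_precision(self):
        d = representative_diameters(BinScheme())
        # sqrt(0.15), sqrt(0.5), sqrt(2.5) — never the rounded published 0.37
        np.testing.assert_allclose(d, [0.3873, 0.7071, 1.5811], atol=5e-5)

    def test_arithmetic_means(self):
        d = representative_diameters(BinScheme(diameter_rule="arithmetic"))
        np.testing.assert_allclose(d, [0.4, 0.75, 1.75])

    def test_explicit_passthrough(self):
        scheme = BinScheme(diameter_rule="explicit", explicit_diameters=(0.37, 0.71, 1.58))
        np.testing.assert_allclose(representative_diameters(scheme), [0.37, 0.71, 1.58])

    def test_explicit_requires_diameters(self):
        with pytest.raises(ValueError):
            BinScheme(diameter_rule="explicit")


class TestAltPm:
    def test_hand_oracle_value(self):
        # sum N d^3 = 58.08 + 35.36 + 39.53 µm³/dL; × π/6 × 1e-2 × CF 3
        assert alt_pm([1000, 100, 10]) == pytest.approx(2.089, abs=5e-4)

    def test_zero_counts_zero_mass(self):
        assert alt_pm([0, 0, 0]) == 0.0

    def test_linear_in_calibration_factor(self):
        cf1 = AlgorithmConfig(calibration_factor=1.0)
        assert alt_pm([1000, 100, 10], cf1) == pytest.approx(alt_pm([1000, 100, 10]) / 3.0)

    def test_pm1_is_partial_sum(self):
        bins = [1000, 100, 10]
        pm1 = alt_pm(bins, n_bins_used=2)
        pm25 = alt_pm(bins, n_bins_used=3)
        assert pm1 < pm25
        assert pm25 - pm1 == pytest.approx(10 * AlgorithmConfig().mass_coefficients()[2])

    def test_bin1_unit_coefficient(self):
        # per-count/dL coefficient of the smallest bin: 3·(π/6)·0.15^1.5·1e-2
        expected = 3 * (math.pi / 6) * 0.15**1.5 * 1e-2
        assert AlgorithmConfig().mass_coefficients()[0] == pytest.approx(expected)
        assert expected == pytest.approx(9.13e-4, abs=5e-7)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="bins"):
            alt_pm([1, 2])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        bins=st.tuples(*[st.floats(0, 1e5) for _ in range(3)]),
        k=st.floats(0, 50),
    )
    def test_homogeneity_and_additivity(self, bins, k):
        b = np.asarray(bins)
        assert alt_pm(k * b) == pytest.approx(k * alt_pm(b), rel=1e-9, abs=1e-12)
        assert alt_pm(b + b) == pytest.approx(2 * alt_pm(b), rel=1e-9, abs=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(bins=st.tuples(st.floats(1, 1e5), st.floats(0, 1e5), st.floats(0, 1e5)))
    def test_strictly_positive_when_smallest_bin_occupied(self, bins):
        # particles are always present in the smallest size category, so the
        # conversion never returns zero on real streams
        assert alt_pm(np.asarray(bins)) > 0


class TestSaturation:
    @pytest.mark.parametrize("value, expected", [(999.9, False), (1000.0, True), (12000.0, True)])
    def test_inclusive_boundary(self, value, expected):
        assert flag_saturation(value) is expected

    def test_vector_flags(self):
        flags = flag_saturation(np.array([0.0, 999.99, 1000.0, 5e3]))
        np.testing.assert_array_equal(flags, [False, False, True, True])


class TestZeroAccounting:
    def test_all_positive_series(self):
        rep = count_reported_zeros([1.0, 2.0, 0.5], "1a", "indoor")
        assert rep.n_zeros == 0 and rep.fraction_zero == 0.0

    def test_counts_exact_zeros_only(self):
        rep = count_reported_zeros([0.0, 0.009, 0.0, 3.0])
        assert rep.n_zeros == 2
        assert rep.fraction_zero == pytest.approx(0.5)

    def test_from_counts_display_rounding(self):
        rep = ZeroReport.from_counts(815_558, 165_732, "1a", "indoor")
        assert rep.fraction_zero_display == 0.20

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            count_reported_zeros([-1.0])


class TestAltMassConverter:
    def test_transform_matches_functions(self):
        X = np.array([[1110, 110, 10, 0], [2000, 500, 100, 20]], dtype=float)
        est = AltMassConverter().fit()
        expected = [alt_pm(cumulative_to_bins(row)) for row in X]
        np.testing.assert_allclose(est.transform(X), expected)

    def test_get_set_params_roundtrip(self):
        est = AltMassConverter(calibration_factor=2.5)
        est2 = AltMassConverter(**est.get_params())
        assert est2.calibration_factor == 2.5
        out1 = est.fit().transform([[100, 10, 1, 0]])
        out2 = est2.fit().transform([[100, 10, 1, 0]])
        np.testing.assert_allclose(out1, out2)
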