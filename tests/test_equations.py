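"""Reference-engine math: LMS/linear z-scores, LLNs, percentiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq
from scipy.stats import norm

from spiroref import (
    LMSPoint,
    LinearPoint,
    SpirometryMeasurement,
    Subject,
    inverse_z,
    is_extrapolated,
    lln,
    percentile_from_z,
    z_from_percentile,
    z_score,
    zscore_difference,
)
from spiroref.equations import EquationSetError
from spiroref.simulate import scale_median


class TestZScore:
    def test_zero_at_median(self):
        for L in (-0.5, 0.0, 1.0, 1.5):
            assert z_score(4.0, LMSPoint(L=L, M=4.0, S=0.12)) == pytest.approx(0.0)

    def test_lognormal_form_unit_z(self):
        point = LMSPoint(L=0.0, M=4.0, S=0.12)
        assert z_score(4.0 * np.exp(0.12), point) == pytest.approx(1.0)

    def test_closed_form_at_lower_centile(self):
        # y chosen by inverting y = M(1 + L*S*z) at z = Phi^-1(0.025)
        point = LMSPoint(L=1.0, M=4.0, S=0.12)
        assert z_score(3.05922, point) == pytest.approx(-1.95996, abs=1e-4)

    def test_linear_point(self):
        point = LinearPoint(predicted=4.0, residual_sd=0.5)
        assert z_score(3.0, point) == pytest.approx(-2.0)
        assert inverse_z(-2.0, point) == pytest.approx(3.0)

    def test_nonpositive_value_rejected_under_lms(self):
        with pytest.raises(ValueError):
            z_score(-1.0, LMSPoint(L=1.0, M=4.0, S=0.12))

    @given(L=st.floats(-1.0, 2.0), M=st.floats(0.5, 8.0),
           S=st.floats(0.05, 0.2),
           y=st.floats(0.5, 8.0), dy=st.floats(1e-3, 1.0))
    @settings(max_examples=200, derandomize=True)
    def test_strictly_increasing_in_y(self, L, M, S, y, dy):
        point = LMSPoint(L=L, M=M, S=S)
        assert z_score(y + dy, point) > z_score(y, point)

    def test_l_equals_one_reduces_to_relative_scale(self):
        # with L = 1 the LMS transform is exactly (y/M - 1)/S
        point = LMSPoint(L=1.0, M=3.2, S=0.11)
        for y in (2.0, 3.2, 4.5):
            assert z_score(y, point) == pytest.approx((y / 3.2 - 1) / 0.11,
                                                      abs=1e-12)

    def test_oracle_equivalence_numeric_inversion(self, rng):
        """1,000 random LMS points: z_score matches brute-force root-finding
        on the LMS quantile function to 1e-7."""
        for _ in range(1000):
            L = rng.uniform(-1.0, 2.0)
            M = rng.uniform(0.5, 8.0)
            S = rng.uniform(0.05, 0.2)
            point = LMSPoint(L=L, M=M, S=S)
            y = M * rng.uniform(0.6, 1.6)
            z_direct = z_score(y, point)
            # bracket around the root, clipped to the LMS domain 1+LSz > 0
            lo, hi = z_direct - 0.5, z_direct + 0.5
            if L > 0:
                lo = max(lo, -0.999 / (L * S))
            elif L < 0:
                hi = min(hi, -0.999 / (L * S))
            z_num = brentq(lambda z: inverse_z(z, point) - y, lo, hi,
                           xtol=1e-12)
            assert z_direct == pytest.approx(z_num, abs=1e-7)


class TestLLN:
    def test_median_percentile_recovers_median(self):
        assert lln(LMSPoint(L=0.7, M=4.0, S=0.12), 50) == pytest.approx(4.0)
        assert lln(LinearPoint(4.0, 0.5), 50) == pytest.approx(4.0)

    def test_value_matches_numeric_root(self):
        point = LMSPoint(L=1.0, M=4.0, S=0.12)
        target = norm.ppf(0.025)
        v = brentq(lambda y: z_score(y, point) - target, 0.1, 10.0, xtol=1e-12)
        assert lln(point, 2.5) == pytest.approx(v, abs=1e-9)
        assert lln(point, 2.5) == pytest.approx(3.05922, abs=1e-5)

    @pytest.mark.parametrize("p", [1, 2.5, 5, 50])
    def test_round_trip(self, p):
        point = LMSPoint(L=0.8, M=3.7, S=0.13)
        assert z_score(lln(point, p), point) == pytest.approx(
            norm.ppf(p / 100), abs=1e-9)

    def test_monotone_in_percentile(self, rng):
        point = LMSPoint(L=1.2, M=5.0, S=0.1)
        ps = np.sort(rng.uniform(0.5, 99.5, size=50))
        values = [lln(point, p) for p in ps]
        assert np.all(np.diff(values) > 0)

    def test_out_of_range_percentile_rejected(self):
        with pytest.raises(ValueError):
            lln(LMSPoint(L=1.0, M=4.0, S=0.12), 0)
        with pytest.raises(ValueError):
            lln(LMSPoint(L=1.0, M=4.0, S=0.12), 100)


class TestPercentileZ:
    def test_median(self):
        assert z_from_percentile(50) == pytest.approx(0.0)

    def test_conventional_limits(self):
        assert round(z_from_percentile(2.5), 2) == -1.96
        assert round(z_from_percentile(5), 3) == -1.645

    @given(st.floats(0.01, 99.99))
    @settings(max_examples=200, derandomize=True)
    def test_round_trip(self, p):
        assert percentile_from_z(z_from_percentile(p)) == pytest.approx(
            p, abs=1e-9)

    def test_agrees_with_erf_form(self):
        from scipy.special import erf
        z = np.linspace(-6, 6, 241)
        expected = 100 * 0.5 * (1 + erf(z / np.sqrt(2)))
        assert np.allclose(percentile_from_z(z), expected, atol=1e-9)

    def test_domain(self):
        for p in (0, 100, -3, 120):
            with pytest.raises(ValueError):
                z_from_percentile(p)


class TestLMSEquationSet:
    def test_grid_point_uses_tabulated_value(self, lms_set):
        c = lms_set.coefficients[("male", "fev1")]
        i = 20
        age = float(c.spline_age[i])
        L, M, S = lms_set.lms_arrays("male", age, 175.0, "fev1")
        assert float(L) == pytest.approx(c.spline_l[i], abs=1e-12)
        expected_m = np.exp(c.m_intercept + c.m_lnheight * np.log(175.0)
                            + c.m_lnage * np.log(age) + c.spline_m[i])
        assert float(M) == pytest.approx(expected_m, rel=1e-12)

    def test_midpoint_interpolates_linearly(self, lms_set):
        c = lms_set.coefficients[("female", "fvc")]
        a0, a1 = c.spline_age[5], c.spline_age[6]
        mid = (a0 + a1) / 2
        L, M, S = lms_set.lms_arrays("female", mid, 165.0, "fvc")
        assert float(L) == pytest.approx((c.spline_l[5] + c.spline_l[6]) / 2,
                                         abs=1e-12)
        msp = (c.spline_m[5] + c.spline_m[6]) / 2
        expected_m = np.exp(c.m_intercept + c.m_lnheight * np.log(165.0)
                            + c.m_lnage * np.log(mid) + msp)
        assert float(M) == pytest.approx(expected_m, rel=1e-12)

    def test_median_increases_with_height(self, lms_set):
        tall = lms_set.predicted("male", 40.0, 185.0, "fev1")
        short = lms_set.predicted("male", 40.0, 170.0, "fev1")
        assert tall > short

    def test_strict_mode_refuses_extrapolation(self, lms_set):
        with pytest.raises(EquationSetError):
            lms_set.lms_at("male", 110.0, 175.0, "fev1", strict=True)

    def test_missing_block_is_configuration_error(self, lms_set):
        with pytest.raises(EquationSetError):
            lms_set.predicted("male", 40.0, 175.0, "dlco")


class TestExtrapolation:
    @pytest.mark.parametrize("age,expected", [(70.0, True), (65.0, False),
                                              (40.0, False), (17.9, True)])
    def test_against_valid_range(self, linear_set, age, expected):
        # the linear fixture declares validity for ages 18-65, inclusive
        assert linear_set.valid_age_range == (18.0, 65.0)
        assert is_extrapolated(linear_set, age) is expected

    def test_vectorised(self, linear_set):
        flags = is_extrapolated(linear_set, np.array([20.0, 66.0, 65.0]))
        assert flags.tolist() == [False, True, False]


class TestZScoreDifference:
    def test_same_set_gives_zero(self, lms_set):
        subject = Subject("a", "male", 48.0, 176.5)
        meas = SpirometryMeasurement(fev1=4.0, fvc=5.1)
        delta, flagged = zscore_difference(subject, meas, lms_set, lms_set,
                                           "fev1")
        assert delta == 0.0 and not flagged

    def test_ten_percent_median_offset_is_flagged(self, lms_set):
        # y = M_a makes z_a = 0; under M_b = 1.1 M_a with L=1 the z is
        # (1/1.1 - 1)/S, so |delta z| = 0.0909/S > 0.3 for realistic S
        offset = scale_median(lms_set, 1.1)
        subject = Subject("a", "male", 48.0, 176.5)
        m_a = lms_set.predicted("male", 48.0, 176.5, "fvc")
        point = lms_set.lms_at("male", 48.0, 176.5, "fvc")
        meas = SpirometryMeasurement(fev1=0.8 * m_a, fvc=m_a)
        delta, flagged = zscore_difference(subject, meas, lms_set, offset,
                                           "fvc")
        expected = -z_score(m_a, offset.lms_at("male", 48.0, 176.5, "fvc"))
        assert delta == pytest.approx(expected, abs=1e-12)
        assert abs(delta) > 0.3 and flagged

    def test_default_threshold_is_point_three(self):
        from spiroref.equations import ZSCORE_DIFFERENCE_THRESHOLD
        assert ZSCORE_DIFFERENCE_THRESHOLD == 0.3

    def test_missing_index_is_configuration_error(self, lms_set, linear_set):
        subject = Subject("a", "male", 48.0, 176.5)
        meas = SpirometryMeasurement(fev1=4.0, fvc=5.1)
        partial = type(linear_set)(
            name="partial",
            coefficients={("male", "fev1"):
                          linear_set.coefficients[("male", "fev1")]},
            valid_age_range=(18.0, 65.0))
        with pytest.raises(EquationSetError):
            zscore_difference(subject, meas, lms_set, partial, "fvc")


class TestRecordInvariants:
    def test_subject_validation(self):
        with pytest.raises(ValueError):
            Subject("x", "other", 40.0, 170.0)
        with pytest.raises(ValueError):
            Subject("x", "male", -1.0, 170.0)

    def test_measurement_flags_fev1_above_fvc(self):
        bad = SpirometryMeasurement(fev1=5.0, fvc=4.0)
        assert not bad.valid
        good = SpirometryMeasurement(fev1=3.9, fvc=4.8)
        assert good.valid
        assert good.ratio == pytest.approx(3.9 / 4.8)
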