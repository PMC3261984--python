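import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dlnmcc.basis import (LagSpec, SplineSpec, ThresholdSpec, equally_spaced_knots,
                          lag_basis, log_spaced_lag_knots, ns_basis, threshold_basis)


class TestKnotRules:
    @pytest.mark.parametrize("lo,hi,df,expected", [
        (0, 10, 2, [5.0]),
        (-11, 31, 5, [-2.6, 5.8, 14.2, 22.6]),
        (0, 10, 1, []),
    ])
    def test_equal_spacing_over_range(self, lo, hi, df, expected):
        assert np.allclose(equally_spaced_knots(lo, hi, df), expected)

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            equally_spaced_knots(5, 5, 3)

    def test_log_spaced_lag_knots_are_log_equispaced(self):
        knots = log_spaced_lag_knots(27, 4)
        assert np.allclose(knots, [3.0, 9.0])
        logs = np.log(knots)
        assert np.allclose(np.diff(logs), logs[0] - 0.0)

    def test_lag_knot_edge_cases(self):
        assert log_spaced_lag_knots(27, 2) == []
        assert all(0 < k < 27 for k in log_spaced_lag_knots(27, 4))
        with pytest.raises(ValueError):
            log_spaced_lag_knots(0, 4)

    @given(lo=st.floats(-50, 50), span=st.floats(0.5, 100),
           df=st.integers(2, 8),
           a=st.floats(0.1, 5), b=st.floats(-20, 20))
    @settings(max_examples=50, deadline=None)
    def test_equal_spacing_affine_equivariance(self, lo, span, df, a, b):
        """Rescaling the range maps the knots through the same affine map."""
        hi = lo + span
        k1 = np.array(equally_spaced_knots(lo, hi, df))
        k2 = np.array(equally_spaced_knots(a * lo + b, a * hi + b, df))
        assert np.allclose(a * k1 + b, k2, atol=1e-8 * max(1, abs(a) * span))


class TestNaturalSpline:
    @given(df=st.integers(1, 7), n=st.integers(1, 40))
    @settings(max_examples=40, deadline=None)
    def test_column_count_equals_df(self, df, n):
        spec = SplineSpec.for_range(-10.0, 30.0, df)
        x = np.linspace(-15, 35, n)
        assert ns_basis(x, spec).shape == (n, df)

    def test_no_interior_knots_gives_affine_column(self):
        spec = SplineSpec.for_range(0.0, 10.0, 1)
        x = np.linspace(-5, 15, 30)
        B = ns_basis(x, spec)
        assert B.shape[1] == 1
        assert np.allclose(np.diff(B[:, 0]) / np.diff(x), 1.0)

    def test_continuity_under_epsilon_shift(self):
        spec = SplineSpec.for_range(-10.0, 30.0, 5)
        x = np.linspace(-12, 32, 101)
        eps = np.finfo(float).eps * 100
        assert np.allclose(ns_basis(x, spec), ns_basis(x + eps, spec), atol=1e-9)

    @pytest.mark.parametrize("side", ["below", "above"])
    def test_linear_extrapolation_beyond_boundary(self, side):
        """Natural splines are affine outside the boundary knots: constant
        slope and vanishing second differences."""
        spec = SplineSpec.for_range(0.0, 20.0, 5)
        x = np.linspace(-15, -5, 30) if side == "below" else np.linspace(25, 35, 30)
        B = ns_basis(x, spec)
        for j in range(B.shape[1]):
            slopes = np.diff(B[:, j]) / np.diff(x)
            assert np.allclose(slopes, slopes[0], atol=1e-8)
            d2 = np.diff(B[:, j], 2)
            assert np.allclose(d2, 0.0, atol=1e-8)

    def test_second_derivative_continuity_at_knots(self):
        spec = SplineSpec.for_range(0.0, 10.0, 4)
        h = 1e-4
        for knot in spec.interior_knots:
            x = np.array([knot - h, knot, knot + h])
            B = ns_basis(x, spec)
            d2 = (B[0] - 2 * B[1] + B[2]) / h**2   # symmetric around the knot
            # second derivative exists: compare to values slightly away
            xa = np.array([knot - 3 * h, knot - 2 * h, knot - h])
            Ba = ns_basis(xa, spec)
            d2a = (Ba[0] - 2 * Ba[1] + Ba[2]) / h**2
            assert np.allclose(d2, d2a, atol=1e-2 * (1 + np.abs(d2).max()))

    def test_nonfinite_input_names_index(self):
        spec = SplineSpec.for_range(0.0, 10.0, 3)
        with pytest.raises(ValueError, match="index 2"):
            ns_basis(np.array([1.0, 2.0, np.nan]), spec)

    def test_empty_input_gives_empty_matrix(self):
        spec = SplineSpec.for_range(0.0, 10.0, 3)
        assert ns_basis(np.array([]), spec).shape == (0, 3)

    def test_df_knot_consistency_enforced(self):
        with pytest.raises(ValueError):
            SplineSpec(df=5, interior_knots=(1.0,), boundary_knots=(0.0, 10.0))


class TestThresholdBasis:
    @pytest.mark.parametrize("x,expected", [
        (-1.0, (1.8, 0.0)),
        (30.0, (0.0, 5.1)),
        (14.0, (0.0, 0.0)),
    ])
    def test_hinge_algebra_at_reference_thresholds(self, x, expected):
        spec = ThresholdSpec(0.8, 24.9)
        assert np.allclose(threshold_basis(np.array([x]), spec)[0], expected)

    @given(x=st.lists(st.floats(-30, 45), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_nonnegative_and_zero_in_comfort_band(self, x):
        spec = ThresholdSpec(0.8, 24.9)
        B = threshold_basis(np.array(x), spec)
        assert (B >= 0).all()
        inside = (np.array(x) >= 0.8) & (np.array(x) <= 24.9)
        assert np.allclose(B[inside], 0.0)

    def test_ordered_thresholds_required(self):
        with pytest.raises(ValueError):
            ThresholdSpec(25.0, 0.0)


class TestLagBasis:
    def test_log_spline_has_intercept_plus_shaped_columns(self):
        spec = LagSpec.log_spline(27, 4)
        B = lag_basis(spec)
        assert B.shape == (28, 4)
        assert np.allclose(B[:, 0], 1.0)
        assert len(spec.knots) == 2

    def test_indicator_is_identity(self):
        B = lag_basis(LagSpec.indicator(3))
        assert np.array_equal(B, np.eye(4))

    def test_df2_is_intercept_plus_linear(self):
        B = lag_basis(LagSpec.log_spline(10, 2))
        assert B.shape == (11, 2)
        assert np.allclose(np.diff(B[:, 1]), B[1, 1] - B[0, 1])
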