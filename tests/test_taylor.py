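"""Delta-method machinery: generic forms, compositions, limits."""

from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st

from coalratios import (DIVERGES, ExactScalar, ratio_mean_approx,
                        ratio_mean_limit, ratio_var_approx, ratio_var_limit,
                        taylor_mean_ratio, taylor_var_ratio)
from coalratios.statistics import B, E, H, I, L, T
from coalratios.taylor import RatioPair, ratio_mean_float, ratio_var_float


class TestGenericTaylorForms:
    @pytest.mark.parametrize("mx, my, vy, c, expected", [
        (Fraction(3), Fraction(7), Fraction(0), Fraction(0), Fraction(3, 7)),
        (Fraction(1), Fraction(2), Fraction(4), Fraction(2), Fraction(1, 2)),
        (Fraction(2), Fraction(2), Fraction(1), Fraction(0), Fraction(5, 4)),
    ])
    def test_mean_ratio_values(self, mx, my, vy, c, expected):
        assert taylor_mean_ratio(mx, my, vy, c) == expected

    @pytest.mark.parametrize("mx, my, vx, vy, c, expected", [
        (Fraction(1), Fraction(2), Fraction(1), Fraction(4), Fraction(2), 0),
        (Fraction(5), Fraction(3), Fraction(0), Fraction(0), Fraction(0), 0),
        (Fraction(1), Fraction(1), Fraction(1), Fraction(1), Fraction(0), 2),
    ])
    def test_var_ratio_values(self, mx, my, vx, vy, c, expected):
        assert taylor_var_ratio(mx, my, vx, vy, c) == expected

    def test_zero_denominator_mean_rejected(self):
        with pytest.raises(ZeroDivisionError):
            taylor_mean_ratio(1, 0, 1, 0)
        with pytest.raises(ZeroDivisionError):
            taylor_var_ratio(0, 1, 1, 1, 0)

    @settings(max_examples=50, derandomize=True)
    @given(st.fractions(min_value=-5, max_value=5),
           st.fractions(min_value=Fraction(1, 10), max_value=5),
           st.fractions(min_value=Fraction(1, 10), max_value=5),
           st.fractions(min_value=0, max_value=5),
           st.fractions(min_value=0, max_value=5))
    def test_var_ratio_nonnegative_under_cauchy_schwarz(self, c, mx, my, vx, vy):
        # |Cov| <= sqrt(Var_x Var_y) forces the bracketed quadratic >= 0
        if c * c > vx * vy:
            return
        assert taylor_var_ratio(mx, my, vx, vy, c) >= 0


class TestRatioPair:
    def test_rejects_identical_and_double_T(self):
        with pytest.raises(ValueError):
            RatioPair(H, H)
        with pytest.raises(ValueError):
            RatioPair(T(2), T(3))

    def test_reciprocal_orientations_both_work(self):
        # both orientations are computable through the generic machinery;
        # the second-order correction inflates each direction (a Jensen
        # effect), so the product of the two approximations exceeds 1
        a = float(ratio_mean_approx(RatioPair(E, H), 10).mean_approx)
        b = float(ratio_mean_approx(RatioPair(H, E), 10).mean_approx)
        assert a > 0 and b > 0 and a != b
        assert a * b > 1


class TestRatioApproximations:
    @pytest.mark.parametrize("pair, n, expected", [
        (RatioPair(H, L), 2, Fraction(1, 2)),
        (RatioPair(H, T(2)), 2, Fraction(1)),
        (RatioPair(E, T(2)), 3, Fraction(3)),
    ])
    def test_mean_examples(self, pair, n, expected):
        assert ratio_mean_approx(pair, n).mean_approx.as_fraction() == expected

    @pytest.mark.parametrize("pair", [
        RatioPair(H, L), RatioPair(H, T(2)),
        RatioPair(E, L), RatioPair(E, T(2)),
    ])
    def test_degenerate_n2_ratios_have_zero_variance(self, pair):
        # at n = 2 all four ratios are deterministic per tree
        assert ratio_var_approx(pair, 2).var_approx == 0

    def test_variance_nonnegative_on_grid(self):
        pairs = [RatioPair(E, H), RatioPair(B, H), RatioPair(L, I),
                 RatioPair(B, E), RatioPair(I, T(3)), RatioPair(B, T(2))]
        for pair in pairs:
            for n in range(pair.min_n, 60):
                assert ratio_var_approx(pair, n).var_approx.as_fraction() >= 0

    def test_mean_of_L_over_Tk_increases_with_n(self):
        for k in (2, 4):
            pair = RatioPair(L, T(k))
            values = [ratio_mean_approx(pair, n).mean_approx.as_fraction()
                      for n in range(k, 80)]
            assert all(b > a for a, b in zip(values, values[1:]))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            ratio_mean_approx(RatioPair(B, H), 3)   # B undefined below 4
        with pytest.raises(ValueError):
            ratio_mean_approx(RatioPair(H, I), 2)   # I undefined below 3
        with pytest.raises(ValueError):
            ratio_mean_approx(RatioPair(L, T(5)), 4)

    def test_approximate_covariance_flag_propagates(self):
        assert ratio_mean_approx(RatioPair(B, E), 6).approximate
        assert ratio_var_approx(RatioPair(B, I), 6).approximate
        assert not ratio_mean_approx(RatioPair(B, H), 6).approximate


class TestRatioLimits:
    def test_E_over_H_limit_is_exactly_pi2_over_3_minus_2(self):
        lim = ratio_mean_limit(RatioPair(E, H))
        assert lim == ExactScalar((-2, Fraction(1, 3), 0, 0, 0, 0))

    @pytest.mark.parametrize("pair, printed", [
        (RatioPair(E, H), 1.28987),
        (RatioPair(B, H), 0.56463),
        (RatioPair(B, E), 0.64493),
        (RatioPair(L, I), 1.0),
        (RatioPair(H, L), 0.0),
    ])
    def test_mean_limit_decimals(self, pair, printed):
        assert float(ratio_mean_limit(pair)) == pytest.approx(printed, abs=1e-5)

    @pytest.mark.parametrize("pair, printed", [
        (RatioPair(B, H), 0.03744),
        (RatioPair(B, E), 0.26159),
        (RatioPair(E, H), 0.28987),
        (RatioPair(H, L), 0.0),
        (RatioPair(L, I), 0.0),
    ])
    def test_var_limit_decimals(self, pair, printed):
        assert float(ratio_var_limit(pair)) == pytest.approx(printed, abs=1e-5)

    def test_ratios_with_diverging_denominator_mean_diverge(self):
        for pair in (RatioPair(L, T(2)), RatioPair(I, T(3))):
            assert ratio_mean_limit(pair) is DIVERGES
            assert ratio_var_limit(pair) is DIVERGES

    def test_fast_converging_entries_near_limit_at_large_n(self):
        # entries whose denominator has bounded mean converge at ~log(n)/n
        big = 10 ** 6
        for pair in (RatioPair(E, H), RatioPair(B, H), RatioPair(B, E),
                     RatioPair(H, T(2)), RatioPair(E, T(3)), RatioPair(B, T(2))):
            assert abs(ratio_mean_float(pair, big)
                       - float(ratio_mean_limit(pair))) < 1e-3
            assert abs(ratio_var_float(pair, big)
                       - float(ratio_var_limit(pair))) < 1e-3

    def test_slow_entries_drift_toward_their_limits(self):
        # pairs with L or I in the denominator converge only like 1/log n;
        # their limits are exact above, here we check the monotone approach
        for pair in (RatioPair(H, L), RatioPair(E, I)):
            v3 = ratio_mean_float(pair, 10 ** 3)
            v6 = ratio_mean_float(pair, 10 ** 6)
            assert 0 < v6 < v3
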