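"""Minimum-Bayes-factor calibrations: closed forms, optimizations, inverses."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2, norm

from pnomogram import (
    CalibrationMethod,
    ChiSquareStatistic,
    ConvergenceError,
    Method,
    NoSolutionError,
    PValue,
    Tails,
    ZStatistic,
    inverse_p_from_bf,
    min_bf,
    min_bf_bs_normal,
    min_bf_bs_symmetric,
    min_bf_bs_unimodal,
    min_bf_chisq,
    min_bf_els,
    min_bf_sbb,
    p_from_z,
    z_from_p,
)

ALL_METHODS = [Method.ELS, Method.BS_SYMMETRIC, Method.BS_UNIMODAL, Method.BS_NORMAL, Method.SBB]


class TestScaleConversions:
    @pytest.mark.parametrize(
        "p, tails, expected_z",
        [
            (0.05, Tails.TWO, 1.959964),
            (0.05, Tails.ONE, 1.644854),
            (0.5, Tails.ONE, 0.0),
        ],
    )
    def test_z_from_p_matches_normal_quantile(self, p, tails, expected_z):
        assert z_from_p(PValue(p, tails)).value == pytest.approx(expected_z, abs=5e-7)

    @pytest.mark.parametrize(
        "z, tails, expected_p",
        [
            (1.959964, Tails.TWO, 0.05),
            (0.0, Tails.TWO, 1.0),
            (3.2905, Tails.TWO, 0.001),
        ],
    )
    def test_p_from_z_matches_normal_cdf(self, z, tails, expected_p):
        assert p_from_z(ZStatistic(z), tails).value == pytest.approx(expected_p, rel=1e-3)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        p=st.floats(min_value=1e-12, max_value=0.999),
        tails=st.sampled_from([Tails.ONE, Tails.TWO]),
    )
    def test_round_trip_p_z_p(self, p, tails):
        if tails is Tails.ONE and p > 0.5:
            return  # one-tailed quantile would be negative; conversion refuses
        back = p_from_z(z_from_p(PValue(p, tails)), tails)
        assert back.value == pytest.approx(p, rel=1e-9, abs=1e-10)

    def test_one_tailed_p_above_half_rejected(self):
        with pytest.raises(ValueError):
            z_from_p(PValue(0.75, Tails.ONE))

    def test_degenerate_p_rejected(self):
        with pytest.raises(ValueError):
            PValue(0.0)
        with pytest.raises(ValueError):
            z_from_p(PValue(1.0))

    def test_tails_recorded_not_inferred(self):
        assert PValue(0.04).tails is Tails.TWO
        assert PValue(0.04, Tails.ONE).tails is Tails.ONE


class TestClosedFormBounds:
    def test_els_no_evidence_at_z_zero(self):
        assert min_bf_els(ZStatistic(0.0)).bf == 1.0

    def test_els_at_one_tailed_five_percent(self):
        z = z_from_p(PValue(0.05, Tails.ONE))
        assert min_bf_els(z).bf == pytest.approx(math.exp(-z.value**2 / 2), rel=1e-12)
        assert min_bf_els(z).bf == pytest.approx(0.2585227, abs=5e-7)

    def test_bs_normal_continuous_cap_at_z_one(self):
        assert min_bf_bs_normal(ZStatistic(1.0)).bf == pytest.approx(1.0, abs=1e-12)
        assert min_bf_bs_normal(ZStatistic(0.5)).bf == 1.0

    def test_bs_normal_value(self):
        assert min_bf_bs_normal(ZStatistic(1.959964)).bf == pytest.approx(0.4734053, abs=1e-6)

    def test_sbb_unity_at_and_above_cutoff(self):
        assert min_bf_sbb(PValue(1.0 / math.e)).bf == 1.0
        assert min_bf_sbb(PValue(0.5)).bf == 1.0

    def test_sbb_value(self):
        assert min_bf_sbb(PValue(0.05)).bf == pytest.approx(0.4071622, abs=1e-6)
        assert min_bf_sbb(PValue(0.003)).bf == pytest.approx(-math.e * 0.003 * math.log(0.003), rel=1e-12)


class TestOptimizedBoundsAgainstGridOracle:
    @pytest.mark.parametrize("z", [0.5, 1.0, 1.5, 1.959964, 2.5758, 3.2905, 4.5, 6.0])
    def test_symmetric_bound_matches_brute_force(self, z, grid_oracle):
        assert min_bf_bs_symmetric(ZStatistic(z)).bf == pytest.approx(
            grid_oracle(z, "symmetric"), rel=1e-6
        )

    @pytest.mark.parametrize("z", [0.5, 1.0, 1.5, 1.959964, 2.5758, 3.2905, 4.5, 6.0])
    def test_unimodal_bound_matches_brute_force(self, z, grid_oracle):
        assert min_bf_bs_unimodal(ZStatistic(z)).bf == pytest.approx(
            grid_oracle(z, "unimodal"), rel=1e-6
        )

    def test_no_evidence_at_z_zero(self):
        assert min_bf_bs_symmetric(ZStatistic(0.0)).bf == 1.0
        assert min_bf_bs_unimodal(ZStatistic(1e-9)).bf == pytest.approx(1.0, abs=1e-9)


class TestChiSquareBound:
    @pytest.mark.parametrize("nu", [0.5, 1.0, 2.0, 7.3])
    def test_unity_at_and_below_the_mean(self, nu):
        assert min_bf_chisq(ChiSquareStatistic(nu, nu)).bf == 1.0
        assert min_bf_chisq(ChiSquareStatistic(nu / 2, nu)).bf == 1.0

    @pytest.mark.parametrize("z", [1.0, 1.5, 1.959964, 2.5758, 4.0])
    def test_df_one_equals_normal_prior_bound(self, z):
        assert min_bf_chisq(ChiSquareStatistic(z * z, 1.0)).bf == pytest.approx(
            min_bf_bs_normal(ZStatistic(z)).bf, rel=1e-12
        )

    @pytest.mark.parametrize("p", [1e-10, 1e-5, 0.001, 0.05, 0.3])
    def test_df_two_equals_sbb_bound(self, p):
        assert min_bf_chisq(ChiSquareStatistic(-2.0 * math.log(p), 2.0)).bf == pytest.approx(
            min_bf_sbb(PValue(p)).bf, rel=1e-12
        )

    @pytest.mark.parametrize("p", [0.001, 0.01, 0.05])
    def test_decreasing_in_df(self, p):
        nus = [1.0, 2.0, 5.0, 20.0, 100.0, 1e4]
        bfs = [
            min_bf(CalibrationMethod(Method.CHISQ, nu), PValue(p)).bf for nu in nus
        ]
        assert all(a > b for a, b in zip(bfs, bfs[1:]))

    @pytest.mark.parametrize("p", [0.001, 0.01])
    def test_els_limit_at_large_df(self, p):
        bf = min_bf(CalibrationMethod(Method.CHISQ, 1e4), PValue(p)).bf
        assert bf == pytest.approx(min_bf(Method.ELS, PValue(p)).bf, abs=1e-3)

    def test_els_limit_convergence_rate(self):
        # the gap to the ELS bound shrinks like 1/sqrt(df)
        els = min_bf(Method.ELS, PValue(0.05)).bf
        gaps = [
            min_bf(CalibrationMethod(Method.CHISQ, nu), PValue(0.05)).bf - els
            for nu in (1e2, 1e4, 1e6)
        ]
        assert gaps[0] > gaps[1] > gaps[2] > 0
        assert gaps[1] / gaps[0] == pytest.approx(0.1, abs=0.05)


class TestDispatch:
    def test_sbb_from_p_value(self):
        r = min_bf(Method.SBB, PValue(0.003))
        assert r.bf == pytest.approx(0.0473727, abs=1e-6)
        assert r.input_scale == "p"
        assert r.method.tag is Method.SBB

    def test_els_uses_one_tailed_quantile_of_two_sided_p(self):
        r = min_bf(Method.ELS, PValue(0.05, Tails.TWO))
        assert r.bf == pytest.approx(0.2585227, abs=5e-7)

    def test_sbb_from_z_converts_two_tailed(self):
        z = z_from_p(PValue(0.05, Tails.TWO))
        assert min_bf(Method.SBB, z).bf == pytest.approx(min_bf_sbb(PValue(0.05)).bf, rel=1e-9)

    def test_chisq_trivial_at_mean(self):
        assert min_bf(Method.CHISQ, ChiSquareStatistic(2.0, 2.0)).bf == 1.0

    def test_chisq_from_p_uses_upper_quantile(self):
        bf = min_bf(CalibrationMethod(Method.CHISQ, 3.0), PValue(0.01))
        x = chi2.isf(0.01, 3.0)
        assert bf.bf == pytest.approx(min_bf_chisq(ChiSquareStatistic(x, 3.0)).bf, rel=1e-12)

    def test_incompatible_pairings_raise(self):
        with pytest.raises(TypeError):
            min_bf(Method.ELS, ChiSquareStatistic(4.0, 1.0))
        with pytest.raises(ValueError):
            min_bf(Method.CHISQ, PValue(0.05))  # df missing
        with pytest.raises(ValueError):
            min_bf(CalibrationMethod(Method.CHISQ, 2.0), ChiSquareStatistic(4.0, 3.0))

    def test_method_df_only_for_chisq(self):
        with pytest.raises(ValueError):
            CalibrationMethod(Method.SBB, 2.0)


class TestInverse:
    @pytest.mark.parametrize("method", ALL_METHODS)
    @pytest.mark.parametrize("p", [1e-10, 1e-6, 1e-4, 0.003, 0.05, 0.3])
    def test_round_trip_through_p(self, method, p):
        bf = min_bf(method, PValue(p)).bf
        if bf >= 1.0:
            pytest.skip("bound capped at 1: nothing to invert")
        back = inverse_p_from_bf(method, bf)
        assert back.value == pytest.approx(p, rel=1e-7, abs=1e-12)
        assert min_bf(method, back).bf == pytest.approx(bf, abs=1e-9)

    def test_chisq_inverse_round_trip(self):
        m = CalibrationMethod(Method.CHISQ, 3.0)
        bf = min_bf(m, PValue(0.01)).bf
        assert inverse_p_from_bf(m, bf).value == pytest.approx(0.01, rel=1e-7)

    def test_sbb_boundary_approaches_cutoff(self):
        p = inverse_p_from_bf(Method.SBB, 1.0 - 1e-12)
        assert p.value == pytest.approx(1.0 / math.e, rel=1e-4)

    def test_target_out_of_range(self):
        with pytest.raises(NoSolutionError):
            inverse_p_from_bf(Method.SBB, 1.0)
        with pytest.raises(ValueError):
            inverse_p_from_bf(Method.SBB, -0.2)


class TestInvariants:
    @pytest.mark.parametrize("z", [1.1, 1.5, 1.959964, 2.5, 3.2905, 4.0, 5.0])
    def test_bound_ordering_by_prior_family_restriction(self, z):
        """Nested prior families order the bounds: point mass <= symmetric <= unimodal <= normal."""
        zs = ZStatistic(z)
        els = min_bf_els(zs).bf
        sym = min_bf_bs_symmetric(zs).bf
        uni = min_bf_bs_unimodal(zs).bf
        nrm = min_bf_bs_normal(zs).bf
        assert els <= sym <= uni <= nrm

    @pytest.mark.parametrize(
        "fn",
        [min_bf_els, min_bf_bs_symmetric, min_bf_bs_unimodal, min_bf_bs_normal],
    )
    def test_bounds_non_increasing_in_z(self, fn):
        zs = np.linspace(0.0, 6.0, 40)
        vals = [fn(ZStatistic(z)).bf for z in zs]
        assert all(a >= b - 1e-9 for a, b in zip(vals, vals[1:]))
        assert all(0.0 < v <= 1.0 for v in vals)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(p=st.floats(min_value=1e-8, max_value=0.36))
    def test_sbb_non_decreasing_in_p(self, p):
        assert min_bf_sbb(PValue(p)).bf <= min_bf_sbb(PValue(min(p * 1.5, 0.9999))).bf + 1e-12
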