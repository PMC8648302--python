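"""Closed-form slope relation, its inverse, and the coupled A(Ci) solver."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mesokit.c4model import (
    C4ModelParams,
    DEFAULT_PARAMS,
    enzyme_limited_assimilation,
    gm_from_initial_slope,
    initial_slope_from_gm,
    predicted_slope_curve,
    solve_A_from_Ci,
)
from mesokit.errors import DomainError


class TestSlopeRelation:
    @pytest.mark.parametrize(
        "gm,expected",
        [
            (0.42, 0.42 * 250 / (0.42 * 82 + 250)),  # 0.3692
            (0.59, 0.59 * 250 / (0.59 * 82 + 250)),  # 0.4944
        ],
    )
    def test_printed_operating_points(self, gm, expected):
        assert initial_slope_from_gm(gm, 250, 82) == pytest.approx(expected, rel=1e-12)
        assert initial_slope_from_gm(0.42, 250, 82) == pytest.approx(0.3692, abs=1e-4)

    def test_asymptote_at_large_gm(self):
        # diffusion ceases to limit; slope -> carboxylation efficiency Vpmax/Kp
        assert initial_slope_from_gm(1e6, 250, 82) == pytest.approx(
            250 / 82, rel=1e-4
        )
        assert 250 / 82 == pytest.approx(3.0488, abs=1e-4)

    def test_small_gm_limit_is_diffusion_dominated(self):
        gm = 1e-6
        assert initial_slope_from_gm(gm) == pytest.approx(gm, rel=1e-4)

    def test_strictly_increasing_in_gm(self):
        grid = np.linspace(0.05, 2.0, 50)
        slopes = [initial_slope_from_gm(g) for g in grid]
        assert np.all(np.diff(slopes) > 0)

    @pytest.mark.parametrize("bad", [0.0, -1.0, float("nan")])
    def test_domain_errors(self, bad):
        with pytest.raises(DomainError):
            initial_slope_from_gm(bad)

    def test_bounded_above_by_both_limits(self):
        for g in (0.1, 0.42, 3.0, 50.0):
            s = initial_slope_from_gm(g)
            assert 0 < s < min(g, 250 / 82)


class TestInverse:
    def test_control_plant_printed_slope(self):
        # slope 0.41 printed for control plants maps just above the printed gm:
        # 0.41*250/(250 - 0.41*82) = 0.4737
        assert gm_from_initial_slope(0.41, 250, 82) == pytest.approx(0.4737, abs=2e-4)

    def test_round_trip_at_paper_value(self):
        slope = initial_slope_from_gm(0.42, 250, 82)
        assert gm_from_initial_slope(slope, 250, 82) == pytest.approx(0.42, rel=1e-10)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_round_trip_property(self, gm):
        slope = initial_slope_from_gm(gm)
        assert gm_from_initial_slope(slope) == pytest.approx(gm, rel=1e-10)

    def test_slope_above_asymptote_rejected(self):
        with pytest.raises(DomainError, match="asymptote"):
            gm_from_initial_slope(250 / 82 + 0.01)

    def test_low_slope_limit(self):
        assert gm_from_initial_slope(1e-6) == pytest.approx(1e-6, rel=1e-4)


class TestEnzymeLimitedModel:
    def test_zero_substrate_zero_assimilation(self):
        p = C4ModelParams(Rd=0.0, Rm=0.0)
        assert enzyme_limited_assimilation(0.0, p) == 0.0

    def test_small_cm_linearisation(self):
        # A ~ Cm*Vpmax/(Cm+Kp) - Rm in the PEPC-limited regime
        p = C4ModelParams(Rm=0.0, Rd=0.0)
        cm = 1.0
        expected = cm * 250 / (cm + 82)
        assert enzyme_limited_assimilation(cm, p) == pytest.approx(
            expected, rel=2e-3  # gbs leak-in term is ~0.1%
        )
        assert expected == pytest.approx(3.012, abs=2e-3)

    def test_saturation_at_large_cm(self):
        a = enzyme_limited_assimilation(5000.0, DEFAULT_PARAMS)
        assert a == pytest.approx(DEFAULT_PARAMS.Vcmax - DEFAULT_PARAMS.Rd)

    def test_monotone_non_decreasing(self):
        cms = np.linspace(0, 2000, 400)
        a = [enzyme_limited_assimilation(c, DEFAULT_PARAMS) for c in cms]
        assert np.all(np.diff(a) >= -1e-12)

    def test_negative_cm_rejected(self):
        with pytest.raises(DomainError):
            enzyme_limited_assimilation(-1.0)

    def test_params_validation(self):
        with pytest.raises(DomainError):
            C4ModelParams(Vpmax=-1)
        with pytest.raises(DomainError):
            C4ModelParams(Rm=2.0, Rd=1.0)


class TestCoupledSolver:
    def test_no_co2_no_assimilation(self):
        p = C4ModelParams(Rd=0.0, Rm=0.0)
        a, cm = solve_A_from_Ci(0.0, 0.42, p)
        assert a == pytest.approx(0.0, abs=1e-9)
        assert cm == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("gm", [0.2, 0.42, 0.59, 1.0])
    def test_solved_slope_matches_closed_form(self, gm):
        # oracle equivalence: finite-difference slope of the solved curve in
        # the linear PEPC regime (small Ci so enzyme curvature is negligible)
        p = C4ModelParams(Rd=0.0, Rm=0.0)
        a1, _ = solve_A_from_Ci(1.0, gm, p)
        a3, _ = solve_A_from_Ci(3.0, gm, p)
        fd = (a3 - a1) / 2.0
        assert fd == pytest.approx(initial_slope_from_gm(gm), rel=0.01)

    def test_infinite_gm_means_no_drawdown(self):
        a, cm = solve_A_from_Ci(100.0, 1e6)
        assert cm == pytest.approx(100.0, rel=1e-4)
        assert a == pytest.approx(enzyme_limited_assimilation(cm), abs=1e-6)

    def test_monotone_in_ci_and_gm(self):
        cis = np.linspace(0, 400, 41)
        a_low = np.array([solve_A_from_Ci(ci, 0.3)[0] for ci in cis])
        a_high = np.array([solve_A_from_Ci(ci, 0.6)[0] for ci in cis])
        assert np.all(np.diff(a_low) >= -1e-9)
        assert np.all(np.diff(a_high) >= -1e-9)
        # higher conductance helps whenever the leaf assimilates; below the
        # compensation point it equally speeds respiratory CO2 efflux
        gaining = a_low >= 0
        assert np.all(a_high[gaining] >= a_low[gaining] - 1e-9)

    def test_fixed_point_residual(self):
        a, cm = solve_A_from_Ci(167.0, 0.42)
        assert a == pytest.approx(0.42 * (167.0 - cm), abs=1e-9)
        assert a == pytest.approx(enzyme_limited_assimilation(cm), abs=1e-9)


class TestPredictedSlopeCurve:
    def test_four_genotype_grid(self):
        # g*250/(g*82+250) evaluated at the four genotype-level conductances
        got = predicted_slope_curve([0.42, 0.46, 0.55, 0.59], 250, 82)
        expected = [0.36915, 0.39969, 0.46594, 0.49434]
        for (g, s), e in zip(got, expected):
            assert s == pytest.approx(e, abs=1e-4)

    def test_singleton_equals_scalar_form(self):
        [(g, s)] = predicted_slope_curve([0.42])
        assert s == initial_slope_from_gm(0.42)

    def test_monotone_and_concave(self):
        grid = list(np.linspace(0.1, 2.0, 30))
        s = np.array([v for _, v in predicted_slope_curve(grid)])
        assert np.all(np.diff(s) > 0)
        assert np.all(np.diff(s, 2) < 0)

    def test_doubling_vpmax_raises_every_slope(self):
        grid = [0.2, 0.5, 1.0]
        s1 = [v for _, v in predicted_slope_curve(grid, 250, 82)]
        s2 = [v for _, v in predicted_slope_curve(grid, 500, 82)]
        assert all(b > a for a, b in zip(s1, s2))

    def test_empty_grid_rejected(self):
        with pytest.raises(DomainError):
            predicted_slope_curve([])
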