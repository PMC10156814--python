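import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bladeopt.curves import (
    NoIntersectionError,
    OperatingPoint,
    PerformanceCurve,
    curve_rmse,
    curves_from_frame,
    curves_to_frame,
    efficiency_at,
    fit_quartic,
    match_operating_point,
    phi_psi,
    rescale_curve,
    reynolds_rotational,
    scale_to_operating_point,
    scaled_speed,
    specific_speed,
)
from bladeopt.geometry import BladeDesign
from bladeopt.virtual_pump import simulate_curve


def make_curve(q, dp, eta=None, omega=20000.0, design_id="t"):
    q = np.asarray(q, dtype=float)
    if eta is None:
        eta = np.linspace(0.1, 0.3, len(q))
    return PerformanceCurve(design_id, omega, q, np.asarray(dp, dtype=float), np.asarray(eta))


class TestQuarticFit:
    def test_exact_polynomial_recovery_matches_normal_equations(self):
        c_true = np.array([1.0, -2.0, 0.0, 3.0, 40.0])
        q = np.arange(0.5, 4.01, 0.5)
        dp = np.polyval(c_true, q)
        fit = fit_quartic(make_curve(q, dp))
        assert np.allclose(fit.coefficients, c_true, atol=1e-8)
        assert fit.rmse_mmhg == pytest.approx(0.0, abs=1e-8)
        # independent normal-equations oracle
        a = np.vander(q, 5)
        oracle = np.linalg.solve(a.T @ a, a.T @ dp)
        assert np.allclose(fit.coefficients, oracle, atol=1e-6)
        assert fit.valid_range == (0.5, 4.0)

    def test_constant_pressure_curve(self):
        q = np.arange(0.5, 4.01, 0.5)
        fit = fit_quartic(make_curve(q, np.full_like(q, 70.0)))
        assert np.allclose(fit.coefficients[:4], 0.0, atol=1e-8)
        assert fit.coefficients[4] == pytest.approx(70.0, abs=1e-8)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_quartic(make_curve([1, 2, 3, 4], [70, 60, 50, 40]))


class TestDimensionlessCoefficients:
    def test_zero_flow_gives_zero_phi(self):
        phi, _ = phi_psi(0.0, 70.0, 20000.0)
        assert phi == 0.0

    def test_hand_checked_values(self):
        phi, psi = phi_psi(2.0, 70.0, 20000.0)
        assert phi == pytest.approx(0.0349, abs=2e-4)
        assert psi == pytest.approx(0.0342, abs=2e-4)


class TestMatchOperatingPoint:
    def test_identity_when_curve_passes_through_target(self):
        q = np.arange(0.5, 4.01, 0.5)
        dp = 100.0 - 10.0 * q  # passes through (2, 80)
        fit = fit_quartic(make_curve(q, dp))
        q2, dp2, extrap = match_operating_point(fit, OperatingPoint(2.0, 80.0))
        assert q2 == pytest.approx(2.0, rel=1e-9)
        assert dp2 == pytest.approx(80.0, rel=1e-9)
        assert not extrap

    def test_root_agrees_with_bisection_oracle_and_affinity_parabola(self, mid_design):
        curve = simulate_curve(mid_design, 20000.0)
        fit = fit_quartic(curve)
        target = OperatingPoint(2.0, 70.0)
        q2, dp2, _ = match_operating_point(fit, target)
        # Q2 lies simultaneously on the fitted curve and the affinity parabola
        assert dp2 == pytest.approx(target.dp_mmhg * (q2 / target.q_lpm) ** 2, rel=1e-9)
        # bisection oracle on g(Q) = fit(Q) - dP1 (Q/Q1)^2
        g = lambda q: fit(q) - target.dp_mmhg * (q / target.q_lpm) ** 2
        lo, hi = 2.0, 4.0
        assert g(lo) > 0 > g(hi)
        for _ in range(200):
            m = 0.5 * (lo + hi)
            lo, hi = (m, hi) if g(m) > 0 else (lo, m)
        assert q2 == pytest.approx(0.5 * (lo + hi), rel=1e-9)

    def test_unreachable_target_raises_with_root_set(self):
        q = np.arange(0.5, 4.01, 0.5)
        dp = -10.0 - 5.0 * q  # curve entirely below zero head
        fit = fit_quartic(make_curve(q, dp))
        # the affinity parabola through any positive target never meets it
        with pytest.raises(NoIntersectionError):
            match_operating_point(fit, OperatingPoint(1.0, 50.0))


class TestScaling:
    def test_scaled_speed_ratios(self):
        assert scaled_speed(20000.0, 2.0, 2.0) == 20000.0
        assert scaled_speed(20000.0, 2.0, 2.5) == pytest.approx(16000.0)

    def test_rescale_identity_and_quadratic_head(self, mid_design):
        c = simulate_curve(mid_design, 20000.0)
        same = rescale_curve(c, 20000.0)
        assert np.allclose(same.dp_mmhg, c.dp_mmhg)
        double = rescale_curve(c, 40000.0)
        assert np.allclose(double.dp_mmhg, 4.0 * c.dp_mmhg, rtol=1e-12)
        assert np.allclose(double.q_lpm, 2.0 * c.q_lpm, rtol=1e-12)
        assert np.array_equal(double.eta, c.eta)

    def test_affinity_round_trip_recovers_source_curve(self, mid_design):
        c = simulate_curve(mid_design, 20000.0)
        sc = scale_to_operating_point(c, OperatingPoint(2.0, 70.0))
        back = rescale_curve(sc.scaled_curve, c.omega_rpm)
        assert np.allclose(back.q_lpm, c.q_lpm, rtol=1e-9)
        assert np.allclose(back.dp_mmhg, c.dp_mmhg, rtol=1e-9)
        # round-tripping the speed itself
        sc2 = scale_to_operating_point(
            sc.scaled_curve, OperatingPoint(sc.q2_lpm, float(fit_quartic(c)(sc.q2_lpm)))
        )
        assert sc2.omega_scaled_rpm == pytest.approx(c.omega_rpm, rel=1e-9)

    @settings(deadline=None, max_examples=25)
    @given(seed=st.integers(0, 10_000))
    def test_scaling_result_satisfies_affinity_parabola(self, seed):
        rng = np.random.default_rng(seed)
        design = BladeDesign(
            beta1=rng.uniform(25, 40),
            beta2=rng.uniform(75, 90),
            alpha2=rng.uniform(25, 40),
            cl_imp=rng.uniform(9, 14),
            cl_diff=rng.uniform(9, 14),
        )
        curve = simulate_curve(design, 20000.0)
        target = OperatingPoint(2.0, 70.0)
        sc = scale_to_operating_point(curve, target)
        assert sc.dp2_mmhg == pytest.approx(
            target.dp_mmhg * (sc.q2_lpm / target.q_lpm) ** 2, rel=1e-9
        )
        # scaled quartic passes through the target exactly
        scaled_fit = fit_quartic(sc.scaled_curve)
        assert scaled_fit(target.q_lpm) == pytest.approx(target.dp_mmhg, abs=1e-6)


class TestInterpolation:
    def test_sample_point_and_midpoint(self):
        c = make_curve([1.5, 2.5, 3.5, 4.0, 4.5], [80, 70, 60, 55, 50],
                       eta=[0.2, 0.3, 0.25, 0.2, 0.15])
        assert efficiency_at(c, 2.5) == 0.3
        assert efficiency_at(c, 2.0) == pytest.approx(0.25)

    def test_extrapolation_refused(self):
        c = make_curve([1.5, 2.5, 3.5, 4.0, 4.5], [80, 70, 60, 55, 50])
        with pytest.raises(ValueError):
            efficiency_at(c, 1.0)
        with pytest.raises(ValueError):
            efficiency_at(c, 5.0)


class TestCurveRmse:
    def test_zero_offset_and_constant_offset(self):
        q = np.arange(0.5, 4.01, 0.5)
        a = make_curve(q, 100 - 10 * q)
        assert curve_rmse(a, a) == 0.0
        b = make_curve(q, 100 - 10 * q + 3.0)
        assert curve_rmse(a, b) == pytest.approx(3.0, rel=1e-12)

    def test_matches_brute_force_formula(self):
        rng = np.random.default_rng(0)
        q = np.arange(0.5, 4.01, 0.5)
        dp_a = 100 - 10 * q
        dp_b = dp_a + rng.normal(0, 2, q.size)
        a, b = make_curve(q, dp_a), make_curve(q, dp_b)
        assert curve_rmse(a, b) == pytest.approx(
            math.sqrt(np.mean((dp_a - dp_b) ** 2)), abs=1e-12
        )

    def test_disjoint_ranges_rejected(self):
        a = make_curve([0.5, 1.0, 1.5, 2.0, 2.5], [90, 85, 80, 75, 70])
        b = make_curve([3.0, 3.5, 4.0, 4.5, 5.0], [60, 55, 50, 45, 40])
        with pytest.raises(ValueError):
            curve_rmse(a, b)


class TestDimensionlessNumbers:
    def test_specific_speed_reference_value(self):
        ns = specific_speed(15000.0, OperatingPoint(2.0, 70.0))
        assert round(ns, 3) == 1.762

    def test_specific_speed_affinity_invariance_and_flow_scaling(self):
        op = OperatingPoint(2.0, 70.0)
        ns = specific_speed(15000.0, op)
        # affinity-scale the operating point to another speed
        k = 1.25
        scaled = OperatingPoint(op.q_lpm * k, op.dp_mmhg * k**2)
        assert specific_speed(15000.0 * k, scaled) == pytest.approx(ns, rel=1e-12)
        # quadrupling flow at fixed head doubles N_s
        ns4 = specific_speed(15000.0, OperatingPoint(8.0, 70.0))
        assert ns4 == pytest.approx(2.0 * ns, rel=1e-12)

    def test_rotational_reynolds(self):
        assert round(reynolds_rotational(20000.0), -3) == 37000
        assert reynolds_rotational(0.0) == 0.0
        from bladeopt.geometry import PumpConstants

        big = PumpConstants(shroud_radius_mm=7.7, diffuser_outlet_angle_deg=90.0)
        assert reynolds_rotational(20000.0, big) == pytest.approx(
            4.0 * reynolds_rotational(20000.0), rel=1e-12
        )


class TestCurveIO:
    def test_frame_round_trip(self, mid_design):
        c = simulate_curve(mid_design, 20000.0)
        frame = curves_to_frame([c])
        assert list(frame.columns) == ["design_id", "omega_rpm", "q_lpm", "dp_mmhg", "eta"]
        (back,) = curves_from_frame(frame)
        assert np.allclose(back.dp_mmhg, c.dp_mmhg)
        assert back.omega_rpm == c.omega_rpm
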