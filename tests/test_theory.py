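"""Scaling theory: exponents, kinetics ODEs, landscape, first-passage times."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from ejectsim.theory import (
    Regime,
    TheoryParams,
    build_landscape,
    critical_number,
    entering_time,
    kinetics_rhs,
    leaving_time,
    m_of_t_confined,
    m_of_t_nonconfined,
    mfpt_quadrature,
    predicted_exponents,
    speed_model,
    stage_time_predictions,
)


class TestExponents:
    def test_two_dimensional_predictions(self):
        p = predicted_exponents(2)
        assert p.nu == pytest.approx(0.75)
        assert p.z1 == pytest.approx(2.0)
        assert p.z2P == pytest.approx(1.5)
        assert p.x1 == pytest.approx(0.5)
        assert p.zeta1 == pytest.approx(1.0)
        assert p.zeta2 == pytest.approx(0.4)

    def test_three_dimensional_predictions(self):
        p = predicted_exponents(3, 0.6)
        assert p.z1 == pytest.approx(1.25)
        assert p.z2P == pytest.approx(1.2)
        assert p.x1 == pytest.approx(1.0 / 3.0)

    def test_composite_exponents(self):
        p = predicted_exponents(2)
        assert p.tau_ej_phi0_fixed_exponent == pytest.approx(11.0 / 6.0)
        assert p.tau2P_phi0_fixed_exponent == pytest.approx(5.0 / 3.0)
        assert p.tau2P_N_exponent == pytest.approx(2.5)

    def test_theory_breakdown_rejected(self):
        with pytest.raises(ValueError):
            predicted_exponents(2, nu=0.5)  # d*nu = 1

    def test_critical_number(self):
        assert critical_number(1.0 + 1e-12, 0.75) == pytest.approx(1.0)
        r = critical_number(16.0, 0.75) / critical_number(8.0, 0.75)
        assert r == pytest.approx(2 ** (4.0 / 3.0), rel=1e-12)
        assert math.isinf(critical_number(math.inf, 0.75))


class TestSpeedModel:
    def test_pure_power_sum_when_B2_zero(self, theory_2d):
        p = theory_2d.with_(B2=0.0)
        m = np.arange(1, 200)
        v = speed_model(m, 512, 10.0, p)
        expect = (p.A1 * m**2.0 / (512**0.5 * 10.0**4.0) + p.A2 * m**-1.5)
        np.testing.assert_allclose(v, expect, rtol=1e-12)

    def test_default_prefactors(self):
        p = TheoryParams()
        assert (p.A1, p.B2, p.A2) == (3.04, 0.010, 0.20)

    def test_second_virial_only_boosts(self, theory_2d):
        m = np.arange(1, 513)
        v0 = speed_model(m, 512, 12.0, theory_2d.with_(B2=0.0))
        v1 = speed_model(m, 512, 12.0, theory_2d)
        assert np.all(v1 >= v0)

    def test_argmin_matches_grid_scan(self, theory_2d):
        for D in (8.0, 12.0, 17.0):
            m = np.arange(1, 513)
            v = speed_model(m, 512, D, theory_2d)
            brute = m[np.argmin(v)]
            # analytic stationarity of the two-power balance (B2 correction
            # is tiny near the minimum): independent oracle
            del v
            grid = np.linspace(1.0, 512.0, 200001)
            fine = speed_model(grid, 512, D, theory_2d)
            assert abs(grid[np.argmin(fine)] - brute) < 1.0


class TestKineticsAndClosedForms:
    def test_confined_ode_matches_closed_form(self, theory_2d):
        # numeric integration of the confined kinetics against the
        # (1 + t/t0)^(-zeta1) solution
        N, D = 256, 10.0
        p = theory_2d.with_(N=N, Nstar=critical_number(D, 0.75), B2=0.0)
        t_end = 5e4
        sol = solve_ivp(lambda t, y: kinetics_rhs(y[0], t, p, "confined"),
                        (0, t_end), [float(N)], rtol=1e-10, atol=1e-10,
                        dense_output=True)
        ts = np.linspace(0, t_end, 50)
        closed = m_of_t_confined(ts, p) * N
        np.testing.assert_allclose(sol.sol(ts)[0], closed, rtol=1e-4)

    def test_confined_rate_power_law(self, theory_2d):
        p = theory_2d.with_(N=256, Nstar=20.0, B2=0.0)
        r1 = kinetics_rhs(50.0, 0.0, p, "confined")
        r2 = kinetics_rhs(100.0, 0.0, p, "confined")
        assert r2 / r1 == pytest.approx(2.0**p.z1, rel=1e-12)

    def test_nonconfined_stationary_at_midpoint(self, theory_2d):
        # entropic pull vanishes when the two tethered segments are equal
        p = theory_2d.with_(N=101, m_p=1)
        m_mid = (101 - 1) / 2.0
        assert kinetics_rhs(m_mid - 1e-9, 0.0, p, "nonconfined") == pytest.approx(0.0, abs=1e-12)

    def test_nonconfined_domain_error(self, theory_2d):
        p = theory_2d.with_(N=100, m_p=2)
        with pytest.raises(ValueError):
            kinetics_rhs(60.0, 0.0, p, "nonconfined")

    def test_entropic_pulling_ode_matches_closed_form(self, theory_2d):
        # dm/dt = -m^{-z2P}/dt0 integrated backward from m = 0 at tau_ej
        p = theory_2d.with_(N=128)
        tau_ej = 500.0
        ts = np.linspace(0.0, tau_ej - 1e-9, 40)
        closed = m_of_t_nonconfined(ts, tau_ej, p) * 128

        def rhs(t, y):
            return -y[0] ** (-p.z2P) / p.dt0

        m0 = closed[0]
        sol = solve_ivp(rhs, (0, ts[-1]), [m0], rtol=1e-9, atol=1e-12,
                        dense_output=True)
        np.testing.assert_allclose(sol.sol(ts[:-1])[0], closed[:-1], rtol=1e-3)

    def test_closed_form_endpoints(self, theory_2d):
        p = theory_2d.with_(N=64, Nstar=10.0)
        assert m_of_t_confined(0.0, p) == pytest.approx(1.0)
        assert m_of_t_nonconfined(123.0, 123.0, p) == 0.0
        with pytest.raises(ValueError):
            m_of_t_nonconfined(124.0, 123.0, p)

    def test_times_scale_with_dt0(self, theory_2d):
        # every returned time is linear in the characteristic monomer time
        p1 = theory_2d.with_(m_p=2)
        p2 = p1.with_(eta0=3.0)
        assert entering_time(p2, 2.0) == pytest.approx(3 * entering_time(p1, 2.0), rel=1e-9)
        assert leaving_time(p2, 2.0) == pytest.approx(3 * leaving_time(p1, 2.0), rel=1e-12)
        s1 = stage_time_predictions(64, 10.0, p1)
        s2 = stage_time_predictions(64, 10.0, p2)
        for a, b in [(s1.tau1, s2.tau1), (s1.tau2E, s2.tau2E), (s1.tau2P, s2.tau2P)]:
            assert b == pytest.approx(3 * a, rel=1e-9)


class TestLandscape:
    def test_regime_I_monotone(self, theory_2d):
        # phi0 above the pore volume fraction: downhill everywhere
        land = build_landscape(128, 10.0, None, theory_2d)  # phi0 = 1.28 > phi_p
        assert land.regime is Regime.I
        s = np.linspace(land.s_min, land.s_max, 2000)
        assert np.all(np.diff(land.F(s)) < 1e-9)

    def test_regime_IV_single_barrier_at_midpoint(self, theory_2d):
        # short chain in a huge cavity: one barrier peaking at m = s
        p = theory_2d.with_(m_p=1, dmu_cp=0.5)
        land = build_landscape(20, 60.0, None, p)
        assert land.regime is Regime.IV
        s = np.linspace(0.0, 19.0, 2001)
        F = land.F(s)
        peak = s[np.argmax(F)]
        assert peak == pytest.approx((20 - 1) / 2.0, abs=0.1)

    def test_regime_boundaries_tie_to_middle(self, theory_2d):
        from ejectsim.geometry import volume_fraction

        p = theory_2d.with_(m_p=1)
        nstar = critical_number(10.0, 0.75)
        # N - m_p just inside (N*, 2N*), quasi-2D phi0 below phi_p
        N = int(1.5 * nstar)
        phi0 = volume_fraction(N, 10.0, 1.5)
        assert phi0 < 0.296
        land = build_landscape(N, 10.0, phi0, p)
        assert land.regime is Regime.III

    def test_continuity_at_junctions(self, theory_2d):
        from ejectsim.geometry import volume_fraction

        p = theory_2d.with_(m_p=2, dmu_cp=1.0, dmu_ps=-2.0)
        land = build_landscape(80, 12.0, volume_fraction(80, 12.0, 1.5), p)
        for sj in (0.0, land.s_star, float(land.N - land.m_p)):
            lo = land.F(sj - 1e-7)
            hi = land.F(sj + 1e-7)
            assert abs(hi - lo) < 1e-4  # slope-limited gap across the junction
        assert land.F(0.0) == pytest.approx(0.0, abs=1e-12)

    def test_inconsistent_triple_rejected(self, theory_2d):
        with pytest.raises(ValueError):
            build_landscape(128, 10.0, 0.9, theory_2d)


class TestFirstPassage:
    def test_flat_potential_diffusive_limit(self, theory_2d):
        # zero chemical-potential difference: tau = eta lp^2 / (2 kT)
        p = theory_2d.with_(dmu_cp=0.0)
        for lp in (1.0, 2.0, 4.0):
            assert entering_time(p, lp) == pytest.approx(lp**2 / 2.0, rel=1e-6)

    def test_arrhenius_limit(self, theory_2d):
        # strong uphill: tau ~ exp(m_p dmu/kT); the prefactor ratio to the
        # Arrhenius form must be constant across m_p
        p = theory_2d.with_(dmu_cp=5.0)
        ratios = [entering_time(p, float(mp)) / math.exp(mp * 5.0)
                  for mp in (4, 6, 8)]
        assert max(ratios) / min(ratios) < 1.15

    def test_drift_limit_linear_in_mp(self, theory_2d):
        # strong downhill: tau ~ (eta sigma^2/|dmu|) m_p
        p = theory_2d.with_(dmu_cp=-10.0)
        taus = np.array([entering_time(p, float(mp)) for mp in (4, 6, 8)])
        per = taus / np.array([4.0, 6.0, 8.0])
        assert max(per) / min(per) < 1.10

    def test_quadrature_grid_convergence(self, theory_2d):
        p = theory_2d.with_(dmu_cp=3.0)
        coarse = entering_time(p, 4.0, n=2001)
        fine = entering_time(p, 4.0, n=4001)
        assert abs(fine - coarse) / fine < 1e-3

    def test_mfpt_monotone_in_barrier(self):
        t_low = mfpt_quadrature(lambda s: 1.0 * s, 0.0, 1.0)
        t_high = mfpt_quadrature(lambda s: 5.0 * s, 0.0, 1.0)
        assert t_high > t_low


class TestStageTimes:
    def test_table_rows(self, theory_2d):
        p = theory_2d.with_(m_p=1)
        # long chain: never a thermal-escape stage
        long = stage_time_predictions(512, 8.0, p)
        assert long.row == "N-m_p > 2N*"
        assert long.tau2E == 0.0
        assert long.tau1 > 0
        # short chain: never confined
        short = stage_time_predictions(12, 40.0, p)
        assert short.row == "N-m_p < N*"
        assert short.tau1 == 0.0
        assert short.tau2E > 0

    def test_tau1_closed_form_equals_ode_integration(self, theory_2d):
        N, D = 512, 8.0
        nstar = critical_number(D, 0.75)
        p = theory_2d.with_(N=N, Nstar=nstar, B2=0.0, m_p=1)
        pred = stage_time_predictions(N, D, p)

        sol = solve_ivp(lambda t, y: kinetics_rhs(y[0], t, p, "confined"),
                        (0, 1e9), [float(N)], rtol=1e-10, atol=1e-10,
                        events=lambda t, y: y[0] - nstar, dense_output=False)
        t_hit = sol.t_events[0][0]
        assert pred.tau1 == pytest.approx(t_hit, rel=1e-3)

    def test_tau2P_forms(self, theory_2d):
        p = theory_2d.with_(m_p=1)
        zp1 = 1 + p.z2P
        long = stage_time_predictions(512, 8.0, p)
        nstar = critical_number(8.0, 0.75)
        assert long.tau2P == pytest.approx(nstar**zp1 / zp1, rel=1e-12)
        short = stage_time_predictions(12, 40.0, p)
        assert short.tau2P == pytest.approx((12 / 2.0) ** zp1 / zp1, rel=1e-12)


class TestLeavingTime:
    def test_linear_in_pore_length_and_driving(self, theory_2d):
        p = theory_2d.with_(dmu_ps=-1.0)
        assert leaving_time(p, 4.0) == pytest.approx(2 * leaving_time(p, 2.0), rel=1e-12)
        p2 = p.with_(dmu_ps=-2.0)
        assert leaving_time(p2, 2.0) == pytest.approx(leaving_time(p, 2.0) / 2, rel=1e-12)

    def test_unit_substitution(self, theory_2d):
        p = theory_2d.with_(dmu_ps=-1.0)
        assert leaving_time(p, 1.0) == pytest.approx(1.0, rel=1e-12)

    def test_uphill_rejected(self, theory_2d):
        with pytest.raises(ValueError):
            leaving_time(theory_2d.with_(dmu_ps=0.5), 1.0)
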