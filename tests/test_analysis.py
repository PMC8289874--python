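"""Trajectory analysis: monotonization, waiting times, trimming, stages, fits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ejectsim.analysis import (
    FIT_WINDOW_CONFINED,
    FIT_WINDOW_NONCONFINED,
    decompose_stages,
    detect_Nstar,
    fit_entering_exponential,
    fit_power_law,
    rescale_speed,
    stage_table,
    state_series,
    trim_nucleation,
    waiting_times,
)
from ejectsim.events import EventSeries
from ejectsim.fixtures import FixtureSpec, generate_event_series
from ejectsim.theory import entering_time, speed_model


def _series_from_m_walk(m_walk, dt=1.0, N=None, m_p=1):
    """Build a schema-valid EventSeries from an m(t) walk ending at 0."""
    m = np.asarray(m_walk, dtype=np.int64)
    N = N if N is not None else int(m.max())
    t = np.arange(len(m), dtype=float) * dt
    s = np.maximum(N - m_p - m, 0)
    # leaving tail to s = N
    t = np.append(t, t[-1] + dt)
    m = np.append(m, 0)
    s = np.append(s, N)
    return EventSeries(t=t, m=m, s=s, N=N, m_p=m_p)


def _brute_last_departure(m, t):
    """Independent oracle: for each level v, last time m drops below v."""
    out = {}
    for k in range(1, len(m)):
        if m[k] < m[k - 1]:
            for v in range(m[k], m[k - 1]):
                out[v] = t[k]
    return out


class TestStateSeries:
    def test_strictly_decreasing_unchanged(self):
        ev = _series_from_m_walk([5, 4, 3, 2, 1, 0])
        ss = state_series(ev)
        assert list(ss["m"]) == [5, 4, 3, 2, 1, 0]
        np.testing.assert_allclose(np.diff(ss["t"]), 1.0)

    def test_recrossing_takes_last_departure(self):
        # 5 -> 4 -> 5 -> 4: one departure from 5, at the final 5 -> 4 time
        ev = _series_from_m_walk([5, 4, 5, 4, 3, 2, 1, 0])
        ss = state_series(ev)
        t_at_4 = float(ss.loc[ss["m"] == 4, "t"].iloc[0])
        assert t_at_4 == 3.0

    @given(st.lists(st.sampled_from([-1, 1]), min_size=4, max_size=60))
    @settings(deadline=None, max_examples=50)
    def test_matches_brute_force_on_random_walks(self, steps):
        m = [8]
        for s_ in steps:
            m.append(min(max(m[-1] + s_, 0), 8))
            if m[-1] == 0:
                break
        if m[-1] != 0:
            m.append(0)
        # strip repeated values (events fire on change only)
        walk = [m[0]] + [b for a, b in zip(m, m[1:]) if b != a]
        if walk[-1] != 0:
            walk.append(0)
        ev = _series_from_m_walk(walk)
        ss = state_series(ev)
        oracle = _brute_last_departure(list(ev.m), list(ev.t))
        got = dict(zip(ss["m"], ss["t"]))
        for v, t_dep in oracle.items():
            assert got[v] == t_dep

    def test_monotone_output(self):
        ev = _series_from_m_walk([6, 5, 6, 5, 4, 5, 4, 3, 2, 1, 0])
        ss = state_series(ev)
        assert (np.diff(ss["m"]) <= 0).all()
        assert (np.diff(ss["t"]) >= 0).all()


class TestWaitingTimes:
    def test_uniform_dwell(self):
        ev = _series_from_m_walk([8, 7, 6, 5, 4, 3, 2, 1, 0], dt=2.5)
        prof = waiting_times([ev])
        ok = np.isfinite(prof.W)
        np.testing.assert_allclose(prof.W[ok], 2.5)
        np.testing.assert_allclose(prof.V[ok], 1 / 2.5)

    def test_unvisited_states_masked_not_zero(self):
        ev = _series_from_m_walk([8, 6, 4, 2, 0])  # odd states skipped
        prof = waiting_times([ev])
        assert np.isnan(prof.W[0])  # m=1 never occupied
        assert np.isfinite(prof.W[1])

    def test_residence_sums_to_ejection_time(self, theory_2d):
        spec = FixtureSpec(N=64, D=8.0, theory=theory_2d, noise="exponential",
                           seed=5, n_runs=10)
        runs = generate_event_series(spec)
        prof = waiting_times(runs)
        tab = stage_table(runs, Nstar=None)
        mean_ej = float(tab.loc[tab["run"] == "mean", "tau_ej"].iloc[0])
        mean_ent = float(tab.loc[tab["run"] == "mean", "tau_ent"].iloc[0])
        # total residence over all states = total pre-leaving span
        assert np.nansum(prof.W) == pytest.approx(mean_ej + mean_ent, rel=1e-9)

    def test_censored_excluded(self, theory_2d):
        spec = FixtureSpec(N=32, D=8.0, theory=theory_2d, seed=1, n_runs=2)
        runs = generate_event_series(spec)
        runs[0].censored = True
        prof = waiting_times(runs)
        assert prof.n.max() == 1
        with pytest.raises(ValueError):
            waiting_times([runs[0]])


class TestDetectNstar:
    def test_matches_model_argmin(self, theory_2d):
        for D in (10.0, 14.0):
            N = 512
            spec = FixtureSpec(N=N, D=D, theory=theory_2d,
                               noise="deterministic", seed=0, n_runs=1)
            prof = waiting_times(generate_event_series(spec))
            found = detect_Nstar(prof)
            grid = np.arange(2, N)
            brute = grid[np.argmin(speed_model(grid, N, D, theory_2d))]
            assert abs(found - brute) <= 2  # within the smoothing window

    def test_monotone_profile_flags_no_minimum(self, theory_2d):
        spec = FixtureSpec(N=128, D=math.inf, theory=theory_2d,
                           noise="deterministic", seed=0, n_runs=1)
        prof = waiting_times(generate_event_series(spec))
        assert detect_Nstar(prof) is None

    def test_too_few_states_rejected(self):
        ev = _series_from_m_walk([3, 2, 1, 0])
        with pytest.raises(ValueError):
            detect_Nstar(waiting_times([ev]))


class TestTrimNucleation:
    def test_identity_normalization(self, theory_2d):
        spec = FixtureSpec(N=32, D=8.0, theory=theory_2d,
                           noise="deterministic", seed=0, n_runs=1)
        runs = generate_event_series(spec)
        curve = trim_nucleation(runs, m_n=0, tau_n=0.0)
        assert curve["m_tilde"].max() == pytest.approx(1.0)
        assert curve["m_tilde"].min() == pytest.approx(0.0)
        assert curve["t_tilde"].min() >= 0.0
        assert curve["t_tilde"].max() <= 1.0 + 1e-12

    def test_default_rule_high_phi0(self, theory_2d):
        # phi0 >= phi_p: no plateau, nothing trimmed
        spec = FixtureSpec(N=32, D=8.0, theory=theory_2d,
                           noise="deterministic", seed=0, n_runs=1)
        runs = generate_event_series(spec)
        c_rule = trim_nucleation(runs, phi0=0.3)
        c_zero = trim_nucleation(runs, m_n=0, tau_n=0.0)
        np.testing.assert_allclose(c_rule["t_tilde"], c_zero["t_tilde"])

    def test_plateau_removed_from_staircase(self, theory_2d):
        # synthetic staircase with m_p stalled initial states
        m_p = 3
        spec = FixtureSpec(N=32, D=8.0, theory=theory_2d, lp=float(m_p),
                           noise="deterministic", seed=0, n_runs=1,
                           include_entering=True, tau_ent_mean=900.0)
        runs = generate_event_series(spec)
        trimmed = trim_nucleation(runs, phi0=0.01)  # low phi0: trim m_p, tau_ent
        # after trimming the curve must not retain the long stall at the top
        top = trimmed[trimmed["m_tilde"] > 0.97]
        assert top["t_tilde"].max() < 0.2

    def test_tau_n_bounds(self, theory_2d):
        spec = FixtureSpec(N=16, D=8.0, theory=theory_2d,
                           noise="deterministic", seed=0, n_runs=1)
        runs = generate_event_series(spec)
        with pytest.raises(ValueError):
            trim_nucleation(runs, m_n=0, tau_n=1e12)


class TestDecomposeStages:
    def test_exact_recovery_from_crafted_series(self):
        # dwell 2.0 at every state, N=12, m_p=1, Nstar=6 -> known segments
        ev = _series_from_m_walk(list(range(12, -1, -1)), dt=2.0, N=12)
        st_ = decompose_stages(ev, Nstar=6.0)
        # s reaches 1 when m = 10 (after pore fill), i.e. at t = 2 steps
        assert st_.tau_ent == pytest.approx(4.0)
        assert st_.tau1 == pytest.approx(2.0 * 4)   # m: 10 -> 6
        # (N - m_p)/2 = 5.5 -> first m <= 5.5 is m = 5
        assert st_.tau2E == pytest.approx(2.0)
        assert st_.tau2P == pytest.approx(2.0 * 5)  # m: 5 -> 0
        assert st_.tau == pytest.approx(ev.span)

    def test_components_sum_to_span(self, theory_2d):
        spec = FixtureSpec(N=64, D=8.0, theory=theory_2d, noise="exponential",
                           seed=9, n_runs=5)
        for ev in generate_event_series(spec):
            st_ = decompose_stages(ev, Nstar=10.0)
            assert st_.tau == pytest.approx(ev.span, abs=1e-9)
            for v in (st_.tau_ent, st_.tau1, st_.tau2E, st_.tau2P, st_.tau_leav):
                assert v >= 0

    def test_no_escape_stage_when_boundary_ordering_allows(self, theory_2d):
        # N - m_p > 2 N*: the confined boundary is already past the midpoint
        ev = _series_from_m_walk(list(range(40, -1, -1)), N=40)
        st_ = decompose_stages(ev, Nstar=8.0)
        assert st_.tau2E == 0.0

    def test_censored_rejected(self):
        ev = _series_from_m_walk([5, 4, 3, 2, 1, 0])
        ev.censored = True
        with pytest.raises(ValueError):
            decompose_stages(ev, Nstar=None)

    def test_mean_row_telescopes(self, theory_2d):
        spec = FixtureSpec(N=32, D=8.0, theory=theory_2d, noise="exponential",
                           seed=2, n_runs=8)
        tab = stage_table(generate_event_series(spec), Nstar=8.0)
        mean = tab[tab["run"] == "mean"].iloc[0]
        total = (mean["tau_ent"] + mean["tau1"] + mean["tau2E"]
                 + mean["tau2P"] + mean["tau_leav"])
        assert total == pytest.approx(mean["tau"], rel=1e-12)


class TestFits:
    def test_exact_power_law(self):
        x = np.linspace(2.0, 50.0, 30)
        fr = fit_power_law(x, 3.0 * x**1.5)
        assert fr.params["exponent"] == pytest.approx(1.5, abs=1e-12)
        assert fr.params["amplitude"] == pytest.approx(3.0, rel=1e-10)

    def test_noisy_exponent_recovery(self):
        # Monte-Carlo oracle: lognormal multiplicative noise, 95% coverage
        rng = np.random.default_rng(42)
        hits = 0
        for _ in range(40):
            x = np.linspace(1.0, 30.0, 50)
            y = x**-1.43 * rng.lognormal(0.0, 0.05, size=50)
            fr = fit_power_law(x, y)
            hits += abs(fr.params["exponent"] + 1.43) < 0.05
        assert hits >= 34

    def test_window_stored_verbatim(self):
        x = np.linspace(0.1, 1.0, 50)
        fr = fit_power_law(x, x**2.0, window=FIT_WINDOW_NONCONFINED)
        assert fr.window == (0.01, 0.5)
        assert FIT_WINDOW_CONFINED == (0.5, 0.95)

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError):
            fit_power_law([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_exponential_fit_exact(self):
        lp = np.array([1.0, 2.0, 3.0, 4.0])
        fr = fit_entering_exponential(lp, 2.0 * np.exp(1.3 * lp))
        assert fr.params["a_n"] == pytest.approx(2.0, abs=1e-8)
        assert fr.params["b_n"] == pytest.approx(1.3, abs=1e-8)

    def test_exponential_fit_against_theory_times(self, theory_2d):
        # entering_time at strong uphill follows the Arrhenius slope
        # b_n ~ dmu_cp/(sigma kT)
        p = theory_2d.with_(dmu_cp=3.0)
        lp = np.arange(1.0, 6.0)
        taus = np.array([entering_time(p, float(v)) for v in lp])
        fr = fit_entering_exponential(lp, taus)
        assert fr.params["b_n"] == pytest.approx(3.0, rel=0.10)
        # weaker driving gives a smaller slope
        p2 = theory_2d.with_(dmu_cp=1.5)
        taus2 = np.array([entering_time(p2, float(v)) for v in lp])
        assert fit_entering_exponential(lp, taus2).params["b_n"] < fr.params["b_n"]

    def test_nonpositive_times_rejected(self):
        with pytest.raises(ValueError):
            fit_entering_exponential([1.0, 2.0, 3.0], [1.0, -2.0, 3.0])


class TestRescaleSpeed:
    def test_confined_window_flat_at_true_exponents(self, theory_2d):
        p = theory_2d.with_(B2=0.0)
        spec = FixtureSpec(N=256, D=10.0, theory=p, noise="deterministic",
                           seed=0, n_runs=1)
        prof = waiting_times(generate_event_series(spec))
        rs = rescale_speed(prof, 256, x1=p.x1, z1=p.z1, z2P=p.z2P)
        assert rs.flatness("confined", FIT_WINDOW_CONFINED) < 0.02

    def test_flatness_degrades_off_truth(self, theory_2d):
        p = theory_2d.with_(B2=0.0)
        spec = FixtureSpec(N=256, D=10.0, theory=p, noise="deterministic",
                           seed=0, n_runs=1)
        prof = waiting_times(generate_event_series(spec))
        f_true = rescale_speed(prof, 256, p.x1, p.z1, p.z2P).flatness(
            "confined", FIT_WINDOW_CONFINED)
        f_lo = rescale_speed(prof, 256, p.x1, p.z1 - 0.1, p.z2P).flatness(
            "confined", FIT_WINDOW_CONFINED)
        f_hi = rescale_speed(prof, 256, p.x1, p.z1 + 0.1, p.z2P).flatness(
            "confined", FIT_WINDOW_CONFINED)
        assert f_lo > f_true and f_hi > f_true

    def test_nonconfined_window_flat_at_true_z2P(self, theory_2d):
        spec = FixtureSpec(N=256, D=math.inf, theory=theory_2d,
                           noise="deterministic", seed=0, n_runs=1)
        prof = waiting_times(generate_event_series(spec))
        rs = rescale_speed(prof, 256, theory_2d.x1, theory_2d.z1, theory_2d.z2P)
        assert rs.flatness("nonconfined", FIT_WINDOW_NONCONFINED) < 0.02

    def test_nonfinite_exponents_rejected(self, theory_2d):
        spec = FixtureSpec(N=32, D=8.0, theory=theory_2d,
                           noise="deterministic", seed=0, n_runs=1)
        prof = waiting_times(generate_event_series(spec))
        with pytest.raises(ValueError):
            rescale_speed(prof, 32, math.nan, 2.0, 1.5)
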