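"""Ensemble analysis of ejection event series.

Turns collections of :class:`~ejectsim.events.EventSeries` into the
quantities the theory predicts: the waiting-time function ``W(m)`` and
ejection speed ``V_ej(m) = sigma/W(m)``, the critical size ``N*`` (minimum of
the speed curve), nucleation-trimmed decay curves of ``m``, the
entering / confined / thermal-escape / entropic-pulling / leaving stage
decomposition, and the log-log and exponential regression fits.

Two dwell conventions coexist deliberately:

* ``W(m)`` uses *raw residence* — total time spent at state ``m``, counting
  re-crossings ("duration of a chain staying at each state");
* stage boundaries use *first-passage / last-departure* semantics — the time
  a level is permanently left downward — so stage times telescope exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .events import EventSeries
from .theory import PHI_P_DEFAULT

__all__ = [
    "SpeedProfile",
    "StageTimes",
    "FitResult",
    "state_series",
    "waiting_times",
    "detect_Nstar",
    "trim_nucleation",
    "decompose_stages",
    "stage_table",
    "fit_power_law",
    "fit_entering_exponential",
    "rescale_speed",
    "RescaledSpeed",
]

#: the two fit windows (in m/N) used for the non-confined / confined speed fits
FIT_WINDOW_NONCONFINED = (0.01, 0.5)
FIT_WINDOW_CONFINED = (0.5, 0.95)


# ---------------------------------------------------------------------------
# per-run timelines
# ---------------------------------------------------------------------------

def state_series(ev: EventSeries) -> pd.DataFrame:
    """Monotone state timeline: last-departure times of each ``m`` level.

    For every level ``v`` visited, records the time of the *final* downward
    crossing ``m >= v -> m <= v-1`` (after which the chain never returns to
    ``>= v``). A re-crossing sequence 5 -> 4 -> 5 -> 4 therefore yields a
    single departure from 5 at the last 5 -> 4 time. The result is a
    DataFrame with columns ``m`` (level, descending) and ``t`` (departure
    time), monotone non-increasing in ``m`` as time advances; the first row
    is the initial state at the initial time.
    """
    if len(ev) == 0:
        raise ValueError("empty event series")
    m, t = ev.m, ev.t
    rows_m = [int(m[0])]
    rows_t = [float(t[0])]
    prev, cur = m[:-1], m[1:]
    for v in range(int(m.max()), int(m.min()), -1):
        mask = (prev >= v) & (cur <= v - 1)
        idx = np.nonzero(mask)[0]
        if idx.size:
            rows_m.append(v - 1)
            rows_t.append(float(t[idx[-1] + 1]))
    df = pd.DataFrame({"m": rows_m, "t": rows_t}).sort_values("t", kind="stable")
    return df.reset_index(drop=True)


def arrival_times(ev: EventSeries) -> pd.DataFrame:
    """Mean-curve helper: time of (final) arrival at every reached level."""
    return state_series(ev)


# ---------------------------------------------------------------------------
# waiting times / speed profile
# ---------------------------------------------------------------------------

@dataclass
class SpeedProfile:
    """Per-state mean dwell time and ejection speed over m = 1..N.

    ``W[m-1]`` is the mean residence time at state ``m`` over the runs that
    visited it (NaN where no run did — never zero-filled); ``V = sigma/W``;
    ``n`` counts contributing runs.
    """

    N: int
    m: np.ndarray
    W: np.ndarray
    V: np.ndarray
    n: np.ndarray
    sigma: float = 1.0

    def defined(self) -> np.ndarray:
        return np.isfinite(self.W)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"m": self.m, "W": self.W, "V": self.V, "n": self.n})


def _residence(ev: EventSeries) -> np.ndarray:
    """Total time spent at each m state (index m, length N+1), raw residence."""
    res = np.zeros(ev.N + 1)
    dt = np.diff(ev.t)
    np.add.at(res, ev.m[:-1], dt)
    return res


def waiting_times(runs: list[EventSeries], sigma: float = 1.0) -> SpeedProfile:
    """Waiting-time function W(m) and speed V(m) = sigma/W(m) of an ensemble.

    Censored runs are excluded. States visited by no run get NaN entries.
    """
    runs = [r for r in runs if not r.censored]
    if not runs:
        raise ValueError("need at least one uncensored run")
    N = runs[0].N
    if any(r.N != N for r in runs):
        raise ValueError("mixed chain lengths in ensemble")
    tot = np.zeros(N + 1)
    cnt = np.zeros(N + 1, dtype=int)
    for ev in runs:
        res = _residence(ev)
        visited = res > 0
        tot[visited] += res[visited]
        cnt[visited] += 1
    m = np.arange(1, N + 1)
    W = np.full(N, np.nan)
    ok = cnt[1:] > 0
    W[ok] = tot[1:][ok] / cnt[1:][ok]
    V = sigma / W
    return SpeedProfile(N=N, m=m, W=W, V=V, n=cnt[1:].copy(), sigma=sigma)


def _geometric_smooth(v: np.ndarray, window: int) -> np.ndarray:
    """Centred moving geometric mean, NaN-aware, window must be odd."""
    if window % 2 != 1:
        raise ValueError("smoothing window must be odd")
    logv = np.log(v)
    out = np.full_like(logv, np.nan)
    h = window // 2
    n = len(v)
    for i in range(n):
        seg = logv[max(0, i - h): min(n, i + h + 1)]
        seg = seg[np.isfinite(seg)]
        if seg.size:
            out[i] = seg.mean()
    return np.exp(out)


def detect_Nstar(profile: SpeedProfile, window: int = 5,
                 contrast: float = 1.5) -> int | None:
    """Critical size N*: position of the minimum of the smoothed speed curve.

    The speed is smoothed by a centred moving geometric mean (default window
    5) and the minimum searched on 1 < m < N. A genuine minimum must be
    interior *and* rise by at least the ``contrast`` factor on both sides;
    otherwise the profile is monotone up to noise (translocation-like,
    D = inf) and ``None`` is returned (NO_MINIMUM).
    """
    ok = profile.defined()
    if ok.sum() < 5:
        raise ValueError("profile must be defined on at least 5 states")
    m = profile.m[ok]
    v = _geometric_smooth(profile.V[ok], window)
    interior = (m > 1) & (m < profile.N)
    if interior.sum() < 3:
        raise ValueError("too few interior states")
    mi, vi = m[interior], v[interior]
    i = int(np.nanargmin(vi))
    if i == 0 or i == len(vi) - 1:
        return None
    left_rise = np.nanmax(vi[:i]) / vi[i]
    right_rise = np.nanmax(vi[i + 1:]) / vi[i]
    if left_rise < contrast or right_rise < contrast:
        return None
    return int(mi[i])


# ---------------------------------------------------------------------------
# decrease of m: mean curves and nucleation trimming
# ---------------------------------------------------------------------------

def mean_arrival_curve(runs: list[EventSeries]) -> pd.DataFrame:
    """Ensemble mean time <t>(m) to (finally) reach each state m.

    Only levels reached by every uncensored run are kept, so the mean is
    over a fixed ensemble at each level.
    """
    runs = [r for r in runs if not r.censored]
    if not runs:
        raise ValueError("need at least one uncensored run")
    N = runs[0].N
    acc = np.zeros(N + 1)
    cnt = np.zeros(N + 1, dtype=int)
    for ev in runs:
        ss = state_series(ev)
        lv = ss["m"].to_numpy()
        tv = ss["t"].to_numpy() - ev.t[0]
        acc[lv] += tv
        cnt[lv] += 1
    full = cnt == len(runs)
    m = np.nonzero(full)[0]
    return pd.DataFrame({"m": m[::-1], "t": acc[full][::-1] / len(runs)})


def trim_nucleation(runs: list[EventSeries], m_n: int | None = None,
                    tau_n: float | None = None, *, phi0: float | None = None,
                    phi_p: float = PHI_P_DEFAULT) -> pd.DataFrame:
    """Nucleation-trimmed, normalized mean decay curve of m.

    Returns columns ``m``, ``m_tilde = (m - m_n)/(N - m_n)`` and
    ``t_tilde = (<t> - tau_n)/(<tau> - tau_n)``.

    Defaults follow the stalling rule: for ``phi0 < phi_p`` the initial
    plateau spans the pore (critical nucleus ``m_n = m_p``) and the
    nucleation time is the mean entering time; for ``phi0 >= phi_p`` both
    are zero (no plateau). Explicit ``m_n``/``tau_n`` override the rule.
    """
    live = [r for r in runs if not r.censored]
    if not live:
        raise ValueError("need at least one uncensored run")
    N, m_p = live[0].N, live[0].m_p
    if m_n is None or tau_n is None:
        if phi0 is None:
            raise ValueError("phi0 required to apply the default trimming rule")
        if phi0 >= phi_p:
            m_n_d, tau_n_d = 0, 0.0
        else:
            m_n_d = m_p
            tau_n_d = float(np.mean([decompose_stages(r, Nstar=None).tau_ent
                                     for r in live]))
        m_n = m_n_d if m_n is None else m_n
        tau_n = tau_n_d if tau_n is None else tau_n
    if m_n < 0 or tau_n < 0:
        raise ValueError("m_n and tau_n must be non-negative")
    curve = mean_arrival_curve(live)
    tau_mean = float(np.mean([r.span for r in live]))
    if tau_n >= tau_mean:
        raise ValueError(f"tau_n={tau_n} >= mean total time {tau_mean}")
    m = curve["m"].to_numpy(dtype=float)
    t = curve["t"].to_numpy()
    keep = m >= m_n
    return pd.DataFrame({
        "m": m[keep],
        "m_tilde": (m[keep] - m_n) / (N - m_n),
        "t_tilde": (t[keep] - tau_n) / (tau_mean - tau_n),
    })


# ---------------------------------------------------------------------------
# stage decomposition
# ---------------------------------------------------------------------------

@dataclass
class StageTimes:
    """Durations of the five stages of one run (reduced time units).

    tau_ent : entering (until the first monomer reaches the semi-space)
    tau1    : confined main ejection (until first passage m <= N*)
    tau2E   : thermal escape (until first passage m <= (N - m_p)/2)
    tau2P   : entropic pulling (until m = 0)
    tau_leav: leaving (until the final record, s = N)
    """

    tau_ent: float
    tau1: float
    tau2E: float
    tau2P: float
    tau_leav: float
    Nstar: float | None = None

    @property
    def tau_ej(self) -> float:
        return self.tau1 + self.tau2E + self.tau2P

    @property
    def tau(self) -> float:
        return self.tau_ent + self.tau_ej + self.tau_leav


def decompose_stages(ev: EventSeries, Nstar: float | None) -> StageTimes:
    """Split one completed run into its five stage durations.

    First-passage boundaries: s >= 1 (entering done), m <= N* (confined
    done), m <= (N - m_p)/2 (thermal escape done; zero duration when N*
    already lies at or below the midpoint), m == 0 (main ejection done),
    end of record (leaving done). ``Nstar = None`` (or >= N) means the run
    is never confined: tau1 = 0.
    """
    if ev.censored:
        raise ValueError("cannot decompose a censored run")
    ev.validate()
    t0 = float(ev.t[0])
    t_end = float(ev.t[-1])

    def first_time(cond: np.ndarray) -> float:
        idx = np.nonzero(cond)[0]
        if idx.size == 0:
            raise ValueError("stage boundary never reached in a complete run")
        return float(ev.t[idx[0]])

    t_ent = first_time(ev.s >= 1)
    mid = (ev.N - ev.m_p) / 2.0
    if mid < 0 or mid > ev.N:
        raise ValueError("stage boundary outside [0, N]")
    if Nstar is None or Nstar >= ev.N:
        t_conf = t_ent  # never confined
        nstar_eff = None
    else:
        if Nstar < 0:
            raise ValueError("Nstar outside [0, N]")
        t_conf = max(first_time(ev.m <= Nstar), t_ent)
        nstar_eff = Nstar
    t_mid = max(first_time(ev.m <= mid), t_conf)
    if nstar_eff is not None and nstar_eff <= mid:
        t_mid = t_conf  # boundary ordering: escape stage absent
    t_zero = max(first_time(ev.m == 0), t_mid)
    return StageTimes(
        tau_ent=t_ent - t0,
        tau1=t_conf - t_ent,
        tau2E=t_mid - t_conf,
        tau2P=t_zero - t_mid,
        tau_leav=t_end - t_zero,
        Nstar=nstar_eff,
    )


def stage_table(runs: list[EventSeries], Nstar: float | None) -> pd.DataFrame:
    """Per-run stage durations plus an ensemble-mean row (censored excluded)."""
    rows = []
    for i, ev in enumerate(runs):
        if ev.censored:
            continue
        st = decompose_stages(ev, Nstar)
        rows.append({"run": i, "tau_ent": st.tau_ent, "tau1": st.tau1,
                     "tau2E": st.tau2E, "tau2P": st.tau2P,
                     "tau_leav": st.tau_leav, "tau_ej": st.tau_ej, "tau": st.tau})
    if not rows:
        raise ValueError("no uncensored runs")
    df = pd.DataFrame(rows)
    mean = df.drop(columns="run").mean()
    mean["run"] = "mean"
    return pd.concat([df, mean.to_frame().T], ignore_index=True)


# ---------------------------------------------------------------------------
# regression fits
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Outcome of a regression fit.

    ``params``/``stderr`` are keyed by parameter name; ``window`` is stored
    verbatim as passed; ``residual_norm`` is the RMS residual of the fitted
    model (in log space for the power law).
    """

    model: str
    params: dict = field(default_factory=dict)
    stderr: dict = field(default_factory=dict)
    window: tuple | None = None
    residual_norm: float = math.nan
    n_points: int = 0


def fit_power_law(x, y, window: tuple[float, float] | None = None,
                  window_on: np.ndarray | None = None) -> FitResult:
    """Least-squares power-law fit, log y = log a + b log x.

    ``window`` restricts the fit to points whose ``window_on`` value
    (default: ``x`` itself) lies strictly inside ``(lo, hi)`` — e.g. pass
    ``window_on = m/N`` with the standard speed-fit windows. Returns the
    exponent and amplitude with 1-sigma standard errors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ref = x if window_on is None else np.asarray(window_on, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y) & (x > 0) & (y > 0)
    if window is not None:
        lo, hi = window
        keep &= (ref > lo) & (ref < hi)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError(f"need >= 3 points in window, got {len(x)}")
    lx, ly = np.log(x), np.log(y)
    if np.ptp(lx) == 0:
        raise ValueError("degenerate x values (zero spread)")
    (b, la), cov = np.polyfit(lx, ly, 1, cov=True)
    resid = ly - (la + b * lx)
    return FitResult(
        model="power-law",
        params={"exponent": float(b), "amplitude": float(np.exp(la))},
        stderr={"exponent": float(np.sqrt(cov[0, 0])),
                "amplitude": float(np.exp(la) * np.sqrt(cov[1, 1]))},
        window=window,
        residual_norm=float(np.sqrt(np.mean(resid**2))),
        n_points=len(x),
    )


def fit_entering_exponential(lp, tau_ent) -> FitResult:
    """Nonlinear fit of the entering time to a_n exp(b_n l_p).

    The exponential form holds for phi0 below the pore volume fraction;
    ``b_n`` estimates dmu_cp/(sigma kT). Requires >= 3 pore lengths and
    positive times.
    """
    lp = np.asarray(lp, dtype=float)
    tau = np.asarray(tau_ent, dtype=float)
    if len(lp) < 3:
        raise ValueError("need at least 3 pore lengths")
    if np.any(tau <= 0):
        raise ValueError("entering times must be positive")
    b0, la0 = np.polyfit(lp, np.log(tau), 1)
    popt, pcov = curve_fit(lambda x, a, b: a * np.exp(b * x), lp, tau,
                           p0=[np.exp(la0), b0], maxfev=10000)
    resid = tau - popt[0] * np.exp(popt[1] * lp)
    err = np.sqrt(np.diag(pcov))
    return FitResult(
        model="exponential",
        params={"a_n": float(popt[0]), "b_n": float(popt[1])},
        stderr={"a_n": float(err[0]), "b_n": float(err[1])},
        window=None,
        residual_norm=float(np.sqrt(np.mean(resid**2))),
        n_points=len(lp),
    )


# ---------------------------------------------------------------------------
# rescaled-speed collapse diagnostics
# ---------------------------------------------------------------------------

@dataclass
class RescaledSpeed:
    """Speed curves rescaled for the confined / non-confined collapses.

    ``confined = V N^(x1+z1) m^(-z1)`` should level off over the confined
    window at the true (x1, z1); ``nonconfined = V N^(x1+z1) m^(z2P)``
    levels off over the non-confined window at the true z2P.
    """

    m: np.ndarray
    confined: np.ndarray
    nonconfined: np.ndarray
    N: int

    def flatness(self, which: str, window: tuple[float, float]) -> float:
        """Relative spread (std/mean) of a rescaled curve over an m/N window;
        small is flat."""
        y = getattr(self, which)
        ref = self.m / self.N
        keep = np.isfinite(y) & (ref > window[0]) & (ref < window[1])
        if keep.sum() < 2:
            raise ValueError("window too narrow")
        yy = y[keep]
        return float(np.std(yy) / np.mean(yy))


def rescale_speed(profile: SpeedProfile, N: int, x1: float, z1: float,
                  z2P: float) -> RescaledSpeed:
    """Rescale V(m) for the two collapse diagnostics (see Fig.-4/5 logic)."""
    for e in (x1, z1, z2P):
        if not math.isfinite(e):
            raise ValueError("exponents must be finite")
    m = profile.m.astype(float)
    fac = N ** (x1 + z1)
    return RescaledSpeed(
        m=profile.m.copy(),
        confined=profile.V * fac * m ** (-z1),
        nonconfined=profile.V * fac * m ** z2P,
        N=N,
    )
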