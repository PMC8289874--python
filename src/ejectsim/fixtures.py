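"""Synthetic event series and tiny deterministic configurations.

The generator samples ejection event series directly from the theory's
speed model, so the whole analysis layer can be exercised in seconds
without molecular dynamics: the dwell time at state ``m`` has mean
``sigma / V_model(m)`` (exponential, gamma or deterministic), an optional
entering plateau stalls the first ``m_p`` states, and a short leaving tail
advances ``s`` to ``N``. The emitted series satisfy exactly the same schema
and invariants as simulator output.

What this emulates — and what it does not: the marginal dwell statistics and
the mean speed curve of the kinetics, but not spatial correlations, m
re-crossings, or censoring. A green analysis test on fixtures establishes
parameter recovery of the analysis pipeline, not correctness of the MD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .events import EventSeries
from .geometry import SystemParams
from .theory import TheoryParams, entering_time, leaving_time, speed_model

__all__ = ["FixtureSpec", "generate_event_series", "tiny_md_configs"]


@dataclass
class FixtureSpec:
    """Recipe for a synthetic ensemble.

    ``D = inf`` yields the monotone (translocation-like) speed profile with
    no interior minimum. Dwell noise models: "exponential" (memoryless,
    default), "gamma" (over-dispersed, shape ``gamma_shape``),
    "deterministic" (dwell equals its mean exactly).
    """

    N: int
    D: float
    theory: TheoryParams = field(default_factory=TheoryParams)
    phi0: float | None = None
    noise: str = "exponential"
    gamma_shape: float = 4.0
    include_entering: bool = False
    tau_ent_mean: float | None = None
    lp: float = 1.0
    seed: int = 0
    n_runs: int = 1

    def __post_init__(self):
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.noise not in ("exponential", "gamma", "deterministic"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        for e in (self.theory.z1, self.theory.z2P, self.theory.x1):
            if not math.isfinite(e) or e <= 0:
                raise ValueError("invalid exponents in theory params")

    @property
    def m_p(self) -> int:
        return max(1, round(self.lp / self.theory.sigma))


def _draw_dwell(rng: np.random.Generator, mean: np.ndarray, spec: FixtureSpec):
    if spec.noise == "deterministic":
        return mean.copy()
    if spec.noise == "exponential":
        return rng.exponential(mean)
    k = spec.gamma_shape
    return rng.gamma(k, mean / k)


def generate_event_series(spec: FixtureSpec) -> list[EventSeries]:
    """Sample ``spec.n_runs`` synthetic ejection runs.

    Each run walks m from N down to 0 with dwell means sigma/V_model(m);
    s advances as N - m_p - m once the pore is full, then a leaving tail
    brings s to N. Deterministic under a fixed seed.
    """
    N, m_p = spec.N, spec.m_p
    p = spec.theory
    mm = np.arange(N, 0, -1)
    dwell_mean = p.sigma / speed_model(mm, N, spec.D, p)

    if spec.include_entering:
        tau_ent = spec.tau_ent_mean
        if tau_ent is None:
            tau_ent = entering_time(p, spec.lp)
        ent_extra = tau_ent / m_p
    else:
        ent_extra = 0.0
    tau_leav_mean = leaving_time(p, spec.lp)

    runs = []
    for i in range(spec.n_runs):
        rng = np.random.default_rng([spec.seed, i])
        dwell = _draw_dwell(rng, dwell_mean, spec)
        if ent_extra > 0.0:
            extra = (np.full(m_p, ent_extra) if spec.noise == "deterministic"
                     else rng.exponential(ent_extra, size=m_p))
            dwell[:m_p] += extra  # stall the first m_p states (m = N .. N-m_p+1)
        t = np.concatenate([[0.0], np.cumsum(dwell)])
        m = np.concatenate([[N], mm - 1])        # N, N-1, ..., 0
        s = np.maximum(N - m_p - m, 0)
        # leaving tail: m = 0, s climbs N-m_p -> N
        leav_step = tau_leav_mean / m_p
        lt = (np.full(m_p, leav_step) if spec.noise == "deterministic"
              else rng.exponential(leav_step, size=m_p))
        t = np.concatenate([t, t[-1] + np.cumsum(lt)])
        m = np.concatenate([m, np.zeros(m_p, dtype=np.int64)])
        s = np.concatenate([s, np.arange(N - m_p + 1, N + 1)])
        ev = EventSeries(t=t, m=m, s=s, N=N, m_p=m_p, seed=int(np.int64(spec.seed) + i),
                         meta={"fixture": True, "D": spec.D, "noise": spec.noise})
        ev.validate()
        runs.append(ev)
    return runs


def tiny_md_configs() -> dict[str, dict]:
    """Named deterministic configurations for force/energy unit tests.

    Returns a mapping name -> {"params": SystemParams, "positions": (n,3),
    "velocities": (n,3)}. All arrays are bitwise-stable across calls.
    """
    configs: dict[str, dict] = {}

    # dimer at bond length sigma, far from every wall, in a large cavity
    p_dimer = SystemParams(N=2, D=40.0, H=1.5)
    g = p_dimer.geometry()
    c = g.cavity_center
    pos = np.array([c + [-0.5, 0.0, 0.0], c + [0.5, 0.0, 0.0]])
    configs["dimer"] = {
        "params": p_dimer,
        "positions": pos,
        "velocities": np.zeros_like(pos),
    }

    # 8-bead zig-zag chain inside a modest cavity (asymmetric on purpose so
    # forces are non-trivial in every direction)
    p_oct = SystemParams(N=8, D=8.0, H=1.5)
    g = p_oct.geometry()
    xs = np.linspace(-2.8, 2.8, 8)
    ys = 0.35 * np.array([1, -1, 1, -1, 1, -1, 1, -1], dtype=float)
    zs = g.z_mid + 0.30 * np.array([1, 1, -1, -1, 1, 1, -1, -1], dtype=float)
    pos = np.column_stack([xs, ys, zs])
    configs["octamer"] = {
        "params": p_oct,
        "positions": pos,
        "velocities": np.zeros_like(pos),
    }

    # 8-bead chain with the head at the pore entrance (start-of-ejection)
    g = p_oct.geometry()
    head = g.pore_entrance
    pos = np.array([head - [i * 0.97, 0.0, 0.0] for i in range(8)])
    pos[1:, 1] += 0.1 * np.array([1, -1, 1, -1, 1, -1, 1], dtype=float)
    configs["head_at_entrance"] = {
        "params": p_oct,
        "positions": pos,
        "velocities": np.zeros_like(pos),
    }
    return configs
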