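"""Langevin dynamics engine and the three-phase ejection protocol.

A run goes through (i) loading — the chain is laid out inside the cavity
with the head monomer at the pore entrance; (ii) equilibration — Langevin
dynamics with the head frozen at the entrance, blocking the only exit;
(iii) ejection — the head is freed, a reflective wall at the pore entrance
(acting on the head only) prevents the chain falling back into the cavity,
and the run ends when the last monomer passes the pore exit. Every change
of the region counts ``(m, s)`` is recorded into an
:class:`~ejectsim.events.EventSeries`.

Thermostat: underdamped GJF Langevin at temperature ``T`` with relaxation
time ``damp`` (friction ``gamma = mass/damp``). Default timestep
``dt = 0.005`` time units — the stiff bond (k = 600) has a vibration period
of ~0.26 t_u, so dt is ~2% of it.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .events import EventSeries
from .geometry import WALL_OFFSET, Geometry, SystemParams, close_pack_phi0

logger = logging.getLogger(__name__)

__all__ = [
    "Phase",
    "ChainState",
    "langevin_steps",
    "load_chain",
    "equilibrate",
    "run_ejection",
    "run_ensemble",
    "EnsembleResult",
    "default_equilibration_time",
]

#: default per-run integration-step budget; runs exceeding it are censored
DEFAULT_STEP_BUDGET = 10**9

#: event-buffer chunk passed to the kernel per call
_EV_CHUNK = 1 << 16
_STEP_CHUNK = 1 << 22


class Phase(enum.Enum):
    LOADING = "loading"
    EQUILIBRATION = "equilibration"
    EJECTION = "ejection"


@dataclass
class ChainState:
    """Positions/velocities of the N beads plus phase bookkeeping."""

    positions: np.ndarray
    velocities: np.ndarray
    time: float = 0.0
    phase: Phase = Phase.LOADING
    head_fixed: bool = False

    @property
    def N(self) -> int:
        return self.positions.shape[0]

    def kinetic_temperature(self, mass: float = 1.0) -> float:
        """Instantaneous kinetic temperature, m<v^2>/3 per bead."""
        return float(mass * np.mean(np.sum(self.velocities**2, axis=1)) / 3.0)


def _geom_scalars(params: SystemParams) -> tuple:
    """Pack the wall geometry into the scalar tuple the kernels take.

    ``x_split1``/``x_split2`` bound the pore-bore cylinder region: the
    sphere--bore rim circle (or the entrance membrane face for D = inf) and
    the exit membrane face.
    """
    g = params.geometry()
    off = WALL_OFFSET * params.sigma
    rp_wall = params.rp + off
    if math.isinf(params.D):
        R_cav = -1.0
        x_split1 = g.x_entrance + off
    else:
        R_cav = params.D / 2.0 + off
        x_split1 = math.sqrt(R_cav**2 - rp_wall**2)
    return (
        -off,                    # z_lo (lower slit wall surface)
        params.H + off,          # z_hi
        g.z_mid,
        R_cav,
        rp_wall,
        x_split1,
        g.x_exit - off,          # x_split2: exit membrane face surface
    )


def _ff_scalars(params: SystemParams) -> tuple:
    return (params.eps, params.sigma, params.k_spring, params.b0,
            params.eps_w, params.sigma_w)


def langevin_steps(state: ChainState, params: SystemParams, n_steps: int,
                   seed: int, mode: int | None = None,
                   gamma: float | None = None) -> int:
    """Advance ``n_steps`` of GJF Langevin dynamics in place.

    ``mode``: 0 free, 1 head frozen, 2 ejection (reflective head rule);
    defaults from ``state``. ``gamma = 0`` disables both friction and noise
    (pure velocity-Verlet limit). Returns the kernel status code. A fixed
    seed gives a bitwise-identical trajectory.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    if mode is None:
        mode = 1 if state.head_fixed else (2 if state.phase == Phase.EJECTION else 0)
    g = params.mass / params.damp if gamma is None else gamma
    seed = int(seed) % (2**31 - 1)
    geom = params.geometry()
    ev = np.empty(0)
    evi = np.empty(0, dtype=np.int64)
    n_ev, steps, status = K.run_md(
        state.positions, state.velocities, params.mass, params.dt, g,
        params.T, seed, n_steps, mode, *_ff_scalars(params),
        *_geom_scalars(params), geom.x_entrance, geom.x_exit,
        False, state.time, ev, evi, evi)
    state.time += steps * params.dt
    if status in (K.STATUS_OVERLAP, K.STATUS_NONFINITE):
        raise FloatingPointError(
            f"integration aborted with status {status} (overlap or NaN); "
            f"reduce dt or check the configuration")
    return status


def langevin_step(state: ChainState, params: SystemParams, seed: int,
                  mode: int | None = None) -> int:
    """One Langevin step (see :func:`langevin_steps`)."""
    return langevin_steps(state, params, 1, seed, mode)


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def _spiral_path(R_eff: float, spacing: float, radial: float) -> np.ndarray:
    """Inward Archimedean spiral starting at (R_eff, 0), arc-spaced points."""
    pts = []
    theta = 0.0
    b = radial / (2.0 * math.pi)
    r = R_eff
    while r > 0.35:
        pts.append((r * math.cos(theta), r * math.sin(theta)))
        theta += spacing / r
        r = R_eff - b * theta
    return np.array(pts) if pts else np.empty((0, 2))


def load_chain(params: SystemParams, rng: np.random.Generator) -> ChainState:
    """Lay the chain inside the cavity, head monomer at the pore entrance.

    The chain is placed along an inward spiral starting next to the pore
    entrance (so consecutive beads are bonded neighbours on the path), then
    relaxed by capped-displacement descent until no pair is closer than
    0.9 sigma. A small random jitter (from ``rng``) decorrelates runs before
    equilibration. Raises if the packing cannot be placed within the retry
    budget (volume fraction too close to close packing).
    """
    if math.isinf(params.D):
        return _load_chain_translocation(params, rng)
    if params.phi0 >= close_pack_phi0(params.H, params.sigma):
        raise ValueError("phi0 at or above close packing; cannot load")
    g = params.geometry()
    N = params.N
    R_eff = params.D / 2.0 - 0.45
    if R_eff <= 0.4:
        raise ValueError(f"cavity D={params.D} too small to hold beads")

    path = None
    for spacing in (1.0, 0.95, 0.9, 0.85, 0.8):
        cand = _spiral_path(R_eff, spacing, 0.9 * spacing)
        if cand.shape[0] >= N - 1:
            path = cand
            break
    if path is None:
        raise ValueError(
            f"could not place N={N} beads in cavity D={params.D:.3g} "
            f"(phi0={params.phi0:.3g}); lower phi0")

    pos = np.empty((N, 3))
    pos[0] = g.pore_entrance
    pos[1:, 0] = path[: N - 1, 0]
    pos[1:, 1] = path[: N - 1, 1]
    pos[1:, 2] = g.z_mid
    pos[1:] += rng.normal(scale=0.02, size=(N - 1, 3))

    for _ in range(6):
        K.relax(pos, 1500, 0.04, True, *_ff_scalars(params), *_geom_scalars(params))
        if _min_pair_distance(pos) >= 0.9 * params.sigma:
            break
    else:
        raise ValueError(
            f"relaxation failed to resolve overlaps at phi0={params.phi0:.3g}; "
            f"lower phi0")

    vel = rng.normal(scale=math.sqrt(params.T / params.mass), size=(N, 3))
    vel[0] = 0.0
    return ChainState(positions=pos, velocities=vel, time=0.0,
                      phase=Phase.LOADING, head_fixed=True)


def _load_chain_translocation(params: SystemParams, rng: np.random.Generator) -> ChainState:
    """D = inf mode: straight chain in the half-slit behind the entrance."""
    g = params.geometry()
    N = params.N
    pos = np.empty((N, 3))
    pos[:, 0] = g.x_entrance - 0.97 * np.arange(N)
    pos[:, 1] = 0.0
    pos[:, 2] = g.z_mid
    pos[1:] += rng.normal(scale=0.02, size=(N - 1, 3))
    K.relax(pos, 300, 0.04, True, *_ff_scalars(params), *_geom_scalars(params))
    vel = rng.normal(scale=math.sqrt(params.T / params.mass), size=(N, 3))
    vel[0] = 0.0
    return ChainState(positions=pos, velocities=vel, time=0.0,
                      phase=Phase.LOADING, head_fixed=True)


def _min_pair_distance(pos: np.ndarray) -> float:
    from scipy.spatial.distance import pdist

    return float(pdist(pos).min()) if pos.shape[0] > 1 else math.inf


# ---------------------------------------------------------------------------
# equilibration and ejection
# ---------------------------------------------------------------------------

def default_equilibration_time(params: SystemParams) -> float:
    """max(1e3 t_u, 10x a Rouse-time estimate N^2 sigma^2 damp/(3 pi^2 T))."""
    rouse = params.N**2 * params.sigma**2 * params.damp / (3.0 * math.pi**2 * params.T)
    return max(1e3, 10.0 * rouse)


def equilibrate(state: ChainState, params: SystemParams, seed: int,
                duration: float | None = None) -> ChainState:
    """Langevin dynamics with the head frozen at the pore entrance."""
    if duration is None:
        duration = default_equilibration_time(params)
    n_steps = int(round(duration / params.dt))
    head0 = state.positions[0].copy()
    state.head_fixed = True
    langevin_steps(state, params, n_steps, seed, mode=1)
    # the head must not have moved
    if not np.allclose(state.positions[0], head0):
        raise AssertionError("head monomer moved during equilibration")
    state.phase = Phase.EQUILIBRATION
    return state


def run_ejection(state: ChainState, params: SystemParams, seed: int,
                 step_budget: int = DEFAULT_STEP_BUDGET) -> EventSeries:
    """Free the head and integrate until the last bead passes the pore exit.

    Records an event whenever the region counts (m, s) change; the
    bookkeeping ``m + pore + s = N`` holds at every recorded frame by
    construction (the counts partition the beads by x-coordinate). Runs
    exceeding ``step_budget`` steps are returned censored.
    """
    state.head_fixed = False
    state.phase = Phase.EJECTION
    g = params.geometry()
    gam = params.mass / params.damp
    ff, gm = _ff_scalars(params), _geom_scalars(params)

    ts = [np.array([state.time])]
    ms_ = [np.array([int(np.sum(state.positions[:, 0] < g.x_entrance))])]
    ss_ = [np.array([int(np.sum(state.positions[:, 0] >= g.x_exit))])]

    steps_total = 0
    chunk_seed = np.random.SeedSequence(seed)
    censored = False
    while True:
        ev_t = np.empty(_EV_CHUNK)
        ev_m = np.empty(_EV_CHUNK, dtype=np.int64)
        ev_s = np.empty(_EV_CHUNK, dtype=np.int64)
        sub = int(chunk_seed.spawn(1)[0].generate_state(1)[0] % (2**31 - 1))
        n_steps = min(_STEP_CHUNK, step_budget - steps_total)
        n_ev, steps, status = K.run_md(
            state.positions, state.velocities, params.mass, params.dt, gam,
            params.T, sub, n_steps, 2, *ff, *gm, g.x_entrance, g.x_exit,
            True, state.time, ev_t, ev_m, ev_s)
        state.time += steps * params.dt
        steps_total += steps
        if n_ev:
            ts.append(ev_t[:n_ev].copy())
            ms_.append(ev_m[:n_ev].copy())
            ss_.append(ev_s[:n_ev].copy())
        if status == K.STATUS_FINISHED:
            break
        if status in (K.STATUS_OVERLAP, K.STATUS_NONFINITE):
            raise FloatingPointError(
                f"ejection aborted with kernel status {status}")
        if steps_total >= step_budget:
            censored = True
            logger.warning("run censored after %d steps (seed %s)", steps_total, seed)
            break
        # STATUS_EV_FULL or chunk exhausted: continue

    ev = EventSeries(
        t=np.concatenate(ts), m=np.concatenate(ms_), s=np.concatenate(ss_),
        N=params.N, m_p=params.m_p, seed=seed, censored=censored,
        meta={"D": params.D, "phi0": params.phi0, "lp": params.lp,
              "steps": steps_total})
    if not censored:
        ev.validate()
    return ev


@dataclass
class EnsembleResult:
    """All event series of an ensemble plus the censoring log."""

    runs: list = field(default_factory=list)
    censored_seeds: list = field(default_factory=list)

    @property
    def n_censored(self) -> int:
        return len(self.censored_seeds)

    @property
    def completed(self) -> list:
        return [r for r in self.runs if not r.censored]


def run_ensemble(params: SystemParams, n_runs: int, base_seed: int,
                 equilibration: float | None = None,
                 step_budget: int = DEFAULT_STEP_BUDGET) -> EnsembleResult:
    """Independent loading + equilibration + ejection, seeds base_seed + i."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    out = EnsembleResult()
    mod = 2**31 - 1
    for i in range(n_runs):
        seed = base_seed + i
        rng = np.random.default_rng(seed)
        try:
            state = load_chain(params, rng)
            equilibrate(state, params, seed=(2 * seed + 1) % mod, duration=equilibration)
            ev = run_ejection(state, params, seed=seed % mod, step_budget=step_budget)
        except (FloatingPointError, ValueError) as exc:
            logger.warning("run %d (seed %d) failed: %s", i, seed, exc)
            out.censored_seeds.append(seed)
            continue
        out.runs.append(ev)
        if ev.censored:
            out.censored_seeds.append(seed)
    logger.info("ensemble: %d/%d completed, %d censored",
                len(out.completed), n_runs, out.n_censored)
    return out
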