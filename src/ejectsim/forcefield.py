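"""Energies and forces of the bead-spring model.

Three interactions:

* excluded volume between all bead pairs: LJ 12-6 shifted and truncated at
  its minimum ``rc = 2^(1/6) sigma`` (WCA), so it is purely repulsive and
  continuous at the cutoff;
* chain connectivity: harmonic springs ``U = k/2 (b - b0)^2`` between
  consecutive beads;
* bead--wall repulsion: LJ 9-3, shifted and truncated at its minimum
  ``rc_w = (2/5)^(1/6) sigma_w`` (also purely repulsive). With the default
  wall strength ``eps_w = 3 eps`` the wall potential reaches ``k_B T`` at a
  distance ``r = 0.76 sigma`` from the wall surface, which motivates the
  0.26-sigma effective wall thickness used throughout the geometry.

This module is the plain-numpy reference implementation; the simulator's
inner loop uses a numba kernel (:mod:`ejectsim._kernels`) that is unit-tested
against these functions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import WALL_OFFSET, Geometry, SystemParams

__all__ = [
    "ForceField",
    "pair_energy",
    "bond_energy",
    "wall_energy",
    "total_energy",
    "total_force",
    "reflect_head",
    "WALL_SHIFT_FACTOR",
    "PAIR_CUTOFF_FACTOR",
    "WALL_CUTOFF_FACTOR",
]

#: pair cutoff in units of sigma: the LJ 12-6 minimum
PAIR_CUTOFF_FACTOR = 2.0 ** (1.0 / 6.0)
#: wall cutoff in units of sigma_w: the LJ 9-3 minimum
WALL_CUTOFF_FACTOR = (2.0 / 5.0) ** (1.0 / 6.0)
#: energy shift making the LJ 9-3 wall potential vanish at its cutoff,
#: in units of eps_w: -U_93(rc_w)/eps_w = (2/3) sqrt(5/2)
WALL_SHIFT_FACTOR = (2.0 / 3.0) * math.sqrt(5.0 / 2.0)

#: hard floor on pair distances; closer approaches abort the run
OVERLAP_FLOOR = 0.3


def pair_energy(r, eps: float = 1.0, sigma: float = 1.0):
    """Shifted-truncated LJ 12-6 (WCA) pair energy at distance ``r``.

    U(r) = 4 eps [(sigma/r)^12 - (sigma/r)^6] + eps   for r < 2^(1/6) sigma,
    zero beyond. ``r = 0`` is rejected (overlap catastrophe).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive (overlapping beads)")
    sr6 = (sigma / r) ** 6
    u = np.where(r < PAIR_CUTOFF_FACTOR * sigma, 4.0 * eps * (sr6 * sr6 - sr6) + eps, 0.0)
    return u if u.ndim else float(u)


def pair_force_mag(r, eps: float = 1.0, sigma: float = 1.0):
    """Magnitude of -dU/dr for the WCA pair potential (positive = repulsive)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")
    sr6 = (sigma / r) ** 6
    f = np.where(r < PAIR_CUTOFF_FACTOR * sigma, 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r, 0.0)
    return f if f.ndim else float(f)


def bond_energy(b, k: float = 600.0, b0: float = 1.0):
    """Harmonic spring energy, U = k/2 (b - b0)^2."""
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("bond length must be non-negative")
    u = 0.5 * k * (b - b0) ** 2
    return u if u.ndim else float(u)


def wall_energy(r, eps_w: float = 3.0, sigma_w: float = 1.0):
    """Shifted-truncated LJ 9-3 wall energy at distance ``r`` from the surface.

    U(r) = eps_w [(2/15)(sigma_w/r)^9 - (sigma_w/r)^3] + (2/3) sqrt(5/2) eps_w
    for r < (2/5)^(1/6) sigma_w, zero beyond; purely repulsive and continuous.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("wall distance must be positive")
    sr3 = (sigma_w / r) ** 3
    u = np.where(
        r < WALL_CUTOFF_FACTOR * sigma_w,
        eps_w * ((2.0 / 15.0) * sr3 * sr3 * sr3 - sr3) + WALL_SHIFT_FACTOR * eps_w,
        0.0,
    )
    return u if u.ndim else float(u)


def wall_force_mag(r, eps_w: float = 3.0, sigma_w: float = 1.0):
    """-dU/dr of the wall potential (positive = pushes away from the wall)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("wall distance must be positive")
    sr3 = (sigma_w / r) ** 3
    f = np.where(
        r < WALL_CUTOFF_FACTOR * sigma_w,
        eps_w * ((18.0 / 15.0) * sr3 * sr3 * sr3 - 3.0 * sr3) / r,
        0.0,
    )
    return f if f.ndim else float(f)


@dataclass(frozen=True)
class ForceField:
    """Parameter bundle for the three interactions."""

    eps: float = 1.0
    sigma: float = 1.0
    k_spring: float = 600.0
    b0: float = 1.0
    eps_w: float = 3.0
    sigma_w: float = 1.0
    rc_pair: float = field(init=False)
    rc_wall: float = field(init=False)
    wall_shift: float = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "rc_pair", PAIR_CUTOFF_FACTOR * self.sigma)
        object.__setattr__(self, "rc_wall", WALL_CUTOFF_FACTOR * self.sigma_w)
        object.__setattr__(self, "wall_shift", WALL_SHIFT_FACTOR * self.eps_w)

    @classmethod
    def from_params(cls, p: SystemParams) -> "ForceField":
        return cls(eps=p.eps, sigma=p.sigma, k_spring=p.k_spring, b0=p.b0,
                   eps_w=p.eps_w, sigma_w=p.sigma_w)

    def pair_energy(self, r):
        return pair_energy(r, self.eps, self.sigma)

    def bond_energy(self, b):
        return bond_energy(b, self.k_spring, self.b0)

    def wall_energy(self, r):
        return wall_energy(r, self.eps_w, self.sigma_w)


def _lateral_gap_single(x: float, y: float, z: float, geom: Geometry,
                        sigma: float = 1.0):
    """Distance and outward normal of the nearest lateral wall surface.

    The lateral surface is the cavity sphere (or, for D = inf, the entrance
    membrane face), the pore-bore cylinder, or the exit membrane face — all
    joined continuously through the bore rim circles: where a bead's
    projection onto a wall falls inside the pore opening, the distance is
    taken to the rim circle instead, so the wall potential is continuous
    everywhere in accessible space.
    """
    off = WALL_OFFSET * sigma
    rp_wall = geom.rp + off
    x_split2 = geom.x_exit - off
    ry, rz = y, z - geom.z_mid
    rho = math.hypot(ry, rz)

    def _rim(x_rim: float):
        dxr = x - x_rim
        drr = rho - rp_wall
        d = math.hypot(dxr, drr)
        if d < 1e-12:
            return 0.0, np.array([1.0, 0.0, 0.0])
        n = np.zeros(3)
        n[0] = dxr / d
        if rho > 1e-12:
            n[1] = (drr / d) * ry / rho
            n[2] = (drr / d) * rz / rho
        return d, n

    if math.isinf(geom.D):
        x_split1 = geom.x_entrance + off
        if x < x_split1:
            if rho >= rp_wall:
                return x_split1 - x, np.array([-1.0, 0.0, 0.0])
            return _rim(x_split1)
    else:
        R_C = geom.cavity_wall_diameter / 2.0
        x_split1 = math.sqrt(R_C**2 - rp_wall**2)
        if x < x_split1:
            r = math.sqrt(x * x + rho * rho)
            if x > 0 and rho * R_C < rp_wall * r:
                return _rim(x_split1)
            if r < 1e-12:
                return math.inf, np.zeros(3)
            return R_C - r, np.array([-x / r, -ry / r, -rz / r])
    if x < x_split2:
        if rho < 1e-12:
            return math.inf, np.zeros(3)
        return rp_wall - rho, np.array([0.0, -ry / rho, -rz / rho])
    if rho >= rp_wall:
        return x - x_split2, np.array([1.0, 0.0, 0.0])
    return _rim(x_split2)


def _wall_gaps(pos: np.ndarray, geom: Geometry, sigma: float = 1.0):
    """Distances to every confining wall surface and the outward unit normals.

    Returns arrays ``dist (3, N)`` and ``normal (3, N, 3)``: the two slit
    planes (surfaces offset outward by the 0.26-sigma effective thickness)
    and the per-bead nearest lateral surface (see
    :func:`_lateral_gap_single`). The caller masks by the wall cutoff.
    """
    N = pos.shape[0]
    off = WALL_OFFSET * sigma
    z = pos[:, 2]
    d_lo = z + off
    n_lo = np.zeros((N, 3))
    n_lo[:, 2] = 1.0
    d_hi = (geom.H + off) - z
    n_hi = np.zeros((N, 3))
    n_hi[:, 2] = -1.0

    d_lat = np.empty(N)
    n_lat = np.zeros((N, 3))
    for i in range(N):
        d_lat[i], n_lat[i] = _lateral_gap_single(
            pos[i, 0], pos[i, 1], pos[i, 2], geom, sigma)

    return (np.array([d_lo, d_hi, d_lat]), np.array([n_lo, n_hi, n_lat]))


def total_energy(pos: np.ndarray, ff: ForceField, geom: Geometry) -> float:
    """Total potential energy: pairs + bonds + walls."""
    N = pos.shape[0]
    e = 0.0
    # non-bonded pairs (brute force; reference implementation)
    for i in range(N - 1):
        d = pos[i + 1:] - pos[i]
        r = np.linalg.norm(d, axis=1)
        if np.any(r < OVERLAP_FLOOR * ff.sigma):
            raise FloatingPointError("bead overlap below the hard floor")
        e += float(np.sum(pair_energy(r, ff.eps, ff.sigma)))
    # bonds
    b = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    e += float(np.sum(bond_energy(b, ff.k_spring, ff.b0)))
    # walls
    dist, _ = _wall_gaps(pos, geom, ff.sigma)
    mask = dist < ff.rc_wall
    if np.any(dist <= 0):
        raise FloatingPointError("bead inside a wall surface")
    e += float(np.sum(wall_energy(dist[mask], ff.eps_w, ff.sigma_w)))
    return e


def total_force(pos: np.ndarray, ff: ForceField, geom: Geometry) -> np.ndarray:
    """Per-bead force vectors, the exact negative gradient of
    :func:`total_energy` (central-difference consistency is part of the test
    suite)."""
    N = pos.shape[0]
    f = np.zeros_like(pos)
    for i in range(N - 1):
        d = pos[i + 1:] - pos[i]
        r = np.linalg.norm(d, axis=1)
        if np.any(r < OVERLAP_FLOOR * ff.sigma):
            raise FloatingPointError("bead overlap below the hard floor")
        mag = pair_force_mag(r, ff.eps, ff.sigma)  # positive = repulsive
        fij = (mag / r)[:, None] * d  # force on j from i
        f[i + 1:] += fij
        f[i] -= fij.sum(axis=0)
    b_vec = np.diff(pos, axis=0)
    b = np.linalg.norm(b_vec, axis=1)
    fb = (-ff.k_spring * (b - ff.b0) / b)[:, None] * b_vec  # on the later bead
    f[1:] += fb
    f[:-1] -= fb
    dist, normal = _wall_gaps(pos, geom, ff.sigma)
    if np.any(dist <= 0):
        raise FloatingPointError("bead inside a wall surface")
    for k in range(dist.shape[0]):
        mask = dist[k] < ff.rc_wall
        if np.any(mask):
            mag = wall_force_mag(dist[k][mask], ff.eps_w, ff.sigma_w)
            f[mask] += mag[:, None] * normal[k][mask]
    return f


def reflect_head(pos: np.ndarray, vel: np.ndarray, geom: Geometry) -> bool:
    """Reflective wall at the pore entrance acting only on the head monomer.

    During ejection, if bead 0 crosses the entrance plane back toward the
    cavity, its position is mirrored about the plane and the normal velocity
    component reversed. Mutates ``pos``/``vel`` in place; returns True if a
    reflection happened.
    """
    if pos[0, 0] < geom.x_entrance:
        pos[0, 0] = 2.0 * geom.x_entrance - pos[0, 0]
        vel[0, 0] = -vel[0, 0]
        return True
    return False
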