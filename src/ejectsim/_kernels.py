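"""Numba-compiled inner loops of the Langevin simulator.

Force model (kept in exact agreement with :mod:`ejectsim.forcefield`, which
is the plain-numpy reference these kernels are unit-tested against):
WCA pairs, harmonic bonds, shifted LJ 9-3 walls.

Wall geometry: two slit planes plus one *lateral* surface per bead — the
cavity sphere (wall radius R_cav), the pore bore cylinder (wall radius
rp_wall), or a membrane face. All surfaces are joined continuously through
their rim circles: where a bead's projection onto a wall falls inside the
pore opening, the wall distance becomes the distance to the rim circle, so
the wall potential has no jump anywhere in accessible space. The lateral
regions are split at ``x_split1`` (sphere/entrance-face -> cylinder) and
``x_split2 = x_exit - 0.26 sigma`` (cylinder -> exit face).

Integrator: Gronbech-Jensen--Farago symmetric splitting of underdamped
Langevin dynamics. With friction gamma = mass/damp and noise variance
2 gamma kT dt it satisfies fluctuation--dissipation at temperature T; at
gamma = 0 it reduces exactly to velocity Verlet.

Modes: 0 = all beads free; 1 = head (bead 0) frozen; 2 = ejection (head
free, specular reflective wall at the pore entrance acting on bead 0 only).

Determinism: each call seeds numba's internal RNG, so a fixed seed gives a
bitwise-identical trajectory on the same build.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# status codes returned by run_md
STATUS_STEPS_DONE = 0   # n_steps exhausted, still running
STATUS_FINISHED = 1     # ejection complete (s == N)
STATUS_EV_FULL = 2      # event buffer full, still running
STATUS_OVERLAP = 3      # bead pair below the hard floor / bead inside a wall
STATUS_NONFINITE = 4    # coordinates went non-finite

_RC2_FACTOR = 2.0 ** (1.0 / 3.0)     # (2^(1/6))^2
_RCW_FACTOR = (2.0 / 5.0) ** (1.0 / 6.0)
_FLOOR = 0.3                          # hard floor on pair distances, in sigma
_BIG = 1.0e9


@njit(cache=True, inline="always")
def _lateral_gap(x, y, z, z_mid, R_cav, rp_wall, x_split1, x_split2):
    """Distance to the nearest lateral wall surface and its outward normal.

    Returns (d, nx, ny, nz); d >= _BIG means no lateral wall within reach.
    The normal points from the surface toward the bead (push direction).
    """
    ry = y
    rz = z - z_mid
    rho2 = ry * ry + rz * rz
    rho = np.sqrt(rho2)
    if x < x_split1:
        if R_cav > 0.0:
            # cavity sphere with a circular bore at the pore mouth
            r = np.sqrt(x * x + rho2)
            if x > 0.0 and rho * R_cav < rp_wall * r:
                # radial projection falls inside the mouth: rim circle
                dxr = x - x_split1
                drr = rho - rp_wall
                d = np.sqrt(dxr * dxr + drr * drr)
                if d < 1e-12:
                    return 0.0, 1.0, 0.0, 0.0
                nx = dxr / d
                nr = drr / d
                if rho > 1e-12:
                    return d, nx, nr * ry / rho, nr * rz / rho
                return d, nx, 0.0, 0.0
            if r < 1e-12:
                return _BIG, 0.0, 0.0, 0.0
            return R_cav - r, -x / r, -ry / r, -rz / r
        # translocation barrier: entrance membrane face with a bore
        if rho >= rp_wall:
            return x_split1 - x, -1.0, 0.0, 0.0
        dxr = x - x_split1
        drr = rho - rp_wall
        d = np.sqrt(dxr * dxr + drr * drr)
        if d < 1e-12:
            return 0.0, -1.0, 0.0, 0.0
        nx = dxr / d
        nr = drr / d
        if rho > 1e-12:
            return d, nx, nr * ry / rho, nr * rz / rho
        return d, nx, 0.0, 0.0
    if x < x_split2:
        # pore bore cylinder (no force exactly on the axis)
        if rho > 1e-12:
            return rp_wall - rho, 0.0, -ry / rho, -rz / rho
        return _BIG, 0.0, 0.0, 0.0
    # semi-space: exit membrane face with a bore
    if rho >= rp_wall:
        return x - x_split2, 1.0, 0.0, 0.0
    dxr = x - x_split2
    drr = rho - rp_wall
    d = np.sqrt(dxr * dxr + drr * drr)
    if d < 1e-12:
        return 0.0, 1.0, 0.0, 0.0
    nx = dxr / d
    nr = drr / d
    if rho > 1e-12:
        return d, nx, nr * ry / rho, nr * rz / rho
    return d, nx, 0.0, 0.0


@njit(cache=True, fastmath=False)
def _forces(pos, f, eps, sigma, kspr, b0, eps_w, sigma_w,
            z_lo, z_hi, z_mid, R_cav, rp_wall, x_split1, x_split2):
    """Fill ``f`` with forces; return 0 on success, nonzero status on abort."""
    N = pos.shape[0]
    for i in range(N):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0
    rc2 = _RC2_FACTOR * sigma * sigma
    floor2 = (_FLOOR * sigma) ** 2
    # WCA pairs, brute force
    for i in range(N - 1):
        xi = pos[i, 0]
        yi = pos[i, 1]
        zi = pos[i, 2]
        for j in range(i + 1, N):
            dx = xi - pos[j, 0]
            dy = yi - pos[j, 1]
            dz = zi - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < floor2:
                return STATUS_OVERLAP
            if r2 < rc2:
                sr2 = sigma * sigma / r2
                sr6 = sr2 * sr2 * sr2
                fmag = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r2
                f[i, 0] += fmag * dx
                f[i, 1] += fmag * dy
                f[i, 2] += fmag * dz
                f[j, 0] -= fmag * dx
                f[j, 1] -= fmag * dy
                f[j, 2] -= fmag * dz
    # harmonic bonds
    for i in range(N - 1):
        dx = pos[i + 1, 0] - pos[i, 0]
        dy = pos[i + 1, 1] - pos[i, 1]
        dz = pos[i + 1, 2] - pos[i, 2]
        b = np.sqrt(dx * dx + dy * dy + dz * dz)
        if b < 1e-12:
            return STATUS_OVERLAP
        c = -kspr * (b - b0) / b
        f[i + 1, 0] += c * dx
        f[i + 1, 1] += c * dy
        f[i + 1, 2] += c * dz
        f[i, 0] -= c * dx
        f[i, 1] -= c * dy
        f[i, 2] -= c * dz
    # walls
    rcw = _RCW_FACTOR * sigma_w
    for i in range(N):
        z = pos[i, 2]
        d = z - z_lo
        if d < rcw:
            if d <= 1e-12:
                return STATUS_OVERLAP
            sr3 = (sigma_w / d) ** 3
            f[i, 2] += eps_w * (1.2 * sr3 * sr3 * sr3 - 3.0 * sr3) / d
        d = z_hi - z
        if d < rcw:
            if d <= 1e-12:
                return STATUS_OVERLAP
            sr3 = (sigma_w / d) ** 3
            f[i, 2] -= eps_w * (1.2 * sr3 * sr3 * sr3 - 3.0 * sr3) / d
        d, nx, ny, nz = _lateral_gap(pos[i, 0], pos[i, 1], z, z_mid,
                                     R_cav, rp_wall, x_split1, x_split2)
        if d < rcw:
            if d <= 1e-12:
                return STATUS_OVERLAP
            sr3 = (sigma_w / d) ** 3
            fm = eps_w * (1.2 * sr3 * sr3 * sr3 - 3.0 * sr3) / d
            f[i, 0] += fm * nx
            f[i, 1] += fm * ny
            f[i, 2] += fm * nz
    return 0


@njit(cache=True)
def potential_energy(pos, eps, sigma, kspr, b0, eps_w, sigma_w,
                     z_lo, z_hi, z_mid, R_cav, rp_wall, x_split1, x_split2):
    """Total potential energy matching ``_forces`` exactly."""
    N = pos.shape[0]
    rc2 = _RC2_FACTOR * sigma * sigma
    rcw = _RCW_FACTOR * sigma_w
    wall_shift = (2.0 / 3.0) * np.sqrt(5.0 / 2.0) * eps_w
    e = 0.0
    for i in range(N - 1):
        for j in range(i + 1, N):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < rc2:
                sr2 = sigma * sigma / r2
                sr6 = sr2 * sr2 * sr2
                e += 4.0 * eps * (sr6 * sr6 - sr6) + eps
    for i in range(N - 1):
        dx = pos[i + 1, 0] - pos[i, 0]
        dy = pos[i + 1, 1] - pos[i, 1]
        dz = pos[i + 1, 2] - pos[i, 2]
        b = np.sqrt(dx * dx + dy * dy + dz * dz)
        e += 0.5 * kspr * (b - b0) ** 2
    for i in range(N):
        z = pos[i, 2]
        d = z - z_lo
        if 0.0 < d < rcw:
            sr3 = (sigma_w / d) ** 3
            e += eps_w * ((2.0 / 15.0) * sr3 * sr3 * sr3 - sr3) + wall_shift
        d = z_hi - z
        if 0.0 < d < rcw:
            sr3 = (sigma_w / d) ** 3
            e += eps_w * ((2.0 / 15.0) * sr3 * sr3 * sr3 - sr3) + wall_shift
        d, nx, ny, nz = _lateral_gap(pos[i, 0], pos[i, 1], z, z_mid,
                                     R_cav, rp_wall, x_split1, x_split2)
        if 0.0 < d < rcw:
            sr3 = (sigma_w / d) ** 3
            e += eps_w * ((2.0 / 15.0) * sr3 * sr3 * sr3 - sr3) + wall_shift
    return e


@njit(cache=True)
def run_md(pos, vel, mass, dt, gamma, kT, seed, n_steps, mode,
           eps, sigma, kspr, b0, eps_w, sigma_w,
           z_lo, z_hi, z_mid, R_cav, rp_wall, x_split1, x_split2,
           x_ent, x_exit, record, t0, ev_t, ev_m, ev_s):
    """Advance the chain ``n_steps`` GJF-Langevin steps.

    When ``record`` is true, appends an event to (ev_t, ev_m, ev_s) whenever
    the region counts (m, s) change (m: beads with x < x_ent; s: beads with
    x >= x_exit) and finishes early once s == N.

    Returns (n_events, steps_done, status).
    """
    np.random.seed(seed)
    N = pos.shape[0]
    denom = 1.0 + gamma * dt / (2.0 * mass)
    a_gjf = (1.0 - gamma * dt / (2.0 * mass)) / denom
    b_gjf = 1.0 / denom
    sig_noise = np.sqrt(2.0 * gamma * kT * dt)

    f = np.zeros((N, 3))
    f_new = np.zeros((N, 3))
    beta = np.zeros((N, 3))

    status = _forces(pos, f, eps, sigma, kspr, b0, eps_w, sigma_w,
                     z_lo, z_hi, z_mid, R_cav, rp_wall, x_split1, x_split2)
    if status != 0:
        return 0, 0, status

    n_ev = 0
    cap = ev_t.shape[0]
    last_m = -1
    last_s = -1
    steps_done = 0
    out_status = STATUS_STEPS_DONE

    for step in range(n_steps):
        i0 = 1 if mode == 1 else 0
        if mode == 1:
            vel[0, 0] = 0.0
            vel[0, 1] = 0.0
            vel[0, 2] = 0.0
        for i in range(i0, N):
            for d in range(3):
                bb = sig_noise * np.random.normal() if sig_noise > 0.0 else 0.0
                beta[i, d] = bb
                pos[i, d] += (b_gjf * dt * vel[i, d]
                              + b_gjf * dt * dt / (2.0 * mass) * f[i, d]
                              + b_gjf * dt / (2.0 * mass) * bb)
        if mode == 2 and pos[0, 0] < x_ent:
            # reflective wall at the pore entrance, head monomer only
            pos[0, 0] = 2.0 * x_ent - pos[0, 0]
            vel[0, 0] = -vel[0, 0]
        status = _forces(pos, f_new, eps, sigma, kspr, b0, eps_w, sigma_w,
                         z_lo, z_hi, z_mid, R_cav, rp_wall, x_split1, x_split2)
        if status != 0:
            out_status = status
            break
        for i in range(i0, N):
            for d in range(3):
                vel[i, d] = (a_gjf * vel[i, d]
                             + dt / (2.0 * mass) * (a_gjf * f[i, d] + f_new[i, d])
                             + b_gjf / mass * beta[i, d])
        for i in range(N):
            for d in range(3):
                f[i, d] = f_new[i, d]
        steps_done = step + 1
        if steps_done % 4096 == 0:
            if not (np.isfinite(pos[0, 0]) and np.isfinite(vel[0, 0])):
                out_status = STATUS_NONFINITE
                break
        if record:
            m_c = 0
            s_c = 0
            for i in range(N):
                if pos[i, 0] < x_ent:
                    m_c += 1
                elif pos[i, 0] >= x_exit:
                    s_c += 1
            if m_c != last_m or s_c != last_s:
                if n_ev >= cap:
                    out_status = STATUS_EV_FULL
                    break
                ev_t[n_ev] = t0 + steps_done * dt
                ev_m[n_ev] = m_c
                ev_s[n_ev] = s_c
                n_ev += 1
                last_m = m_c
                last_s = s_c
            if s_c == N:
                out_status = STATUS_FINISHED
                break
    return n_ev, steps_done, out_status


@njit(cache=True)
def relax(pos, n_iter, step_cap, pin_head,
          eps, sigma, kspr, b0, eps_w, sigma_w,
          z_lo, z_hi, z_mid, R_cav, rp_wall, x_split1, x_split2):
    """Capped-displacement steepest descent (overlap/stretch push-off).

    Moves each bead along its force by at most ``step_cap`` per iteration;
    the WCA core and wall gaps are clamped so that slightly overlapping
    generated configurations produce large-but-finite push-offs. Returns
    the final maximum per-bead force norm.
    """
    N = pos.shape[0]
    f = np.zeros((N, 3))
    alpha = 1e-4
    fmax = 0.0
    rc2 = _RC2_FACTOR * sigma * sigma
    rcw = _RCW_FACTOR * sigma_w
    for _ in range(n_iter):
        for i in range(N):
            f[i, 0] = 0.0
            f[i, 1] = 0.0
            f[i, 2] = 0.0
        for i in range(N - 1):
            for j in range(i + 1, N):
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                dz = pos[i, 2] - pos[j, 2]
                r2 = dx * dx + dy * dy + dz * dz
                if r2 < 1e-12:
                    r2 = 1e-12
                if r2 < rc2:
                    rr2 = max(r2, (0.8 * sigma) ** 2)
                    sr2 = sigma * sigma / rr2
                    sr6 = sr2 * sr2 * sr2
                    fmag = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / rr2
                    f[i, 0] += fmag * dx
                    f[i, 1] += fmag * dy
                    f[i, 2] += fmag * dz
                    f[j, 0] -= fmag * dx
                    f[j, 1] -= fmag * dy
                    f[j, 2] -= fmag * dz
        for i in range(N - 1):
            dx = pos[i + 1, 0] - pos[i, 0]
            dy = pos[i + 1, 1] - pos[i, 1]
            dz = pos[i + 1, 2] - pos[i, 2]
            b = np.sqrt(dx * dx + dy * dy + dz * dz)
            if b > 1e-9:
                c = -kspr * (b - b0) / b
                f[i + 1, 0] += c * dx
                f[i + 1, 1] += c * dy
                f[i + 1, 2] += c * dz
                f[i, 0] -= c * dx
                f[i, 1] -= c * dy
                f[i, 2] -= c * dz
        for i in range(N):
            z = pos[i, 2]
            d = max(z - z_lo, 0.05)
            if d < rcw:
                sr3 = (sigma_w / d) ** 3
                f[i, 2] += eps_w * (1.2 * sr3 * sr3 * sr3 - 3.0 * sr3) / d
            d = max(z_hi - z, 0.05)
            if d < rcw:
                sr3 = (sigma_w / d) ** 3
                f[i, 2] -= eps_w * (1.2 * sr3 * sr3 * sr3 - 3.0 * sr3) / d
            d, nx, ny, nz = _lateral_gap(pos[i, 0], pos[i, 1], z, z_mid,
                                         R_cav, rp_wall, x_split1, x_split2)
            d = max(d, 0.05)
            if d < rcw:
                sr3 = (sigma_w / d) ** 3
                fm = eps_w * (1.2 * sr3 * sr3 * sr3 - 3.0 * sr3) / d
                f[i, 0] += fm * nx
                f[i, 1] += fm * ny
                f[i, 2] += fm * nz
        fmax = 0.0
        i0 = 1 if pin_head else 0
        for i in range(i0, N):
            fn = np.sqrt(f[i, 0] ** 2 + f[i, 1] ** 2 + f[i, 2] ** 2)
            if fn > fmax:
                fmax = fn
            scale = alpha
            if fn * alpha > step_cap:
                scale = step_cap / fn
            pos[i, 0] += scale * f[i, 0]
            pos[i, 1] += scale * f[i, 1]
            pos[i, 2] += scale * f[i, 2]
    return fmax
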