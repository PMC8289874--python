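"""Reduced-unit parameters and the cavity--pore--slit geometry.

Everything is expressed in reduced units: the monomer diameter ``sigma`` is
the length unit, the pair interaction strength ``eps`` the energy unit, the
bead mass the mass unit, and ``t_u = sigma*sqrt(mass/eps)`` the time unit.

The system is a quasi two-dimensional "disk-like cavity -- pore channel --
semi-space" geometry: a sphere of (effective) diameter ``D`` intersected with
a slit of gap height ``H``, connected through a short cylindrical pore of
effective diameter ``d_p`` and length ``l_p`` to an open slit half-space.

Coordinate convention (all geometry is deterministic given the parameters):

* the cavity sphere is centred at the origin in ``(x, y)`` and at the slit
  midplane ``z = H/2``;
* the pore axis runs along ``+x`` through the cavity centre at ``y = 0``,
  ``z = H/2``;
* the pore entrance plane is tangent to the sphere of diameter ``D``
  (``x = D/2``), the exit plane sits at ``x = D/2 + l_p``;
* the translocation limit ``D = inf`` places the entrance plane at ``x = 0``
  (the cavity degenerates to the half-slit ``x < 0``).

Confining walls carry an effective thickness of ``0.26 sigma`` per surface
(the LJ 9-3 wall reaches k_B T at r = 0.76 sigma from the nominal surface),
so wall *surfaces* are offset outward by 0.26 sigma from the effective
boundaries: the cavity wall sphere has diameter ``D_C = D + 0.52 sigma``, the
pore wall cylinder ``d_p + 0.52 sigma``, and the slit wall planes sit at
``z = -0.26 sigma`` and ``z = H + 0.26 sigma``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Region",
    "SystemParams",
    "Geometry",
    "volume_fraction",
    "diameter_for_generation",
    "phi_pore",
    "close_pack_phi0",
    "classify_region",
]

#: effective wall half-thickness per surface, in sigma units
WALL_OFFSET = 0.26

#: base volume fraction of the generation grid, phi_{0,g} = 0.3 * 2**-g
PHI0_BASE = 0.3


class Region(enum.Enum):
    """Label of the accessible region a monomer centre occupies."""

    CAVITY = "cavity"
    PORE = "pore"
    SEMI = "semi"


def volume_fraction(N: int, D: float, H: float, sigma: float = 1.0) -> float:
    """Initial volume fraction of ``N`` monomers in the quasi-2D cavity.

    phi0 = N (sigma/D)^2 * [ 2 sigma / (3 H (1 - (1/3)(H/D)^2)) ]

    The factor in brackets converts the 2D areal fraction ``N (sigma/D)^2``
    to a volume fraction of spheres in the lens-shaped disk of diameter ``D``
    and gap ``H``; for ``H << D`` it reduces to ``2 sigma / (3 H)``.

    Parameters
    ----------
    N : int
        Number of monomers, >= 1.
    D : float
        Effective cavity diameter (sigma units). Must exceed ``H``.
    H : float
        Slit gap height (sigma units), > 0.
    """
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    if H <= 0 or D <= 0:
        raise ValueError("D and H must be positive")
    if D <= H:
        raise ValueError(f"require D > H, got D={D}, H={H}")
    return N * (sigma / D) ** 2 * (2.0 * sigma / (3.0 * H * (1.0 - (H / D) ** 2 / 3.0)))


def diameter_for_generation(gD: int, H: float, sigma: float = 1.0) -> float:
    """Cavity diameter ``D_gD`` of the generation grid.

    D_g = sigma sqrt(2^g / 0.3) * sqrt( 2 sigma/(3H) + (1/3)(H/sigma)^2 * 0.3 * 2^-g )

    With ``gD = gN + gF`` this inverts :func:`volume_fraction` exactly on the
    grid ``N = 2^gN``, ``phi0 = 0.3 * 2^-gF``.
    """
    if gD < 0:
        raise ValueError(f"generation number must be >= 0, got {gD}")
    if H <= 0:
        raise ValueError("H must be positive")
    two_g = 2.0**gD
    return (
        sigma
        * math.sqrt(two_g / PHI0_BASE)
        * math.sqrt(2.0 * sigma / (3.0 * H) + (H / sigma) ** 2 / 3.0 * PHI0_BASE / two_g)
    )


def diameter_for_phi0(N: int, phi0: float, H: float, sigma: float = 1.0) -> float:
    """Invert :func:`volume_fraction`: the ``D`` giving volume fraction phi0.

    Closed form: D^2 = N sigma^2/phi0 * 2 sigma/(3H) + H^2/3.
    """
    if phi0 <= 0:
        raise ValueError("phi0 must be positive")
    if N < 1 or H <= 0:
        raise ValueError("invalid N or H")
    D2 = N * sigma**2 / phi0 * 2.0 * sigma / (3.0 * H) + H * H / 3.0
    D = math.sqrt(D2)
    if D <= H:
        raise ValueError(f"phi0={phi0} too large: implied D={D:.3f} <= H={H}")
    return D


def phi_pore(rp: float, sigma: float = 1.0) -> float:
    """Local volume fraction of one monomer sitting in the pore channel.

    phi_p = (1/6) pi sigma^3 / (pi rp^2 sigma) = sigma^2 / (6 rp^2)

    (monomer-sphere volume over the pore-cylinder volume of height sigma).
    For the default pore radius rp = 0.75 sigma this is ~0.296.
    """
    if rp <= 0:
        raise ValueError("pore radius must be positive")
    return sigma**2 / (6.0 * rp**2)


def close_pack_phi0(H: float, sigma: float = 1.0) -> float:
    """Maximum (close-packed) initial volume fraction of the quasi-2D cavity.

    phi_cl^(2D) = pi/(2 sqrt(3)) = 0.9069 is the 2D hexagonal packing
    fraction; the quasi-2D volume fraction is phi_cl^(2D) * 2 sigma/(3H),
    ~0.4030 at H = 1.5 sigma.
    """
    if H <= 0:
        raise ValueError("H must be positive")
    return math.pi / (2.0 * math.sqrt(3.0)) * 2.0 * sigma / (3.0 * H)


@dataclass(frozen=True)
class SystemParams:
    """All physical constants of a run, in reduced units.

    Exactly one of ``D`` / ``phi0`` must be supplied; the other is derived
    through the quasi-2D volume-fraction relation. ``D = inf`` selects the
    translocation (no cavity) limit with ``phi0 = 0``.
    """

    N: int
    D: float | None = None
    phi0: float | None = None
    H: float = 1.5
    lp: float = 1.0
    dp: float = 1.5
    k_spring: float = 600.0
    b0: float = 1.0
    eps_w: float = 3.0
    sigma_w: float = 1.0
    T: float = 1.0
    damp: float = 1.0
    dt: float = 0.005
    sigma: float = 1.0
    eps: float = 1.0
    mass: float = 1.0

    def __post_init__(self):
        if self.N < 2:
            raise ValueError(f"N must be >= 2, got {self.N}")
        for name in ("H", "lp", "dp", "k_spring", "b0", "eps_w", "sigma_w",
                     "T", "damp", "dt", "sigma", "eps", "mass"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.dp >= 2.0 * self.sigma:
            raise ValueError(
                f"pore diameter dp={self.dp} must admit exactly one monomer (dp < 2 sigma)")
        if self.m_p < 1:
            raise ValueError(f"pore must hold at least one monomer, lp={self.lp}")
        if self.D is None and self.phi0 is None:
            raise ValueError("exactly one of D or phi0 is required")
        if self.D is not None and self.phi0 is not None:
            # both given: must be mutually consistent
            if math.isinf(self.D):
                if self.phi0 != 0.0:
                    raise ValueError("D=inf requires phi0=0")
            else:
                implied = volume_fraction(self.N, self.D, self.H, self.sigma)
                if abs(implied - self.phi0) > 1e-9 * max(implied, self.phi0):
                    raise ValueError(
                        f"inconsistent D/phi0: D={self.D} implies phi0={implied:.9g}, "
                        f"got {self.phi0:.9g}")
        elif self.D is None:
            if self.phi0 == 0.0:
                object.__setattr__(self, "D", math.inf)
            else:
                object.__setattr__(
                    self, "D", diameter_for_phi0(self.N, self.phi0, self.H, self.sigma))
        else:
            if math.isinf(self.D):
                object.__setattr__(self, "phi0", 0.0)
            else:
                object.__setattr__(
                    self, "phi0", volume_fraction(self.N, self.D, self.H, self.sigma))
        if not math.isinf(self.D):
            phimax = close_pack_phi0(self.H, self.sigma)
            if self.phi0 >= phimax:
                raise ValueError(
                    f"phi0={self.phi0:.4f} at or above the quasi-2D close-pack "
                    f"bound {phimax:.4f}; lower phi0 or enlarge D")

    @property
    def rp(self) -> float:
        """Effective pore radius, dp/2."""
        return self.dp / 2.0

    @property
    def m_p(self) -> int:
        """Number of monomers spanning the pore, round(lp/sigma), >= 1."""
        return round(self.lp / self.sigma)

    def geometry(self) -> "Geometry":
        return Geometry.from_params(self)

    def with_(self, **kw) -> "SystemParams":
        """Copy with replaced fields (D/phi0 re-derived if one is changed)."""
        if "D" in kw and "phi0" not in kw:
            kw["phi0"] = None
        if "phi0" in kw and "D" not in kw:
            kw["D"] = None
        return replace(self, **kw)


@dataclass(frozen=True)
class Geometry:
    """Derived geometric quantities and region tests.

    ``x_entrance``/``x_exit`` are the pore entrance/exit planes along the
    pore axis; PORE membership is half-open, ``[entrance, exit)``, so the
    exit plane itself belongs to SEMI and the integer bookkeeping
    ``N = m + m_pore + s`` is unambiguous.
    """

    D: float
    H: float
    lp: float
    rp: float
    sigma: float = 1.0
    cavity_wall_diameter: float = field(init=False)
    x_entrance: float = field(init=False)
    x_exit: float = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "cavity_wall_diameter", self.D + 2 * WALL_OFFSET * self.sigma)
        xe = 0.0 if math.isinf(self.D) else self.D / 2.0
        object.__setattr__(self, "x_entrance", xe)
        object.__setattr__(self, "x_exit", xe + self.lp)

    @classmethod
    def from_params(cls, p: SystemParams) -> "Geometry":
        return cls(D=p.D, H=p.H, lp=p.lp, rp=p.rp, sigma=p.sigma)

    @property
    def z_mid(self) -> float:
        return self.H / 2.0

    @property
    def pore_entrance(self) -> np.ndarray:
        """Point on the pore axis at the entrance plane."""
        return np.array([self.x_entrance, 0.0, self.z_mid])

    @property
    def cavity_center(self) -> np.ndarray:
        return np.array([0.0, 0.0, self.z_mid])

    def in_slit(self, z: float, tol: float = 0.0) -> bool:
        return -tol <= z <= self.H + tol


def classify_region(position: np.ndarray, geometry: Geometry, tol: float = 1e-9) -> Region:
    """Classify a monomer-centre position into CAVITY / PORE / SEMI.

    The three labels partition the accessible space. Positions inside walls
    (outside every accessible region) raise ``ValueError`` as a diagnostic.
    """
    x, y, z = (float(position[0]), float(position[1]), float(position[2]))
    if not (math.isfinite(x) and math.isfinite(y) and math.isfinite(z)):
        raise ValueError("non-finite coordinates")
    g = geometry
    if not g.in_slit(z, tol):
        raise ValueError(f"position z={z} outside the slit [0, {g.H}]")
    rho2 = y * y + (z - g.z_mid) ** 2
    if g.x_entrance <= x < g.x_exit:
        if rho2 <= (g.rp + tol) ** 2:
            return Region.PORE
        raise ValueError("position inside the pore wall")
    if x >= g.x_exit:
        return Region.SEMI
    # cavity side of the entrance plane
    if math.isinf(g.D):
        return Region.CAVITY
    r2 = x * x + y * y + (z - g.z_mid) ** 2
    if r2 <= (g.D / 2.0 + tol) ** 2:
        return Region.CAVITY
    raise ValueError("position outside the cavity sphere (inside wall)")
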