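"""D3Q27 velocity set and physical <-> lattice unit scaling.

The solver works in lattice units (dx = dt = 1, reference density 1).
:class:`UnitScaling` holds the conversion factors to SI for a given grid
resolution and target lattice Mach number.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["VelocitySet", "D3Q27", "UnitScaling"]

CS2 = 1.0 / 3.0  # squared lattice sound speed


def _build_d3q27():
    dirs = []
    for i in (0, 1, -1):
        for j in (0, 1, -1):
            for k in (0, 1, -1):
                dirs.append((i, j, k))
    # order: rest first, then by |e|^2 (convention only; nothing depends on it)
    dirs.sort(key=lambda e: (e[0] ** 2 + e[1] ** 2 + e[2] ** 2))
    e = np.array(dirs, dtype=np.int64)
    norm2 = (e ** 2).sum(axis=1)
    w = np.empty(27)
    w[norm2 == 0] = 8.0 / 27.0
    w[norm2 == 1] = 2.0 / 27.0
    w[norm2 == 2] = 1.0 / 54.0
    w[norm2 == 3] = 1.0 / 216.0
    opp = np.array([int(np.where((e == -e[a]).all(axis=1))[0][0]) for a in range(27)])
    return e, w, opp


@dataclass(frozen=True)
class VelocitySet:
    """Discrete velocity set: direction vectors ``e``, weights ``w``,
    opposite-direction index map ``opp`` and sound speed ``cs2``."""

    e: np.ndarray
    w: np.ndarray
    opp: np.ndarray
    cs2: float = CS2

    @property
    def q(self) -> int:
        return len(self.w)


_e, _w, _opp = _build_d3q27()
D3Q27 = VelocitySet(e=_e, w=_w, opp=_opp)


@dataclass
class UnitScaling:
    """Conversion between SI and lattice units.

    Parameters
    ----------
    dx : metres per lattice spacing.
    dt : seconds per lattice time step.
    nu_phys : kinematic viscosity of the working fluid, m^2/s.
    rho_phys : reference density, kg/m^3 (maps to lattice density 1).
    """

    dx: float
    dt: float
    nu_phys: float
    rho_phys: float = 1.225

    def __post_init__(self):
        if self.dx <= 0 or self.dt <= 0:
            raise ValueError("dx and dt must be positive")
        if self.tau <= 0.5:
            raise ValueError(
                f"molecular relaxation time tau={self.tau} <= 0.5; "
                "decrease dt or refine the grid"
            )

    # --- derived quantities -------------------------------------------------
    @property
    def nu_lat(self) -> float:
        return self.nu_phys * self.dt / self.dx ** 2

    @property
    def tau(self) -> float:
        """Dimensionless BGK relaxation time from the molecular viscosity."""
        return 0.5 + self.nu_lat / CS2

    # --- converters ---------------------------------------------------------
    def u_to_lattice(self, u_phys):
        return np.asarray(u_phys) * (self.dt / self.dx)

    def u_to_physical(self, u_lat):
        return np.asarray(u_lat) * (self.dx / self.dt)

    def accel_to_lattice(self, a_phys):
        return np.asarray(a_phys) * (self.dt ** 2 / self.dx)

    def nu_to_lattice(self, nu_phys):
        return np.asarray(nu_phys) * (self.dt / self.dx ** 2)

    def force_to_physical(self, f_lat):
        """Lattice force (mass·dx/dt²) to newtons."""
        mass_unit = self.rho_phys * self.dx ** 3
        return np.asarray(f_lat) * mass_unit * self.dx / self.dt ** 2

    # --- constructors -------------------------------------------------------
    @classmethod
    def for_inlet(
        cls,
        n: int,
        u_inlet: float,
        domain_size: float = 1.5,
        u_lat: float = 0.05,
        nu_phys: float = 1.7894e-5 / 1.225,
        rho_phys: float = 1.225,
    ) -> "UnitScaling":
        """Pick dt so that the inlet speed maps to ``u_lat`` lattice units.

        Defaults describe the 1.5 m cubic air domain with air at
        rho = 1.225 kg/m^3 and mu = 1.7894e-5 Pa·s.
        """
        if not 0 < u_lat <= 0.1:
            raise ValueError("target lattice velocity must be in (0, 0.1]")
        if u_inlet <= 0:
            raise ValueError("inlet speed must be positive")
        dx = domain_size / n
        dt = u_lat * dx / u_inlet
        return cls(dx=dx, dt=dt, nu_phys=nu_phys, rho_phys=rho_phys)
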