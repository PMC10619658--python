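"""Wall-adapting local eddy-viscosity (WALE) subgrid closure and
finite-difference field operators (velocity gradient, vorticity).

WALE computes a turbulent eddy viscosity from the resolved velocity
gradient tensor g_ab = du_a/dx_b:

    nu_t = (Bw*Delta)^2 * (Sd:Sd)^{3/2} / [ (S:S)^{5/2} + (Sd:Sd)^{5/4} ]

with S the symmetric strain rate and Sd the traceless symmetric part of
g^2.  The model vanishes identically in pure shear and rigid rotation,
which makes it well behaved near walls without damping functions.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lattice import CS2, D3Q27

__all__ = [
    "WaleConstants",
    "velocity_gradient",
    "wale_viscosity",
    "strain_from_nonequilibrium",
    "vorticity",
]


@dataclass(frozen=True)
class WaleConstants:
    """WALE model constants: coefficient ``b_w`` and filter scale ``delta``
    (defaults: 0.325 and one grid spacing)."""

    b_w: float = 0.325
    delta: float = 1.0


def velocity_gradient(u, dx: float = 1.0):
    """Velocity gradient tensor g[a, b] = du_a/dx_b on the full grid.

    Second-order central differences in the interior, one-sided at the
    boundary faces.  ``u`` has shape (3, nx, ny, nz); the result has shape
    (3, 3, nx, ny, nz).
    """
    u = np.asarray(u)
    if u.shape[0] != 3 or u.ndim != 4:
        raise ValueError("u must have shape (3, nx, ny, nz)")
    if min(u.shape[1:]) < 3:
        raise ValueError("grid must be at least 3 nodes per axis")
    g = np.empty((3, 3) + u.shape[1:], dtype=u.dtype)
    for a in range(3):
        for b in range(3):
            g[a, b] = np.gradient(u[a], dx, axis=b)
    return g


def wale_viscosity(g, constants: WaleConstants = WaleConstants()):
    """Eddy viscosity field from the velocity-gradient tensor.

    ``g`` has shape (3, 3, ...).  Both contractions vanishing (e.g. fluid
    at rest, pure shear) is a 0/0 guarded to nu_t = 0.
    """
    g = np.asarray(g, dtype=float)
    s = 0.5 * (g + np.swapaxes(g, 0, 1))
    g2 = np.einsum("ar...,rb...->ab...", g, g)
    tr_g2 = np.einsum("aa...->...", g2)
    sd = 0.5 * (g2 + np.swapaxes(g2, 0, 1))
    for a in range(3):
        sd[a, a] -= tr_g2 / 3.0
    ss = np.einsum("ab...,ab...->...", s, s)
    sdsd = np.einsum("ab...,ab...->...", sd, sd)
    num = sdsd ** 1.5
    den = ss ** 2.5 + sdsd ** 1.25
    nu_t = np.where(den > 0.0, (constants.b_w * constants.delta) ** 2
                    * np.divide(num, den, out=np.zeros_like(num), where=den > 0.0),
                    0.0)
    return nu_t


def strain_from_nonequilibrium(f, f_eq, tau, rho=None):
    """Strain-rate tensor from the second moment of the non-equilibrium
    populations (lattice units, dt = 1):

        S_ab = -1/(2 rho cs^2 tau) * sum_alpha (f - f_eq) e_a e_b

    Diagnostic alternative to :func:`velocity_gradient`; it cannot supply
    the full (antisymmetric part of the) gradient that WALE needs, so the
    default LES path uses finite differences.
    """
    fneq = np.asarray(f) - np.asarray(f_eq)
    if rho is None:
        rho = np.asarray(f).sum(axis=0)
    e = D3Q27.e.astype(float)
    pi = np.einsum("q...,qa,qb->ab...", fneq, e, e)
    return -pi / (2.0 * rho * CS2 * tau)


def vorticity(u, dx: float = 1.0):
    """Vorticity magnitude |curl u| via central differences."""
    g = velocity_gradient(u, dx)
    wx = g[2, 1] - g[1, 2]
    wy = g[0, 2] - g[2, 0]
    wz = g[1, 0] - g[0, 1]
    return np.sqrt(wx ** 2 + wy ** 2 + wz ** 2)
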