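"""Uniform-grid D3Q27 lattice-Boltzmann BGK solver.

Single-relaxation-time (BGK) collision with Guo forcing, optional WALE
large-eddy closure folded into a local effective relaxation time, half-way
bounce-back interior obstacles, and box-face boundary conditions
(velocity inlet / zero-gradient outflow / periodic).

Everything here is in lattice units (dx = dt = 1); :class:`~canopyflow.lattice.UnitScaling`
provides the SI conversions.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lattice import CS2, D3Q27, UnitScaling
from .les import WaleConstants, velocity_gradient, wale_viscosity

__all__ = [
    "FluidState",
    "BoxBoundaries",
    "StabilityError",
    "equilibrium",
    "macroscopics",
    "collide_and_stream",
    "apply_boundaries",
]

_AXIS_OF = {"x": 0, "y": 1, "z": 2}


class StabilityError(RuntimeError):
    """Raised when the local effective relaxation time breaches tau <= 0.5."""


def equilibrium(rho, u):
    """Second-order D3Q27 equilibrium distribution.

    ``rho`` has any shape S, ``u`` shape (3,) + S.  Returns shape (27,) + S.
    Moments: sum_a f_eq = rho, sum_a f_eq e_a = rho u.
    """
    rho = np.asarray(rho, dtype=float)
    u = np.asarray(u, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("density must be positive")
    if np.any(np.linalg.norm(u, axis=0) > 0.3):
        raise ValueError("lattice velocity exceeds 0.3; reduce dt (Mach limit)")
    e = D3Q27.e.astype(float)
    eu = np.einsum("qa,a...->q...", e, u)
    u2 = np.einsum("a...,a...->...", u, u)
    w = D3Q27.w.reshape((27,) + (1,) * rho.ndim)
    return w * rho * (1.0 + 3.0 * eu + 4.5 * eu ** 2 - 1.5 * u2)


def macroscopics(f, force=None):
    """Density and velocity moments of ``f`` (shape (27,) + S).

    With Guo forcing active the velocity carries the half-force
    correction u = (sum f e + F/2) / rho.
    """
    f = np.asarray(f)
    rho = f.sum(axis=0)
    if np.any(rho <= 0):
        raise ValueError("non-positive density encountered")
    mom = np.einsum("q...,qa->a...", f, D3Q27.e.astype(float))
    if force is not None:
        mom = mom + 0.5 * np.asarray(force)
    return rho, mom / rho


def _guo_source(u, force, tau):
    """Guo forcing source term per direction (already includes 1 - 1/(2 tau))."""
    e = D3Q27.e.astype(float)
    eu = np.einsum("qa,a...->q...", e, u)
    ef = np.einsum("qa,a...->q...", e, force)
    uf = np.einsum("a...,a...->...", u, force)
    w = D3Q27.w.reshape((27,) + (1,) * eu[0].ndim)
    s = w * (3.0 * (ef - uf) + 9.0 * eu * ef)
    return (1.0 - 0.5 / tau) * s


@dataclass
class BoxBoundaries:
    """Boundary condition on each face of the box, plus an inlet velocity.

    ``faces`` maps 'x-','x+','y-','y+','z-','z+' to one of
    'periodic' | 'inlet' | 'outflow' | 'wall'.  The canopy default is a
    downward jet: inlet on 'z+', outflow on the bottom and the four sides.
    """

    faces: dict = field(default_factory=lambda: {
        "x-": "outflow", "x+": "outflow",
        "y-": "outflow", "y+": "outflow",
        "z-": "outflow", "z+": "inlet",
    })
    inlet_velocity: np.ndarray = field(
        default_factory=lambda: np.zeros(3))  # lattice units
    inlet_patch: tuple | None = None  # (center_frac_2d, radius_frac) circular jet

    def __post_init__(self):
        valid = {"periodic", "inlet", "outflow", "wall"}
        for k, v in self.faces.items():
            if k[0] not in _AXIS_OF or k[1] not in "+-" or v not in valid:
                raise ValueError(f"bad face spec {k!r}: {v!r}")
        self.inlet_velocity = np.asarray(self.inlet_velocity, dtype=float)

    @classmethod
    def downward_inlet(cls, u_lat: float, patch=None) -> "BoxBoundaries":
        return cls(inlet_velocity=np.array([0.0, 0.0, -float(u_lat)]),
                   inlet_patch=patch)


@dataclass
class FluidState:
    """Distributions plus cached macroscopic fields on a uniform lattice."""

    f: np.ndarray                     # (27, nx, ny, nz)
    rho: np.ndarray
    u: np.ndarray                     # (3, nx, ny, nz)
    nu_t: np.ndarray                  # lattice eddy viscosity
    solid: np.ndarray | None = None   # bool mask, bounce-back obstacles
    step_count: int = 0

    @classmethod
    def initialize(cls, shape, rho=1.0, u=None, solid=None) -> "FluidState":
        """Fresh state at equilibrium for the given (rho, u)."""
        shape = tuple(shape)
        rho_f = np.full(shape, float(rho))
        u_f = np.zeros((3,) + shape)
        if u is not None:
            u_f += np.asarray(u, dtype=float).reshape(3, 1, 1, 1)
        f = equilibrium(rho_f, u_f)
        return cls(f=f, rho=rho_f, u=u_f, nu_t=np.zeros(shape), solid=solid)

    @property
    def shape(self):
        return self.f.shape[1:]


def _face_index(shape, face):
    ax = _AXIS_OF[face[0]]
    idx = [slice(None)] * 3
    idx[ax] = -1 if face[1] == "+" else 0
    return ax, tuple(idx)


def _neighbor_index(shape, face):
    ax = _AXIS_OF[face[0]]
    idx = [slice(None)] * 3
    idx[ax] = -2 if face[1] == "+" else 1
    return tuple(idx)


def apply_boundaries(state: FluidState, bounds: BoxBoundaries) -> FluidState:
    """Impose face boundary conditions on the post-streaming distributions.

    Inlet: non-equilibrium extrapolation with the prescribed velocity.
    Outflow: zero-gradient copy from the first interior layer.
    Wall faces: treated as no-slip via on-face bounce-back is not supported
    here — embed wall layers in ``state.solid`` instead.
    """
    f = state.f
    for face, kind in bounds.faces.items():
        if kind in ("periodic", "wall"):
            continue
        ax, fidx = _face_index(state.shape, face)
        nidx = _neighbor_index(state.shape, face)
        f_nb = f[(slice(None),) + nidx]
        rho_nb = f_nb.sum(axis=0)
        if kind == "outflow":
            f[(slice(None),) + fidx] = f_nb
        elif kind == "inlet":
            mom = np.einsum("q...,qa->a...", f_nb, D3Q27.e.astype(float))
            u_nb = mom / rho_nb
            u_in = np.broadcast_to(
                bounds.inlet_velocity.reshape(3, 1, 1), u_nb.shape).copy()
            if bounds.inlet_patch is not None:
                (c0, c1), rad = bounds.inlet_patch
                n0, n1 = u_nb.shape[1], u_nb.shape[2]
                i0, i1 = np.meshgrid(np.arange(n0), np.arange(n1), indexing="ij")
                r2 = ((i0 / n0 - c0) ** 2 + (i1 / n1 - c1) ** 2)
                u_in[:, r2 > rad ** 2] = 0.0
            f[(slice(None),) + fidx] = (
                equilibrium(rho_nb, u_in) + (f_nb - equilibrium(rho_nb, u_nb)))
    return state


def collide_and_stream(
    state: FluidState,
    tau: float,
    bounds: BoxBoundaries | None = None,
    forcing=None,
    les: WaleConstants | None = None,
    tau_floor: float | None = None,
) -> FluidState:
    """Advance the state by one lattice time step (in place).

    Implements the BGK evolution
    f_a(r + e_a, t+1) - f_a(r, t) = -(f_a - f_a^eq)/tau_eff + F_a
    with tau_eff = tau + nu_t/cs^2 from the WALE closure when ``les`` is
    given, followed by streaming, half-way bounce-back on ``state.solid``
    and the face boundary conditions.

    ``forcing`` is a lattice force-density field of shape (3, nx, ny, nz)
    or a constant (3,) vector (e.g. rho * g for a body force).

    ``tau_floor`` imposes a minimum effective relaxation time — a
    numerical background viscosity.  At desk-scale resolutions the air's
    molecular tau sits within ~1e-5 of the BGK stability limit, and the
    resolved-gradient WALE term alone cannot damp the non-hydrodynamic
    modes that grow in under-resolved shear layers.
    """
    f = state.f
    if forcing is not None:
        forcing = np.asarray(forcing, dtype=float)
        if forcing.ndim == 1:
            forcing = forcing.reshape(3, 1, 1, 1) * np.ones((3,) + state.shape)
    rho, u = macroscopics(f, forcing)

    if les is not None:
        g = velocity_gradient(u, 1.0)
        nu_t = wale_viscosity(g, les)
        tau_eff = tau + nu_t / CS2
        state.nu_t = nu_t
    else:
        tau_eff = tau
        state.nu_t = np.zeros(state.shape)
    if tau_floor is not None:
        tau_eff = np.maximum(tau_eff, tau_floor)
    tau_min = np.min(tau_eff)
    if tau_min <= 0.5:
        loc = np.unravel_index(int(np.argmin(np.broadcast_to(tau_eff, state.shape))),
                               state.shape)
        raise StabilityError(f"tau_eff = {tau_min} <= 0.5 at node {loc}")

    feq = equilibrium(rho, u)
    fstar = f - (f - feq) / tau_eff
    if forcing is not None:
        fstar += _guo_source(u, forcing, tau_eff)

    # streaming (periodic wrap; face BCs overwrite the wrapped layers)
    e = D3Q27.e
    fnew = np.empty_like(fstar)
    for a in range(27):
        fnew[a] = np.roll(fstar[a], shift=tuple(e[a]), axis=(0, 1, 2))

    # half-way bounce-back on interior obstacles: a population that streamed
    # into a solid node is returned, reversed, to the node it came from
    if state.solid is not None and state.solid.any():
        opp = D3Q27.opp
        for a in range(27):
            if not e[a].any():
                continue
            # fluid nodes whose neighbour along +e_a is solid
            nb_solid = np.roll(state.solid, shift=tuple(-e[a]), axis=(0, 1, 2))
            src = nb_solid & ~state.solid
            fnew[opp[a]][src] = fstar[a][src]
        # solid nodes carry no fluid; park them at the rest equilibrium
        fnew[:, state.solid] = D3Q27.w[:, None]

    state.f = fnew
    if bounds is not None:
        apply_boundaries(state, bounds)
    state.rho, state.u = macroscopics(state.f, forcing)
    state.step_count += 1
    return state
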