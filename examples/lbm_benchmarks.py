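"""Classic lattice-Boltzmann benchmarks on small grids.

Poiseuille: body-force-driven channel against the exact parabola (wall
planes sit half a lattice spacing beyond the last fluid node under
half-way bounce-back).  Taylor-Green: viscous decay of an extruded
vortex against the Stokes rate.
"""
import numpy as np

from canopyflow import FluidState, collide_and_stream, equilibrium
from canopyflow.lbm import macroscopics

# --- Poiseuille ----------------------------------------------------------
h, tau, g = 32, 0.9, 1e-6
nu = (tau - 0.5) / 3
shape = (3, h + 2, 3)
solid = np.zeros(shape, bool)
solid[:, 0] = solid[:, -1] = True
st = FluidState.initialize(shape, solid=solid)
for _ in range(12000):
    collide_and_stream(st, tau=tau, forcing=np.array([g, 0.0, 0.0]))
y = np.arange(1, h + 1, dtype=float)
u_ana = g / (2 * nu) * (y - 0.5) * (h + 0.5 - y)
err = np.abs(st.u[0, 1, 1:-1, 1] - u_ana).max() / u_ana.max()
print(f"Poiseuille ({h} nodes): max profile error {100 * err:.3f}% "
      "(the parabola is recovered to well under 1%)")

# --- Taylor-Green --------------------------------------------------------
n, tau = 32, 0.8
nu = (tau - 0.5) / 3
k = 2 * np.pi / n
X, Y = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
u = np.zeros((3, n, n, n))
u[0] = (0.01 * np.cos(k * X) * np.sin(k * Y))[:, :, None]
u[1] = (-0.01 * np.sin(k * X) * np.cos(k * Y))[:, :, None]
st = FluidState.initialize((n, n, n))
st.f = equilibrium(np.ones((n, n, n)), u)
st.rho, st.u = macroscopics(st.f)
ke0 = (st.u ** 2).sum()
steps = 200
for _ in range(steps):
    collide_and_stream(st, tau=tau)
rate = -np.log((st.u ** 2).sum() / ke0) / steps
print(f"Taylor-Green: KE decay rate {rate:.3e} per step, "
      f"Stokes rate {4 * nu * k ** 2:.3e} "
      f"({100 * abs(rate / (4 * nu * k ** 2) - 1):.2f}% off)")
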