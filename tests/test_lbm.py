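"""Lattice-Boltzmann core: moments, conservation, boundaries, operators."""
import numpy as np
import pytest

from canopyflow.lattice import CS2, D3Q27, UnitScaling
from canopyflow.lbm import (BoxBoundaries, FluidState, collide_and_stream,
                            equilibrium, macroscopics)
from canopyflow.les import velocity_gradient, vorticity


class TestVelocitySet:
    def test_moment_isotropy(self):
        e = D3Q27.e.astype(float)
        assert D3Q27.w.sum() == pytest.approx(1.0, abs=1e-14)
        assert np.allclose(np.einsum("q,qa->a", D3Q27.w, e), 0.0, atol=1e-15)
        assert np.allclose(np.einsum("q,qa,qb->ab", D3Q27.w, e, e),
                           CS2 * np.eye(3), atol=1e-15)

    def test_opposites(self):
        assert np.array_equal(D3Q27.e[D3Q27.opp], -D3Q27.e)


class TestEquilibrium:
    def test_rest_state_is_weights(self):
        feq = equilibrium(np.ones((2, 2, 2)), np.zeros((3, 2, 2, 2)))
        assert np.allclose(feq, D3Q27.w.reshape(27, 1, 1, 1), atol=1e-15)

    def test_moments_by_direct_sum(self, rng):
        rho = 1.0 + 0.1 * rng.random((3, 3, 3))
        u = 0.05 * rng.standard_normal((3, 3, 3, 3)).transpose(0, 1, 2, 3)
        u = 0.05 * rng.standard_normal((3, 3, 3, 3))
        feq = equilibrium(rho, u)
        # brute-force 27-term sums
        m0 = sum(feq[a] for a in range(27))
        m1 = sum(feq[a][None] * D3Q27.e[a].reshape(3, 1, 1, 1)
                 for a in range(27))
        assert np.allclose(m0, rho, atol=1e-12)
        assert np.allclose(m1, rho * u, atol=1e-12)

    def test_galilean_shift_of_moments(self):
        rho = np.full((2, 2, 2), 1.2)
        u0 = np.zeros((3, 2, 2, 2))
        shift = np.array([0.04, -0.03, 0.02]).reshape(3, 1, 1, 1)
        r1, v1 = macroscopics(equilibrium(rho, u0 + shift))
        assert np.allclose(v1, shift, atol=1e-13)
        assert np.allclose(r1, rho, atol=1e-13)

    def test_rejects_nonphysical(self):
        with pytest.raises(ValueError):
            equilibrium(np.zeros((2, 2, 2)), np.zeros((3, 2, 2, 2)))
        with pytest.raises(ValueError):
            equilibrium(np.ones((2, 2, 2)), 0.5 * np.ones((3, 2, 2, 2)))


class TestCollideStream:
    def test_uniform_rest_is_fixed_point(self):
        st = FluidState.initialize((4, 4, 4))
        f0 = st.f.copy()
        collide_and_stream(st, tau=0.8)
        assert np.allclose(st.f, f0, atol=1e-15)

    def test_single_step_matches_bruteforce(self, rng):
        """One periodic step equals a hand-rolled 27-direction update."""
        shape = (3, 3, 3)
        u = 0.03 * rng.standard_normal((3,) + shape)
        rho = 1.0 + 0.05 * rng.random(shape)
        f = equilibrium(rho, u) * (1.0 + 0.01 * rng.random((27,) + shape))
        st = FluidState.initialize(shape)
        st.f = f.copy()
        tau = 0.7
        collide_and_stream(st, tau=tau)
        # oracle: explicit loops
        r = f.sum(axis=0)
        mom = np.zeros((3,) + shape)
        for a in range(27):
            for c in range(3):
                mom[c] += f[a] * D3Q27.e[a, c]
        uu = mom / r
        feq = equilibrium(r, uu)
        fstar = f - (f - feq) / tau
        fnew = np.empty_like(f)
        for a in range(27):
            ex, ey, ez = D3Q27.e[a]
            for i in range(3):
                for j in range(3):
                    for k in range(3):
                        fnew[a, (i + ex) % 3, (j + ey) % 3, (k + ez) % 3] = \
                            fstar[a, i, j, k]
        assert np.allclose(st.f, fnew, atol=1e-14)

    def test_mass_conserved_periodic(self, rng):
        st = FluidState.initialize((8, 8, 8))
        st.f = equilibrium(np.ones((8, 8, 8)),
                           0.02 * rng.standard_normal((3, 8, 8, 8)))
        m0 = st.f.sum()
        for _ in range(200):
            collide_and_stream(st, tau=0.8)
        assert abs(st.f.sum() - m0) / m0 < 1e-12


class TestBoundaries:
    def test_zero_inlet_stays_at_rest(self):
        st = FluidState.initialize((8, 8, 8))
        bb = BoxBoundaries.downward_inlet(0.0)
        for _ in range(50):
            collide_and_stream(st, tau=0.7, bounds=bb)
        assert np.abs(st.u).max() < 1e-12

    def test_plug_flow_passthrough(self):
        """Empty domain with a downward inlet reaches uniform flow."""
        st = FluidState.initialize((10, 10, 20))
        bb = BoxBoundaries.downward_inlet(0.05)
        for _ in range(400):
            collide_and_stream(st, tau=0.6, bounds=bb)
        interior = st.u[2, 3:-3, 3:-3, 3:-3]
        assert np.abs(interior + 0.05).max() / 0.05 < 0.01


class TestFieldOperators:
    def test_gradient_exact_for_linear_field(self):
        shape = (5, 6, 7)
        y = np.arange(shape[1]).reshape(1, -1, 1) * np.ones(shape)
        u = np.zeros((3,) + shape)
        u[0] = 3.5 * y
        g = velocity_gradient(u, 1.0)
        assert np.allclose(g[0, 1], 3.5, atol=1e-12)
        g0 = velocity_gradient(np.ones((3,) + shape), 1.0)
        assert np.abs(g0).max() == 0.0

    def test_gradient_second_order(self):
        errs = []
        for n in (16, 32):
            x = np.linspace(0, 2 * np.pi, n, endpoint=False)
            dx = x[1] - x[0]
            u = np.zeros((3, n, 4, 4))
            u[0] = np.sin(x)[:, None, None]
            g = velocity_gradient(u, dx)
            ana = np.cos(x)[:, None, None]
            errs.append(np.abs(g[0, 0][1:-1] - ana[1:-1]).max())
        order = np.log2(errs[0] / errs[1])
        assert order > 1.8

    def test_vorticity_rigid_rotation(self):
        n = 12
        idx = np.arange(n) - n / 2
        xg, yg = np.meshgrid(idx, idx, indexing="ij")
        omega = 0.3
        u = np.zeros((3, n, n, 5))
        u[0] = -omega * yg[:, :, None]
        u[1] = omega * xg[:, :, None]
        w = vorticity(u, 1.0)
        assert np.allclose(w[2:-2, 2:-2, 2:-2], 2 * omega, atol=1e-10)

    def test_vorticity_uniform_zero(self):
        assert np.abs(vorticity(np.ones((3, 5, 5, 5)), 1.0)).max() == 0.0

    def test_small_grid_rejected(self):
        with pytest.raises(ValueError):
            velocity_gradient(np.zeros((3, 2, 5, 5)), 1.0)


class TestUnitScaling:
    def test_inlet_mapping(self):
        sc = UnitScaling.for_inlet(40, 5.0)
        assert sc.u_to_lattice(5.0) == pytest.approx(0.05)
        assert sc.u_to_physical(sc.u_to_lattice(3.3)) == pytest.approx(3.3)
        assert sc.tau > 0.5

    def test_mach_guard(self):
        with pytest.raises(ValueError):
            UnitScaling.for_inlet(40, 5.0, u_lat=0.5)
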