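"""Plane-strain CST elements: constitutive checks, patch test, beam oracle."""

import numpy as np
import pytest

from needlefem.fe_solid import (BulkSystem, Material, NewtonResult,
                                StepRejected, TriangleBulk, newton_solve)
from needlefem.mesh import structured_rectangle

MAT = Material(E=14.8e3, nu=0.475)


def make_bulk(mesh, mat=MAT, **kw):
    lam, mu = mat.lame
    return TriangleBulk(mesh.nodes, mesh.tris, lam, mu, **kw)


class TestElementBasics:
    def test_zero_displacement_zero_force(self):
        bulk = make_bulk(structured_rectangle(0, 0, 1, 1, 3, 3))
        f = bulk.internal_force(np.zeros(2 * len(bulk.nodes)))
        assert np.allclose(f, 0.0)

    def test_rigid_translation_zero_force_and_energy(self):
        bulk = make_bulk(structured_rectangle(0, 0, 1, 1, 4, 4))
        u = np.tile([0.37, -1.2], len(bulk.nodes))
        assert np.allclose(bulk.internal_force(u), 0.0, atol=1e-9)
        assert bulk.total_strain_energy(u) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_rotation_zero_energy_total_lagrangian(self):
        # objectivity of the SVK formulation: finite rotation stores no energy
        bulk = make_bulk(structured_rectangle(0, 0, 1, 1, 4, 4))
        ang = 0.4
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        u = (bulk.nodes @ R.T - bulk.nodes).reshape(-1)
        assert bulk.total_strain_energy(u) == pytest.approx(0.0, abs=1e-16)
        assert np.allclose(bulk.internal_force(u), 0.0, atol=1e-8)

    def test_small_strain_misses_rotation_objectivity(self):
        # the debugging switch is genuinely linear: rotations store energy
        bulk = make_bulk(structured_rectangle(0, 0, 1, 1, 2, 2),
                         small_strain=True)
        ang = 0.4
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        u = (bulk.nodes @ R.T - bulk.nodes).reshape(-1)
        assert bulk.total_strain_energy(u) > 1e-3

    def test_uniaxial_small_strain_matches_plane_strain_hooke(self):
        eps = 1e-6
        mesh = structured_rectangle(0, 0, 1, 1, 1, 1)
        bulk = make_bulk(mesh)
        u = np.zeros((len(mesh.nodes), 2))
        u[:, 1] = eps * mesh.nodes[:, 1]      # uniform eps_yy
        lam, mu = MAT.lame
        sig_yy = (lam + 2 * mu) * eps
        sed = bulk.strain_energy_density(u.reshape(-1))
        assert np.allclose(sed, 0.5 * sig_yy * eps, rtol=1e-5)
        # reaction on the top edge equals sigma_yy * width
        f = bulk.internal_force(u.reshape(-1))
        top = np.where(mesh.nodes[:, 1] > 1 - 1e-12)[0]
        assert f[2 * top + 1].sum() == pytest.approx(sig_yy * 1.0, rel=1e-5)

    def test_inverted_element_raises_step_rejection(self):
        mesh = structured_rectangle(0, 0, 1, 1, 1, 1)
        bulk = make_bulk(mesh)
        u = np.zeros((len(mesh.nodes), 2))
        u[mesh.nodes[:, 1] > 0.5, 1] = -1.5    # fold the square onto itself
        with pytest.raises(StepRejected):
            bulk.check_admissible(u.reshape(-1))

    def test_tangent_matches_finite_difference(self):
        rng = np.random.default_rng(2)
        mesh = structured_rectangle(0, 0, 1, 1, 2, 2)
        bulk = make_bulk(mesh)
        u = rng.normal(0, 0.02, 2 * len(mesh.nodes))
        K = bulk.tangent(u).toarray()
        f0 = bulk.internal_force(u)
        eps = 1e-7
        for j in range(0, 2 * len(mesh.nodes), 5):
            du = u.copy()
            du[j] += eps
            col = (bulk.internal_force(du) - f0) / eps
            assert np.allclose(K[:, j], col, rtol=1e-4,
                               atol=1e-6 * np.abs(K).max())

    def test_tangent_symmetry_at_equilibrium(self):
        mesh = structured_rectangle(0, 0, 1, 1, 3, 3)
        bulk = make_bulk(mesh)
        rng = np.random.default_rng(4)
        u = rng.normal(0, 0.01, 2 * len(mesh.nodes))
        K = bulk.tangent(u).toarray()
        assert np.allclose(K, K.T, rtol=1e-12, atol=1e-9 * np.abs(K).max())


class TestPatchTest:
    def test_affine_boundary_displacement_gives_uniform_strain(self):
        # irregular interior: perturb inner nodes, then impose an affine
        # map on the boundary; CST must reproduce the affine field exactly
        mesh = structured_rectangle(0, 0, 1, 1, 5, 5)
        rng = np.random.default_rng(8)
        interior = np.where(
            (mesh.nodes[:, 0] > 1e-9) & (mesh.nodes[:, 0] < 1 - 1e-9)
            & (mesh.nodes[:, 1] > 1e-9) & (mesh.nodes[:, 1] < 1 - 1e-9))[0]
        mesh.nodes[interior] += rng.uniform(-0.04, 0.04, (len(interior), 2))
        mesh.orient_ccw()
        bulk = make_bulk(mesh)
        A = np.array([[1e-3, 4e-4], [-2e-4, 6e-4]])   # small affine strain
        u_exact = mesh.nodes @ A.T

        boundary = np.setdiff1d(np.arange(len(mesh.nodes)), interior)
        fixed = np.concatenate([2 * boundary, 2 * boundary + 1])
        vals = np.concatenate([u_exact[boundary, 0], u_exact[boundary, 1]])
        res = newton_solve(BulkSystem(bulk), np.zeros(2 * len(mesh.nodes)),
                           fixed, vals, tol=1e-12)
        assert res.converged
        assert np.allclose(res.u.reshape(-1, 2), u_exact, atol=1e-12)
        sed = bulk.strain_energy_density(res.u)
        assert np.ptp(sed) <= 1e-9 * sed.mean()


class TestCantileverBeamOracle:
    def test_tip_deflection_within_5pct_of_beam_theory(self):
        # slender strip, small tip load => Euler-Bernoulli P L^3 / 3 E I
        L, t = 0.1, 0.004
        mat = Material(E=1e6, nu=0.0)     # nu = 0: plane strain = plane stress
        mesh = structured_rectangle(0, 0, L, t, 200, 10)
        bulk = make_bulk(mesh, mat)
        n = len(mesh.nodes)
        P = 1e-4                          # N per unit depth: tiny, linear range
        Iz = t ** 3 / 12
        w_beam = P * L ** 3 / (3 * mat.E * Iz)

        clamp = np.where(mesh.nodes[:, 0] < 1e-12)[0]
        fixed = np.concatenate([2 * clamp, 2 * clamp + 1])
        tip_nodes = np.where(mesh.nodes[:, 0] > L - 1e-12)[0]
        f_ext = np.zeros(2 * n)
        f_ext[2 * tip_nodes + 1] = -P / len(tip_nodes)

        class LoadedSystem:
            def residual(self, u):
                bulk.check_admissible(u)
                return bulk.internal_force(u) - f_ext

            def tangent(self, u):
                return bulk.tangent(u)

        res = newton_solve(LoadedSystem(), np.zeros(2 * n), fixed,
                           np.zeros(fixed.size), tol=1e-10)
        assert res.converged
        tip_mid = tip_nodes[np.argmin(np.abs(mesh.nodes[tip_nodes, 1] - t / 2))]
        w = -res.u[2 * tip_mid + 1]
        assert w == pytest.approx(w_beam, rel=0.05)


class TestNewtonSolver:
    def test_zero_load_zero_solution_one_iteration(self):
        mesh = structured_rectangle(0, 0, 1, 1, 3, 3)
        bulk = make_bulk(mesh)
        boundary = np.where(mesh.nodes[:, 1] < 1e-12)[0]
        fixed = np.concatenate([2 * boundary, 2 * boundary + 1])
        res = newton_solve(BulkSystem(bulk), np.zeros(2 * len(mesh.nodes)),
                           fixed, np.zeros(fixed.size))
        assert res.converged and res.iterations == 0
        assert np.allclose(res.u, 0.0)

    def test_global_equilibrium_reactions_balance(self):
        # stretched block: reactions at the two clamped edges cancel
        mesh = structured_rectangle(0, 0, 1, 1, 6, 6)
        bulk = make_bulk(mesh)
        left = np.where(mesh.nodes[:, 0] < 1e-12)[0]
        right = np.where(mesh.nodes[:, 0] > 1 - 1e-12)[0]
        fixed = np.concatenate([2 * left, 2 * left + 1, 2 * right, 2 * right + 1])
        vals = np.concatenate([np.zeros(2 * left.size),
                               np.full(right.size, 0.02),
                               np.zeros(right.size)])
        res = newton_solve(BulkSystem(bulk), np.zeros(2 * len(mesh.nodes)),
                           fixed, vals)
        assert res.converged
        total = res.reactions.reshape(-1, 2).sum(axis=0)
        assert np.allclose(total, 0.0, atol=1e-8 * np.abs(res.reactions).max())

    def test_energy_objectivity_under_superposed_translation(self):
        mesh = structured_rectangle(0, 0, 1, 1, 4, 4)
        bulk = make_bulk(mesh)
        rng = np.random.default_rng(9)
        u = rng.normal(0, 0.01, 2 * len(mesh.nodes))
        shifted = u.reshape(-1, 2) + np.array([3.0, -7.0])
        assert bulk.total_strain_energy(u) == pytest.approx(
            bulk.total_strain_energy(shifted.reshape(-1)), rel=1e-12)
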