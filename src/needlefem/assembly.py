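"""Composite system assembly: bulk continuum + cohesive interfaces +
contact, with the augmented-Lagrangian outer loop around Newton."""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .fe_solid import NewtonResult, StepRejected, newton_solve


class FESystem:
    """Residual/tangent aggregator over the model components.

    Parameters
    ----------
    nodes : (N, 2) reference coordinates of all nodes (substrate +
        needle + any auxiliary rigid nodes)
    bulks : TriangleBulk instances (substrate, needle)
    cohesive : CohesiveSet or None
    contacts : NodeSegmentContact instances
    walls : TrocarWalls instances
    """

    def __init__(self, nodes: np.ndarray, bulks, cohesive=None,
                 contacts=(), walls=()):
        self.nodes = np.asarray(nodes, dtype=float)
        self.n_dof = 2 * len(self.nodes)
        self.bulks = list(bulks)
        self.cohesive = cohesive
        self.contacts = list(contacts)
        self.walls = list(walls)
        # adaptive stabilization: small artificial springs to a reference
        # state, engaged only when a plain solve fails on a snap-through
        self._stab_k: np.ndarray | None = None
        self._stab_ref: np.ndarray | None = None
        self.stabilization_energy = 0.0

    def set_stabilization(self, k_diag: np.ndarray, u_ref: np.ndarray) -> None:
        self._stab_k = k_diag
        self._stab_ref = u_ref.copy()

    def clear_stabilization(self, u_final: np.ndarray | None = None) -> None:
        if self._stab_k is not None and u_final is not None:
            d = u_final - self._stab_ref
            self.stabilization_energy += float(0.5 * np.sum(
                self._stab_k * d * d))
        self._stab_k = None
        self._stab_ref = None

    def deformed(self, u: np.ndarray) -> np.ndarray:
        return self.nodes + u.reshape(-1, 2)

    def residual(self, u: np.ndarray) -> np.ndarray:
        for b in self.bulks:
            b.check_admissible(u)
        R = np.zeros(self.n_dof)
        for b in self.bulks:
            R += b.internal_force(u)
        if self.cohesive is not None:
            Rc, _ = self.cohesive.force_and_tangent(u, self.n_dof)
            R += Rc
        x = self.deformed(u)
        for c in self.contacts:
            Rc, _, _ = c.force_and_tangent(x, self.n_dof)
            R += Rc
        for w in self.walls:
            Rw, _ = w.force_and_tangent(x, self.n_dof)
            R += Rw
        if self._stab_k is not None:
            R += self._stab_k * (u - self._stab_ref)
        return R

    def tangent(self, u: np.ndarray):
        K = sp.coo_matrix((self.n_dof, self.n_dof))
        for b in self.bulks:
            K = K + b.tangent(u)
        if self.cohesive is not None:
            _, Kc = self.cohesive.force_and_tangent(u, self.n_dof)
            K = K + Kc
        x = self.deformed(u)
        for c in self.contacts:
            _, Kc, _ = c.force_and_tangent(x, self.n_dof)
            K = K + Kc
        for w in self.walls:
            _, Kw = w.force_and_tangent(x, self.n_dof)
            K = K + Kw
        if self._stab_k is not None:
            K = K + sp.diags(self._stab_k)
        return K

    def residual_and_tangent(self, u: np.ndarray):
        """Fused evaluation (single pass over all components)."""
        for b in self.bulks:
            b.check_admissible(u)
        R = np.zeros(self.n_dof)
        K = sp.coo_matrix((self.n_dof, self.n_dof))
        for b in self.bulks:
            R += b.internal_force(u)
            K = K + b.tangent(u)
        if self.cohesive is not None:
            Rc, Kc = self.cohesive.force_and_tangent(u, self.n_dof)
            R += Rc
            K = K + Kc
        x = self.deformed(u)
        for c in self.contacts:
            Rc, Kc, _ = c.force_and_tangent(x, self.n_dof)
            R += Rc
            K = K + Kc
        for w in self.walls:
            Rw, Kw = w.force_and_tangent(x, self.n_dof)
            R += Rw
            K = K + Kw
        if self._stab_k is not None:
            R += self._stab_k * (u - self._stab_ref)
            K = K + sp.diags(self._stab_k)
        return R, K

    # -- energies ------------------------------------------------------------

    def strain_energy(self, u: np.ndarray) -> float:
        """Bulk + recoverable cohesive energy, J per unit depth."""
        total = sum(b.total_strain_energy(u) for b in self.bulks)
        if self.cohesive is not None:
            total += self.cohesive.recoverable_energy(u)
        return float(total)

    def commit(self, u: np.ndarray) -> None:
        """Make the converged increment irreversible: cohesive damage and
        frictional slip references / dissipation."""
        if self.cohesive is not None:
            # refresh trial states at the converged u before committing
            self.cohesive.force_and_tangent(u, self.n_dof)
            self.cohesive.commit()
        x = self.deformed(u)
        for c in self.contacts:
            c.commit(x)


def solve_augmented(system: FESystem, u0: np.ndarray, fixed: np.ndarray,
                    vals: np.ndarray, newton_tol: float = 1e-8,
                    max_newton: int = 40, max_augment: int = 10,
                    penetration_tol: float = 1e-7,
                    stall_accept: float = 1e-2,
                    stall_abs: float = 0.0) -> NewtonResult:
    """Newton solve wrapped in the augmented-Lagrangian contact loop.

    The contact response is continuous and (through the smoothed
    Coulomb law) differentiable, so plain Newton converges; multipliers
    are then updated until the worst penetration drops below
    `penetration_tol` (m) or stops improving.

    Raises StepRejected on Newton failure, letting the caller bisect.
    """
    u = u0.copy()
    if not system.contacts:
        return newton_solve(system, u, fixed, vals, tol=newton_tol,
                            max_iter=max_newton)
    res = None
    pen_best = np.inf
    bad_rounds = 0
    for aug in range(max_augment):
        res = newton_solve(system, u, fixed, vals, tol=newton_tol,
                           max_iter=max_newton, stall_accept=stall_accept,
                           stall_abs=stall_abs)
        u = res.u
        x = system.deformed(u)
        pen = max(c.augment(x) for c in system.contacts)
        if pen <= penetration_tol:
            return res
        if pen < 0.8 * pen_best:
            pen_best = pen
            bad_rounds = 0
        else:
            bad_rounds += 1
            if bad_rounds >= 2:
                break                # augmentation no longer improving
    # accept the remaining penetration: it is bounded by pressure/eps_n
    # and reported through the contact pairs
    return res
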