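"""Plane-strain continuum elements and the implicit static solver.

Linear (constant-strain) triangles in a total-Lagrangian setting.  Three
constitutive models share the Lame constants of the linear-elastic input
and coincide at small strain:

- "neohookean" (driver default): compressible neo-Hookean,
  P = mu (F - F^-T) + lambda ln(J) F^-T.  Its energy blows up as J -> 0,
  which keeps the severely compressed elements under the blunt needle
  tip from inverting — matching the behaviour of corotational
  "linear elastic + nonlinear geometry" formulations.
- "svk": Saint-Venant-Kirchhoff, S = lambda tr(E) I + 2 mu E on the
  Green-Lagrange strain (simple, but collapses under strong compression).
- "small": linearised kinematics (debugging switch).

The displacement formulation is kept even at nu = 0.475 (mild volumetric
locking is guarded by mesh-convergence tests rather than mixed elements).

Equilibrium is found by Newton iteration on the assembled residual with
displacement-controlled loading; element inversion (negative Jacobian)
raises a step-rejection signal that the load-step controller catches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla


class StepRejected(RuntimeError):
    """The current trial state is unusable (inverted element, diverging
    Newton loop); the load-step controller should bisect."""


@dataclass(frozen=True)
class Material:
    """Isotropic linear-elastic constants.

    E : Young's modulus (Pa), nu : Poisson ratio (plane strain).
    """

    E: float
    nu: float

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError("Young's modulus must be positive")
        if not 0 <= self.nu < 0.5:
            raise ValueError("Poisson ratio must lie in [0, 0.5)")

    @property
    def lame(self) -> tuple[float, float]:
        lam = self.E * self.nu / ((1 + self.nu) * (1 - 2 * self.nu))
        mu = self.E / (2 * (1 + self.nu))
        return lam, mu


GELATINE = Material(E=14.8e3, nu=0.475)


class TriangleBulk:
    """Vectorised force/tangent/energy evaluation for a set of CST
    elements with per-element material constants.

    Parameters
    ----------
    nodes : (N, 2) reference coordinates
    tris : (M, 3) connectivity (positively oriented)
    lam, mu : per-element Lame constants, scalars or (M,) arrays
    small_strain : use linearised kinematics (debugging switch)
    """

    MODELS = ("neohookean", "svk", "small")

    def __init__(self, nodes: np.ndarray, tris: np.ndarray, lam, mu,
                 small_strain: bool = False, model: str | None = None):
        self.nodes = np.asarray(nodes, dtype=float)
        self.tris = np.asarray(tris, dtype=int)
        m = len(self.tris)
        self.lam = np.broadcast_to(np.asarray(lam, dtype=float), (m,)).copy()
        self.mu = np.broadcast_to(np.asarray(mu, dtype=float), (m,)).copy()
        if model is None:
            model = "small" if small_strain else "svk"
        if model not in self.MODELS:
            raise ValueError(f"unknown constitutive model {model!r}")
        self.model = model
        self.small_strain = model == "small"

        X = self.nodes[self.tris]                     # (M, 3, 2)
        d1 = X[:, 1] - X[:, 0]
        d2 = X[:, 2] - X[:, 0]
        det = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
        if np.any(det <= 0):
            bad = int(np.argmin(det))
            raise ValueError(
                f"triangle {bad} is degenerate or negatively oriented "
                f"(2A = {det[bad]:.3e})")
        self.area = 0.5 * det
        # shape-function gradients dN_a/dX_j : (M, 3, 2)
        G = np.empty((m, 3, 2))
        G[:, 1, 0] = d2[:, 1] / det
        G[:, 1, 1] = -d2[:, 0] / det
        G[:, 2, 0] = -d1[:, 1] / det
        G[:, 2, 1] = d1[:, 0] / det
        G[:, 0] = -G[:, 1] - G[:, 2]
        self.G = G
        # scatter indices for assembly
        dof = np.stack([2 * self.tris, 2 * self.tris + 1], axis=2).reshape(m, 6)
        self.rows = np.repeat(dof, 6, axis=1).reshape(-1)
        self.cols = np.tile(dof, (1, 6)).reshape(-1)
        self.dof = dof
        self.n_dof = 2 * len(self.nodes)

    # -- kinematics ---------------------------------------------------------

    def _deformation(self, u: np.ndarray):
        ue = u.reshape(-1, 2)[self.tris]              # (M, 3, 2)
        H = np.einsum("eai,eaj->eij", ue, self.G)     # displacement gradient
        F = H.copy()
        F[:, 0, 0] += 1.0
        F[:, 1, 1] += 1.0
        return H, F

    def check_admissible(self, u: np.ndarray) -> None:
        """Raise StepRejected if any element is inverted."""
        _, F = self._deformation(u)
        J = F[:, 0, 0] * F[:, 1, 1] - F[:, 0, 1] * F[:, 1, 0]
        if np.any(J <= 0):
            raise StepRejected(
                f"{int((J <= 0).sum())} inverted element(s), min J = {J.min():.3e}")

    def _stress(self, H, F):
        """Green-Lagrange strain and 2nd Piola-Kirchhoff stress for the
        svk/small models."""
        if self.small_strain:
            Egl = 0.5 * (H + np.swapaxes(H, 1, 2))
        else:
            Egl = 0.5 * (H + np.swapaxes(H, 1, 2)
                         + np.einsum("eki,ekj->eij", H, H))
        tr = Egl[:, 0, 0] + Egl[:, 1, 1]
        S = 2.0 * self.mu[:, None, None] * Egl
        S[:, 0, 0] += self.lam * tr
        S[:, 1, 1] += self.lam * tr
        return Egl, S

    @staticmethod
    def _inv_det(F):
        J = F[:, 0, 0] * F[:, 1, 1] - F[:, 0, 1] * F[:, 1, 0]
        Finv = np.empty_like(F)
        Finv[:, 0, 0] = F[:, 1, 1]
        Finv[:, 0, 1] = -F[:, 0, 1]
        Finv[:, 1, 0] = -F[:, 1, 0]
        Finv[:, 1, 1] = F[:, 0, 0]
        Finv /= J[:, None, None]
        return Finv, J

    def _piola(self, H, F):
        """First Piola-Kirchhoff stress for the active model."""
        if self.model == "neohookean":
            Finv, J = self._inv_det(F)
            FinvT = np.swapaxes(Finv, 1, 2)
            lnJ = np.log(J)
            return (self.mu[:, None, None] * (F - FinvT)
                    + (self.lam * lnJ)[:, None, None] * FinvT)
        Egl, S = self._stress(H, F)
        return S if self.small_strain else np.einsum("eik,ekj->eij", F, S)

    # -- forces, tangent, energy -------------------------------------------

    def internal_force(self, u: np.ndarray) -> np.ndarray:
        H, F = self._deformation(u)
        P = self._piola(H, F)
        fe = self.area[:, None, None] * np.einsum("eij,eaj->eai", P, self.G)
        f = np.zeros(self.n_dof)
        np.add.at(f, self.dof.reshape(-1), fe.reshape(-1))
        return f

    def tangent(self, u: np.ndarray) -> sp.coo_matrix:
        H, F = self._deformation(u)
        m = len(self.tris)
        I2 = np.eye(2)
        if self.model == "neohookean":
            Finv, J = self._inv_det(F)
            lnJ = np.log(J)
            # C_iJkL = mu d_ik d_JL + lam Finv_Ji Finv_Lk
            #          - (lam lnJ - mu) Finv_Jk Finv_Li
            C = (np.einsum("e,ik,JL->eiJkL", self.mu, I2, I2)
                 + np.einsum("e,eJi,eLk->eiJkL", self.lam, Finv, Finv)
                 - np.einsum("e,eJk,eLi->eiJkL",
                             self.lam * lnJ - self.mu, Finv, Finv))
        else:
            Egl, S = self._stress(H, F)
            D = (np.einsum("e,MJ,NL->eMJNL", self.lam, I2, I2)
                 + np.einsum("e,MN,JL->eMJNL", self.mu, I2, I2)
                 + np.einsum("e,ML,JN->eMJNL", self.mu, I2, I2))
            if self.small_strain:
                C = D
            else:
                C = (np.einsum("ik,eJL->eiJkL", I2, S)
                     + np.einsum("eiM,eMJNL,ekN->eiJkL", F, D, F))
        Ke = self.area[:, None, None, None, None] * np.einsum(
            "eiJkL,eaJ,ebL->eaibk", C, self.G, self.G)
        vals = Ke.reshape(m, 6, 6).reshape(-1)
        return sp.coo_matrix((vals, (self.rows, self.cols)),
                             shape=(self.n_dof, self.n_dof))

    def strain_energy_density(self, u: np.ndarray) -> np.ndarray:
        """Per-element strain energy density (J/m^3)."""
        H, F = self._deformation(u)
        if self.model == "neohookean":
            _, J = self._inv_det(F)
            lnJ = np.log(J)
            I1 = np.einsum("eij,eij->e", F, F) + 1.0   # plane strain: F33=1
            return (0.5 * self.mu * (I1 - 3.0) - self.mu * lnJ
                    + 0.5 * self.lam * lnJ ** 2)
        Egl, S = self._stress(H, F)
        return 0.5 * np.einsum("eij,eij->e", S, Egl)

    def total_strain_energy(self, u: np.ndarray) -> float:
        """Integrated strain energy per unit out-of-plane depth (J/m)."""
        return float(np.dot(self.strain_energy_density(u), self.area))

    def centroids(self, u: np.ndarray | None = None) -> np.ndarray:
        """Element centroids (the single Gauss point of a CST), in the
        deformed configuration when u is given."""
        x = self.nodes if u is None else self.nodes + u.reshape(-1, 2)
        return x[self.tris].mean(axis=1)


@dataclass
class NewtonResult:
    u: np.ndarray
    converged: bool
    iterations: int
    residual_norm: float
    reactions: np.ndarray       # full-size vector, nonzero at fixed dofs


def newton_solve(system, u0: np.ndarray, fixed_dofs: np.ndarray,
                 fixed_vals: np.ndarray, tol: float = 1e-8,
                 abs_tol: float = 1e-12, max_iter: int = 25,
                 stall_accept: float | None = None,
                 stall_abs: float = 0.0) -> NewtonResult:
    """Solve R(u) = 0 under prescribed displacements.

    `system` provides residual(u) -> (2N,) and tangent(u) -> sparse,
    with the convention residual = internal forces (no external loads in
    displacement-driven penetration).  Convergence: the free-dof residual
    norm falls below tol * (reference force) + abs_tol, the reference
    being the largest internal force magnitude seen this solve.

    With `stall_accept` set (relative to the reference force), a solve
    that stagnates — typically on the nonsmooth switches of contact
    states — returns its best iterate with converged=False instead of
    raising, provided the residual is below that acceptance level.
    Raises StepRejected on genuine divergence so the caller can bisect.
    """
    n = u0.size
    u = u0.copy()
    u[fixed_dofs] = fixed_vals
    free = np.ones(n, dtype=bool)
    free[fixed_dofs] = False
    ref = 0.0
    res_norm = np.inf
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    history: list[float] = []
    fused = getattr(system, "residual_and_tangent", None)
    for it in range(1, max_iter + 1):
        if fused is not None:
            R, Kc = fused(u)
        else:
            R = system.residual(u)
            Kc = None
        ref = max(ref, float(np.abs(R).max()), 1e-30)
        res_norm = float(np.linalg.norm(R[free]))
        history.append(res_norm)
        if best is None or res_norm < best[0]:
            best = (res_norm, u.copy(), R.copy())
        if res_norm <= tol * ref + abs_tol:
            return NewtonResult(u=u, converged=True, iterations=it - 1,
                                residual_norm=res_norm,
                                reactions=_reactions(R, free))
        if (stall_accept is not None and len(history) >= 4
                and best[0] <= stall_accept * ref + stall_abs
                and history[-1] > 0.5 * history[-4]):
            b_res, b_u, b_R = best
            return NewtonResult(u=b_u, converged=False, iterations=it - 1,
                                residual_norm=b_res,
                                reactions=_reactions(b_R, free))
        K = (Kc if Kc is not None else system.tangent(u)).tocsr()
        Kff = K[free][:, free]
        try:
            du = spla.spsolve(Kff.tocsc(), -R[free])
        except RuntimeError as exc:     # singular factorisation
            raise StepRejected(f"linear solve failed: {exc}") from exc
        if not np.all(np.isfinite(du)):
            raise StepRejected("non-finite Newton correction")
        # monotone backtracking on the residual norm; if no scale
        # reduces the residual (cycling around a contact-state corner),
        # take the least-bad scale so progress can resume elsewhere
        scale = 1.0
        best_try: tuple[float, np.ndarray] | None = None
        accepted = False
        for _ in range(12):
            u_try = u.copy()
            u_try[free] += scale * du
            try:
                R_try = system.residual(u_try)
            except StepRejected:
                scale *= 0.5
                continue
            r_try = float(np.linalg.norm(R_try[free]))
            if best_try is None or r_try < best_try[0]:
                best_try = (r_try, u_try)
            if r_try < res_norm:
                u = u_try
                accepted = True
                break
            scale *= 0.5
        if not accepted:
            if best_try is None:
                raise StepRejected("backtracking line search exhausted")
            u = best_try[1]
    if stall_accept is not None and best is not None \
            and best[0] <= stall_accept * ref + stall_abs:
        b_res, b_u, b_R = best
        return NewtonResult(u=b_u, converged=False, iterations=max_iter,
                            residual_norm=b_res,
                            reactions=_reactions(b_R, free))
    raise StepRejected(
        f"Newton did not converge in {max_iter} iterations "
        f"(residual {res_norm:.3e}, ref {ref:.3e})")


def _reactions(R: np.ndarray, free: np.ndarray) -> np.ndarray:
    out = np.zeros_like(R)
    out[~free] = R[~free]
    return out


class BulkSystem:
    """Minimal system adapter: bulk elements only (used by the element
    verification tests; the insertion driver assembles a richer system)."""

    def __init__(self, bulk: TriangleBulk):
        self.bulk = bulk

    def residual(self, u):
        self.bulk.check_admissible(u)
        return self.bulk.internal_force(u)

    def tangent(self, u):
        return self.bulk.tangent(u)
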