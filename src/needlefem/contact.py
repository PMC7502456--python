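"""Frictional needle-substrate contact and the frictionless trocar guide.

Node-to-segment contact with an augmented-Lagrangian treatment of the
non-penetration constraint: within each Newton loop the normal pressure
is p = max(0, lambda - eps_n * g) (g = signed gap, negative when
penetrated); after convergence the multiplier is augmented,
lambda <- p, and the solve repeats until the residual penetration drops
below tolerance.  Tangential interaction follows the Coulomb law with a
penalty-regularised stick state and a return mapping to the friction
cone |t_t| <= f * p; frictional dissipation is accumulated at each
converged increment from the traction times the irreversible slip.

The trocar that guides the needle shaft above the substrate surface is
a pair of rigid, fixed, frictionless vertical walls at x = +-b/2,
enforced with the same penalty machinery on the needle boundary nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

OPEN, STICK, SLIP = "open", "stick", "slip"


@dataclass
class ContactPair:
    """Diagnostic snapshot of one follower node's contact state."""

    follower: int
    segment: tuple[int, int]
    gap: float
    pressure: float
    tangential: float
    status: str


class NodeSegmentContact:
    """One-way node-to-segment contact between a follower node set and an
    ordered target chain, both living in the same global node array.

    Parameters
    ----------
    follower_ids : node indices of the follower surface
    target_chain : ordered node indices of the target surface; outward
        normal = (t_y, -t_x) for chain tangent t (CCW boundary of the
        target body)
    friction : Coulomb coefficient f (0 = frictionless)
    eps_n, eps_t : penalty stiffnesses (Pa/m: traction per gap)
    trib : tributary lengths of the follower nodes (m)
    search_radius : pairs further than this are inactive
    """

    def __init__(self, follower_ids, target_chain, friction: float,
                 eps_n: float, eps_t: float, trib, search_radius: float):
        self.followers = np.asarray(follower_ids, dtype=int)
        self.chain = np.asarray(target_chain, dtype=int)
        if len(self.chain) < 2:
            raise ValueError("target chain needs at least 2 nodes")
        self.f = float(friction)
        self.eps_n = float(eps_n)
        self.eps_t = float(eps_t)
        self.trib = np.broadcast_to(np.asarray(trib, dtype=float),
                                    self.followers.shape).copy()
        self.radius = float(search_radius)
        n = len(self.followers)
        self.lam = np.zeros(n)            # AL normal multipliers
        self.s_ref = np.full(n, np.nan)   # stick reference arclength
        self._s_last = np.full(n, np.nan)   # position at last commit
        self._tt_last = np.zeros(n)         # traction at last commit
        self.dissipation = 0.0
        self._last_pairs: list[ContactPair] = []

    # -- geometry -----------------------------------------------------------

    def _project(self, x: np.ndarray):
        """Closest-point projection of each follower on the target chain.

        Returns (seg index, xi, gap, normal, tangent, s, active mask).
        """
        pts = x[self.followers]
        a = x[self.chain[:-1]]
        b = x[self.chain[1:]]
        d = b - a                                  # (S, 2)
        L = np.hypot(d[:, 0], d[:, 1])
        L = np.where(L > 0, L, 1e-30)
        # xi for every follower-segment combination: (F, S)
        diff = pts[:, None, :] - a[None, :, :]
        xi = np.clip((diff * d[None, :, :]).sum(-1) / L[None, :] ** 2, 0.0, 1.0)
        proj = a[None, :, :] + xi[..., None] * d[None, :, :]
        dist = np.hypot(*(pts[:, None, :] - proj).T).T
        seg = np.argmin(dist, axis=1)
        idx = np.arange(len(pts))
        xi_best = xi[idx, seg]
        proj_best = proj[idx, seg]
        tan = d[seg] / L[seg][:, None]
        # smoothed vertex normals: the outward normal varies linearly
        # along each segment, so gap and force direction stay continuous
        # when a follower's projection crosses a facet junction of a
        # curved target (e.g. the needle tip cap)
        seg_n = np.column_stack([d[:, 1], -d[:, 0]]) / L[:, None]
        vert_n = np.zeros((len(self.chain), 2))
        vert_n[:-1] += seg_n
        vert_n[1:] += seg_n
        vert_n /= np.maximum(np.hypot(vert_n[:, 0], vert_n[:, 1]),
                             1e-30)[:, None]
        nrm = (1.0 - xi_best)[:, None] * vert_n[seg] \
            + xi_best[:, None] * vert_n[seg + 1]
        nrm /= np.maximum(np.hypot(nrm[:, 0], nrm[:, 1]), 1e-30)[:, None]
        gap = ((pts - proj_best) * nrm).sum(axis=1)
        cum = np.concatenate([[0.0], np.cumsum(L)])
        s = cum[seg] + xi_best * L[seg]
        # penetrated followers (negative gap = inside the target body for
        # a closed CCW chain) stay active no matter how deep: otherwise a
        # node that slipped inside would be classified "far" and released
        active = (dist[idx, seg] <= self.radius) | (gap < 0)
        return seg, xi_best, gap, nrm, tan, s, active

    # -- assembly -----------------------------------------------------------

    def force_and_tangent(self, x: np.ndarray, n_dof: int):
        """Residual contribution and consistent tangent at current
        coordinates x ((N, 2) deformed positions).

        The normal response is the augmented-Lagrangian pressure
        p = max(0, lambda - eps_n * g).  The tangential response is a
        smooth (tanh-saturated) Coulomb law,

            t_t = f p tanh(eps_t (s_ref - s) / (f p)),

        which coincides with penalty stick for small relative slip and
        saturates to the friction cone |t_t| = f p under finite slip;
        the smoothing removes the stick/slip tangent switch that makes
        plain Newton cycle around the cone.  Returns (R, K_coo, pairs).
        """
        seg, xi, gap, nrm, tan, s, near = self._project(x)
        R = np.zeros(n_dof)
        rows, cols, vals = [], [], []
        pairs = []
        for k in range(len(self.followers)):
            p = max(0.0, self.lam[k] - self.eps_n * gap[k])
            is_active = (bool(near[k]) or self.lam[k] > 0) and p > 0.0
            fol = self.followers[k]
            ia, ib = self.chain[seg[k]], self.chain[seg[k] + 1]
            if not is_active:
                if near[k] or self.lam[k] > 0:
                    pairs.append(ContactPair(int(fol), (int(ia), int(ib)),
                                             float(gap[k]), 0.0, 0.0, OPEN))
                continue
            A = self.trib[k]
            n_k, t_k = nrm[k], tan[k]
            w = np.array([1.0, -(1.0 - xi[k]), -xi[k]])
            dofs = np.array([2 * fol, 2 * fol + 1, 2 * ia, 2 * ia + 1,
                             2 * ib, 2 * ib + 1])
            D = np.concatenate([w[0] * n_k, w[1] * n_k, w[2] * n_k])
            status = STICK
            tt = 0.0
            R[dofs] += -p * A * D
            Kp = (A * self.eps_n) * np.outer(D, D)
            # friction only once a committed stick reference exists (a
            # pair entering contact this increment starts traction free;
            # the reference is set at commit)
            if self.f > 0.0 and self.eps_t > 0.0 \
                    and not np.isnan(self.s_ref[k]):
                T = np.concatenate([w[0] * t_k, w[1] * t_k, w[2] * t_k])
                delta = self.s_ref[k] - s[k]
                tmax = self.f * p
                a = self.eps_t * delta / tmax if tmax > 0 else 0.0
                th = np.tanh(a)
                tt = tmax * th
                if abs(a) > 1.0:
                    status = SLIP
                sech2 = 1.0 - th * th
                dtt_ddelta = self.eps_t * sech2
                dtt_dp = self.f * (th - a * sech2)
                # d(delta)/du = -T, d(p)/du = -eps_n * D
                Kp = Kp + (A * dtt_ddelta) * np.outer(T, T) \
                    + (A * dtt_dp * self.eps_n) * np.outer(T, D)
                R[dofs] += -tt * A * T
            rows.append(np.repeat(dofs, 6))
            cols.append(np.tile(dofs, 6))
            vals.append(Kp.reshape(-1))
            pairs.append(ContactPair(int(fol), (int(ia), int(ib)),
                                     float(gap[k]), float(p), float(tt),
                                     status))
        if rows:
            K = sp.coo_matrix((np.concatenate(vals),
                               (np.concatenate(rows), np.concatenate(cols))),
                              shape=(n_dof, n_dof))
        else:
            K = sp.coo_matrix((n_dof, n_dof))
        self._last_pairs = pairs
        return R, K, pairs

    # -- augmented-Lagrangian outer loop ------------------------------------

    def augment(self, x: np.ndarray) -> float:
        """Update multipliers; returns the maximum residual penetration."""
        seg, xi, gap, nrm, tan, s, active = self._project(x)
        pen = 0.0
        for k in range(len(self.followers)):
            if active[k] or self.lam[k] > 0:
                p = max(0.0, self.lam[k] - self.eps_n * gap[k])
                self.lam[k] = p
                if p > 0:
                    pen = max(pen, max(0.0, -gap[k]))
            else:
                self.lam[k] = 0.0
        return pen

    def commit(self, x: np.ndarray) -> float:
        """End-of-increment update: accumulate frictional work from the
        actual (tanh-law) traction over the relative slip of the
        increment (trapezoidal), and return-map the stick references.
        Returns the dissipation increment (J per unit depth)."""
        seg, xi, gap, nrm, tan, s, active = self._project(x)
        dW = 0.0
        for k in range(len(self.followers)):
            p = max(0.0, self.lam[k] - self.eps_n * gap[k])
            if not active[k] or p <= 0.0:
                self.s_ref[k] = np.nan
                self._s_last[k] = np.nan
                self._tt_last[k] = 0.0
                continue
            if np.isnan(self.s_ref[k]):
                self.s_ref[k] = s[k]
                self._s_last[k] = s[k]
                self._tt_last[k] = 0.0
                continue
            if self.f <= 0.0 or self.eps_t <= 0.0:
                self.s_ref[k] = s[k]
                self._s_last[k] = s[k]
                continue
            tmax = self.f * p
            a = self.eps_t * (self.s_ref[k] - s[k]) / tmax if tmax > 0 else 0.0
            tt = tmax * math_tanh(a)
            if not np.isnan(self._s_last[k]):
                dW += 0.5 * (tt + self._tt_last[k]) \
                    * (self._s_last[k] - s[k]) * self.trib[k]
            self._tt_last[k] = tt
            self._s_last[k] = s[k]
            # return mapping of the stick reference (bilinear equivalent)
            tt_lin = self.eps_t * (self.s_ref[k] - s[k])
            if abs(tt_lin) > tmax:
                self.s_ref[k] = s[k] + math_copysign(tmax, tt_lin) / self.eps_t
        self.dissipation += dW
        return dW

    def reset(self) -> None:
        self.lam[:] = 0.0
        self.s_ref[:] = np.nan
        self._s_last[:] = np.nan
        self._tt_last[:] = 0.0
        self.dissipation = 0.0

    @property
    def pairs(self) -> list[ContactPair]:
        return self._last_pairs


def math_copysign(mag: float, sign_of: float) -> float:
    return mag if sign_of >= 0 else -mag


def math_tanh(a: float) -> float:
    import math
    return math.tanh(a)


class TrocarWalls:
    """Rigid frictionless vertical guide walls at x = +-half_gap for
    needle nodes above y_top (the substrate surface)."""

    def __init__(self, node_ids, half_gap: float, eps: float,
                 trib, y_top: float = 0.0):
        self.nodes = np.asarray(node_ids, dtype=int)
        self.half_gap = float(half_gap)
        self.eps = float(eps)
        self.trib = np.broadcast_to(np.asarray(trib, dtype=float),
                                    self.nodes.shape).copy()
        self.y_top = float(y_top)

    def force_and_tangent(self, x: np.ndarray, n_dof: int):
        R = np.zeros(n_dof)
        rows, cols, vals = [], [], []
        xs = x[self.nodes]
        above = xs[:, 1] > self.y_top
        over = np.abs(xs[:, 0]) - self.half_gap
        for k in np.where(above & (over > 0))[0]:
            i = self.nodes[k]
            sgn = 1.0 if xs[k, 0] > 0 else -1.0
            # push back toward the gap: force along -sgn x
            R[2 * i] += self.eps * self.trib[k] * over[k] * sgn
            rows.append(2 * i)
            cols.append(2 * i)
            vals.append(self.eps * self.trib[k])
        K = sp.coo_matrix((vals, (rows, cols)), shape=(n_dof, n_dof))
        return R, K

    def max_violation(self, x: np.ndarray) -> float:
        xs = x[self.nodes]
        over = np.abs(xs[:, 0]) - self.half_gap
        over[xs[:, 1] <= self.y_top] = 0.0
        return float(np.clip(over, 0.0, None).max(initial=0.0))


def chain_tributary_lengths(nodes: np.ndarray, chain_ids: np.ndarray
                            ) -> np.ndarray:
    """Half the summed length of the segments adjacent to each chain node
    (reference configuration)."""
    pts = nodes[np.asarray(chain_ids, dtype=int)]
    seg = np.hypot(*(pts[1:] - pts[:-1]).T)
    trib = np.zeros(len(pts))
    trib[:-1] += 0.5 * seg
    trib[1:] += 0.5 * seg
    return trib
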