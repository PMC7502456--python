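"""Bilinear cohesive-zone model for the cutting interface.

The fracture process zone ahead of the needle tip is lumped into a line
of zero-thickness four-node interface elements.  Each element carries a
bilinear traction-separation law: a linear elastic rise of stiffness
K = sigma_max / delta_max up to the cohesive strength sigma_max, then
linear softening to zero traction at the critical opening delta_c.  The
area under the envelope is the fracture energy,

    G_c = 1/2 * sigma_max * delta_c.

The same law acts, uncoupled, in the normal and tangential directions of
the local interface frame.  Damage is irreversible: each integration
point remembers its largest historical separation and unloads along the
secant to the origin.  Normal interpenetration is resisted elastically
with a dedicated compressive stiffness (defaulting to the initial
stiffness K; the insertion driver raises it to the contact-penalty
scale), which doubles as the crack-face self-contact resistance behind
the needle.

Calibration ties the law to the needle geometry: the opening at peak
traction equals the tip diameter, delta_max = 2 * rho_tip, and delta_c
must stay below the needle outer diameter b so that the substrate is
fully cut by the time the shaft passes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class CalibrationError(ValueError):
    """A cohesive calibration constraint is violated."""


@dataclass(frozen=True)
class CohesiveLaw:
    """Bilinear traction-separation law.

    Parameters
    ----------
    sigma_max : cohesive strength (Pa)
    delta_max : separation at peak traction (m)
    delta_c : separation at complete failure (m)
    """

    sigma_max: float
    delta_max: float
    delta_c: float
    K_compression: float | None = None    # interpenetration penalty, Pa/m

    def __post_init__(self) -> None:
        if self.sigma_max <= 0:
            raise CalibrationError("sigma_max must be positive")
        if not 0 < self.delta_max < self.delta_c:
            raise CalibrationError(
                "separations must satisfy 0 < delta_max < delta_c "
                f"(got delta_max={self.delta_max}, delta_c={self.delta_c})")

    @property
    def K(self) -> float:
        """Initial (penalty) stiffness sigma_max / delta_max, Pa/m."""
        return self.sigma_max / self.delta_max

    @property
    def K_comp(self) -> float:
        """Stiffness resisting normal interpenetration.  Defaults to the
        initial stiffness K; the insertion driver raises it to the
        contact-penalty scale, since K of a soft-tissue law is orders of
        magnitude too compliant to keep closed crack faces apart."""
        return self.K if self.K_compression is None else self.K_compression

    @property
    def G_c(self) -> float:
        """Fracture energy, the area under the envelope: 1/2 sigma_max delta_c."""
        return 0.5 * self.sigma_max * self.delta_c

    # -- envelope -----------------------------------------------------------

    def envelope(self, delta):
        """Virgin loading traction at separation delta (vectorised).

        The tie at exactly delta == delta_max belongs to the elastic
        branch; both branches are continuous there with value sigma_max.
        """
        d = np.asarray(delta, dtype=float)
        rising = self.K * d
        softening = self.sigma_max * (self.delta_c - d) / (self.delta_c - self.delta_max)
        out = np.where(d <= self.delta_max, rising,
                       np.where(d <= self.delta_c, softening, 0.0))
        return out if out.shape else float(out)

    def envelope_area(self, delta):
        """Area under the envelope from 0 to delta (J/m^2), vectorised."""
        d = np.minimum(np.asarray(delta, dtype=float), self.delta_c)
        a_el = 0.5 * self.K * np.minimum(d, self.delta_max) ** 2
        d_soft = np.clip(d - self.delta_max, 0.0, None)
        sig_end = self.envelope(np.minimum(d, self.delta_c))
        a_soft = np.where(d > self.delta_max,
                          0.5 * (self.sigma_max + sig_end) * d_soft, 0.0)
        out = a_el + a_soft
        return out if out.shape else float(out)

    # -- state-dependent response ------------------------------------------

    def traction(self, delta, hist=0.0):
        """Traction at separation delta given the historical maximum `hist`.

        Positive delta opens the interface.  Negative (normal
        compression) is resisted with K_comp regardless of damage.
        Unloading/reloading below the historical maximum follows the
        secant to the origin.
        """
        d = np.asarray(delta, dtype=float)
        h = np.broadcast_to(np.asarray(hist, dtype=float), d.shape).copy() if d.shape \
            else float(hist)
        h = np.maximum(h, 0.0)
        eff = np.maximum(d, 0.0)
        on_env = eff >= h
        env = self.envelope(np.maximum(eff, h))
        sec_stiff = np.where(np.maximum(eff, h) > 0, env / np.where(
            np.maximum(eff, h) > 0, np.maximum(eff, h), 1.0), self.K)
        sec_stiff = np.where(np.maximum(eff, h) > 0, sec_stiff, self.K)
        opening = np.where(on_env, env, sec_stiff * eff)
        out = np.where(d < 0, self.K_comp * d, opening)
        return out if out.shape else float(out)

    def tangent_stiffness(self, delta: float, hist: float = 0.0) -> float:
        """d(traction)/d(delta) consistent with `traction`."""
        if delta < 0:
            return self.K_comp
        h = max(hist, 0.0)
        if delta < h:                         # secant unloading branch
            return self.envelope(h) / h if h > 0 else self.K
        if delta <= self.delta_max:
            return self.K
        if delta <= self.delta_c:
            return -self.sigma_max / (self.delta_c - self.delta_max)
        return 0.0

    def dissipated(self, hist):
        """Energy irreversibly dissipated per unit interface area (J/m^2)
        for a point whose historical maximum separation is `hist`."""
        h = np.clip(np.asarray(hist, dtype=float), 0.0, self.delta_c)
        out = self.envelope_area(h) - 0.5 * self.envelope(h) * h
        return out if np.ndim(out) else float(out)

    def recoverable(self, delta, hist=0.0):
        """Elastically stored energy per unit area at separation delta."""
        d = np.asarray(delta, dtype=float)
        sig = self.traction(d, hist)
        out = 0.5 * np.abs(sig) * np.abs(d)
        return out if out.shape else float(out)

    def weakened(self, factor: float = 1e-2) -> "CohesiveLaw":
        """Reduced-strength variant used for the pre-seeded notch elements.

        Strength is scaled by `factor`; delta_c is rescaled by 1/factor so
        the fracture energy G_c is unchanged.  The resulting delta_c may
        exceed the needle diameter — acceptable only for seeded elements,
        which exist to ease the first convergence, not to model the cut.
        """
        return CohesiveLaw(sigma_max=self.sigma_max * factor,
                           delta_max=self.delta_max,
                           delta_c=self.delta_c / factor,
                           K_compression=self.K_comp)


def calibrate_cohesive_law(G_c: float, sigma_max: float, rho_tip: float,
                           b: float) -> CohesiveLaw:
    """Calibrate the bilinear law from fracture energy and needle geometry.

    delta_max = 2 * rho_tip (opening at peak = tip diameter);
    delta_c   = 2 * G_c / sigma_max (fracture-energy identity);
    requires delta_max < delta_c < b.

    Raises
    ------
    CalibrationError naming the violated inequality.
    """
    if G_c <= 0 or sigma_max <= 0 or rho_tip <= 0 or b <= 0:
        raise CalibrationError("G_c, sigma_max, rho_tip and b must be positive")
    delta_max = 2.0 * rho_tip
    delta_c = 2.0 * G_c / sigma_max
    if delta_c >= b:
        raise CalibrationError(
            f"delta_c = 2 G_c / sigma_max = {delta_c:.6g} m >= needle diameter "
            f"b = {b:.6g} m: the substrate would never be fully cut "
            "(raise sigma_max)")
    if delta_c <= delta_max:
        raise CalibrationError(
            f"delta_c = {delta_c:.6g} m <= delta_max = 2 rho_tip = "
            f"{delta_max:.6g} m: no softening branch (lower sigma_max)")
    return CohesiveLaw(sigma_max=sigma_max, delta_max=delta_max, delta_c=delta_c)


def admissible_strength_window(G_c: float, rho_tip: float, b: float) -> tuple[float, float]:
    """Open interval of sigma_max values satisfying delta_max < delta_c < b."""
    return 2.0 * G_c / b, G_c / rho_tip


def process_zone_estimate(E: float, G_c: float, sigma_max: float) -> float:
    """Hillerborg-type estimate of the cohesive process-zone length,
    L_coh ~ E G_c / sigma_max^2 (proportionality constant 1).

    A meshing sanity diagnostic: the tip element size must stay well
    below this length for the cohesive zone to be resolved.
    """
    if E < 0 or G_c < 0 or sigma_max <= 0:
        raise ValueError("E and G_c must be non-negative, sigma_max positive")
    return E * G_c / sigma_max ** 2


# ---------------------------------------------------------------------------
# zero-thickness 4-node interface element

class DamageState:
    """Irreversible damage memory for a set of cohesive elements.

    Two integration points per element (Newton-Cotes at the two ends),
    two uncoupled directions (tangential, normal).  `hist` holds the
    maximum historical separation per point and direction, committed only
    at converged increments.
    """

    def __init__(self, n_elements: int = 0):
        self.hist = np.zeros((n_elements, 2, 2))   # (elem, end, [t, n])

    def copy(self) -> "DamageState":
        out = DamageState(0)
        out.hist = self.hist.copy()
        return out

    @property
    def n_elements(self) -> int:
        return self.hist.shape[0]

    def grow(self, n_new: int) -> None:
        self.hist = np.vstack([self.hist, np.zeros((n_new, 2, 2))])

    def flags(self, law_delta_max: float, law_delta_c: float) -> np.ndarray:
        """Per-point status: 0 intact, 1 softening, 2 failed (by the
        larger of the two directional histories)."""
        h = self.hist.max(axis=2)
        return np.where(h >= law_delta_c, 2, np.where(h > law_delta_max, 1, 0))


def cohesive_force_and_tangent(x_ref: np.ndarray, u: np.ndarray, law: CohesiveLaw,
                               hist: np.ndarray):
    """Internal force and consistent tangent of one interface element.

    Node order [m1, m2, p2, p1]: (m1, p1) and (m2, p2) are the duplicated
    pairs at the two ends; the minus edge runs m1 -> m2 along the crack
    (toward the tip) so the local normal rot90(t) points to the plus side.

    Parameters
    ----------
    x_ref : (4, 2) reference coordinates
    u : (4, 2) displacements
    law : CohesiveLaw
    hist : (2, 2) committed history maxima [(end), (t, n)]

    Returns
    -------
    f : (8,) internal force (global dof order [m1x, m1y, m2x, ..., p1y])
    K : (8, 8) tangent
    new_hist : (2, 2) trial updated history
    """
    x = x_ref + u
    mid1 = 0.5 * (x[0] + x[3])
    mid2 = 0.5 * (x[1] + x[2])
    tvec = mid2 - mid1
    L0 = float(np.hypot(*(x_ref[1] - x_ref[0])))
    Lc = float(np.hypot(*tvec))
    if L0 <= 0 or Lc <= 0:
        raise ValueError("degenerate cohesive element (zero length)")
    t = tvec / Lc
    n = np.array([-t[1], t[0]])
    R = np.stack([t, n])                      # rows: local axes

    # separations at the two ends, local frame
    gap1 = R @ (x[3] - x[0] - (x_ref[3] - x_ref[0]))
    gap2 = R @ (x[2] - x[1] - (x_ref[2] - x_ref[1]))
    gaps = np.stack([gap1, gap2])             # (end, [t, n])

    new_hist = np.maximum(hist, np.maximum(gaps, 0.0))
    f = np.zeros(8)
    K = np.zeros((8, 8))
    # end -> (minus node slot, plus node slot) in the 4-node ordering
    pairs = ((0, 3), (1, 2))
    w = 0.5 * L0                              # Newton-Cotes end weights
    for e, (im, ip) in enumerate(pairs):
        sig_loc = np.array([law.traction(gaps[e, 0], hist[e, 0]),
                            law.traction(gaps[e, 1], hist[e, 1])])
        D_loc = np.diag([law.tangent_stiffness(gaps[e, 0], hist[e, 0]),
                         law.tangent_stiffness(gaps[e, 1], hist[e, 1])])
        sig = R.T @ sig_loc                   # global traction on plus face
        D = R.T @ D_loc @ R
        sp, sm = slice(2 * ip, 2 * ip + 2), slice(2 * im, 2 * im + 2)
        f[sp] += w * sig
        f[sm] -= w * sig
        K[sp, sp] += w * D
        K[sm, sm] += w * D
        Kpm = -w * D
        K[sp, sm] += Kpm
        K[sm, sp] += Kpm
    return f, K, new_hist


def element_dissipation(law: CohesiveLaw, hist: np.ndarray, L0: float) -> float:
    """Energy dissipated so far by one element (J per unit out-of-plane
    depth), Newton-Cotes over the two ends, both directions summed."""
    per_end = law.dissipated(hist).sum(axis=1)       # (2,)
    return float(0.5 * L0 * per_end.sum())


class CohesiveSet:
    """A collection of interface elements sharing one calibrated law,
    with optional reduced-strength (notch-seeded) members and committed
    damage history.

    Connectivity rows follow the [m1, m2, p2, p1] convention of
    `cohesive_force_and_tangent`; reference coordinates are frozen at
    construction.  `force_and_tangent` evaluates trial states from the
    committed history; `commit` makes the trial irreversible.
    """

    def __init__(self, nodes_ref: np.ndarray, conn: np.ndarray,
                 law: CohesiveLaw, weak: np.ndarray | None = None,
                 weak_factor: float = 1e-2,
                 hist: np.ndarray | None = None):
        self.conn = np.asarray(conn, dtype=int).reshape(-1, 4)
        self.x_ref = np.asarray(nodes_ref, dtype=float)[self.conn]
        self.law = law
        self.weak_law = law.weakened(weak_factor)
        n = len(self.conn)
        self.weak = np.zeros(n, dtype=bool) if weak is None \
            else np.asarray(weak, dtype=bool)
        self.state = DamageState(n)
        if hist is not None:
            self.state.hist[:] = hist
        self.trial = self.state.hist.copy()
        self.L0 = np.hypot(*(self.x_ref[:, 1] - self.x_ref[:, 0]).T)

    def law_of(self, e: int) -> CohesiveLaw:
        return self.weak_law if self.weak[e] else self.law

    def force_and_tangent(self, u: np.ndarray, n_dof: int):
        import scipy.sparse as sp
        R = np.zeros(n_dof)
        rows, cols, vals = [], [], []
        u2 = u.reshape(-1, 2)
        for e, quad in enumerate(self.conn):
            f, K, new_hist = cohesive_force_and_tangent(
                self.x_ref[e], u2[quad], self.law_of(e), self.state.hist[e])
            self.trial[e] = new_hist
            dofs = np.stack([2 * quad, 2 * quad + 1], axis=1).reshape(-1)
            R[dofs] += f
            rows.append(np.repeat(dofs, 8))
            cols.append(np.tile(dofs, 8))
            vals.append(K.reshape(-1))
        K = sp.coo_matrix((np.concatenate(vals),
                           (np.concatenate(rows), np.concatenate(cols))),
                          shape=(n_dof, n_dof)) if rows \
            else sp.coo_matrix((n_dof, n_dof))
        return R, K

    def commit(self) -> None:
        self.state.hist[:] = np.maximum(self.state.hist, self.trial)

    def dissipated_energy(self) -> float:
        """Total cohesive dissipation U_G (J per unit depth), committed."""
        return sum(element_dissipation(self.law_of(e), self.state.hist[e],
                                       float(self.L0[e]))
                   for e in range(len(self.conn)))

    def recoverable_energy(self, u: np.ndarray) -> float:
        """Elastically stored interface energy at displacement u."""
        u2 = u.reshape(-1, 2)
        total = 0.0
        for e, quad in enumerate(self.conn):
            law = self.law_of(e)
            x_ref = self.x_ref[e]
            x = x_ref + u2[quad]
            mid1 = 0.5 * (x[0] + x[3])
            mid2 = 0.5 * (x[1] + x[2])
            t = mid2 - mid1
            t = t / max(np.hypot(*t), 1e-30)
            Rm = np.stack([t, np.array([-t[1], t[0]])])
            g1 = Rm @ (x[3] - x[0] - (x_ref[3] - x_ref[0]))
            g2 = Rm @ (x[2] - x[1] - (x_ref[2] - x_ref[1]))
            for end, g in enumerate((g1, g2)):
                for j in range(2):
                    sig = law.traction(g[j], self.state.hist[e, end, j])
                    total += 0.5 * abs(sig * g[j]) * 0.5 * self.L0[e]
        return float(total)

    def openings_at_path_nodes(self, u: np.ndarray, crack) -> np.ndarray:
        """Normal opening delta_n = (u+ - u-) . n at each crack path node
        (NaN where no duplicated pair exists, i.e. at the tip)."""
        u2 = u.reshape(-1, 2)
        P = len(crack.path)
        out = np.full(P, np.nan)
        seg = crack.path[1:] - crack.path[:-1]
        seg = seg / np.hypot(seg[:, 0], seg[:, 1])[:, None]
        tang = np.zeros((P, 2))
        tang[:-1] += seg
        tang[1:] += seg
        tang /= np.hypot(tang[:, 0], tang[:, 1])[:, None]
        for k in range(P - 1):
            n = np.array([-tang[k, 1], tang[k, 0]])   # plus side normal
            d = u2[crack.plus_ids[k]] - u2[crack.minus_ids[k]]
            out[k] = d @ n
        out[P - 1] = 0.0       # equivalent tip: separation tends to zero
        return out
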