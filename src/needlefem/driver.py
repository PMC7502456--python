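"""The outer insertion algorithm.

Each iteration drives the needle quasi-statically from the undeformed
configuration (D_e = 0) into the substrate along the crack established
so far, until the CTOD propagation criterion fires.  The analysis is
then interrupted: the kinking angle is found by the MSED criterion on
the deformed tip ring, one cohesive element of tip-region length h is
inserted along the kinked direction, the inner region is remeshed, and
the next iteration restarts from D_e = 0 (the new interface changes the
model stiffness, so the loading history must be replayed).  The force
curve and the energy bookkeeping reported to the user come from the
last iteration, which travels the full established path.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .assembly import FESystem, solve_augmented
from .cohesive import CohesiveLaw, CohesiveSet, calibrate_cohesive_law
from .contact import (NodeSegmentContact, TrocarWalls,
                      chain_tributary_lengths)
from .fe_solid import Material, StepRejected, TriangleBulk
from .fracture import (AdmissibleRange, characteristic_distance,
                       ctod_at_distance, msed_kink_angle, propagation_check,
                       ring_sed_samples)
from .geometry import DomainSpec, NeedleSpec, rotate, unit
from .mesh import REGION_RING
from .mesh_adapt import (CrackState, SubstrateMesh, SubstrateMesher,
                         initial_crack, mesh_needle)
from .postprocess import PenetrationPath

log = logging.getLogger("needlefem")


@dataclass
class SimulationConfig:
    """Complete description of one insertion simulation (SI units)."""

    needle: NeedleSpec
    domain: DomainSpec
    substrate: Material = field(default_factory=lambda: Material(14.8e3, 0.475))
    G_c: float = 1.1
    sigma_max: float = 550.0
    friction: float = 0.3
    target_depth: float = 0.02            # imposed displacement to reach (m)
    seed: int = 0
    n_seed_symmetric: int = 10
    weak_factor: float = 1e-2
    standoff_factor: float = 0.9          # initial tip standoff / notch depth
    admissible_range_deg: float = 75.0
    # load stepping (fractions of h_tip)
    step_coarse: float = 2.0
    step_fine: float = 0.2
    ctod_fine_fraction: float = 0.75      # switch to fine steps above this
    min_step: float = 0.002
    # numerics
    newton_tol: float = 1e-6
    penalty_factor: float = 30.0          # eps_n = factor * E / h_tip
    penetration_tol_factor: float = 1e-3  # tol = factor * h_tip
    max_iterations: int = 400
    relax_iters: int = 40
    constitutive_model: str = "neohookean"
    needle_x_jitter: float = 0.0          # tie-breaking lateral offset (m)
    stabilization_factor: float = 2e-3    # fallback spring / tangent diag
    max_degraded_steps: int = 25          # relaxed-residual rescues / iter
    stall_abs_factor: float = 0.02        # abs residual floor / (E h_tip)
    quality_min_angle_deg: float = 20.0

    def __post_init__(self) -> None:
        from dataclasses import replace as _replace
        law = calibrate_cohesive_law(self.G_c, self.sigma_max,
                                     self.needle.rho_tip, self.needle.b)
        # closed crack faces must not interpenetrate: compression acts at
        # the contact-penalty scale, not the (very soft) law stiffness
        self.law = _replace(law, K_compression=self.penalty_factor
                            * self.substrate.E / self.domain.h_tip)
        self.L_bar = characteristic_distance(self.needle.rho_tip,
                                             self.needle.alpha, law=self.law)
        if self.target_depth <= 0:
            raise ValueError("target_depth must be positive")


@dataclass
class IncrementRecord:
    D_e: float
    force: float          # insertion reaction per unit depth (N/m)
    U_S: float
    U_f: float
    U_G: float
    crack_length: float
    tip_x: float
    tip_y: float
    ctod: float | None


@dataclass
class IterationRecord:
    index: int
    D_e_crit: float
    theta_c: float | None
    tip: tuple[float, float]
    n_increments: int
    propagated: bool


@dataclass
class InsertionHistory:
    increments: list[IncrementRecord]
    iterations: list[IterationRecord]
    crack_path: np.ndarray
    config: SimulationConfig

    @property
    def D_e(self) -> np.ndarray:
        return np.array([r.D_e for r in self.increments])

    @property
    def force(self) -> np.ndarray:
        return np.array([r.force for r in self.increments])

    def tip_path(self) -> PenetrationPath:
        tips = np.array([[r.tip_x, r.tip_y] for r in self.increments])
        return PenetrationPath(D_e=self.D_e, tip=tips)


# ---------------------------------------------------------------------------
# one-iteration model

class IterationModel:
    """Assembled FE model for one iteration (fixed crack topology)."""

    def __init__(self, config: SimulationConfig, sub: SubstrateMesh,
                 needle_mesh, needle_boundary):
        self.cfg = config
        self.sub = sub
        cfg = config
        nd = cfg.needle
        n_sub = sub.mesh.n_nodes
        nodes = np.vstack([sub.mesh.nodes, needle_mesh.nodes])
        self.nodes = nodes
        self.n_sub = n_sub

        lam_s, mu_s = cfg.substrate.lame
        lam_n, mu_n = Material(nd.E, nd.nu).lame
        tris = np.vstack([sub.mesh.tris, needle_mesh.tris + n_sub])
        lam = np.concatenate([np.full(sub.mesh.n_tris, lam_s),
                              np.full(needle_mesh.n_tris, lam_n)])
        mu = np.concatenate([np.full(sub.mesh.n_tris, mu_s),
                             np.full(needle_mesh.n_tris, mu_n)])
        self.bulk = TriangleBulk(nodes, tris, lam, mu,
                                 model=cfg.constitutive_model)
        self.n_bulk_sub = sub.mesh.n_tris

        self.cohesive = CohesiveSet(nodes, sub.crack.cohesive_connectivity(),
                                    cfg.law, weak=sub.crack.weak,
                                    weak_factor=cfg.weak_factor)

        # contact: substrate cavity + nearby top surface against the
        # needle boundary chain (closed so the inside test is meaningful)
        bnd = (np.append(needle_boundary, needle_boundary[0])
               + n_sub).astype(int)
        followers = list(sub.cavity_chain)
        for i in sub.top_ids:
            if abs(nodes[i, 0]) <= 1.5 * nd.b and i not in followers:
                followers.append(int(i))
        followers = np.array(followers, dtype=int)
        trib = _follower_tributaries(nodes, sub, followers)
        h = cfg.domain.h_tip
        eps_n = cfg.penalty_factor * cfg.substrate.E / h
        self.contact = NodeSegmentContact(
            followers, bnd, cfg.friction, eps_n, eps_n, trib,
            search_radius=3.0 * h)
        # trocar on needle boundary nodes
        trib_n = chain_tributary_lengths(nodes, bnd)
        eps_w = cfg.penalty_factor * nd.E / (0.25 * nd.b)
        self.walls = TrocarWalls(bnd, half_gap=nd.b / 2 + 1e-9, eps=eps_w,
                                 trib=trib_n)

        self.system = FESystem(nodes, [self.bulk], cohesive=self.cohesive,
                               contacts=[self.contact], walls=[self.walls])

        # boundary conditions
        sub_nodes = sub.mesh.nodes
        W, H = cfg.domain.half_width, cfg.domain.height
        lateral = np.where(np.abs(np.abs(sub_nodes[:, 0]) - W) < 1e-9)[0]
        bottom = np.setdiff1d(
            np.where(np.abs(sub_nodes[:, 1] + H) < 1e-9)[0], lateral)
        top_needle = np.where(
            np.abs(needle_mesh.nodes[:, 1]
                   - needle_mesh.nodes[:, 1].max()) < 1e-9)[0] + n_sub
        self.driven = top_needle
        fixed = [2 * lateral, 2 * lateral + 1, 2 * bottom + 1,
                 2 * top_needle, 2 * top_needle + 1]
        self.fixed = np.concatenate(fixed)
        self._n_lat = lateral.size
        self._n_bot = bottom.size
        # needle tip node (apex = lowest reference node)
        self.tip_node = int(np.argmin(needle_mesh.nodes[:, 1])) + n_sub

    def dirichlet_values(self, D_e: float) -> np.ndarray:
        return np.concatenate([
            np.zeros(2 * self._n_lat + self._n_bot),
            np.zeros(self.driven.size),              # u_x = 0 at the drive
            np.full(self.driven.size, -D_e)])

    def insertion_force(self, reactions: np.ndarray) -> float:
        """Reaction per unit out-of-plane depth resisting the drive
        (positive during penetration)."""
        return float(-reactions[2 * self.driven + 1].sum())

    def ctod(self, u: np.ndarray) -> float | None:
        """Crack-face opening at arclength L_bar behind the equivalent
        crack tip, measured on the deformed configuration.

        The equivalent crack comprises the cohesive faces and the
        traction-free notch walls, so the probe walks the two sides of
        the cavity chain from the tip; under the large deformations of
        deep indentation the deformed arclength differs substantially
        from the reference one, and it is the deformed separation the
        propagation condition compares against delta_max.  If the cavity
        is shorter than L_bar, the probe clamps to the notch mouth.
        """
        x = self.system.deformed(u)
        chain = self.sub.cavity_chain
        tip_id = int(self.sub.crack.minus_ids[-1])
        where = np.where(chain == tip_id)[0]
        if len(where) != 1:
            return None
        i_tip = int(where[0])
        plus_side = x[chain[:i_tip + 1][::-1]]     # tip -> plus face -> wall
        minus_side = x[chain[i_tip:]]              # tip -> minus face -> wall
        if len(plus_side) < 2 or len(minus_side) < 2:
            return None
        s_p = np.concatenate([[0.0], np.cumsum(
            np.hypot(*np.diff(plus_side, axis=0).T))])
        s_m = np.concatenate([[0.0], np.cumsum(
            np.hypot(*np.diff(minus_side, axis=0).T))])
        L = min(self.cfg.L_bar,
                0.999 * float(min(s_p[-1], s_m[-1])))
        pp = np.array([np.interp(L, s_p, plus_side[:, 0]),
                       np.interp(L, s_p, plus_side[:, 1])])
        pm = np.array([np.interp(L, s_m, minus_side[:, 0]),
                       np.interp(L, s_m, minus_side[:, 1])])
        return float(np.hypot(*(pp - pm)))

    def kink_angle(self, u: np.ndarray) -> float:
        """MSED kink angle from the deformed ring elements.

        The angular SED distribution identifies a meaningful kink only
        when the near-tip state is crack-like (faces parting in an
        opening mode).  During the blunt-indentation transient the tip
        zone is still pressed shut and the distribution reflects the
        compressive bulb instead; the crack then continues straight
        (theta_c = 0) until a genuine tip opening develops.
        """
        crack = self.sub.crack
        x = self.system.deformed(u)
        if len(crack.path) >= 2:
            tip_open = float(np.hypot(*(x[crack.plus_ids[-2]]
                                        - x[crack.minus_ids[-2]])))
        else:
            tip_open = 0.0
        if tip_open < 0.05 * self.cfg.law.delta_max:
            return 0.0
        ring_sel = self.sub.mesh.region == REGION_RING
        sel = np.zeros(len(self.bulk.tris), dtype=bool)
        sel[:self.n_bulk_sub] = ring_sel
        sed = self.bulk.strain_energy_density(u)[sel]
        cents = self.bulk.centroids(u)[sel]
        u2 = u.reshape(-1, 2)
        tip_def = crack.tip + u2[crack.minus_ids[-1]]
        prev_def = crack.path[-2] + 0.5 * (u2[crack.minus_ids[-2]]
                                           + u2[crack.plus_ids[-2]])
        tip_dir_def = unit(tip_def - prev_def)
        ang, vals = ring_sed_samples(tip_def, tip_dir_def, cents, sed)
        theta = msed_kink_angle(
            ang, vals,
            AdmissibleRange(math.radians(self.cfg.admissible_range_deg)))
        return float(theta)


def _follower_tributaries(nodes, sub: SubstrateMesh,
                          followers: np.ndarray) -> np.ndarray:
    chain_trib = chain_tributary_lengths(nodes, sub.cavity_chain)
    lookup = dict(zip(sub.cavity_chain.tolist(), chain_trib))
    top = sub.top_ids
    if len(top) > 1:
        top_trib = chain_tributary_lengths(nodes, top)
        for i, t in zip(top.tolist(), top_trib):
            lookup.setdefault(int(i), float(t))
    fallback = float(np.median(chain_trib))
    return np.array([lookup.get(int(i), fallback) for i in followers])


# ---------------------------------------------------------------------------
# iteration driver

@dataclass
class IterationResult:
    critical: bool
    D_e: float
    u: np.ndarray
    theta_c: float | None
    increments: list[IncrementRecord]
    model: IterationModel
    truncated: bool = False


def run_iteration(config: SimulationConfig, sub: SubstrateMesh,
                  needle_mesh, needle_boundary,
                  stop_depth: float | None = None,
                  record: bool = True,
                  warm_until: float = 0.0) -> IterationResult:
    """Drive the needle from D_e = 0 until the propagation criterion
    fires or `stop_depth` (default: config.target_depth) is reached.

    `warm_until` enables the warm-path replay: below that displacement
    (a margin inside the previous iteration's critical point, where the
    response is already known to be smooth) the drive advances with
    larger steps; results runs replay the full history regardless.
    """
    cfg = config
    target = cfg.target_depth if stop_depth is None else stop_depth
    model = IterationModel(cfg, sub, needle_mesh, needle_boundary)
    h = cfg.domain.h_tip
    pen_tol = cfg.penetration_tol_factor * h

    u = np.zeros(2 * len(model.nodes))
    stall_abs = cfg.stall_abs_factor * cfg.substrate.E * h
    D_e = 0.0
    increments: list[IncrementRecord] = []
    W_ext = 0.0
    F_prev = 0.0
    step = cfg.step_coarse * h
    theta_c = None
    critical = False
    degraded = 0

    while D_e < target - 1e-15:
        step = min(step, target - D_e)
        try:
            res = solve_augmented(model.system, u, model.fixed,
                                  model.dirichlet_values(D_e + step),
                                  newton_tol=cfg.newton_tol,
                                  penetration_tol=pen_tol,
                                  stall_abs=stall_abs)
        except StepRejected as err:
            # snap-throughs (cohesive softening, contact release) have no
            # static equilibrium at fixed drive: retry once with small
            # artificial springs to the last converged state, tracking
            # the dissipated stabilization energy, before bisecting
            stab_ok = False
            if cfg.stabilization_factor > 0:
                diag0 = np.maximum(model.system.tangent(u).diagonal(), 0.0)
                diag0[model.fixed] = 0.0    # never spring the driven dofs
                for esc in (1.0, 10.0, 100.0):
                    model.system.set_stabilization(
                        diag0 * cfg.stabilization_factor * esc, u)
                    try:
                        res = solve_augmented(
                            model.system, u, model.fixed,
                            model.dirichlet_values(D_e + step),
                            newton_tol=cfg.newton_tol,
                            penetration_tol=pen_tol,
                            stall_abs=stall_abs)
                        stab_ok = True
                    except StepRejected:
                        pass
                    finally:
                        model.system.clear_stabilization(
                            res.u if stab_ok else None)
                    if stab_ok:
                        # corrector: re-converge the plain equilibrium
                        # from the post-snap state, removing the spring
                        # forces from the accepted solution
                        try:
                            res = solve_augmented(
                                model.system, res.u, model.fixed,
                                model.dirichlet_values(D_e + step),
                                newton_tol=cfg.newton_tol,
                                penetration_tol=pen_tol,
                                stall_abs=stall_abs)
                        except StepRejected:
                            stab_ok = False
                        break
            if not stab_ok:
                step *= 0.5
                if step < cfg.min_step * h:
                    # last resort for an isolated pathological state (a
                    # snap with no nearby static equilibrium): accept the
                    # best quasi-equilibrium at a relaxed residual bound,
                    # bounded in count and reported via degraded_steps
                    if degraded < cfg.max_degraded_steps:
                        try:
                            res = solve_augmented(
                                model.system, u, model.fixed,
                                model.dirichlet_values(D_e + 8 * step),
                                newton_tol=cfg.newton_tol,
                                penetration_tol=pen_tol,
                                stall_accept=0.08,
                                stall_abs=stall_abs)
                            degraded += 1
                            step = 8 * step
                            log.warning(
                                "degraded increment at D_e=%.4g mm "
                                "(residual %.2e)", (D_e + step) * 1e3,
                                res.residual_norm)
                        except StepRejected:
                            if increments:
                                log.warning(
                                    "iteration truncated at D_e=%.4g mm: %s",
                                    D_e * 1e3, err)
                                return IterationResult(
                                    critical=False, D_e=D_e, u=u,
                                    theta_c=None, increments=increments,
                                    model=model, truncated=True)
                            raise StepRejected(
                                f"load step collapsed below "
                                f"{cfg.min_step} * h at D_e = {D_e:.6g} m: "
                                f"{err}") from err
                    else:
                        if increments:
                            log.warning(
                                "iteration truncated at D_e=%.4g mm: %s",
                                D_e * 1e3, err)
                            return IterationResult(
                                critical=False, D_e=D_e, u=u, theta_c=None,
                                increments=increments, model=model,
                                truncated=True)
                        raise StepRejected(
                            f"load step collapsed below {cfg.min_step} * h "
                            f"at D_e = {D_e:.6g} m: {err}") from err
                else:
                    continue
        u = res.u
        D_e += step
        model.system.commit(u)
        F = model.insertion_force(res.reactions)
        W_ext += 0.5 * (F + F_prev) * step
        F_prev = F
        delta_n = model.ctod(u)
        if record:
            u2 = u.reshape(-1, 2)
            tip_pos = model.nodes[model.tip_node] + u2[model.tip_node]
            increments.append(IncrementRecord(
                D_e=D_e, force=F,
                U_S=model.system.strain_energy(u),
                U_f=model.contact.dissipation,
                U_G=model.cohesive.dissipated_energy(),
                crack_length=sub.crack.length,
                tip_x=float(tip_pos[0]), tip_y=float(tip_pos[1]),
                ctod=delta_n))
        if propagation_check(delta_n, cfg.law):
            critical = True
            theta_c = model.kink_angle(u)
            log.info("criticality at D_e=%.4g mm, CTOD=%.4g mm, "
                     "theta_c=%.2f deg", D_e * 1e3,
                     (delta_n or 0) * 1e3, math.degrees(theta_c))
            break
        # adapt step: coarse warm-path replay, fine near criticality
        frac = 0.0 if delta_n is None else delta_n / cfg.law.delta_max
        if D_e < warm_until and frac < cfg.ctod_fine_fraction:
            want = 3.0 * cfg.step_coarse * h
        elif frac >= cfg.ctod_fine_fraction:
            want = cfg.step_fine * h
        else:
            want = cfg.step_coarse * h
        step = min(2.0 * step, want)

    return IterationResult(critical=critical, D_e=D_e, u=u, theta_c=theta_c,
                           increments=increments, model=model)


def run_insertion(config: SimulationConfig,
                  progress: bool = False) -> InsertionHistory:
    """The full adaptive algorithm: iterate (drive to criticality ->
    kink -> insert cohesive element -> remesh) until the needle reaches
    the target depth; results come from the last iteration."""
    cfg = config
    mesher = SubstrateMesher(cfg.domain, cfg.needle, seed=cfg.seed,
                             quality_min_angle_deg=cfg.quality_min_angle_deg,
                             relax_iters=cfg.relax_iters)
    crack = initial_crack(cfg.needle, cfg.domain, cfg.n_seed_symmetric)
    # the blunted material tip starts with a standoff above the congruent
    # notch bottom: flank wedging then opens the seeded crack before the
    # blunt cap reaches intact material, easing the indentation transient
    d_notch = cfg.domain.notch_depth_factor * cfg.needle.rho_tip
    bottom_y0 = -d_notch * (1.0 - cfg.standoff_factor)
    tip_y0 = bottom_y0 - float(cfg.needle.tip_bottom_offset[1])
    needle_mesh, needle_boundary = mesh_needle(
        cfg.needle, cfg.domain, tip_y=tip_y0, seed=cfg.seed,
        relax_iters=cfg.relax_iters)
    # micron-scale lateral offset: keeps left/right contact events from
    # being exactly simultaneous on symmetric fixtures (degenerate
    # snap-throughs stall Newton); the induced lateral bias is O(um)
    needle_mesh.nodes[:, 0] += cfg.needle_x_jitter

    iterations: list[IterationRecord] = []
    result = None
    warm_until = 0.0
    for it in range(cfg.max_iterations):
        sub = mesher.build(crack)
        try:
            result = run_iteration(cfg, sub, needle_mesh, needle_boundary,
                                   warm_until=warm_until)
        except StepRejected as err:
            if result is None:
                raise
            # no static equilibrium beyond this point at the current
            # resolution (typically the tip-shaft transition): report
            # the insertion up to the last completed iteration
            log.warning("insertion terminated early: %s", err)
            break
        iterations.append(IterationRecord(
            index=it, D_e_crit=result.D_e, theta_c=result.theta_c,
            tip=(float(crack.tip[0]), float(crack.tip[1])),
            n_increments=len(result.increments),
            propagated=result.critical))
        if progress:
            print(f"iteration {it}: D_e = {result.D_e * 1e3:.3f} mm, "
                  f"crack = {crack.length * 1e3:.3f} mm, "
                  f"theta_c = {None if result.theta_c is None else round(math.degrees(result.theta_c), 2)}")
        if result.truncated:
            log.warning("insertion terminated early at D_e = %.4g mm",
                        result.D_e * 1e3)
            break
        if not result.critical:
            break                      # reached target depth: final pass
        warm_until = 0.85 * result.D_e
        new_dir = rotate(crack.tip_dir, result.theta_c)
        crack = crack.extended(new_dir, cfg.domain.h_tip)
    else:
        log.warning("max_iterations reached before target depth")

    return InsertionHistory(increments=result.increments,
                            iterations=iterations,
                            crack_path=crack.path.copy(), config=cfg)


# ---------------------------------------------------------------------------
# energy balance

def energy_balance(history: InsertionHistory):
    """Terms of the quasi-static energy balance
    W_ext = U_S + U_f + U_G over the final iteration.

    Returns (W_ext, U_S, U_f, U_G, relative residual)."""
    inc = history.increments
    if not inc:
        return 0.0, 0.0, 0.0, 0.0, 0.0
    D = np.array([r.D_e for r in inc])
    F = np.array([r.force for r in inc])
    D = np.concatenate([[0.0], D])
    F = np.concatenate([[0.0], F])
    W_ext = float(np.trapezoid(F, D))
    U_S = inc[-1].U_S
    U_f = inc[-1].U_f
    U_G = inc[-1].U_G
    resid = W_ext - (U_S + U_f + U_G)
    rel = resid / W_ext if W_ext > 0 else 0.0
    return W_ext, U_S, U_f, U_G, rel
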