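"""Adaptive meshing of the substrate: graded triangulation, crack-tip
ring, cohesive-interface node duplication and iterative remeshing.

The substrate is split into an outer region, meshed once and never
touched again, and an inner region containing the insertion corridor,
which is regenerated at every crack extension.  Mesh generation is
DistMesh-style: graded point seeding from a sizing field, spring
relaxation sweeps, Delaunay triangulation, and removal of triangles
outside the region polygon.  Structural edges (crack-path segments,
boundary chains, the forward tip-ring spoke) are protected by exclusion
zones so the Delaunay step reproduces them, and their presence is
verified; the ring of radial elements around the equivalent crack tip
keeps two element edges collinear with the current propagation
direction (the forward spoke and the last crack-path segment).

The crack is a polyline of mesh nodes from the entry point (the notch
apex) to the equivalent crack tip.  All path nodes except the tip are
duplicated into plus/minus faces (plus = +x side for a downward path)
and bridged by zero-thickness cohesive elements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import shapely
from scipy.spatial import Delaunay, cKDTree
from shapely.geometry import LineString, Point, Polygon

from .geometry import DomainSpec, NeedleSpec, rotate, unit
from .mesh import REGION_INNER, REGION_OUTER, REGION_RING, TriMesh


class MeshingError(RuntimeError):
    """The mesh generator could not satisfy its constraints."""


class GeometryError(ValueError):
    """Invalid or inconsistent geometric configuration."""


# ---------------------------------------------------------------------------
# crack state

@dataclass
class CrackState:
    """Equivalent-crack geometry and its mesh bookkeeping.

    path : (P, 2) node coordinates from entry (notch apex) to the
        equivalent crack tip, consecutive spacing = tip element size h.
    tip_dir : unit vector of the current propagation direction.
    weak : (P-1,) per-segment flag, True for the reduced-strength
        notch-seeded cohesive elements.
    minus_ids / plus_ids : (P,) node indices of the two face copies in
        the current substrate mesh (identical at the tip, which is not
        duplicated).
    """

    path: np.ndarray
    tip_dir: np.ndarray
    weak: np.ndarray
    minus_ids: np.ndarray | None = None
    plus_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.path = np.asarray(self.path, dtype=float)
        self.tip_dir = unit(np.asarray(self.tip_dir, dtype=float))
        self.weak = np.asarray(self.weak, dtype=bool)
        if len(self.weak) != len(self.path) - 1:
            raise ValueError("weak flags must have one entry per segment")

    @property
    def tip(self) -> np.ndarray:
        return self.path[-1]

    @property
    def n_segments(self) -> int:
        return len(self.path) - 1

    @property
    def length(self) -> float:
        seg = self.path[1:] - self.path[:-1]
        return float(np.hypot(seg[:, 0], seg[:, 1]).sum())

    @property
    def face_pairs(self) -> np.ndarray:
        """(P-1, 2) duplicated (plus, minus) node-id pairs (tip excluded)."""
        return np.column_stack([self.plus_ids[:-1], self.minus_ids[:-1]])

    def cohesive_connectivity(self) -> np.ndarray:
        """(P-1, 4) node quadruples [m_i, m_{i+1}, p_{i+1}, p_i] per
        crack segment, ordered entry -> tip."""
        m, p = self.minus_ids, self.plus_ids
        return np.column_stack([m[:-1], m[1:], p[1:], p[:-1]])

    def extended(self, direction: np.ndarray, length: float) -> "CrackState":
        """Pure-geometry crack extension by one segment of the given
        length along `direction` (mesh ids dropped; remesh to restore)."""
        d = unit(np.asarray(direction, dtype=float))
        new_tip = self.tip + length * d
        path = np.vstack([self.path, new_tip])
        if not LineString(path).is_simple:
            raise GeometryError("extended crack path would self-intersect")
        return CrackState(path=path, tip_dir=d,
                          weak=np.append(self.weak, False))


# ---------------------------------------------------------------------------
# notch and initial crack

def notch_chain(needle: NeedleSpec, domain: DomainSpec,
                h: float | None = None) -> tuple[np.ndarray, int]:
    """Starter notch congruent with the blunted needle tip profile.

    The needle tip is a wedge truncated by a tangent fillet of radius
    rho_tip, so its material bottom is a circular cap sitting well above
    the theoretical apex.  The notch reproduces that profile, cut into
    the top surface to depth = notch_depth_factor * rho_tip (measured to
    the cap bottom): straight flank walls along the wedge faces and the
    fillet cap at the bottom.

    Returns (chain, entry_index): the chain runs from the -x top corner,
    down the left wall, around the cap (with an exact vertex at the cap
    bottom = the crack entry point), and up to the +x top corner;
    entry_index locates the bottom vertex.
    """
    d = domain.notch_depth_factor * needle.rho_tip
    a = needle.alpha
    rho = needle.rho_tip
    half = needle.wedge_half_angle
    off = needle.tip_bottom_offset
    # theoretical apex in the needle frame (outline apex at x = 0); only
    # the depth is adjusted, so the notch profile and the needle outline
    # coincide exactly when the needle is translated vertically
    apex = np.array([0.0, -d - off[1]])
    if needle.c == 0.0:
        d1 = np.array([math.sin(a), math.cos(a)])     # right face, upward
        d2 = np.array([-math.sin(a), math.cos(a)])    # left face, upward
    else:
        d1 = np.array([0.0, 1.0])                     # inner vertical face
        d2 = np.array([-math.sin(a), math.cos(a)])    # bevel face
    dist = needle.fillet_center_distance
    centre = apex + dist * unit(d1 + d2)
    bottom = centre - np.array([0.0, rho])
    t1 = apex + dist * math.cos(half) * d1
    t2 = apex + dist * math.cos(half) * d2
    if t1[1] >= -1e-12 or t2[1] >= -1e-12:
        raise GeometryError(
            "notch too shallow: the fillet tangency reaches the surface "
            "(increase notch_depth_factor)")
    corner1 = apex + (-apex[1] / d1[1]) * d1          # right top corner
    corner2 = apex + (-apex[1] / d2[1]) * d2          # left top corner
    if abs(corner1[0]) >= needle.b / 2 or abs(corner2[0]) >= needle.b / 2:
        raise GeometryError("notch wider than the needle")
    a1 = math.atan2(t1[1] - centre[1], t1[0] - centre[0])
    a2 = math.atan2(t2[1] - centre[1], t2[0] - centre[0])
    a_bot = -0.5 * math.pi
    # cap resolution tied to the tip element size
    h_eff = 0.8 * (h if h is not None else domain.h_tip)
    n_side = int(np.clip(round(rho * abs(a_bot - a2) / h_eff), 1, 16))

    def arc(afrom, ato, n, include_start):
        angs = np.linspace(afrom, ato, n + 1)
        if not include_start:
            angs = angs[1:]
        return [centre + rho * np.array([math.cos(t), math.sin(t)])
                for t in angs]

    # left wall down, cap (left tangency -> bottom -> right tangency),
    # right wall up; note a2 > a_bot > a1 in the standard orientation
    chain = [corner2]
    chain += arc(a2, a_bot, n_side, include_start=True)
    entry_index = len(chain) - 1
    chain += arc(a_bot, a1, n_side, include_start=False)
    chain.append(corner1)
    return np.array(chain), entry_index


def notch_depth(needle: NeedleSpec, domain: DomainSpec) -> float:
    return domain.notch_depth_factor * needle.rho_tip


def initial_crack(needle: NeedleSpec, domain: DomainSpec,
                  n_seed_symmetric: int = 10) -> CrackState:
    """Pre-seeded crack below the notch bottom: ten weak cohesive
    elements along x = const for the symmetric tip, a single weak
    element along the bevel-angle bisector for the PBN."""
    h = domain.h_tip
    chain, entry = notch_chain(needle, domain)
    start = chain[entry]
    if needle.c == 0.0:
        ks = np.arange(n_seed_symmetric + 1)
        path = start[None, :] + np.outer(ks, h * np.array([0.0, -1.0]))
        weak = np.ones(n_seed_symmetric, dtype=bool)
        tip_dir = np.array([0.0, -1.0])
    else:
        d = needle.bevel_bisector
        path = np.vstack([start, start + h * d])
        weak = np.array([True])
        tip_dir = d
    return CrackState(path=path, tip_dir=tip_dir, weak=weak)


# ---------------------------------------------------------------------------
# sizing field, chain grading, point seeding

class SizingField:
    """h(x) = clip(h_min + grade * distance_to_features, h_min, h_max)."""

    def __init__(self, features: list | None, h_min: float, h_max: float,
                 grade: float = 0.35):
        self.geom = shapely.union_all(features) if features else None
        self.h_min = float(h_min)
        self.h_max = float(h_max)
        self.grade = float(grade)

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        if self.geom is None:
            return np.full(len(pts), self.h_max)
        d = shapely.distance(shapely.points(pts), self.geom)
        return np.clip(self.h_min + self.grade * d, self.h_min, self.h_max)


def grade_chain(chain: np.ndarray, sizing) -> np.ndarray:
    """Subdivide a polyline so node spacing follows the sizing field;
    original vertices are kept exactly.  Within each edge, nodes are
    placed at equal increments of the metric integral ds / h(s), so the
    spacing tracks a strongly varying sizing field."""
    out = [np.asarray(chain[0], dtype=float)]
    for p0, p1 in zip(chain[:-1], chain[1:]):
        p0 = np.asarray(p0, dtype=float)
        p1 = np.asarray(p1, dtype=float)
        L = float(np.hypot(*(p1 - p0)))
        if L < 1e-15:
            continue
        m = max(16, min(int(4 * L / sizing.h_min), 4000))
        t = np.linspace(0.0, 1.0, m + 1)
        probe = p0 + np.outer(t, p1 - p0)
        dens = 1.0 / sizing(probe)
        cum = np.concatenate([[0.0], np.cumsum(
            0.5 * (dens[1:] + dens[:-1]) * (L / m))])
        n = max(int(round(cum[-1])), 1)
        targets = np.linspace(0.0, cum[-1], n + 1)[1:]
        tk = np.interp(targets, cum, t)
        for val in tk:
            out.append(p0 + val * (p1 - p0))
    return np.array(out)


def _seed_interior(poly: Polygon, sizing: SizingField,
                   rng: np.random.Generator) -> np.ndarray:
    """Staggered grid at the finest size, thinned with probability
    (h_min / h(x))^2 — the classic DistMesh graded rejection seeding."""
    minx, miny, maxx, maxy = poly.bounds
    h = sizing.h_min
    xs = np.arange(minx + h / 2, maxx, h)
    ys = np.arange(miny + 0.43 * h, maxy, 0.866 * h)
    if len(xs) == 0 or len(ys) == 0:
        return np.zeros((0, 2))
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    xx = xx + (np.arange(len(ys)) % 2)[None, :] * h / 2
    cand = np.column_stack([xx.ravel(), yy.ravel()])
    cand = cand + rng.uniform(-0.08 * h, 0.08 * h, cand.shape)
    hloc = sizing(cand)
    keep = rng.random(len(cand)) < (h / hloc) ** 2
    cand = cand[keep]
    if not len(cand):
        return cand
    inside = shapely.contains(poly, shapely.points(cand))
    return cand[inside]


def _relax(points: np.ndarray, n_fixed: int, poly: Polygon,
           sizing: SizingField, n_iter: int,
           sym: tuple[int, int] | None = None) -> np.ndarray:
    """DistMesh-style spring relaxation: repulsive-only forces along
    Delaunay edges with rest length 1.2 * local size; the first n_fixed
    points never move; escapers are projected back to the boundary.

    `sym` = (n_axis, n_half): the free points are laid out as
    [axis, half, mirror-of-half] and are re-projected onto exact mirror
    symmetry about x = 0 after every sweep.
    """
    pts = points.copy()
    rings = [poly.exterior] + list(poly.interiors)
    for _ in range(n_iter):
        tri = Delaunay(pts)
        e = np.vstack([tri.simplices[:, [0, 1]], tri.simplices[:, [1, 2]],
                       tri.simplices[:, [2, 0]]])
        e = np.unique(np.sort(e, axis=1), axis=0)
        d = pts[e[:, 1]] - pts[e[:, 0]]
        L = np.hypot(d[:, 0], d[:, 1])
        mid = 0.5 * (pts[e[:, 0]] + pts[e[:, 1]])
        L0 = 1.2 * sizing(mid)
        Fmag = np.clip(L0 - L, 0.0, None) / np.maximum(L, 1e-30)
        Fvec = Fmag[:, None] * d
        move = np.zeros_like(pts)
        np.add.at(move, e[:, 0], -0.3 * Fvec)
        np.add.at(move, e[:, 1], +0.3 * Fvec)
        move[:n_fixed] = 0.0
        pts = pts + move
        free = pts[n_fixed:]
        if len(free):
            inside = shapely.contains(poly, shapely.points(free))
            for k in np.where(~inside)[0]:
                p = Point(free[k])
                best = None
                for ring in rings:
                    q = ring.interpolate(ring.project(p))
                    if best is None or q.distance(p) < best.distance(p):
                        best = q
                free[k] = (best.x, best.y)
            pts[n_fixed:] = free
        if sym is not None:
            n_axis, n_half = sym
            a0 = n_fixed
            h0 = a0 + n_axis
            m0 = h0 + n_half
            pts[a0:h0, 0] = 0.0
            avg = 0.5 * (pts[h0:m0] + pts[m0:m0 + n_half] * [-1.0, 1.0])
            pts[h0:m0] = avg
            pts[m0:m0 + n_half] = avg * [-1.0, 1.0]
    return pts


def _dedupe(pts: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Remove duplicate coordinates, keeping first occurrences in order."""
    if len(pts) == 0:
        return pts
    tree = cKDTree(pts)
    pairs = tree.query_pairs(tol, output_type="ndarray")
    drop = set(int(max(a, b)) for a, b in pairs)
    keep = [i for i in range(len(pts)) if i not in drop]
    return pts[keep]


def _min_angle(pts: np.ndarray, tris: np.ndarray) -> float:
    X = pts[tris]
    vals = []
    for k in range(3):
        a = X[:, (k + 1) % 3] - X[:, k]
        b = X[:, (k + 2) % 3] - X[:, k]
        na = np.hypot(a[:, 0], a[:, 1])
        nb = np.hypot(b[:, 0], b[:, 1])
        cosv = np.clip((a * b).sum(axis=1) / np.maximum(na * nb, 1e-300),
                       -1.0, 1.0)
        vals.append(np.arccos(cosv))
    return float(np.min(vals)) if len(tris) else math.pi


def triangulate_region(chains: list[np.ndarray], poly: Polygon,
                       sizing: SizingField, rng: np.random.Generator,
                       required_edges=(), exclusion=None,
                       n_relax: int = 15,
                       mirror_x: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Mesh one region; returns (points, CCW triangles).

    `chains` are pre-graded node chains reproduced verbatim (first in
    the node ordering).  `required_edges` are coordinate pairs whose
    presence as triangulation edges is verified.  `exclusion` lists
    geometries whose 0.9*h neighbourhood is kept free of interior seeds.
    """
    fixed = _dedupe(np.vstack(chains))
    interior = _seed_interior(poly, sizing, rng)
    if len(interior) and len(fixed):
        tree = cKDTree(fixed)
        dist, _ = tree.query(interior)
        interior = interior[dist > 0.65 * sizing(interior)]
    if exclusion and len(interior):
        geom = shapely.union_all(exclusion)
        inside_excl = shapely.intersects(shapely.points(interior), geom)
        interior = interior[~inside_excl]
    sym = None
    if mirror_x and len(interior):
        # symmetric configurations get mirror-symmetric interior seeds so
        # the discretisation does not bias the lateral response; seeds
        # close to the axis are snapped onto it, and the symmetry is
        # re-imposed after every relaxation sweep
        hloc = sizing(interior)
        on_axis = np.abs(interior[:, 0]) <= 0.25 * hloc
        axis_pts = interior[on_axis].copy()
        axis_pts[:, 0] = 0.0
        half = interior[~on_axis & (interior[:, 0] > 0)]
        interior = np.vstack([axis_pts, half,
                              half * np.array([-1.0, 1.0])])
        sym = (len(axis_pts), len(half))
    pts = np.vstack([fixed, interior]) if len(interior) else fixed
    pts = _relax(pts, len(fixed), poly, sizing, n_iter=n_relax, sym=sym)
    if len(pts) > len(fixed):
        free = pts[len(fixed):]
        tree = cKDTree(pts[:len(fixed)])
        dist, _ = tree.query(free)
        dist_bnd = shapely.distance(shapely.points(free), poly.boundary)
        h_free = sizing(free)
        keep = np.concatenate([np.ones(len(fixed), dtype=bool),
                               (dist > 0.4 * h_free)
                               & (dist_bnd > 0.45 * h_free)])
        pts = pts[keep]
    tri = Delaunay(pts)
    cent = pts[tri.simplices].mean(axis=1)
    inside = shapely.contains(poly, shapely.points(cent))
    tris = np.asarray(tri.simplices[inside], dtype=int)
    _force_ccw(pts, tris)
    edge_set = _edge_set(tris)
    for (a, b) in required_edges:
        ia, ib = _find_node(pts, a), _find_node(pts, b)
        if (min(ia, ib), max(ia, ib)) not in edge_set:
            raise MeshingError(f"required edge {a} -> {b} missing")
    # drop orphan points referenced by no triangle (they would leave
    # singular, unconstrained dofs downstream)
    used = np.zeros(len(pts), dtype=bool)
    used[tris.ravel()] = True
    if not used.all():
        remap = np.cumsum(used) - 1
        pts = pts[used]
        tris = remap[tris]
    return pts, tris


def _edge_set(tris: np.ndarray) -> set[tuple[int, int]]:
    e = np.vstack([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
    e = np.sort(e, axis=1)
    return set(map(tuple, e.tolist()))


def _force_ccw(pts: np.ndarray, tris: np.ndarray) -> None:
    X = pts[tris]
    d1 = X[:, 1] - X[:, 0]
    d2 = X[:, 2] - X[:, 0]
    a = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
    flip = a < 0
    tris[flip] = tris[flip][:, [0, 2, 1]]


def _find_node(pts: np.ndarray, p, tol: float = 1e-9) -> int:
    d = np.hypot(pts[:, 0] - p[0], pts[:, 1] - p[1])
    i = int(np.argmin(d))
    if d[i] > tol:
        raise MeshingError(f"node at {p} not found (nearest {d[i]:.3e} away)")
    return i


# ---------------------------------------------------------------------------
# ring nodes around the crack tip

def ring_points(tip: np.ndarray, tip_dir: np.ndarray, radius: float,
                sectors: int) -> np.ndarray:
    """Candidate ring nodes with node 0 exactly ahead along tip_dir."""
    angles = 2 * math.pi * np.arange(sectors) / sectors
    d = unit(tip_dir)
    return np.array([tip + radius * rotate(d, a) for a in angles])


# ---------------------------------------------------------------------------
# substrate mesh container

@dataclass
class SubstrateMesh:
    """Substrate triangulation with crack bookkeeping.

    `cavity_chain` is the ordered contact-boundary node chain from the
    +x notch-top corner, down the +x wall, down the plus crack face to
    the tip, back up the minus face and the -x wall.  `top_ids` are the
    remaining top-surface nodes (outside the notch).
    """

    mesh: TriMesh
    crack: CrackState
    cavity_chain: np.ndarray
    top_ids: np.ndarray
    n_outer_tris: int

    @property
    def nodes(self) -> np.ndarray:
        return self.mesh.nodes


class SubstrateMesher:
    """Builds and rebuilds the substrate mesh around an evolving crack.

    The outer region is meshed once (deterministic for a given seed) and
    cached; every build regenerates only the inner region, so outer
    nodes 0..n_outer keep their coordinates and numbering across
    remeshes.
    """

    def __init__(self, domain: DomainSpec, needle: NeedleSpec,
                 seed: int = 0, quality_min_angle_deg: float = 20.0,
                 max_retries: int = 3, relax_iters: int = 40):
        self.domain = domain
        self.needle = needle
        self.seed = int(seed)
        self.quality_min_angle = math.radians(quality_min_angle_deg)
        self.max_retries = max_retries
        self.relax_iters = relax_iters
        self._outer_cache = None
        notch, _ = notch_chain(needle, domain)
        if np.any(np.abs(notch[:, 0]) > domain.inner_half_width):
            raise GeometryError("notch extends outside the inner region")

    # -- outer region -------------------------------------------------------

    def _interface_chain(self) -> np.ndarray:
        d = self.domain
        w, dep = d.inner_half_width, d.inner_depth
        corners = np.array([[w, 0.0], [w, -dep], [-w, -dep], [-w, 0.0]])
        return grade_chain(corners, SizingField(None, d.h_inner, d.h_inner))

    def outer_region(self):
        """(points, triangles, interface chain coords); cached."""
        if self._outer_cache is not None:
            return self._outer_cache
        d = self.domain
        rng = np.random.default_rng(self.seed + 1)
        W, H = d.half_width, d.height
        wi, di = d.inner_half_width, d.inner_depth
        inner_rect = np.array([[wi, 0.0], [wi, -di], [-wi, -di], [-wi, 0.0],
                               [wi, 0.0]])
        # U-shaped outer region: the inner rectangle opens onto the top edge
        outer_open = np.array([[wi, 0.0], [W, 0.0], [W, -H], [-W, -H],
                               [-W, 0.0], [-wi, 0.0]])
        interface = self._interface_chain()
        sizing = SizingField([LineString(inner_rect)], d.h_inner, d.h_outer,
                             grade=0.6)
        outer_chain = grade_chain(outer_open, sizing)
        poly = Polygon(np.vstack([outer_open, interface[::-1][1:-1]]))
        required = [(interface[i], interface[i + 1])
                    for i in range(len(interface) - 1)]
        pts, tris = triangulate_region([outer_chain, interface], poly, sizing,
                                       rng, required_edges=required,
                                       n_relax=self.relax_iters)
        self._outer_cache = (pts, tris, interface)
        return self._outer_cache

    # -- full build ---------------------------------------------------------

    def build(self, crack: CrackState) -> SubstrateMesh:
        """Substrate mesh honouring the given crack path: the
        remesh-inner-region operation (also used for the initial mesh).

        Retries with perturbed interior seeds on generator failure."""
        last_err = None
        for attempt in range(self.max_retries):
            try:
                return self._build_once(crack, attempt)
            except MeshingError as err:
                last_err = err
        raise MeshingError(
            f"substrate meshing failed after {self.max_retries} attempts: "
            f"{last_err}")

    def _build_once(self, crack: CrackState, attempt: int) -> SubstrateMesh:
        d, needle = self.domain, self.needle
        rng = np.random.default_rng(self.seed + 97 * attempt + 13)
        out_pts, out_tris, interface = self.outer_region()
        wi = d.inner_half_width
        notch, notch_entry = notch_chain(needle, d)
        if crack.length + d.ring_radius > d.inner_depth - 2 * d.h_inner:
            raise GeometryError("crack corridor reaches the inner-region "
                                "boundary; enlarge inner_depth")

        top_right = np.array([[wi, 0.0], notch[-1]])
        top_left = np.array([notch[0], [-wi, 0.0]])
        loop = np.vstack([interface,              # (wi,0) ... (-wi,0)
                          top_left[::-1][1:],     # -> notch left corner
                          notch[1:],              # -> apex -> right corner
                          top_right[::-1][1:]])   # -> (wi, 0) = start
        poly = Polygon(loop[:-1])
        if not poly.is_valid:
            poly = poly.buffer(0)

        path, tip = crack.path, crack.tip
        ring_all = ring_points(tip, crack.tip_dir, d.ring_radius,
                               d.ring_sectors)
        ring = _filter_ring(ring_all, path, notch, poly, d.h_tip)

        features = [LineString(path), Point(tip).buffer(d.ring_radius),
                    LineString(notch)]
        sizing = SizingField(features, d.h_tip, d.h_inner, grade=0.35)

        notch_graded = grade_chain(notch, sizing)
        chains = [grade_chain(top_right, sizing), grade_chain(top_left, sizing),
                  notch_graded, interface, path, ring]
        required = [(path[i], path[i + 1]) for i in range(len(path) - 1)]
        required += [(notch_graded[i], notch_graded[i + 1])
                     for i in range(len(notch_graded) - 1)]
        required.append((tip, ring_all[0]))       # forward spoke
        exclusion = [LineString(path).buffer(0.62 * d.h_tip),
                     Point(tip).buffer(d.ring_radius + 0.62 * d.h_tip),
                     LineString(notch).buffer(0.6 * d.h_tip)]

        pts, tris = triangulate_region(chains, poly, sizing, rng,
                                       required_edges=required,
                                       exclusion=exclusion,
                                       n_relax=self.relax_iters)
        q = _min_angle(pts, tris)
        if q < self.quality_min_angle:
            raise MeshingError(
                f"inner mesh quality {math.degrees(q):.1f} deg below the "
                f"{math.degrees(self.quality_min_angle):.0f} deg bound")

        mesh, n_outer_tris = _merge_outer_inner(out_pts, out_tris, pts, tris)
        _tag_regions(mesh, n_outer_tris, tip, d.ring_radius)
        return _split_crack_faces(mesh, crack, notch_graded, n_outer_tris, wi)


def _filter_ring(ring: np.ndarray, path: np.ndarray, notch: np.ndarray,
                 poly: Polygon, h: float) -> np.ndarray:
    """Drop ring candidates outside the material, too close to the crack
    path nodes, or too close to the notch walls; the forward node
    (index 0) must survive."""
    keep = []
    tree = cKDTree(path)
    wallgeom = LineString(notch)
    for i, p in enumerate(ring):
        if not poly.contains(Point(p)):
            if i == 0:
                raise MeshingError("forward ring node outside the domain")
            continue
        dpath, _ = tree.query(p)
        if dpath < 0.6 * h and i != 0:
            continue
        if wallgeom.distance(Point(p)) < 0.5 * h and i != 0:
            continue
        keep.append(p)
    return np.array(keep)


def _tag_regions(mesh: TriMesh, n_outer_tris: int, tip: np.ndarray,
                 ring_radius: float) -> None:
    cent = mesh.nodes[mesh.tris].mean(axis=1)
    r = np.hypot(cent[:, 0] - tip[0], cent[:, 1] - tip[1])
    mesh.region[:] = REGION_INNER
    mesh.region[:n_outer_tris] = REGION_OUTER
    sel = np.arange(len(mesh.tris)) >= n_outer_tris
    mesh.region[sel & (r <= ring_radius * (1 + 1e-9))] = REGION_RING


def _merge_outer_inner(out_pts, out_tris, in_pts, in_tris):
    """Concatenate outer + inner, identifying shared (interface) nodes by
    coordinate; outer numbering is untouched."""
    tree = cKDTree(out_pts)
    d, idx = tree.query(in_pts)
    mapping = np.empty(len(in_pts), dtype=int)
    shared = d < 1e-9
    mapping[shared] = idx[shared]
    mapping[~shared] = len(out_pts) + np.arange(int((~shared).sum()))
    nodes = np.vstack([out_pts, in_pts[~shared]])
    tris = np.vstack([out_tris, mapping[in_tris]])
    region = np.full(len(tris), REGION_INNER, dtype=int)
    return TriMesh(nodes, tris, region), len(out_tris)


def _chain_ids(nodes: np.ndarray, chain: np.ndarray) -> np.ndarray:
    tree = cKDTree(nodes)
    d, idx = tree.query(chain)
    if np.any(d > 1e-9):
        raise MeshingError("chain node missing from mesh")
    return idx


def _split_crack_faces(mesh: TriMesh, crack: CrackState,
                       notch_graded: np.ndarray,
                       n_outer_tris: int, inner_half_width: float
                       ) -> SubstrateMesh:
    """Duplicate crack-path nodes (all but the tip) into plus/minus
    copies; triangles on the +x side of the path tangent are rewired to
    the plus copies."""
    nodes = mesh.nodes
    path_ids = _chain_ids(nodes, crack.path)

    P = len(path_ids)
    seg = crack.path[1:] - crack.path[:-1]
    seg = seg / np.hypot(seg[:, 0], seg[:, 1])[:, None]
    tang = np.zeros((P, 2))
    tang[:-1] += seg
    tang[1:] += seg
    tang /= np.hypot(tang[:, 0], tang[:, 1])[:, None]

    tris = mesh.tris.copy()
    minus_ids = path_ids.copy()
    plus_ids = path_ids.copy()
    extra = []
    next_id = len(nodes)
    for k in range(P - 1):
        v = int(path_ids[k])
        t = tang[k]
        incident = np.where((tris == v).any(axis=1))[0]
        dup = next_id
        next_id += 1
        extra.append(crack.path[k])
        plus_ids[k] = dup
        for ti in incident:
            cent = nodes[mesh.tris[ti]].mean(axis=0)
            cross = t[0] * (cent[1] - crack.path[k][1]) \
                - t[1] * (cent[0] - crack.path[k][0])
            if cross > 0:          # CCW side of the tangent = +x side for a
                tris[ti][tris[ti] == v] = dup   # downward path -> plus face
    all_nodes = np.vstack([nodes, np.array(extra)]) if extra else nodes
    out = TriMesh(all_nodes, tris, mesh.region.copy())

    crack2 = CrackState(path=crack.path.copy(), tip_dir=crack.tip_dir.copy(),
                        weak=crack.weak.copy(),
                        minus_ids=minus_ids, plus_ids=plus_ids)
    cavity = _cavity_chain(out, crack2, notch_graded)
    top = _top_surface_ids(out, notch_graded, inner_half_width)
    return SubstrateMesh(mesh=out, crack=crack2, cavity_chain=cavity,
                         top_ids=top, n_outer_tris=n_outer_tris)


def _cavity_chain(mesh: TriMesh, crack: CrackState,
                  notch_graded: np.ndarray) -> np.ndarray:
    """Contact-boundary node chain: +x notch top corner, down the +x
    wall/cap, down the plus crack face to the tip, back up the minus
    face and the -x wall/cap."""
    nodes = mesh.nodes
    entry = crack.path[0]
    k_entry = int(np.argmin(np.hypot(*(notch_graded - entry).T)))
    if not np.allclose(notch_graded[k_entry], entry, atol=1e-9):
        raise MeshingError("crack entry is not a notch-chain vertex")
    left_pts = notch_graded[:k_entry]            # -x corner ... near-bottom
    right_pts = notch_graded[k_entry + 1:]       # near-bottom ... +x corner
    left_wall = [int(i) for i in _chain_ids(nodes, left_pts)] if len(left_pts) else []
    right_wall = [int(i) for i in _chain_ids(nodes, right_pts)] if len(right_pts) else []
    chain = (right_wall[::-1]
             + list(crack.plus_ids[:-1]) + [int(crack.minus_ids[-1])]
             + list(crack.minus_ids[:-1][::-1])
             + left_wall[::-1])
    return np.asarray(chain, dtype=int)


def _top_surface_ids(mesh: TriMesh, notch: np.ndarray,
                     inner_half_width: float) -> np.ndarray:
    """Top-surface nodes (y = 0) outside the notch mouth, ordered by x."""
    nodes = mesh.nodes
    on_top = np.where(np.abs(nodes[:, 1]) < 1e-9)[0]
    sel = on_top[np.argsort(nodes[on_top, 0])]
    return sel


def _nodes_on_segment(nodes: np.ndarray, a, b, tol: float = 1e-9) -> list[int]:
    """Node ids lying on segment a->b, ordered from a to b."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ab = b - a
    L = float(np.hypot(*ab))
    d = nodes - a
    t = (d @ ab) / (L * L)
    perp = np.abs(d[:, 0] * ab[1] - d[:, 1] * ab[0]) / L
    on = np.where((perp < tol) & (t > -tol) & (t < 1 + tol))[0]
    return list(on[np.argsort(t[on])])


# ---------------------------------------------------------------------------
# needle meshing

def mesh_needle(needle: NeedleSpec, domain: DomainSpec, tip_y: float,
                seed: int = 0, h_tip_factor: float = 1.2,
                h_shaft_factor: float = 0.25,
                relax_iters: int = 40) -> tuple[TriMesh, np.ndarray]:
    """Triangulate the needle with refinement toward the tip.

    Returns (mesh, boundary chain node ids ordered CCW around the
    outline).  Element size grows from h_tip_factor * h_tip at the tip
    to h_shaft_factor * b on the shaft.
    """
    h_fine = h_tip_factor * domain.h_tip
    h_coarse = max(h_shaft_factor * needle.b, h_fine)
    # fillet arc resolution matched to the local element size
    sweep = math.pi - 2 * needle.alpha if needle.c == 0 \
        else 0.5 * math.pi - needle.alpha
    n_arc = int(np.clip(round(sweep * needle.rho_tip / (0.8 * h_fine)), 2, 10))
    n_arc += n_arc % 2          # even count: symmetric fillet sampling
    outline = needle.outline(tip_y, n_arc=n_arc)
    # size from the wedge apexes with grade ~ tan(alpha), so the element
    # size never exceeds the local across-wedge width of the bevel tip
    tips = [Point(0.0, tip_y + needle.rho_tip)]
    if needle.c > 0:
        tips.append(Point(0.0, tip_y + needle.c + needle.rho_tip))
    sizing = SizingField(tips, h_fine, h_coarse,
                         grade=0.8 * math.tan(needle.alpha))
    loop = np.vstack([outline, outline[:1]])
    chain = grade_chain(loop, sizing)[:-1]
    poly = Polygon(outline)
    rng = np.random.default_rng(seed + 7)
    # the needle interior is deliberately left unmirrored even for the
    # symmetric tip: its mild asymmetry breaks the exact left/right
    # simultaneity of contact events that stalls the implicit solver,
    # while the (much larger) substrate mesh stays unbiased
    pts, tris = triangulate_region([chain], poly, sizing, rng,
                                   n_relax=relax_iters)
    from .mesh import REGION_NEEDLE
    mesh = TriMesh(pts, tris, np.full(len(tris), REGION_NEEDLE, dtype=int))
    boundary_ids = _chain_ids(pts, chain)
    return mesh, boundary_ids


# ---------------------------------------------------------------------------
# convenience operations over the mesher

def build_initial_mesh(domain: DomainSpec, needle: NeedleSpec, seed: int = 0,
                       n_seed_symmetric: int = 10
                       ) -> tuple[SubstrateMesher, SubstrateMesh]:
    """Initial substrate mesh with notch, seeded crack and tip ring."""
    mesher = SubstrateMesher(domain, needle, seed=seed)
    crack = initial_crack(needle, domain, n_seed_symmetric)
    return mesher, mesher.build(crack)


def remesh_inner_region(mesher: SubstrateMesher,
                        crack: CrackState) -> SubstrateMesh:
    """Rebuild the inner region around the (possibly extended) crack;
    the cached outer region and the stored crack-path coordinates are
    reproduced exactly."""
    return mesher.build(crack)


def insert_cohesive_segment(mesher: SubstrateMesher, sub: SubstrateMesh,
                            direction, length: float) -> SubstrateMesh:
    """Advance the equivalent crack tip by one element of the given
    length along `direction`, duplicate the new face nodes, add the
    bridging cohesive element and remesh."""
    return mesher.build(sub.crack.extended(direction, length))
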