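"""Substrate/needle meshing: grading, crack-tip ring, node duplication,
remeshing contracts."""

import math

import numpy as np
import pytest
from scipy.spatial import cKDTree

from needlefem.geometry import DomainSpec, NeedleSpec
from needlefem.mesh import REGION_INNER, REGION_OUTER, REGION_RING
from needlefem.mesh_adapt import (CrackState, GeometryError, SubstrateMesher,
                                  initial_crack, mesh_needle, notch_chain,
                                  ring_points)

NEEDLE_SYM = NeedleSpec(b=8e-3, alpha=math.radians(10.0), c=0.0,
                        rho_tip=0.5e-3)
NEEDLE_PBN = NeedleSpec(b=8e-3, alpha=math.radians(10.0), c=22e-3,
                        rho_tip=0.5e-3)
# scaled-down block for fast meshing tests; h_tip = 0.5*rho_tip holds at
# full scale, here doubled for speed
DOM = DomainSpec(half_width=0.04, height=0.06, inner_half_width=0.012,
                 inner_depth=0.03, h_tip=0.5e-3, h_inner=2e-3, h_outer=6e-3)


@pytest.fixture(scope="module")
def sym_build():
    mesher = SubstrateMesher(DOM, NEEDLE_SYM, seed=0)
    crack = initial_crack(NEEDLE_SYM, DOM)
    return mesher, mesher.build(crack)


@pytest.fixture(scope="module")
def pbn_build():
    mesher = SubstrateMesher(DOM, NEEDLE_PBN, seed=0)
    crack = initial_crack(NEEDLE_PBN, DOM)
    return mesher, mesher.build(crack)


class TestInitialCrack:
    def test_symmetric_has_ten_weak_seeds_on_axis(self):
        crack = initial_crack(NEEDLE_SYM, DOM)
        assert crack.n_segments == 10
        assert crack.weak.all()
        assert np.allclose(crack.path[:, 0], 0.0)
        # entry at the notch bottom, one tip-element spacing per segment
        assert crack.path[0][1] == pytest.approx(
            -DOM.notch_depth_factor * NEEDLE_SYM.rho_tip)
        seg = np.diff(crack.path[:, 1])
        assert np.allclose(seg, -DOM.h_tip)

    def test_pbn_has_one_seed_on_bevel_bisector(self):
        crack = initial_crack(NEEDLE_PBN, DOM)
        assert crack.n_segments == 1
        d = crack.path[1] - crack.path[0]
        bis = NEEDLE_PBN.bevel_bisector
        assert np.allclose(d / np.hypot(*d), bis, atol=1e-12)
        assert d[0] > 0          # steers toward the withdrawn-segment side

    def test_extension_appends_tip_along_direction(self):
        crack = initial_crack(NEEDLE_SYM, DOM)
        tip0 = crack.tip.copy()
        ext = crack.extended(np.array([0.0, -1.0]), 0.25e-3)
        assert np.allclose(ext.tip, tip0 + [0.0, -0.25e-3])
        assert ext.n_segments == crack.n_segments + 1
        assert not ext.weak[-1]

    def test_self_intersecting_extension_rejected(self):
        crack = initial_crack(NEEDLE_SYM, DOM)
        with pytest.raises(GeometryError, match="self-intersect"):
            crack.extended(np.array([0.0, 1.0]), 20e-3)   # fold back upward


class TestTipElementSize:
    def test_h_tip_is_half_tip_radius_by_default(self):
        d = DomainSpec.for_needle(NEEDLE_SYM)
        assert d.h_tip == pytest.approx(0.25e-3)


class TestBuildSymmetric:
    def test_mesh_is_conforming_and_positively_oriented(self, sym_build):
        _, sub = sym_build
        assert sub.mesh.is_conforming()
        assert (sub.mesh.areas() > 0).all()

    def test_quality_bound(self, sym_build):
        _, sub = sym_build
        assert math.degrees(sub.mesh.min_angle()) >= 20.0

    def test_all_regions_present(self, sym_build):
        _, sub = sym_build
        regions = set(sub.mesh.region.tolist())
        assert {REGION_OUTER, REGION_INNER, REGION_RING} <= regions

    def test_ring_triangles_surround_tip(self, sym_build):
        _, sub = sym_build
        tip = sub.crack.tip
        cent = sub.mesh.nodes[sub.mesh.tris[sub.mesh.region == REGION_RING]] \
            .mean(axis=1)
        r = np.hypot(cent[:, 0] - tip[0], cent[:, 1] - tip[1])
        assert (r <= DOM.ring_radius + 1e-12).all()
        assert len(r) >= 8

    def test_crack_nodes_duplicated_with_coincident_pairs(self, sym_build):
        _, sub = sym_build
        crack = sub.crack
        nodes = sub.mesh.nodes
        pairs = crack.face_pairs
        assert len(pairs) == crack.n_segments
        assert np.allclose(nodes[pairs[:, 0]], nodes[pairs[:, 1]])
        # the tip itself is a single node
        assert crack.minus_ids[-1] == crack.plus_ids[-1]

    def test_forward_spoke_and_last_segment_collinear_with_direction(
            self, sym_build):
        _, sub = sym_build
        nodes, crack = sub.mesh.nodes, sub.crack
        tip_id = int(crack.minus_ids[-1])
        d = crack.tip_dir
        # edge tip -> forward ring node
        fwd = crack.tip + DOM.ring_radius * d
        j = int(np.argmin(np.hypot(*(nodes - fwd).T)))
        assert sub.mesh.has_edge(tip_id, j)
        e = nodes[j] - crack.tip
        sin = abs(e[0] * d[1] - e[1] * d[0]) / np.hypot(*e)
        assert sin < 1e-12
        # last crack segment
        e2 = crack.path[-1] - crack.path[-2]
        sin2 = abs(e2[0] * d[1] - e2[1] * d[0]) / np.hypot(*e2)
        assert sin2 < 1e-12

    def test_cavity_chain_runs_plus_face_then_minus_face(self, sym_build):
        _, sub = sym_build
        nodes = sub.mesh.nodes
        chain = nodes[sub.cavity_chain]
        # starts and ends at the notch top corners
        notch, _ = notch_chain(NEEDLE_SYM, DOM)
        assert np.allclose(chain[0], notch[-1], atol=1e-12)
        assert np.allclose(chain[-1], notch[0], atol=1e-12)
        # passes through the tip exactly once
        tip_hits = np.where(np.all(np.isclose(chain, sub.crack.tip), axis=1))[0]
        assert len(tip_hits) == 1


class TestBuildPBN:
    def test_single_seed_and_conformity(self, pbn_build):
        _, sub = pbn_build
        assert sub.crack.n_segments == 1
        assert sub.mesh.is_conforming()
        assert math.degrees(sub.mesh.min_angle()) >= 20.0


class TestRemesh:
    def test_crack_path_preserved_bitwise(self, sym_build):
        mesher, sub = sym_build
        ext = sub.crack.extended(np.array([0.15, -1.0]), DOM.h_tip)
        sub2 = mesher.build(ext)
        tree = cKDTree(sub2.mesh.nodes)
        d, _ = tree.query(sub.crack.path)
        assert np.all(d == 0.0)

    def test_outer_region_nodes_and_numbering_unchanged(self, sym_build):
        mesher, sub = sym_build
        out_pts, out_tris, _ = mesher.outer_region()
        ext = sub.crack.extended(np.array([0.0, -1.0]), DOM.h_tip)
        sub2 = mesher.build(ext)
        n = len(out_pts)
        assert np.array_equal(sub.mesh.nodes[:n], out_pts)
        assert np.array_equal(sub2.mesh.nodes[:n], out_pts)
        assert np.array_equal(sub.mesh.tris[:len(out_tris)],
                              sub2.mesh.tris[:len(out_tris)])

    def test_ring_reoriented_with_kink(self, sym_build):
        mesher, sub = sym_build
        theta = math.radians(12.0)
        d = np.array([math.sin(theta), -math.cos(theta)])
        ext = sub.crack.extended(d, DOM.h_tip)
        sub2 = mesher.build(ext)
        nodes, crack2 = sub2.mesh.nodes, sub2.crack
        fwd = crack2.tip + DOM.ring_radius * d
        j = int(np.argmin(np.hypot(*(nodes - fwd).T)))
        e = nodes[j] - crack2.tip
        sin = abs(e[0] * d[1] - e[1] * d[0]) / np.hypot(*e)
        assert sin < 1e-12

    def test_cohesive_count_grows_by_one_per_extension(self, sym_build):
        mesher, sub = sym_build
        ext = sub.crack.extended(sub.crack.tip_dir, DOM.h_tip)
        sub2 = mesher.build(ext)
        assert len(sub2.crack.cohesive_connectivity()) \
            == len(sub.crack.cohesive_connectivity()) + 1
        # crack polyline length grows by exactly h
        assert sub2.crack.length == pytest.approx(
            sub.crack.length + DOM.h_tip, rel=1e-12)


class TestRingPoints:
    def test_fore_node_exactly_ahead(self):
        tip = np.array([1e-3, -5e-3])
        d = np.array([0.3, -0.95])
        d = d / np.hypot(*d)
        ring = ring_points(tip, d, 1e-3, 16)
        assert len(ring) == 16
        assert np.allclose(ring[0], tip + 1e-3 * d, atol=1e-15)
        r = np.hypot(*(ring - tip).T)
        assert np.allclose(r, 1e-3)


class TestNotch:
    def test_symmetric_notch_congruent_with_blunted_tip(self):
        notch, entry = notch_chain(NEEDLE_SYM, DOM)
        depth = DOM.notch_depth_factor * NEEDLE_SYM.rho_tip
        # cap bottom on the axis at the nominal depth
        assert np.allclose(notch[entry], [0.0, -depth])
        # top corners symmetric, wider than the sharp-V mouth because the
        # blunted tip profile is wider than the theoretical wedge
        assert notch[0][0] == pytest.approx(-notch[-1][0])
        assert notch[-1][0] > depth * math.tan(NEEDLE_SYM.alpha)
        # congruence: notch mouth equals the needle profile width at the
        # surface when the material tip bottom sits at the cap bottom
        tip_y = -depth - NEEDLE_SYM.tip_bottom_offset[1]
        outline = NEEDLE_SYM.outline(tip_y)
        from shapely.geometry import LineString, Polygon
        poly = Polygon(outline)
        width = poly.intersection(LineString([(-4e-3, 0), (4e-3, 0)])).length
        assert width == pytest.approx(2 * notch[-1][0], rel=1e-6)

    def test_pbn_notch_has_vertical_wall(self):
        notch, entry = notch_chain(NEEDLE_PBN, DOM)
        assert notch[-1][0] == pytest.approx(0.0, abs=1e-12)   # vertical wall
        assert notch[entry][1] == pytest.approx(
            -DOM.notch_depth_factor * NEEDLE_PBN.rho_tip)

    def test_oversized_notch_rejected(self):
        tiny = NeedleSpec(b=2.2e-3, alpha=math.radians(40.0), c=0.0,
                          rho_tip=1.0e-3)
        with pytest.raises(GeometryError, match="notch"):
            notch_chain(tiny, DomainSpec(notch_depth_factor=3.0,
                                         h_tip=0.5e-3))


class TestNeedleMesh:
    @pytest.mark.parametrize("needle", [NEEDLE_SYM, NEEDLE_PBN],
                             ids=["symmetric", "pbn"])
    def test_quality_and_conformity(self, needle):
        mesh, boundary_ids = mesh_needle(needle, DOM, tip_y=-1e-3, seed=0)
        assert mesh.is_conforming()
        assert (mesh.areas() > 0).all()
        # the slender tip wedge tolerates slightly thinner triangles than
        # the substrate generator's 20-degree contract
        assert math.degrees(mesh.min_angle()) >= 15.0
        # boundary chain nodes all on the outline
        assert len(boundary_ids) > 20


    def test_material_bottom_vertex_exact(self):
        tip_y = -2e-3
        mesh, _ = mesh_needle(NEEDLE_SYM, DOM, tip_y=tip_y, seed=0)
        # the lowest node is the exact fillet bottom, offset from the
        # theoretical apex by the tangent-fillet truncation
        expect = tip_y + NEEDLE_SYM.tip_bottom_offset[1]
        assert mesh.nodes[:, 1].min() == pytest.approx(expect, abs=1e-12)
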