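"""Triangle-mesh container, conformity/quality checks and exports.

The substrate and needle discretisations share one `TriMesh` container:
node coordinates, positively oriented connectivity and a per-triangle
region tag (outer substrate, refined inner substrate, crack-tip ring,
needle).  Crack faces are represented by duplicated node pairs, so the
crack line appears as two coincident boundary edge chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

REGION_OUTER = 0
REGION_INNER = 1
REGION_RING = 2
REGION_NEEDLE = 3

REGION_NAMES = {REGION_OUTER: "outer", REGION_INNER: "inner",
                REGION_RING: "ring", REGION_NEEDLE: "needle"}


@dataclass
class TriMesh:
    nodes: np.ndarray                 # (N, 2) float
    tris: np.ndarray                  # (M, 3) int, CCW
    region: np.ndarray                # (M,) int region codes

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.tris = np.asarray(self.tris, dtype=int)
        self.region = np.asarray(self.region, dtype=int)
        if self.tris.ndim != 2 or self.tris.shape[1] != 3:
            raise ValueError("tris must be (M, 3)")
        if self.region.shape != (len(self.tris),):
            raise ValueError("region must be (M,)")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_tris(self) -> int:
        return len(self.tris)

    def areas(self) -> np.ndarray:
        X = self.nodes[self.tris]
        d1 = X[:, 1] - X[:, 0]
        d2 = X[:, 2] - X[:, 0]
        return 0.5 * (d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])

    def orient_ccw(self) -> None:
        """Flip negatively oriented triangles in place."""
        a = self.areas()
        flip = a < 0
        self.tris[flip] = self.tris[flip][:, [0, 2, 1]]

    def min_angle(self) -> float:
        """Smallest interior angle over all triangles (rad)."""
        X = self.nodes[self.tris]
        angles = []
        for k in range(3):
            a = X[:, (k + 1) % 3] - X[:, k]
            b = X[:, (k + 2) % 3] - X[:, k]
            na = np.hypot(a[:, 0], a[:, 1])
            nb = np.hypot(b[:, 0], b[:, 1])
            cosv = np.clip((a * b).sum(axis=1) / (na * nb), -1.0, 1.0)
            angles.append(np.arccos(cosv))
        return float(np.min(angles))

    def edge_triangle_counts(self) -> dict[tuple[int, int], int]:
        out: dict[tuple[int, int], int] = {}
        for tri in self.tris:
            for k in range(3):
                e = (int(tri[k]), int(tri[(k + 1) % 3]))
                key = (min(e), max(e))
                out[key] = out.get(key, 0) + 1
        return out

    def is_conforming(self) -> bool:
        """Every edge shared by at most two triangles and no duplicated
        triangles (duplicated crack-face edges each appear once per side
        because the node indices differ, so they do not violate this)."""
        counts = self.edge_triangle_counts()
        if any(c > 2 for c in counts.values()):
            return False
        seen = {tuple(sorted(t)) for t in map(tuple, self.tris)}
        return len(seen) == len(self.tris)

    def boundary_edges(self) -> np.ndarray:
        """(K, 2) directed boundary edges (appearing in exactly one
        triangle), oriented as stored in the triangle (domain on the left)."""
        counts = self.edge_triangle_counts()
        out = []
        for tri in self.tris:
            for k in range(3):
                e = (int(tri[k]), int(tri[(k + 1) % 3]))
                if counts[(min(e), max(e))] == 1:
                    out.append(e)
        return np.array(out, dtype=int).reshape(-1, 2)

    def has_edge(self, a: int, b: int) -> bool:
        key = (min(a, b), max(a, b))
        return key in self.edge_triangle_counts()

    def copy(self) -> "TriMesh":
        return TriMesh(self.nodes.copy(), self.tris.copy(), self.region.copy())


def structured_rectangle(x0: float, y0: float, x1: float, y1: float,
                         nx: int, ny: int,
                         region: int = REGION_INNER) -> TriMesh:
    """Right-triangle mesh of an axis-aligned rectangle (crossed
    diagonals alternating for symmetry about the midlines)."""
    xs = np.linspace(x0, x1, nx + 1)
    ys = np.linspace(y0, y1, ny + 1)
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    nodes = np.column_stack([xx.ravel(), yy.ravel()])

    def nid(i, j):
        return i * (ny + 1) + j

    tris = []
    for i in range(nx):
        for j in range(ny):
            n00, n10 = nid(i, j), nid(i + 1, j)
            n01, n11 = nid(i, j + 1), nid(i + 1, j + 1)
            if (i + j) % 2 == 0:
                tris.append([n00, n10, n11])
                tris.append([n00, n11, n01])
            else:
                tris.append([n00, n10, n01])
                tris.append([n10, n11, n01])
    tris = np.array(tris, dtype=int)
    mesh = TriMesh(nodes, tris, np.full(len(tris), region, dtype=int))
    mesh.orient_ccw()
    return mesh


def merge_meshes(a: TriMesh, b: TriMesh) -> tuple[TriMesh, int]:
    """Concatenate two meshes without node identification; returns the
    merged mesh and the node-index offset applied to `b`."""
    offset = a.n_nodes
    nodes = np.vstack([a.nodes, b.nodes])
    tris = np.vstack([a.tris, b.tris + offset])
    region = np.concatenate([a.region, b.region])
    return TriMesh(nodes, tris, region), offset
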