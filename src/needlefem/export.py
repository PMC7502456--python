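"""Run outputs: VTK legacy-ASCII snapshots, CSV histories, JSON summary.

Meshes and field snapshots are written as VTK unstructured grids
(triangles plus the cohesive interfaces as line cells) readable by
standard viewers; histories and crack paths go to plain CSV; every run
directory carries a JSON summary and a copy of its configuration.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .units import to_mm


def write_vtk(path, nodes: np.ndarray, tris: np.ndarray,
              lines: np.ndarray | None = None,
              point_data: dict | None = None,
              cell_data: dict | None = None,
              line_data: dict | None = None) -> None:
    """Legacy-ASCII VTK unstructured grid.

    `cell_data` arrays align with `tris`, `line_data` with `lines`; both
    are concatenated in that order in the output (VTK requires one cell-
    data block).
    """
    nodes = np.asarray(nodes, dtype=float)
    tris = np.asarray(tris, dtype=int)
    lines = np.zeros((0, 2), dtype=int) if lines is None \
        else np.asarray(lines, dtype=int)
    n_cells = len(tris) + len(lines)
    out = ["# vtk DataFile Version 3.0", "needlefem snapshot", "ASCII",
           "DATASET UNSTRUCTURED_GRID",
           f"POINTS {len(nodes)} double"]
    out += [f"{x:.17g} {y:.17g} 0" for x, y in nodes]
    out.append(f"CELLS {n_cells} {4 * len(tris) + 3 * len(lines)}")
    out += [f"3 {a} {b} {c}" for a, b, c in tris]
    out += [f"2 {a} {b}" for a, b in lines]
    out.append(f"CELL_TYPES {n_cells}")
    out += ["5"] * len(tris) + ["3"] * len(lines)
    if point_data:
        out.append(f"POINT_DATA {len(nodes)}")
        for name, arr in point_data.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim == 2:
                out.append(f"VECTORS {name} double")
                out += [f"{v[0]:.17g} {v[1]:.17g} 0" for v in arr]
            else:
                out += [f"SCALARS {name} double 1", "LOOKUP_TABLE default"]
                out += [f"{v:.17g}" for v in arr]
    if cell_data or line_data:
        out.append(f"CELL_DATA {n_cells}")
        names = set()
        if cell_data:
            names |= set(cell_data)
        if line_data:
            names |= set(line_data)
        for name in sorted(names):
            tri_arr = np.asarray(cell_data.get(name, np.zeros(len(tris)))
                                 if cell_data else np.zeros(len(tris)),
                                 dtype=float)
            lin_arr = np.asarray(line_data.get(name, np.zeros(len(lines)))
                                 if line_data else np.zeros(len(lines)),
                                 dtype=float)
            full = np.concatenate([tri_arr, lin_arr])
            out += [f"SCALARS {name} double 1", "LOOKUP_TABLE default"]
            out += [f"{v:.17g}" for v in full]
    Path(path).write_text("\n".join(out) + "\n")


def read_vtk_points(path) -> np.ndarray:
    """Minimal reader for round-trip checks: returns the (N, 2) points."""
    lines = Path(path).read_text().splitlines()
    for i, ln in enumerate(lines):
        if ln.startswith("POINTS"):
            n = int(ln.split()[1])
            pts = [list(map(float, lines[i + 1 + k].split()[:2]))
                   for k in range(n)]
            return np.array(pts)
    raise ValueError(f"{path}: no POINTS block")


def write_crack_path_csv(path, crack_path: np.ndarray) -> None:
    """Crack path from entry to tip as (x_mm, y_mm)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["x_mm", "y_mm"])
        for x, y in np.asarray(crack_path, dtype=float):
            w.writerow([f"{to_mm(x):.9f}", f"{to_mm(y):.9f}"])


def read_crack_path_csv(path) -> np.ndarray:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))[1:]
    return np.array([[float(a) * 1e-3, float(b) * 1e-3] for a, b in rows])


HISTORY_COLUMNS = ["D_e_mm", "F_N_per_m", "U_S", "U_f", "U_G", "crack_len_mm"]


def write_history_csv(path, history) -> None:
    """Final-iteration increment records."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(HISTORY_COLUMNS)
        for r in history.increments:
            w.writerow([f"{to_mm(r.D_e):.9f}", f"{r.force:.9g}",
                        f"{r.U_S:.9g}", f"{r.U_f:.9g}", f"{r.U_G:.9g}",
                        f"{to_mm(r.crack_length):.9f}"])


@dataclass
class RunSummary:
    """Headline record of one insertion run, JSON-serialisable."""

    preset: str
    config_hash: str
    version: str
    seed: int
    iterations: int
    final_depth_mm: float
    crack_length_mm: float
    max_force_N_per_m: float
    energy: dict = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def summarise(history, preset: str = "", config_path: str | None = None):
    """Build a RunSummary from an InsertionHistory."""
    import hashlib

    from . import __version__
    from .driver import energy_balance
    W, US, Uf, UG, rel = energy_balance(history)
    cfg_hash = ""
    if config_path is not None:
        cfg_hash = hashlib.sha256(
            Path(config_path).read_bytes()).hexdigest()[:16]
    force = history.force
    return RunSummary(
        preset=preset, config_hash=cfg_hash, version=__version__,
        seed=history.config.seed, iterations=len(history.iterations),
        final_depth_mm=to_mm(history.D_e[-1]) if len(force) else 0.0,
        crack_length_mm=to_mm(float(np.hypot(
            *np.diff(history.crack_path, axis=0).T).sum())),
        max_force_N_per_m=float(force.max()) if len(force) else 0.0,
        energy=dict(W_ext=W, U_S=US, U_f=Uf, U_G=UG, residual_rel=rel))


def export_state(prefix, mesh, u: np.ndarray, crack, sed=None,
                 cohesive_damage=None) -> list[str]:
    """Write the VTK snapshot and crack-path CSV for one converged state.

    Returns the list of files written.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    u2 = np.asarray(u, dtype=float).reshape(-1, 2)[:mesh.n_nodes]
    lines = crack.cohesive_connectivity()[:, [0, 1]] if crack is not None \
        else None
    point_data = {"displacement": u2}
    cell_data = {"region": mesh.region.astype(float)}
    if sed is not None:
        cell_data["strain_energy_density"] = np.asarray(sed)[:mesh.n_tris]
    line_data = None
    if cohesive_damage is not None and lines is not None:
        line_data = {"cohesive_damage": np.asarray(cohesive_damage,
                                                   dtype=float)}
        cell_data.setdefault("cohesive_damage",
                             np.zeros(mesh.n_tris))
    files = []
    vtk = prefix.with_suffix(".vtk")
    write_vtk(vtk, mesh.nodes, mesh.tris, lines=lines,
              point_data=point_data, cell_data=cell_data,
              line_data=line_data)
    files.append(str(vtk))
    if crack is not None:
        csv_path = prefix.parent / (prefix.name + "_crack_path.csv")
        write_crack_path_csv(csv_path, crack.path)
        files.append(str(csv_path))
    return files
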