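"""File formats: legacy ASCII VTK unstructured grids, Matrix Market, CSV, JSON.

The VTK legacy format is a simple line-oriented text format; reading and
writing are implemented here directly (tetrahedral cells only, with
region labels as cell data and intensity fields as point data).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import scipy.io
import scipy.sparse as sp

from .forward_model import SystemMatrix
from .phantom_mesh import TetMesh

__all__ = [
    "write_vtk",
    "read_vtk",
    "write_system_matrix",
    "read_system_matrix",
    "write_measurements",
    "read_measurements",
    "write_truth",
    "read_truth",
]

_VTK_TET = 10


def write_vtk(
    path: str | Path,
    mesh: TetMesh,
    point_data: dict[str, np.ndarray] | None = None,
) -> None:
    """Write a mesh (plus optional per-node scalar fields) as legacy ASCII VTK.

    Region labels are stored as an integer cell field ``region_id`` with
    the name table in the header comment line.
    """
    names = sorted(set(map(str, mesh.region_label)))
    name_to_id = {n: i for i, n in enumerate(names)}
    region_ids = np.array([name_to_id[str(r)] for r in mesh.region_label])

    lines = ["# vtk DataFile Version 3.0"]
    lines.append("peddrs mesh; regions=" + ",".join(names) + f"; spacing={mesh.spacing!r}")
    lines.append("ASCII")
    lines.append("DATASET UNSTRUCTURED_GRID")
    lines.append(f"POINTS {mesh.n_nodes} double")
    lines.extend(" ".join(repr(float(v)) for v in row) for row in mesh.nodes)
    lines.append(f"CELLS {mesh.n_tets} {mesh.n_tets * 5}")
    lines.extend("4 " + " ".join(map(str, t)) for t in mesh.tets)
    lines.append(f"CELL_TYPES {mesh.n_tets}")
    lines.extend([str(_VTK_TET)] * mesh.n_tets)
    lines.append(f"CELL_DATA {mesh.n_tets}")
    lines.append("SCALARS region_id int 1")
    lines.append("LOOKUP_TABLE default")
    lines.extend(map(str, region_ids))
    if point_data:
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        for name, values in point_data.items():
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(repr(float(v)) for v in np.asarray(values))
    Path(path).write_text("\n".join(lines) + "\n")


def read_vtk(path: str | Path) -> tuple[TetMesh, dict[str, np.ndarray]]:
    """Read a legacy ASCII VTK unstructured grid written by :func:`write_vtk`."""
    tokens_lines = Path(path).read_text().splitlines()
    header = tokens_lines[1]
    names: list[str] = []
    spacing = 1.0
    for part in header.split(";"):
        part = part.strip()
        if part.startswith("regions="):
            names = part[len("regions=") :].split(",")
        elif part.startswith("spacing="):
            spacing = float(part[len("spacing=") :])

    nodes = tets = region_ids = None
    point_data: dict[str, np.ndarray] = {}

    def tokens_after(count: int, lines_iter) -> list[str]:
        out: list[str] = []
        while len(out) < count:
            out.extend(next(lines_iter).split())
        return out

    lines_iter = iter(tokens_lines)
    for line in lines_iter:
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "POINTS":
            n = int(parts[1])
            vals = tokens_after(3 * n, lines_iter)
            nodes = np.array(vals, dtype=float).reshape(n, 3)
        elif parts[0] == "CELLS":
            m = int(parts[1])
            vals = tokens_after(int(parts[2]), lines_iter)
            arr = np.array(vals, dtype=np.int64)
            tets = arr.reshape(m, 5)[:, 1:]
        elif parts[0] == "CELL_TYPES":
            tokens_after(int(parts[1]), lines_iter)
        elif parts[0] == "SCALARS":
            name = parts[1]
            next(lines_iter)  # LOOKUP_TABLE
            # counts: region_id over cells, other scalars over points
            if name == "region_id":
                vals = tokens_after(len(tets), lines_iter)
                region_ids = np.array(vals, dtype=np.int64)
            else:
                vals = tokens_after(len(nodes), lines_iter)
                point_data[name] = np.array(vals, dtype=float)

    if nodes is None or tets is None:
        raise ValueError(f"{path} is not a VTK unstructured grid")
    if region_ids is None:
        region_ids = np.zeros(len(tets), dtype=np.int64)
        names = names or ["Muscle"]
    labels = np.array([names[i] for i in region_ids], dtype=object)

    from .phantom_mesh import _face_census

    uniq, counts = _face_census(tets)
    mesh = TetMesh(
        nodes=nodes,
        tets=tets,
        boundary_faces=uniq[counts == 1],
        region_label=labels,
        spacing=spacing,
    )
    return mesh, point_data


def write_system_matrix(path: str | Path, system: SystemMatrix) -> None:
    """Matrix Market export of A plus a sidecar JSON with row/col node indices."""
    scipy.io.mmwrite(str(path), sp.coo_matrix(system.A))
    Path(str(path) + ".json").write_text(
        json.dumps(
            {
                "row_nodes": system.row_nodes.tolist(),
                "col_nodes": system.col_nodes.tolist(),
            }
        )
    )


def read_system_matrix(path: str | Path) -> SystemMatrix:
    A = scipy.io.mmread(str(path))
    if sp.issparse(A):
        A = A.toarray()
    meta = json.loads(Path(str(path) + ".json").read_text())
    return SystemMatrix(
        A=np.asarray(A, dtype=float),
        row_nodes=np.array(meta["row_nodes"], dtype=np.int64),
        col_nodes=np.array(meta["col_nodes"], dtype=np.int64),
    )


def write_measurements(path: str | Path, B: np.ndarray, row_nodes: np.ndarray) -> None:
    """Boundary flux as a two-column CSV (node index, flux)."""
    with open(path, "w") as fh:
        fh.write("node,flux\n")
        for i, b in zip(row_nodes, B):
            fh.write(f"{int(i)},{float(b)!r}\n")


def read_measurements(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    data = np.genfromtxt(path, delimiter=",", names=True, dtype=None, encoding="utf-8")
    return np.atleast_1d(data["flux"]).astype(float), np.atleast_1d(data["node"]).astype(
        np.int64
    )


def write_truth(path: str | Path, truth: dict) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(truth, indent=2, default=_default))


def read_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
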