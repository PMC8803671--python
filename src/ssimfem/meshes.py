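"""Mesh containers and text-based mesh I/O.

Surface meshes are plain :class:`trimesh.Trimesh` objects (PLY/STL via
trimesh).  Tetrahedral meshes use the small :class:`TetMesh` container below
with a hand-rolled legacy ASCII VTK reader/writer (unstructured grid, cell
type 10), including optional per-element scalar fields as CELL_DATA.
Node and element indexing is 0-based internally regardless of file dialect;
coordinates are millimetres unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional

import numpy as np

__all__ = ["TetMesh", "write_vtk", "read_vtk"]


@dataclass
class TetMesh:
    """Tetrahedral volume mesh: ``points`` (m, 3) and ``cells`` (e, 4)."""

    points: np.ndarray
    cells: np.ndarray

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.cells = np.asarray(self.cells, dtype=np.int64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be (m, 3)")
        if self.cells.ndim != 2 or self.cells.shape[1] != 4:
            raise ValueError("cells must be (e, 4)")
        if self.cells.size and self.cells.max() >= len(self.points):
            raise ValueError("cell index out of range")

    @property
    def n_elements(self) -> int:
        return len(self.cells)

    def signed_volumes(self) -> np.ndarray:
        p = self.points
        a, b, c, d = (p[self.cells[:, k]] for k in range(4))
        return np.einsum("ij,ij->i", np.cross(b - a, c - a), d - a) / 6.0

    def volumes(self) -> np.ndarray:
        return np.abs(self.signed_volumes())

    def centroids(self) -> np.ndarray:
        return self.points[self.cells].mean(axis=1)

    def with_points(self, new_points: np.ndarray) -> "TetMesh":
        """Same connectivity on new node positions (iso-topological copy)."""
        return TetMesh(np.asarray(new_points, dtype=float), self.cells)

    def orient_positive(self) -> "TetMesh":
        """Swap node order of inverted elements so all volumes are > 0."""
        sv = self.signed_volumes()
        cells = self.cells.copy()
        neg = sv < 0
        cells[neg, 2], cells[neg, 3] = self.cells[neg, 3], self.cells[neg, 2]
        return TetMesh(self.points, cells)

    def boundary_faces(self) -> np.ndarray:
        """Triangular faces that belong to exactly one element."""
        faces = self.cells[:, [[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]]]
        faces = faces.reshape(-1, 3)
        key = np.sort(faces, axis=1)
        _, idx, counts = np.unique(key, axis=0, return_index=True,
                                   return_counts=True)
        return faces[idx[counts == 1]]


def write_vtk(path, mesh: TetMesh,
              cell_data: Optional[Dict[str, np.ndarray]] = None,
              title: str = "ssimfem tetrahedral mesh") -> None:
    """Write a legacy ASCII VTK unstructured grid with optional element
    scalar fields."""
    pts = mesh.points
    cells = mesh.cells
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {len(pts)} double",
    ]
    lines += [f"{x:.17g} {y:.17g} {z:.17g}" for x, y, z in pts]
    lines.append(f"CELLS {len(cells)} {5 * len(cells)}")
    lines += ["4 " + " ".join(str(int(i)) for i in row) for row in cells]
    lines.append(f"CELL_TYPES {len(cells)}")
    lines += ["10"] * len(cells)
    if cell_data:
        lines.append(f"CELL_DATA {len(cells)}")
        for name, values in cell_data.items():
            values = np.asarray(values, dtype=float).ravel()
            if values.size != len(cells):
                raise ValueError(f"cell field '{name}' has {values.size} "
                                 f"values for {len(cells)} elements")
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines += [f"{v:.17g}" for v in values]
    Path(path).write_text("\n".join(lines) + "\n")


def read_vtk(path):
    """Read a legacy ASCII VTK unstructured grid written by :func:`write_vtk`.

    Returns ``(TetMesh, cell_data_dict)``.
    """
    tokens = Path(path).read_text().split("\n")
    it = iter(range(len(tokens)))
    pts = None
    cells = None
    cell_data: Dict[str, np.ndarray] = {}
    i = 0
    while i < len(tokens):
        line = tokens[i].strip()
        if line.startswith("POINTS"):
            n = int(line.split()[1])
            pts = np.loadtxt(tokens[i + 1:i + 1 + n])
            i += n
        elif line.startswith("CELLS"):
            n = int(line.split()[1])
            raw = np.loadtxt(tokens[i + 1:i + 1 + n], dtype=np.int64,
                             ndmin=2)
            if not np.all(raw[:, 0] == 4):
                raise ValueError("only tetrahedral cells supported")
            cells = raw[:, 1:]
            i += n
        elif line.startswith("SCALARS"):
            name = line.split()[1]
            n = len(cells)
            vals = np.loadtxt(tokens[i + 2:i + 2 + n])
            cell_data[name] = np.atleast_1d(vals)
            i += n + 1
        i += 1
    if pts is None or cells is None:
        raise ValueError(f"{path}: not a supported VTK unstructured grid")
    return TetMesh(np.atleast_2d(pts), cells), cell_data
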