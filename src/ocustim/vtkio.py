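"""Minimal writers for standard exchange formats.

Field solutions are exported as legacy-ASCII VTK unstructured grids (cell
scalars/vectors on tetrahedra) readable by ParaView/VTK-based tools, and as
CSV tables of per-element field magnitudes.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .phantom import TissuePhantom
from .solver import FieldSolution

__all__ = ["write_vtk", "write_field_vtk", "write_field_csv"]

_VTK_TETRA = 10


def write_vtk(path, nodes: np.ndarray, tets: np.ndarray,
              cell_data: dict | None = None,
              point_data: dict | None = None,
              title: str = "ocustim unstructured grid") -> None:
    """Write a tetrahedral mesh with optional cell/point data (legacy VTK)."""
    nodes = np.asarray(nodes, dtype=float)
    tets = np.asarray(tets, dtype=int)
    lines = ["# vtk DataFile Version 3.0", title, "ASCII",
             "DATASET UNSTRUCTURED_GRID",
             f"POINTS {len(nodes)} double"]
    lines += [" ".join(f"{x:.9g}" for x in p) for p in nodes]
    lines.append(f"CELLS {len(tets)} {len(tets) * 5}")
    lines += ["4 " + " ".join(str(i) for i in t) for t in tets]
    lines.append(f"CELL_TYPES {len(tets)}")
    lines += [str(_VTK_TETRA)] * len(tets)

    def _emit(block: dict, kind: str, count: int):
        out = [f"{kind} {count}"]
        for name, arr in block.items():
            arr = np.asarray(arr)
            if arr.ndim == 1:
                out.append(f"SCALARS {name} double 1")
                out.append("LOOKUP_TABLE default")
                out += [f"{v:.9g}" for v in arr]
            else:
                out.append(f"VECTORS {name} double")
                out += [" ".join(f"{x:.9g}" for x in v) for v in arr]
        return out

    if cell_data:
        lines += _emit(cell_data, "CELL_DATA", len(tets))
    if point_data:
        lines += _emit(point_data, "POINT_DATA", len(nodes))
    Path(path).write_text("\n".join(lines) + "\n")


def write_field_vtk(path, phantom: TissuePhantom,
                    solution: FieldSolution) -> None:
    """Export a field solution: |E| as a cell scalar, E as a cell vector,
    tissue code as a cell scalar and V as point data."""
    codes, inv = np.unique(phantom.tet_labels, return_inverse=True)
    write_vtk(path, phantom.nodes, phantom.tets,
              cell_data={"E_magnitude": solution.element_field_magnitude,
                         "tissue_code": inv.astype(float),
                         "E": solution.element_field},
              point_data={"V": solution.potential})


def write_field_csv(path, solution: FieldSolution) -> None:
    """CSV of (element id, |E| in V/m)."""
    pd.DataFrame({
        "element": np.arange(solution.n_elements),
        "E_magnitude": solution.element_field_magnitude,
    }).to_csv(path, index=False)
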