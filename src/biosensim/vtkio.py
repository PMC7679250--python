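"""Minimal legacy-VTK (ASCII structured grid) writer for field snapshots."""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["write_structured_vtk"]


def write_structured_vtk(path, mesh, point_data: dict[str, np.ndarray]) -> None:
    """Write nodal scalar fields on the structured mesh.

    Point order follows the mesh numbering (x fastest), which matches
    the VTK structured-grid convention for DIMENSIONS (Nx, Ny, 1).
    """
    nx, ny = mesh.shape
    n = mesh.n_nodes
    lines = [
        "# vtk DataFile Version 3.0",
        "biosensim fields",
        "ASCII",
        "DATASET STRUCTURED_GRID",
        f"DIMENSIONS {nx} {ny} 1",
        f"POINTS {n} double",
    ]
    for k in range(n):
        lines.append(f"{mesh.node_x[k]:.12e} {mesh.node_y[k]:.12e} 0.0")
    if point_data:
        lines.append(f"POINT_DATA {n}")
        for name, values in point_data.items():
            values = np.asarray(values)
            if values.shape != (n,):
                raise ValueError(f"field {name!r} has shape {values.shape}, expected ({n},)")
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{v:.12e}" for v in values)
    Path(path).write_text("\n".join(lines) + "\n")
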