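"""Minimal legacy-ASCII VTK writers for structured (uniform-grid) fields.

Writes VTK STRUCTURED_POINTS datasets, readable by ParaView/VisIt.
Cell-centred (nx, ny) arrays are emitted as point data on the grid of
cell centres, which is what every downstream viewer expects for a
uniform Cartesian simulation.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from clotsim2d.geometry import Grid2D

__all__ = ["write_structured_points"]


def write_structured_points(
    path: str | Path,
    grid: Grid2D,
    fields: dict[str, np.ndarray],
    title: str = "clotsim2d fields",
) -> Path:
    """Write cell-centred scalar fields to a legacy VTK file."""
    path = Path(path)
    nx, ny, h = grid.nx, grid.ny, grid.h
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} 1",
        f"ORIGIN {h / 2:.6g} {h / 2:.6g} 0",
        f"SPACING {h:.6g} {h:.6g} 1",
        f"POINT_DATA {nx * ny}",
    ]
    for name, arr in fields.items():
        if arr.shape != (nx, ny):
            raise ValueError(f"field {name!r} has shape {arr.shape}, expected {(nx, ny)}")
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        # VTK expects x fastest: iterate j (y) outer, i (x) inner
        flat = arr.T.ravel()
        lines.extend(" ".join(f"{v:.8g}" for v in flat[k : k + 9]) for k in range(0, flat.size, 9))
    path.write_text("\n".join(lines) + "\n")
    return path
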