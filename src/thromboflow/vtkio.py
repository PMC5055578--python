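"""Legacy-ASCII VTK structured-points writer/reader.

Cell data on the full rectangular grid (solid cells carry zeros).  The
writer prints floats with ``repr`` precision so a write/read round trip is
bit-exact, which is what the output tests demand; files are plain text and
open directly in ParaView.
"""

from __future__ import annotations

import numpy as np

__all__ = ["write_vtk", "read_vtk"]


def write_vtk(path, grid, fields: dict) -> None:
    """Write named cell fields of ``grid`` to a legacy VTK file."""
    ny, nx = grid.ny, grid.nx
    lines = [
        "# vtk DataFile Version 3.0",
        "thromboflow structured grid",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx + 1} {ny + 1} 1",
        "ORIGIN 0.0 0.0 0.0",
        f"SPACING {grid.dx!r} {grid.dy!r} 1.0",
        f"CELL_DATA {nx * ny}",
    ]
    for name, arr in fields.items():
        a = np.asarray(arr, dtype=float)
        if a.shape != (ny, nx):
            raise ValueError(f"field {name!r} has shape {a.shape}, "
                             f"expected {(ny, nx)}")
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(repr(float(v)) for v in a.ravel())
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vtk(path):
    """Read a file written by :func:`write_vtk`; returns (meta, fields)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    meta = {}
    fields = {}
    i = 0
    nx = ny = None
    while i < len(lines):
        tok = lines[i].split()
        if not tok:
            i += 1
            continue
        if tok[0] == "DIMENSIONS":
            nx, ny = int(tok[1]) - 1, int(tok[2]) - 1
            meta["dimensions"] = (nx, ny)
        elif tok[0] == "SPACING":
            meta["spacing"] = (float(tok[1]), float(tok[2]))
        elif tok[0] == "SCALARS":
            name = tok[1]
            i += 2  # skip LOOKUP_TABLE
            vals = np.array([float(x) for x in lines[i:i + nx * ny]])
            fields[name] = vals.reshape(ny, nx)
            i += nx * ny
            continue
        i += 1
    return meta, fields
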