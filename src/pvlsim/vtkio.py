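"""Legacy-ASCII VTK export of structured solver fields and domain masks.

The grids are uniform and rectilinear, so the STRUCTURED_POINTS dataset with
CELL_DATA arrays is sufficient; any VTK-reading tool (ParaView, VisIt,
pyvista) opens these files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


def write_structured_vtk(path, domain, cell_arrays: dict, title: str = "pvlsim") -> Path:
    """Write cell-centered arrays on a uniform structured grid (legacy ASCII).

    ``cell_arrays`` maps names to (nx, ny) float or bool arrays.
    """
    path = Path(path)
    nx, ny = domain.nx, domain.ny
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx + 1} {ny + 1} 2",
        f"ORIGIN {domain.x0:.9e} 0.0 0.0",
        f"SPACING {domain.dx:.9e} {domain.dy:.9e} {min(domain.dx, domain.dy):.9e}",
        f"CELL_DATA {nx * ny}",
    ]
    for name, arr in cell_arrays.items():
        a = np.asarray(arr, dtype=float)
        if a.shape != (nx, ny):
            raise ValueError(f"array {name!r} has shape {a.shape}, expected {(nx, ny)}")
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        # VTK cell order: x fastest
        lines.extend(" ".join(f"{v:.6e}" for v in a[:, j]) for j in range(ny))
    path.write_text("\n".join(lines) + "\n")
    return path


def export_domain(path, domain) -> Path:
    """Write the domain's region masks and boundary tags as cell arrays."""
    tag = np.zeros((domain.nx, domain.ny))
    tag[domain.lv_plenum] = 1
    tag[domain.lumen] = 2
    tag[domain.la_plenum] = 3
    return write_structured_vtk(
        path,
        domain,
        {"fluid": domain.fluid, "region": tag},
        title=f"pvlsim domain ({domain.mode})",
    )


def export_field(path, domain, field, extra: dict | None = None) -> Path:
    """Write velocity components, speed, pressure and turbulence fields."""
    uc = 0.5 * (field.u[:-1, :] + field.u[1:, :])
    vc = 0.5 * (field.v[:, :-1] + field.v[:, 1:])
    arrays = {
        "u": uc,
        "v": vc,
        "speed": np.sqrt(uc**2 + vc**2),
        "p": field.p,
        "k": field.k,
        "omega": field.omega,
    }
    if extra:
        arrays.update(extra)
    return write_structured_vtk(path, domain, arrays, title="pvlsim field")
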