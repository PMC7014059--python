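"""Field and table writers: legacy-VTK structured grids, PNG heatmaps,
fixed-format CSV.

The legacy ASCII VTK writer emits a ``STRUCTURED_POINTS`` dataset with
cell data (plasma fraction, fibrinogen mass fraction, pressure, per-cell
component masses) and the cell-averaged velocity vector, readable by
ParaView and pyvista.  CSV numbers are formatted with 6 significant
digits so identical runs produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import StructuredMesh
from .metrics import _cell_masses
from .properties import FluidProperties

CSV_FLOAT_FORMAT = "%.6g"


def write_series_csv(series: pd.DataFrame, path: str | Path) -> None:
    series.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)


def write_vtk(state, mesh: StructuredMesh, path: str | Path,
              props: FluidProperties | None = None) -> None:
    """One legacy-VTK snapshot: 4 scalar cell fields + 1 vector field."""
    props = props or FluidProperties()
    nx, ny = mesh.nx, mesh.ny
    h = mesh.cell_size * 1e-3
    fib, plas = _cell_masses(state, mesh, props)

    def scalars(name, arr):
        lines = [f"SCALARS {name} float 1", "LOOKUP_TABLE default"]
        lines += [" ".join(f"{v:.6g}" for v in arr[:, j]) for j in range(ny)]
        return lines

    uc = 0.5 * (state.u[:-1, :] + state.u[1:, :])
    vc = 0.5 * (state.v[:, :-1] + state.v[:, 1:])
    vec = ["VECTORS velocity float"]
    for j in range(ny):
        vec.append(" ".join(f"{uc[i, j]:.6g} {vc[i, j]:.6g} 0"
                            for i in range(nx)))

    lines = [
        "# vtk DataFile Version 3.0",
        f"implantflow snapshot t={state.time:.6g}s",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx + 1} {ny + 1} 1",
        "ORIGIN 0 0 0",
        f"SPACING {h:.6g} {h:.6g} {h:.6g}",
        f"CELL_DATA {nx * ny}",
    ]
    lines += scalars("alpha_plasma", state.alpha_p)
    lines += scalars("Y0_fibrinogen", state.Y0)
    lines += scalars("pressure", state.p)
    lines += scalars("fibrinogen_mass_mg", 1e6 * fib)
    lines += vec
    Path(path).write_text("\n".join(lines) + "\n")


def write_png(state, mesh: StructuredMesh, path: str | Path,
              field: str = "fibrinogen",
              props: FluidProperties | None = None) -> None:
    """Heatmap of the per-cell fibrinogen or plasma mass (mg)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    props = props or FluidProperties()
    fib, plas = _cell_masses(state, mesh, props)
    data = 1e6 * (fib if field == "fibrinogen" else plas)
    data = np.where(mesh.is_fluid, data, np.nan)
    fig, ax = plt.subplots(figsize=(3, 8))
    extent = (0, mesh.nx * mesh.cell_size, 0, mesh.ny * mesh.cell_size)
    im = ax.imshow(data.T, origin="lower", extent=extent, aspect="equal",
                   cmap="viridis")
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    ax.set_title(f"{field} mass, t = {state.time:.2f} s")
    fig.colorbar(im, ax=ax, label="mg per cell")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def export_fields(states, path: str | Path, format: str = "vtk",
                  mesh: StructuredMesh | None = None,
                  props: FluidProperties | None = None) -> list[Path]:
    """Write every snapshot in ``states`` as VTK and/or PNG files."""
    if not states:
        raise ValueError("no states to export")
    if mesh is None:
        raise ValueError("mesh is required")
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for k, state in enumerate(states):
        stem = f"snapshot_{k:03d}_t{state.time:.3f}s"
        if format in ("vtk", "both"):
            f = outdir / f"{stem}.vtk"
            write_vtk(state, mesh, f, props)
            written.append(f)
        if format in ("png", "both"):
            for fieldname in ("fibrinogen", "plasma"):
                f = outdir / f"{stem}_{fieldname}.png"
                write_png(state, mesh, f, fieldname, props)
                written.append(f)
    return written
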