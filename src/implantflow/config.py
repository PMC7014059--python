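"""Run configuration: a validated, YAML-round-trippable description of a
scenario (geometry, material constants, boundary conditions, solver
settings, outputs).

YAML is the one canonical on-disk dialect.  Omitted fields take the
physiological defaults; the contact angle has no default and must be
given explicitly (it is the study's control variable).  Unknown keys are
rejected by name.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .geometry import GeometryLayout, StructuredMesh, build_layout, rasterize
from .properties import FluidProperties
from .solver import BoundarySpec, SolverConfig

_SECTIONS = ("geometry", "properties", "boundary", "solver", "output")


@dataclass
class RunConfig:
    """Everything needed to reproduce one simulation run."""

    layout: GeometryLayout
    bc: BoundarySpec
    cell_size: float = 0.05            # mm
    props: FluidProperties = field(default_factory=FluidProperties)
    solver: SolverConfig = field(default_factory=SolverConfig)
    outdir: str = "runs"
    export_csv: bool = True
    export_vtk: bool = False
    export_png: bool = False

    def mesh(self) -> StructuredMesh:
        return rasterize(self.layout, self.cell_size)

    # -- serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        geo = dataclasses.asdict(self.layout)
        geo["thread_profile"] = self.layout.thread_profile.value
        geo["cell_size"] = self.cell_size
        props = {k: v for k, v in dataclasses.asdict(self.props).items()
                 if k != "viscosity_pieces"}
        bnd = dataclasses.asdict(self.bc)
        sol = dataclasses.asdict(self.solver)
        sol["snapshot_times"] = list(self.solver.snapshot_times)
        out = {"outdir": self.outdir, "export_csv": self.export_csv,
               "export_vtk": self.export_vtk, "export_png": self.export_png}
        return {"geometry": geo, "properties": props, "boundary": bnd,
                "solver": sol, "output": out}

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = data or {}
        unknown = set(data) - set(_SECTIONS)
        if unknown:
            raise ValueError(f"unknown config section(s): {sorted(unknown)}")

        def take(section: str, allowed: set[str]) -> dict:
            sub = dict(data.get(section) or {})
            bad = set(sub) - allowed
            if bad:
                raise ValueError(
                    f"unknown key(s) in [{section}]: {sorted(bad)}")
            return sub

        geo = take("geometry", {f.name for f in dataclasses.fields(GeometryLayout)}
                   | {"cell_size"})
        cell_size = float(geo.pop("cell_size", 0.05))
        layout = build_layout(**geo)

        prop_fields = {f.name for f in dataclasses.fields(FluidProperties)} - {
            "viscosity_pieces"}
        props = FluidProperties(**take("properties", prop_fields))

        bnd = take("boundary", {f.name for f in dataclasses.fields(BoundarySpec)})
        if "contact_angle" not in bnd:
            raise ValueError("boundary.contact_angle must be given explicitly")
        bc = BoundarySpec(**bnd)

        sol = take("solver", {f.name for f in dataclasses.fields(SolverConfig)})
        if "snapshot_times" in sol:
            sol["snapshot_times"] = tuple(sol["snapshot_times"])
        solver = SolverConfig(**sol)

        out = take("output", {"outdir", "export_csv", "export_vtk", "export_png"})
        return cls(layout=layout, bc=bc, cell_size=cell_size, props=props,
                   solver=solver, **out)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    An empty file yields the full default configuration *except* the
    contact angle, which must always be present.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is not None and not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    return RunConfig.from_dict(raw or {})
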