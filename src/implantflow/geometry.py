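"""Bone-implant channel geometry and structured-mesh rasterization.

The computational domain is a 2D vertical channel between an alveolar-bone
wall (left) and a threaded implant surface (right).  Whole blood enters at
the bottom edge and through the bone wall and leaves at the top.  The
implant threads are solid polygons carved out of the fluid rectangle; the
fluid region is split into an *interfacial zone* (between the implant body
and the vertical line joining the thread peaks) and an *outer zone* —
the interfacial zone is where osseointegration-relevant infiltration is
measured.

Coordinate convention: ``x`` in [0, domain_width] mm, implant on the right
wall; ``y`` in [0, domain_height] mm, bulk flow upward; origin bottom-left;
cell-centred 0-based indices, ``[i, j]`` = (x, y).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
from shapely.geometry import Polygon
from shapely import contains_xy
from shapely.ops import unary_union


class ThreadProfile(str, enum.Enum):
    TRIANGULAR = "triangular"
    RECTANGULAR = "rectangular"
    TRAPEZOIDAL = "trapezoidal"


class BoundaryTag(enum.IntEnum):
    NONE = 0
    BLOOD_INLET = 1      # bottom edge (velocity inlet)
    ALVEOLAR_BONE = 2    # left edge (velocity inlet)
    IMPLANT_SURFACE = 3  # right edge + thread faces (no-slip wall, wetting)
    BLOOD_OUTLET = 4     # top edge (pressure outlet)


class Zone(enum.IntEnum):
    SOLID = -1
    OUTER = 0
    INTERFACIAL = 1


@dataclass(frozen=True)
class GeometryLayout:
    """Parametric description of the bone-implant channel (lengths in mm)."""

    domain_height: float = 10.0
    domain_width: float = 1.5
    n_threads: int = 10
    thread_height: float = 1.0
    thread_depth: float = 0.5
    thread_profile: ThreadProfile = ThreadProfile.TRIANGULAR

    def __post_init__(self) -> None:
        for name in ("domain_height", "domain_width", "thread_height", "thread_depth"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be strictly positive")
        if self.n_threads < 0:
            raise ValueError("n_threads must be non-negative")
        if self.n_threads * self.thread_height > self.domain_height + 1e-12:
            raise ValueError(
                f"{self.n_threads} threads of height {self.thread_height} mm "
                f"do not fit in a {self.domain_height} mm domain"
            )
        if self.thread_depth >= self.domain_width:
            raise ValueError("thread_depth must be smaller than domain_width")

    # -- thread outline -------------------------------------------------

    def thread_polygons(self) -> list[Polygon]:
        """Solid thread cross-sections attached to the right (implant) wall.

        The thread stack is centred vertically (a no-op for the default
        10 x 1.0 mm configuration, which fills the full height).
        """
        w, d, h = self.domain_width, self.thread_depth, self.thread_height
        y0 = 0.5 * (self.domain_height - self.n_threads * h)
        polys = []
        for k in range(self.n_threads):
            ylo = y0 + k * h
            yhi = ylo + h
            ymid = 0.5 * (ylo + yhi)
            if self.thread_profile is ThreadProfile.TRIANGULAR:
                pts = [(w, ylo), (w, yhi), (w - d, ymid)]
            elif self.thread_profile is ThreadProfile.RECTANGULAR:
                pts = [(w, ylo), (w, yhi), (w - d, yhi), (w - d, ylo)]
            else:  # trapezoidal: inner face spans the middle half of the pitch
                pts = [(w, ylo), (w, yhi), (w - d, ylo + 0.75 * h), (w - d, ylo + 0.25 * h)]
            polys.append(Polygon(pts))
        return polys

    def thread_solid_area(self) -> float:
        """Exact total solid cross-section area of the threads (mm^2)."""
        return float(sum(p.area for p in self.thread_polygons()))

    @property
    def peak_line_x(self) -> float:
        """x of the vertical line joining the thread peaks (mm)."""
        return self.domain_width - self.thread_depth


def build_layout(**overrides) -> GeometryLayout:
    """Validated layout; defaults are the reference implant dimensions."""
    if "thread_profile" in overrides:
        overrides["thread_profile"] = ThreadProfile(overrides["thread_profile"])
    return GeometryLayout(**overrides)


@dataclass
class StructuredMesh:
    """Uniform quadrilateral grid with solid mask, boundary tags and zones.

    2D fields use shape ``(nx, ny)``; x-face arrays are ``(nx+1, ny)`` and
    y-face arrays ``(nx, ny+1)``.  Masses are reported per ``depth`` = 1 m
    of out-of-plane depth (the usual 2D per-unit-depth convention).
    """

    layout: GeometryLayout
    cell_size: float            # mm
    nx: int
    ny: int
    is_fluid: np.ndarray        # (nx, ny) bool
    zone: np.ndarray            # (nx, ny) int8, Zone values
    x_face_tag: np.ndarray      # (nx+1, ny) int8, BoundaryTag values
    y_face_tag: np.ndarray      # (nx, ny+1) int8
    depth: float = 1.0          # m

    @property
    def cell_area(self) -> float:
        """Cell area in m^2 (cell_size is in mm)."""
        return (self.cell_size * 1e-3) ** 2

    @property
    def dx(self) -> float:
        """Cell size in metres."""
        return self.cell_size * 1e-3

    @property
    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate grids of cell centres in mm, each (nx, ny)."""
        x = (np.arange(self.nx) + 0.5) * self.cell_size
        y = (np.arange(self.ny) + 0.5) * self.cell_size
        return np.meshgrid(x, y, indexing="ij")

    @property
    def n_fluid(self) -> int:
        return int(self.is_fluid.sum())

    def fluid_area(self) -> float:
        """Total fluid area (mm^2)."""
        return self.n_fluid * self.cell_size**2

    def zone_area(self, zone: Zone) -> float:
        """Area of one zone (mm^2)."""
        return int((self.zone == zone).sum()) * self.cell_size**2

    def boundary_face_counts(self) -> dict[BoundaryTag, int]:
        counts = {}
        for tag in (BoundaryTag.BLOOD_INLET, BoundaryTag.ALVEOLAR_BONE,
                    BoundaryTag.IMPLANT_SURFACE, BoundaryTag.BLOOD_OUTLET):
            counts[tag] = int((self.x_face_tag == tag).sum()
                              + (self.y_face_tag == tag).sum())
        return counts


def rasterize(layout: GeometryLayout, cell_size: float) -> StructuredMesh:
    """Rasterize a layout onto a uniform quad grid.

    Cells whose centres lie inside a thread polygon are solid.  Boundary
    faces are tagged: bottom = BLOOD_INLET, left = ALVEOLAR_BONE,
    top = BLOOD_OUTLET, right edge and every fluid-solid face =
    IMPLANT_SURFACE.  Zones are assigned as part of rasterization (see
    :func:`assign_zones`).
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    if layout.n_threads > 0 and cell_size > layout.thread_depth:
        raise ValueError(
            f"cell_size {cell_size} mm exceeds thread_depth "
            f"{layout.thread_depth} mm: threads are unresolvable"
        )
    nx = round(layout.domain_width / cell_size)
    ny = round(layout.domain_height / cell_size)
    for n, length, name in ((nx, layout.domain_width, "domain_width"),
                            (ny, layout.domain_height, "domain_height")):
        if n < 1 or abs(n * cell_size - length) > 1e-9 * max(1.0, length):
            raise ValueError(f"cell_size {cell_size} mm does not divide {name} {length} mm")

    xc = (np.arange(nx) + 0.5) * cell_size
    yc = (np.arange(ny) + 0.5) * cell_size
    X, Y = np.meshgrid(xc, yc, indexing="ij")

    is_fluid = np.ones((nx, ny), dtype=bool)
    polys = layout.thread_polygons()
    if polys:
        solid = contains_xy(unary_union(polys), X.ravel(), Y.ravel())
        is_fluid = ~solid.reshape(nx, ny)

    x_face_tag = np.zeros((nx + 1, ny), dtype=np.int8)
    y_face_tag = np.zeros((nx, ny + 1), dtype=np.int8)

    # domain-edge faces adjacent to fluid cells
    x_face_tag[0, is_fluid[0, :]] = BoundaryTag.ALVEOLAR_BONE
    x_face_tag[nx, is_fluid[nx - 1, :]] = BoundaryTag.IMPLANT_SURFACE
    y_face_tag[is_fluid[:, 0], 0] = BoundaryTag.BLOOD_INLET
    y_face_tag[is_fluid[:, ny - 1], ny] = BoundaryTag.BLOOD_OUTLET

    # interior fluid-solid faces belong to the implant surface
    fx = is_fluid[1:, :] ^ is_fluid[:-1, :]
    x_face_tag[1:nx, :][fx] = BoundaryTag.IMPLANT_SURFACE
    fy = is_fluid[:, 1:] ^ is_fluid[:, :-1]
    y_face_tag[:, 1:ny][fy] = BoundaryTag.IMPLANT_SURFACE

    mesh = StructuredMesh(
        layout=layout, cell_size=cell_size, nx=nx, ny=ny,
        is_fluid=is_fluid, zone=np.zeros((nx, ny), dtype=np.int8),
        x_face_tag=x_face_tag, y_face_tag=y_face_tag,
    )
    return assign_zones(mesh, layout)


def assign_zones(mesh: StructuredMesh, layout: GeometryLayout) -> StructuredMesh:
    """Label fluid cells: x >= peak line -> INTERFACIAL, else OUTER.

    The peak line is the vertical line connecting the thread peaks,
    ``x = domain_width - thread_depth``.
    """
    X, _ = mesh.cell_centers
    zone = np.where(X >= layout.peak_line_x - 1e-12, Zone.INTERFACIAL, Zone.OUTER)
    zone = zone.astype(np.int8)
    zone[~mesh.is_fluid] = Zone.SOLID
    mesh.zone = zone
    return mesh


def build_mesh(layout: GeometryLayout | None = None,
               cell_size: float = 0.05, **overrides) -> StructuredMesh:
    """Convenience: layout (defaults + overrides) -> rasterized, zoned mesh."""
    if layout is None:
        layout = build_layout(**overrides)
    return rasterize(layout, cell_size)
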