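"""Geometry: layout validation, rasterization, zones, boundary tags."""

import numpy as np
import pytest

from implantflow import BoundaryTag, Zone, build_layout, build_mesh, rasterize
from implantflow.geometry import ThreadProfile, assign_zones


class TestLayout:
    def test_defaults_match_reference_implant(self):
        lay = build_layout()
        assert lay.domain_height == 10.0
        assert lay.domain_width == 1.5
        assert lay.n_threads == 10
        assert (lay.thread_height, lay.thread_depth) == (1.0, 0.5)
        assert lay.thread_profile is ThreadProfile.TRIANGULAR

    def test_no_thread_limit_is_valid(self):
        lay = build_layout(n_threads=0)
        assert lay.thread_polygons() == []
        assert lay.thread_solid_area() == 0.0

    @pytest.mark.parametrize("kwargs", [
        dict(thread_height=1.1, n_threads=10),   # 11 mm of threads in 10 mm
        dict(domain_width=-1.5),
        dict(thread_depth=0.0),
        dict(thread_depth=1.5),                  # as deep as the channel
        dict(n_threads=-1),
    ])
    def test_invalid_layouts_rejected(self, kwargs):
        with pytest.raises(ValueError):
            build_layout(**kwargs)

    @pytest.mark.parametrize("profile,area", [
        ("triangular", 10 * 0.5 * 1.0 * 0.5),        # 2.5 mm^2
        ("rectangular", 10 * 1.0 * 0.5),             # 5.0 mm^2
        ("trapezoidal", 10 * (1.0 + 0.5) / 2 * 0.5),  # 3.75 mm^2
    ])
    def test_thread_cross_section_areas(self, profile, area):
        lay = build_layout(thread_profile=profile)
        assert lay.thread_solid_area() == pytest.approx(area, rel=1e-12)


class TestRasterize:
    def test_grid_dimensions(self):
        mesh = build_mesh(cell_size=0.025)
        assert (mesh.nx, mesh.ny) == (60, 400)
        assert mesh.nx * mesh.ny == 24000

    def test_no_threads_all_fluid(self):
        mesh = build_mesh(cell_size=0.05, n_threads=0)
        assert mesh.is_fluid.all()
        assert mesh.zone_area(Zone.INTERFACIAL) == pytest.approx(5.0)

    def test_solid_area_converges_first_order(self):
        exact = 2.5
        errs = [abs(15.0 - build_mesh(cell_size=h).fluid_area() - exact)
                for h in (0.05, 0.025, 0.0125)]
        assert errs[2] < errs[0]
        assert errs[0] / exact < 0.04
        assert errs[2] / exact < 0.01

    def test_cell_size_errors(self):
        with pytest.raises(ValueError):
            build_mesh(cell_size=0.6)          # larger than thread depth
        with pytest.raises(ValueError):
            build_mesh(cell_size=0.07)         # does not divide 1.5 mm

    def test_total_fluid_plus_solid_is_domain(self):
        mesh = build_mesh(cell_size=0.05)
        solid_cells = (~mesh.is_fluid).sum()
        assert mesh.n_fluid + solid_cells == mesh.nx * mesh.ny


class TestZones:
    def test_partition_every_fluid_cell_labelled_once(self):
        mesh = build_mesh(cell_size=0.05)
        fluid_zones = mesh.zone[mesh.is_fluid]
        assert np.isin(fluid_zones, [Zone.OUTER, Zone.INTERFACIAL]).all()
        assert (mesh.zone[~mesh.is_fluid] == Zone.SOLID).all()

    def test_interfacial_area_near_exact_value(self):
        # exact: 10 x 0.5 strip minus 2.5 mm^2 of thread solid = 2.5 mm^2
        a_coarse = build_mesh(cell_size=0.05).zone_area(Zone.INTERFACIAL)
        a_fine = build_mesh(cell_size=0.0125).zone_area(Zone.INTERFACIAL)
        assert abs(a_fine - 2.5) <= abs(a_coarse - 2.5)
        assert a_coarse == pytest.approx(2.5, rel=0.04)
        assert a_fine == pytest.approx(2.5, rel=0.01)

    def test_interfacial_cells_lie_beyond_peak_line(self):
        mesh = build_mesh(cell_size=0.05)
        X, _ = mesh.cell_centers
        inter = mesh.zone == Zone.INTERFACIAL
        assert (X[inter] >= 1.0 - 1e-9).all()
        outer = mesh.zone == Zone.OUTER
        assert (X[outer] < 1.0).all()

    def test_assign_zones_idempotent(self):
        mesh = build_mesh(cell_size=0.05)
        before = mesh.zone.copy()
        assign_zones(mesh, mesh.layout)
        assert (mesh.zone == before).all()


class TestBoundaryTags:
    def test_edge_tags_and_counts(self):
        mesh = build_mesh(cell_size=0.05)
        counts = mesh.boundary_face_counts()
        # left edge: every row is fluid at x=0
        assert counts[BoundaryTag.ALVEOLAR_BONE] == mesh.ny
        assert counts[BoundaryTag.BLOOD_OUTLET] == int(mesh.is_fluid[:, -1].sum())
        assert counts[BoundaryTag.BLOOD_INLET] == int(mesh.is_fluid[:, 0].sum())
        # implant faces: right-edge fluid faces plus all fluid-solid faces,
        # recomputed independently from the mask
        fx = (mesh.is_fluid[1:, :] ^ mesh.is_fluid[:-1, :]).sum()
        fy = (mesh.is_fluid[:, 1:] ^ mesh.is_fluid[:, :-1]).sum()
        expected = int(fx + fy + mesh.is_fluid[-1, :].sum())
        assert counts[BoundaryTag.IMPLANT_SURFACE] == expected

    def test_perimeter_closure_no_threads(self):
        mesh = build_mesh(cell_size=0.05, n_threads=0)
        counts = mesh.boundary_face_counts()
        total = sum(counts.values())
        assert total == 2 * mesh.nx + 2 * mesh.ny
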