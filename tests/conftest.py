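"""Shared fixtures: expensive solver runs are session-scoped so the
analytic benchmarks and the contact-angle sweep are computed once and
reused by unit and acceptance tests alike."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from hypothesis import settings

from implantflow import (FluidProperties, build_layout, build_mesh,
                         rasterize, run_sweep, scaled_scenario)
from implantflow.benchmarks import (droplet_case, gaussian_diffusion_case,
                                    measure_contact_angle, poiseuille_case)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

SWEEP_ANGLES = (5.0, 30.0, 50.0, 70.0, 100.0)


@pytest.fixture(scope="session")
def props() -> FluidProperties:
    return FluidProperties()


@pytest.fixture(scope="session")
def coarse_mesh():
    return build_mesh(cell_size=0.05)


@pytest.fixture(scope="session")
def fine_mesh():
    return build_mesh(cell_size=0.025)


@pytest.fixture(scope="session")
def poiseuille_results():
    """Measured Poiseuille metrics at three resolutions (for the
    analytic check and the grid-refinement study)."""
    out = {}
    for n in (16, 30, 32):
        case = poiseuille_case(n)
        out[n] = case.evaluate(case.run(), case)
    return out


@pytest.fixture(scope="session")
def gaussian_result():
    case = gaussian_diffusion_case()
    return case, case.evaluate(case.run(), case)


@pytest.fixture(scope="session")
def droplet90():
    """Sessile drop at 90 degrees: case, final state and measurements."""
    case = droplet_case(90.0, attached=True)
    final = case.run()
    return case, final, case.evaluate(final, case)


@pytest.fixture(scope="session")
def free_droplet():
    case = droplet_case(90.0, attached=False)
    final = case.run()
    return case, final, case.evaluate(final, case)


@pytest.fixture(scope="session")
def droplet_angle_sweep():
    """Measured apparent angle after a fixed wetting time, per imposed
    contact angle."""
    out = {}
    for theta in SWEEP_ANGLES:
        case = droplet_case(theta, attached=True, t_end=10e-3)
        out[theta] = measure_contact_angle(case.run(), case.mesh)
    return out


@pytest.fixture(scope="session")
def scenario_report(tmp_path_factory):
    """The five-angle coarse-preset scenario sweep (the expensive one:
    five 3-second runs; shared by every test that needs real dynamics)."""
    cfg = scaled_scenario(5.0, "coarse")
    cfg = dataclasses.replace(cfg, outdir=str(tmp_path_factory.mktemp("sweep")),
                              export_csv=False)
    return run_sweep(cfg, list(SWEEP_ANGLES))
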