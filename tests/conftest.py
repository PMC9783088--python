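"""Shared fixtures: CF4 parameter sets and calibrated permeabilities.

Solver calibrations are session-scoped because the bisection re-runs
the transient solver several times.
"""

from __future__ import annotations

import pytest

import wicksim as ws
from wicksim import calibration, darcy


@pytest.fixture(scope="session")
def cf4():
    """(MembraneSpec, PorousMediumParams, StripGeometry) for CF4."""
    return ws.get_preset("CF4")


@pytest.fixture(scope="session")
def cf4_lw_params(cf4):
    """Lucas-Washburn parameters calibrated to the CF4 wicking rate."""
    spec, medium, _ = cf4
    cal = calibration.permeability_from_wicking_rate(spec, ws.SALIVA, medium, "lw")
    return ws.LWParams(
        permeability=cal.value,
        surface_tension=ws.SALIVA.surface_tension,
        contact_angle=ws.SALIVA.contact_angle,
        porosity=medium.porosity,
        viscosity=ws.SALIVA.dynamic_viscosity,
        pore_radius=medium.pore_radius,
    )


@pytest.fixture(scope="session")
def cf4_solver_k(cf4):
    """Solver permeability calibrated to the CF4 wicking rate (120 cells)."""
    spec, medium, geom = cf4
    cal = calibration.permeability_from_wicking_rate(
        spec,
        ws.SALIVA,
        medium,
        "solver",
        geom=geom,
        nonwetting=ws.AIR,
        solver_config=darcy.SolverConfig(cell_count=120, end_time=2000.0),
    )
    return cal.value


@pytest.fixture(scope="session")
def cf4_calibrated_medium(cf4, cf4_solver_k):
    _, medium, _ = cf4
    return medium.with_permeability(cf4_solver_k)
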