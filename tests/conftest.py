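"""Shared fixtures: meshes, field solutions and treatment runs.

Solver fixtures are session-scoped and use reduced (desk-scale) mesh
resolutions; the electrostatic quantities they feed into assertions were
checked to be converged well inside the asserted tolerances (thresholds
shift <1% against meshes an order of magnitude finer).
"""

from __future__ import annotations

import numpy as np
import pytest

from inspiresim.calibration import VolumeFieldCurve
from inspiresim.controller import (ControllerConfig, PulseProtocol,
                                   simulate_treatment)
from inspiresim.electro import MaterialProperties, adaptive_solve, solve_potential
from inspiresim.geometry import ApplicatorGeometry, build_geometry
from inspiresim.mesh import RefinementRule, generate_mesh, spherical_shell_mesh
from inspiresim.thermal import ThermalBoundary

EXPOSURES = (0.5, 1.0, 1.5, 2.0)

# test-scale meshing (see module docstring)
NEAR_CURVE, FAR_CURVE = 0.02, 0.514
NEAR_TREAT, FAR_TREAT = 0.04, 0.8


@pytest.fixture(scope="session")
def materials():
    return MaterialProperties()


@pytest.fixture(scope="session")
def sphere_field(materials):
    """Concentric spheres a=0.1 cm / b=10 cm at 6000 V: every quantity has
    a closed form."""
    mesh = spherical_shell_mesh(0.1, 10.0, 100, 100)
    return solve_potential(mesh, materials, applied_voltage=6000.0)


@pytest.fixture(scope="session")
def geometry15():
    return build_geometry(ApplicatorGeometry(exposure_length=1.5))


@pytest.fixture(scope="session")
def mesh15(geometry15):
    return generate_mesh(geometry15, NEAR_CURVE, FAR_CURVE)


@pytest.fixture(scope="session")
def solved15(mesh15, materials):
    """1.5 cm geometry solved with the standard two refinement rounds."""
    field, history = adaptive_solve(mesh15, materials, 6000.0,
                                    RefinementRule(rounds=2))
    return field, history


@pytest.fixture(scope="session")
def fields(materials, solved15):
    """Refined field solutions for all four exposures (solve + 2 rounds)."""
    out = {}
    for exp in EXPOSURES:
        if exp == 1.5:
            out[exp] = solved15[0]
            continue
        geom = build_geometry(ApplicatorGeometry(exposure_length=exp))
        mesh = generate_mesh(geom, NEAR_CURVE, FAR_CURVE)
        field, _ = adaptive_solve(mesh, materials, 6000.0,
                                  RefinementRule(rounds=2))
        out[exp] = field
    return out


@pytest.fixture(scope="session")
def curves(fields):
    """Volume-vs-field curves for all four exposures."""
    return {exp: VolumeFieldCurve.from_field(f) for exp, f in fields.items()}


@pytest.fixture(scope="session")
def treatment_logs(materials):
    """Full temperature-controlled treatments for all four exposures."""
    boundary = ThermalBoundary()
    protocol = PulseProtocol()
    config = ControllerConfig()
    logs = {}
    for exp in EXPOSURES:
        geom = build_geometry(ApplicatorGeometry(exposure_length=exp))
        mesh = generate_mesh(geom, NEAR_TREAT, FAR_TREAT)
        field, _ = adaptive_solve(mesh, materials, 6000.0,
                                  RefinementRule(rounds=1))
        logs[exp] = simulate_treatment(field.mesh, field, materials, boundary,
                                       protocol, config)
    return logs
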