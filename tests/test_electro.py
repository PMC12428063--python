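"""Electrostatics against closed-form oracles and conservation laws."""

import numpy as np
import pytest

from inspiresim.electro import (MaterialProperties, SolverError,
                                field_volume_curve, solve_potential,
                                volume_above_field)
from inspiresim.mesh import rectangle_mesh, spherical_shell_mesh
from inspiresim.geometry import AXIS, FARFIELD, INSULATION

A_CM, B_CM = 0.1, 10.0
SIGMA_CM = 0.004  # 0.4 S/m


def analytic_sphere_resistance():
    return (1.0 / (4.0 * np.pi * SIGMA_CM)) * (1.0 / A_CM - 1.0 / B_CM)


class TestConcentricSpheres:
    def test_total_current_matches_closed_form(self, sphere_field):
        expected = 6000.0 / analytic_sphere_resistance()
        assert sphere_field.electrode_current == pytest.approx(expected,
                                                               rel=0.01)

    def test_potential_matches_closed_form(self, sphere_field):
        mesh = sphere_field.mesh
        rad = np.hypot(*mesh.points.T)
        v_exact = 6000.0 * (1 / rad - 1 / B_CM) / (1 / A_CM - 1 / B_CM)
        err = np.abs(sphere_field.potential - v_exact).max() / 6000.0
        assert err < 0.01

    def test_volume_above_field_matches_inverse_square_law(self, sphere_field):
        # E(rho) = C / rho^2 with C = V / (1/a - 1/b)
        c = 6000.0 / (1 / A_CM - 1 / B_CM)
        e_set = 1000.0
        r_star = np.sqrt(c / e_set)
        expected = 4.0 / 3.0 * np.pi * (r_star**3 - A_CM**3)
        got = volume_above_field(sphere_field, e_set)
        assert got == pytest.approx(expected, rel=0.01)
        assert expected == pytest.approx(1.95, abs=0.03)


class TestNeedleSolution:
    def test_charge_conservation(self, solved15):
        field, _ = solved15
        imbalance = abs(field.electrode_current - field.pad_current) \
            / field.electrode_current
        assert imbalance < 1e-3

    def test_mesh_convergence_of_current(self, solved15):
        """Total current changes <1% between refinement rounds 1 and 2."""
        _, history = solved15
        assert len(history) >= 3
        (_, i1), (_, i2) = history[-2], history[-1]
        assert abs(i2 - i1) / abs(i1) < 0.01

    def test_dirichlet_on_electrode_and_pad(self, solved15):
        from inspiresim.geometry import ELECTRODE, PAD
        field, _ = solved15
        mesh = field.mesh
        assert np.allclose(field.potential[mesh.nodes_on(ELECTRODE)], 6000.0)
        assert np.allclose(field.potential[mesh.nodes_on(PAD)], 0.0)

    def test_zero_voltage_gives_null_field(self, mesh15, materials):
        f = solve_potential(mesh15, materials, applied_voltage=0.0)
        assert np.allclose(f.potential, 0.0)
        assert np.allclose(f.e_magnitude, 0.0)
        assert f.electrode_current == pytest.approx(0.0, abs=1e-9)

    def test_linearity_in_voltage(self, mesh15, materials):
        f1 = solve_potential(mesh15, materials, applied_voltage=3000.0)
        f2 = solve_potential(mesh15, materials, applied_voltage=6000.0)
        np.testing.assert_allclose(f2.potential, 2.0 * f1.potential,
                                   atol=1e-6 * 6000)
        np.testing.assert_allclose(f2.e_magnitude, 2.0 * f1.e_magnitude,
                                   rtol=1e-9, atol=1e-9)
        assert f2.electrode_current == pytest.approx(
            2.0 * f1.electrode_current, rel=1e-9)

    def test_negative_voltage_rejected(self, mesh15, materials):
        with pytest.raises(ValueError):
            solve_potential(mesh15, materials, applied_voltage=-1.0)

    def test_missing_dirichlet_tag_rejected(self, materials):
        m = rectangle_mesh(1.0, 2.0, 0.0, 1.0, 0.25,
                           tags={"left": INSULATION, "right": INSULATION,
                                 "bottom": AXIS, "top": FARFIELD})
        with pytest.raises(SolverError, match="Dirichlet"):
            solve_potential(m, materials, applied_voltage=10.0)

    def test_nonpositive_conductivity_rejected(self, mesh15, materials):
        cold = np.full(mesh15.n_points, -100.0)  # sigma(T) < 0 everywhere
        with pytest.raises(SolverError, match="sigma"):
            solve_potential(mesh15, materials, temperature=cold)


class TestVolumeAboveField:
    def test_zero_level_returns_tissue_volume(self, solved15):
        field, _ = solved15
        geom = field.mesh.geometry
        assert volume_above_field(field, 0.0) == pytest.approx(
            geom.tissue_volume(), rel=1e-9)

    def test_monotone_in_level(self, solved15):
        field, _ = solved15
        grid = np.arange(200.0, 2001.0, 10.0)
        vols = field_volume_curve(field, grid)
        assert (np.diff(vols) <= 1e-9).all()

    def test_scale_invariance(self, mesh15, materials):
        """volume(c*V0, c*E_set) == volume(V0, E_set)."""
        f1 = solve_potential(mesh15, materials, applied_voltage=6000.0)
        f2 = solve_potential(mesh15, materials, applied_voltage=3000.0)
        v1 = volume_above_field(f1, 600.0)
        v2 = volume_above_field(f2, 300.0)
        assert v2 == pytest.approx(v1, rel=1e-9)

    def test_level_above_max_gives_zero(self, solved15):
        field, _ = solved15
        assert volume_above_field(field, 1e9) == 0.0

    def test_element_mode_brackets_interpolated(self, solved15):
        field, _ = solved15
        vi = volume_above_field(field, 600.0)
        ve = volume_above_field(field, 600.0, method="element")
        assert ve == pytest.approx(vi, rel=0.15)

    def test_sigma_temperature_law(self, materials):
        assert materials.sigma(materials.reference_temperature) == \
            pytest.approx(0.4)
        assert materials.sigma(materials.reference_temperature + 10.0) == \
            pytest.approx(0.4 * 1.15)
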