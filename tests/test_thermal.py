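"""Heat conduction: closed-form benchmarks, conservation and boundary
behaviour."""

import numpy as np
import pytest

from inspiresim.electro import MaterialProperties, solve_potential
from inspiresim.geometry import (AXIS, FARFIELD, INSULATION, PAD,
                                 ApplicatorGeometry, build_geometry)
from inspiresim.mesh import generate_mesh, rectangle_mesh
from inspiresim.thermal import (ThermalBoundary, ThermalError, ThermalSolver,
                                ThermalState, joule_source, probe_temperature)


class TestJouleSource:
    def test_zero_rate_gives_zero_source(self, solved15):
        field, _ = solved15
        assert not joule_source(field, 0.0).any()

    def test_continuous_delivery_limit(self, solved15):
        """At R = 1e6 us/s (duty cycle 1) the source is sigma*|E|^2."""
        field, _ = solved15
        qe = joule_source(field, 1e6)
        np.testing.assert_allclose(
            qe, field.sigma_elem_cm * field.e_magnitude**2, rtol=1e-12)

    def test_negative_rate_rejected(self, solved15):
        field, _ = solved15
        with pytest.raises(ValueError):
            joule_source(field, -1.0)

    def test_power_balance_with_total_current(self, solved15):
        """Integrated source equals rate * V * I (Galerkin energy identity)."""
        field, _ = solved15
        rate = 50.0
        qe = joule_source(field, rate)
        mesh = field.mesh
        total = 2.0 * np.pi * (qe * mesh.areas * mesh.centroids[:, 0]).sum()
        expected = rate * 1e-6 * 6000.0 * field.electrode_current
        assert total == pytest.approx(expected, rel=1e-9)


class TestStep:
    def test_equilibrium_is_preserved(self, materials):
        """No source, coolant at baseline: uniform temperature is a fixed
        point for any dt."""
        geom = build_geometry(ApplicatorGeometry(exposure_length=1.0))
        mesh = generate_mesh(geom, 0.08, 2.0)
        bnd = ThermalBoundary(baseline_tissue_temperature=33.0,
                              coolant_temperature=33.0)
        solver = ThermalSolver(mesh, materials, bnd)
        state = solver.initial_state()
        for dt in (0.1, 2.0, 50.0):
            state = solver.step(state, None, dt)
            np.testing.assert_allclose(state.temperature, 33.0, atol=1e-9)

    def test_slab_transient_matches_series_solution(self, materials):
        """Uniform slab between two cold faces: classic Fourier series."""
        L = 1.0
        mesh = rectangle_mesh(5.0, 6.0, 0.0, L, 0.05,
                              tags={"left": AXIS, "right": INSULATION,
                                    "bottom": PAD, "top": FARFIELD})
        bnd = ThermalBoundary(baseline_tissue_temperature=0.0,
                              coolant_temperature=0.0)
        solver = ThermalSolver(mesh, materials, bnd)
        state = solver.initial_state()
        t0 = np.ones(mesh.n_points)
        t0[solver.fixed] = 0.0
        state = ThermalState(mesh, t0, 0.0)
        t_end, dt = 50.0, 0.25
        for _ in range(int(t_end / dt)):
            state = solver.step(state, None, dt)
        alpha = materials.k_cm / materials.volumetric_heat_capacity_cm
        z = mesh.points[:, 1]
        exact = np.zeros_like(z)
        for n in range(1, 100, 2):
            exact += 4.0 / (n * np.pi) * np.sin(n * np.pi * z / L) * \
                np.exp(-(n * np.pi / L) ** 2 * alpha * t_end)
        assert np.abs(state.temperature - exact).max() < 0.005

    def test_uniform_heating_of_insulated_domain(self, materials):
        """With all-natural boundaries, mean T rises by Qe*dt/(rho*Cp)."""
        mesh = rectangle_mesh(2.0, 3.0, 0.0, 1.0, 0.2,
                              tags={k: INSULATION for k in
                                    ("left", "right", "bottom", "top")})
        bnd = ThermalBoundary()
        solver = ThermalSolver(mesh, materials, bnd)
        assert len(solver.fixed) == 0
        state = ThermalState(mesh, np.full(mesh.n_points, 20.0), 0.0)
        qe = np.full(mesh.n_triangles, 5.0)  # W/cm^3
        dt = 2.0
        state = solver.step(state, qe, dt)
        expected = 20.0 + 5.0 * dt / materials.volumetric_heat_capacity_cm
        np.testing.assert_allclose(state.temperature, expected, rtol=1e-9)

    def test_discrete_energy_balance(self, materials):
        """On free nodes, stored-energy change equals (source - conduction)
        exactly per implicit step."""
        geom = build_geometry(ApplicatorGeometry(exposure_length=1.0))
        mesh = generate_mesh(geom, 0.08, 2.0)
        solver = ThermalSolver(mesh, materials, ThermalBoundary())
        field = solve_potential(mesh, materials, applied_voltage=6000.0)
        qe = joule_source(field, 40.0)
        state = solver.steady_state()
        dt = 0.5
        new = solver.step(state, qe, dt)
        free = solver.free
        d_energy = (solver.mass * (new.temperature - state.temperature))[free].sum()
        F = solver._robin_rhs + solver.source_load(qe)
        rhs_power = (F - solver.K @ new.temperature)[free].sum()
        assert d_energy == pytest.approx(dt * rhs_power,
                                         rel=1e-6, abs=1e-8 * abs(d_energy))

    def test_maximum_principle_without_source(self, materials):
        mesh = rectangle_mesh(5.0, 6.0, 0.0, 1.0, 0.1)
        bnd = ThermalBoundary(baseline_tissue_temperature=0.0,
                              coolant_temperature=0.0)
        solver = ThermalSolver(mesh, materials, bnd)
        rng = np.random.default_rng(1)
        t0 = rng.uniform(0.0, 1.0, mesh.n_points)
        t0[solver.fixed] = 0.0
        state = ThermalState(mesh, t0, 0.0)
        for _ in range(20):
            state = solver.step(state, None, 1.0)
            assert state.temperature.min() >= -1e-9
            assert state.temperature.max() <= 1.0 + 1e-9

    def test_bad_dt_rejected(self, materials):
        mesh = rectangle_mesh(0.0, 1.0, 0.0, 1.0, 0.5)
        solver = ThermalSolver(mesh, materials, ThermalBoundary())
        with pytest.raises(ValueError):
            solver.step(solver.initial_state(), None, 0.0)


class TestCoolingAndProbe:
    def test_cooled_wall_region_is_colder_than_far_field(self, materials):
        """The steady cooled state reproduces a cold sheath along the
        applicator: tissue next to the cooled shaft sits below baseline
        while tissue at the same radius far below the tip stays at it."""
        geom = build_geometry(ApplicatorGeometry(exposure_length=1.5))
        mesh = generate_mesh(geom, 0.05, 1.0)
        solver = ThermalSolver(mesh, materials, ThermalBoundary())
        state = solver.steady_state()
        near_shaft = probe_temperature(state, (0.15, geom.z_cooled + 1.0))
        far_below = probe_temperature(state, (0.15, geom.z_tip - 6.0))
        assert near_shaft < 30.0
        assert far_below > 32.0  # within a degree of baseline
        assert far_below - near_shaft > 3.0
        assert state.temperature.min() >= \
            ThermalBoundary().coolant_temperature - 1e-6

    def test_probe_reads_uniform_field(self, materials):
        mesh = rectangle_mesh(0.0, 1.0, 0.0, 1.0, 0.25)
        state = ThermalState(mesh, np.full(mesh.n_points, 45.0), 0.0)
        assert probe_temperature(state, (0.4, 0.6)) == pytest.approx(45.0)

    def test_probe_identity_at_node(self, materials):
        mesh = rectangle_mesh(0.0, 1.0, 0.0, 1.0, 0.25)
        rng = np.random.default_rng(2)
        temp = rng.uniform(20.0, 40.0, mesh.n_points)
        state = ThermalState(mesh, temp, 0.0)
        i = 7
        got = probe_temperature(state, tuple(mesh.points[i]))
        assert got == pytest.approx(temp[i], abs=1e-9)

    def test_probe_outside_mesh_rejected(self, materials):
        mesh = rectangle_mesh(0.0, 1.0, 0.0, 1.0, 0.25)
        state = ThermalState(mesh, np.zeros(mesh.n_points), 0.0)
        with pytest.raises(ThermalError, match="outside"):
            probe_temperature(state, (2.0, 2.0))

    def test_probe_below_tissue_maximum_during_treatment(self, treatment_logs):
        """The sensor near the cooled shaft reads less than the hottest
        tissue, which sits at the uncooled tip."""
        log = treatment_logs[1.5]
        final = log.final_state
        assert log.probe_trace.max() < final.temperature.max()
        geom = final.mesh.geometry
        r_hot, z_hot = final.hottest_point()
        d_tip = np.hypot(r_hot, z_hot - geom.z_tip)
        assert d_tip < geom.applicator.uncooled_tip_length
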