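"""Dose accounting and the temperature-feedback delivery loop."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from inspiresim.controller import (ControllerConfig, DoseError, PulseProtocol,
                                   pulse_count, simulate_treatment,
                                   update_rate, waveform_count)
from inspiresim.electro import adaptive_solve
from inspiresim.geometry import ApplicatorGeometry, build_geometry
from inspiresim.mesh import RefinementRule, generate_mesh
from inspiresim.thermal import ThermalBoundary


class TestDoseAccounting:
    def test_default_protocol_is_twenty_thousand_pulses(self):
        p = PulseProtocol()  # 0.02 s dose of 1000 ns pulses
        assert pulse_count(p) == 20_000
        assert waveform_count(p) == 10_000

    def test_microsecond_pulse_accounting(self):
        # 100 pulses of 100 us carry a 0.01 s dose
        p = PulseProtocol(pulse_width_ns=100_000.0, prescribed_dose_s=0.01)
        assert pulse_count(p) == 100
        assert p.prescribed_dose_s == pytest.approx(100 * 100e-6)

    def test_zero_dose_is_zero_pulses(self):
        assert pulse_count(PulseProtocol(prescribed_dose_s=0.0)) == 0

    def test_indivisible_dose_reported(self):
        p = PulseProtocol(pulse_width_ns=1500.0, prescribed_dose_s=1e-5)
        with pytest.raises(DoseError, match="remainder"):
            pulse_count(p)

    def test_invalid_protocol_rejected(self):
        with pytest.raises(DoseError):
            PulseProtocol(pulse_width_ns=0.0)


class TestThrottleLaw:
    def test_far_below_setpoint_runs_at_max_rate(self):
        cfg = ControllerConfig()
        assert update_rate(20.0, cfg) == cfg.max_rate

    def test_at_setpoint_runs_at_floor(self):
        cfg = ControllerConfig()
        assert update_rate(cfg.setpoint, cfg) == \
            pytest.approx(cfg.floor * cfg.max_rate)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(0.0, 100.0), st.floats(0.0, 100.0))
    def test_monotone_nonincreasing_and_bounded(self, t1, t2):
        cfg = ControllerConfig()
        lo, hi = sorted([t1, t2])
        r_lo, r_hi = update_rate(lo, cfg), update_rate(hi, cfg)
        assert r_lo >= r_hi
        assert cfg.floor * cfg.max_rate <= r_hi <= cfg.max_rate

    def test_nonfinite_probe_rejected(self):
        with pytest.raises(ValueError):
            update_rate(float("nan"), ControllerConfig())


@pytest.fixture(scope="module")
def small_setup(materials):
    geom = build_geometry(ApplicatorGeometry(exposure_length=1.0))
    mesh = generate_mesh(geom, 0.08, 1.5)
    field, _ = adaptive_solve(mesh, materials, 6000.0,
                              RefinementRule(rounds=0))
    return field


class TestSimulateTreatment:
    def test_unreachable_setpoint_gives_unthrottled_duration(self, small_setup,
                                                             materials):
        """With the setpoint above any achievable temperature the dose is
        delivered at max_rate: duration = dose / (max_rate * 1e-6)."""
        cfg = ControllerConfig(setpoint=500.0, max_rate=100.0)
        log = simulate_treatment(small_setup.mesh, small_setup, materials,
                                 ThermalBoundary(), PulseProtocol(), cfg)
        assert log.duration_s == pytest.approx(200.0, rel=1e-9)
        assert (log.records.rate_us_per_s == 100.0).all()

    def test_dose_delivered_exactly(self, treatment_logs):
        for log in treatment_logs.values():
            assert log.delivered_dose_s == log.protocol.prescribed_dose_s
            dose = log.records.cumulative_dose_s.to_numpy()
            assert (np.diff(dose) >= 0).all()
            assert dose[-1] == log.protocol.prescribed_dose_s

    def test_duration_bounded_below_by_unthrottled_time(self, treatment_logs):
        for log in treatment_logs.values():
            floor_time = log.protocol.prescribed_dose_s / (
                log.config.max_rate * 1e-6)
            assert log.duration_s >= floor_time - 1e-9

    def test_probe_plateau_and_overshoot(self, treatment_logs):
        """The probe ramps from a cooled baseline, then holds the setpoint:
        within +/-1 degC over the final half, overshoot <= 1 degC."""
        for log in treatment_logs.values():
            rec = log.records
            assert rec.probe_temperature_c.iloc[0] < 30.0
            half = rec[rec.time_s >= 0.5 * log.duration_s]
            assert np.abs(half.probe_temperature_c - 45.0).max() <= 1.0
            reached = rec[rec.probe_temperature_c >= 45.0]
            if len(reached):
                after = rec[rec.time_s >= reached.time_s.iloc[0]]
                assert after.probe_temperature_c.max() <= 46.0

    def test_durations_decrease_with_exposure_length(self, treatment_logs):
        exposures = sorted(treatment_logs)
        durations = [treatment_logs[e].duration_s for e in exposures]
        assert all(a > b for a, b in zip(durations, durations[1:]))

    def test_deterministic_replay(self, small_setup, materials):
        cfg = ControllerConfig(setpoint=500.0, max_rate=400.0)
        args = (small_setup.mesh, small_setup, materials, ThermalBoundary(),
                PulseProtocol(), cfg)
        a = simulate_treatment(*args)
        b = simulate_treatment(*args)
        assert a.records.equals(b.records)
        assert a.duration_s == b.duration_s
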