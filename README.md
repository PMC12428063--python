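# inspiresim

Axisymmetric electro-thermal modelling of temperature-controlled
nanosecond pulsed-field ablation (INSPIRE-type irreversible
electroporation) delivered through a single internally cooled needle
electrode against a grounding pad — plus the calibration and statistics
stages that turn measured ablation volumes into lethal electric-field
thresholds.

It is written for researchers in computational bioelectromagnetics and
ablation treatment planning who want a tested, scriptable reimplementation
of this class of model: the quasi-static conduction problem
∇·(σ∇V) = 0 around the needle, duty-cycled Joule heating
Q_e = R(t)·10⁻⁶·(J·E) under a temperature-feedback delivery controller,
and the inverse step — matching a measured ablation volume to the
simulated volume-above-field curve to estimate the lethal threshold
E_lethal at the ablation margin.  Because animal data are published only
as group summaries, a truncated-normal synthetic-cohort generator with
exactly those summaries (n = 9/6/7/5; volumes 7.95 ± 3.74, 11.56 ± 5.32,
12.83 ± 2.61, 7.64 ± 2.50 cm³) makes the calibration and statistics
stages fully testable.  The model and every default are documented in
[docs/methods.md](docs/methods.md).

## Worked example

```python
from inspiresim import *
from inspiresim.electro import adaptive_solve

geom = build_geometry(ApplicatorGeometry(exposure_length=1.5))
mesh = generate_mesh(geom, max_size_near=0.02, max_size_far=0.514)
field, _ = adaptive_solve(mesh, MaterialProperties(), 6000.0,
                          RefinementRule(field_threshold=250.0, rounds=2))
curve = VolumeFieldCurve.from_field(field)
match = calibrate_threshold(curve, 12.83)   # measured mean volume, cm^3
print(f"I = {field.electrode_current:.1f} A, "
      f"E_lethal = {match.threshold:.0f} V/cm")

log = simulate_treatment(field.mesh, field, MaterialProperties(),
                         ThermalBoundary(), PulseProtocol(),
                         ControllerConfig())
print(f"duration = {log.duration_s:.0f} s, "
      f"V(>45 degC) = {log.final_state.iso_volume_above(45.0):.1f} cm^3")
```

prints (exact duration depends on mesh resolution; see the methods note):

```
I = 79.5 A, E_lethal = 745 V/cm
duration = 248 s, V(>45 degC) = 22.8 cm^3
```

79.5 A is the total current the 1.5 cm electrode drives at 6000 V;
745 V/cm is the field level whose enclosed tissue volume equals the
measured 12.83 cm³ ablation; the treatment delivers the full 0.02 s dose
(20,000 × 1000 ns pulses) in 248 s while the feedback controller holds the
probe at 45 ± 1 °C, leaving 22.8 cm³ of tissue above 45 °C with the
hottest point at the uncooled electrode tip.

## Analysis pipeline

The numbered drivers under `analysis/` retrace the study end to end and
write their tables to `results/`:

1. `01_mesh_and_field.py` — meshes the four exposure geometries
   (0.5–2.0 cm), solves at 6000 V with two field-driven refinement passes,
   reports currents and charge conservation.
2. `02_volume_field_curves.py` — tissue volume above each field level,
   200–2000 V/cm in 10 V/cm steps, per geometry.
3. `03_calibrate_thresholds.py` — matches the measured group-mean volumes
   to the curves: lethal thresholds, predicted ablation dimensions and
   elongation.
4. `04_simulate_treatments.py` — full temperature-controlled treatments:
   durations, probe plateaus, thermal iso-volumes (45/55/65 °C).
5. `05_cohort_statistics.py` — synthetic cohort, Welch comparisons,
   treatment-time trend, per-replicate threshold recovery.

The same stages are available as a CLI (`inspiresim simulate | curve |
calibrate | cohort | report | pipeline`) configured by unit-suffixed YAML
keys; an empty config reproduces the study conditions.

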