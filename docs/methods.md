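# Methods

`inspiresim` models a single internally cooled needle electrode delivering
temperature-controlled bipolar nanosecond pulsed-field (INSPIRE-type)
ablation against a grounding pad, and implements the calibration that turns
measured ablation volumes into lethal electric-field thresholds.  This note
records the model, its assumptions, the parameters that matter, and the
choices made where the published protocol leaves the design open.

## Electrostatic model

The nanosecond pulses are slow compared with charge relaxation in tissue at
σ ≈ 0.4 S/m, so each pulse is treated as stationary conduction:

    ∇·J = 0,  J = σE,  E = −∇V

solved in 2-D axisymmetric (r, z) coordinates on the meridian plane of a
45 cm long, 45 cm radius tissue cylinder.  Dirichlet conditions: the exposed
electrode surface (distal shaft wall plus flat tip face) at the applied
voltage (6000 V), the grounding pad (a 7.6 cm radius disc on the bottom
face) at 0 V.  Zero normal current on the insulated shaft, the symmetry
axis and the remaining outer boundary.  Tissue permittivity, electrode
polarisation and dynamic electroporation conductivity are out of scope.

Discretisation is P1 (linear) triangles with the axisymmetric weight r; the
element integral ∫r dA = A·r̄ is exact for linear shape functions.  Total
currents are extracted from the stiffness residual at the Dirichlet nodes,
which makes electrode and pad currents agree to machine precision on any
mesh.  Against the concentric-spheres closed form
R = (1/4πσ)(1/a − 1/b), the solver is within 0.2% on current and 0.1% on
potential at the resolutions used here.

With uniform σ the field distribution is independent of the conductivity
magnitude, so the baseline calibration below is purely geometric.  A
coupled mode re-evaluates σ(T) = σ₀(1 + α(T − T_ref)) element-wise from a
temperature field; α is not published — the default 0.015 /°C is a typical
soft-tissue literature value and is the dominant uncertainty of coupled
runs.

## Meshing and adaptive refinement

A graded structured background mesh resolves the needle (shaft radius
0.08255 cm, insulation 0.02032 cm, channel 0.0228 cm — the channel is not
meshed, see cooling below), with forced grid lines on every material
feature.  Elements within 1 mm of the energised surface are subdivided
until their diameter is at most √2 × the 100 µm near-field size; elsewhere
sizes grade geometrically up to 5.14 mm.  Field-driven refinement then
subdivides every element with |E| > 250 V/cm, twice, re-solving in
between.  Subdivision is conforming red–green–blue (longest-edge) marking,
so no hanging nodes arise and element quality is bounded.  Final meshes run
~110k–265k triangles per geometry; the last refinement round moves the
total current by <0.5%.

The tip is modelled as a flat disc face (the physical trocar bevel is not
described in the treatment-planning geometry); the insertion depth is not
published and defaults to 10 cm, chosen so every lethal iso-contour stays
≥5 cm from any boundary — thresholds shift by only ±2% between 5 and 20 cm
insertion.  Boundary tags ELECTRODE / INSULATION / PAD / FARFIELD / AXIS
are assigned geometrically (hence survive refinement); the coolant
"CHANNEL" boundary is exposed as the subset of the needle wall at and
above the end of the uncooled tip, since the coolant loop is collapsed
onto the wall.

## Threshold calibration

The volume of tissue with |E| above a level E_set is integrated by
revolving the clipped super-level set of the nodal field (2π r̄ A per
clipped polygon), over the grid 200–2000 V/cm in 10 V/cm steps.  Against
the isolated-sphere 1/r² field the volume integral is within 0.1% of the
closed form.  The lethal threshold of a measured ablation volume is the
field level whose curve volume matches it — by monotone linear
interpolation (default) or nearest grid point.  Matching group means
against the four measured mean volumes (7.95, 11.56, 12.83, 7.64 cm³)
gives 556, 631, 742 and 1210 V/cm for the 0.5, 1.0, 1.5 and 2.0 cm
exposures.

These reproduce the published ordering — the 2.0 cm geometry, with its
smaller measured volume despite the largest energised surface, calibrates
to by far the highest threshold — but sit 15–30% above the published means
(433, 548, 581, 918 V/cm).  The offset is a nearly constant field-scale
factor ~0.8 across all four geometries and is robust here: thresholds are
mesh-converged to <0.5%, agree with a prolate-spheroid capacitance
estimate, and move *away* from the published values if the calibration is
repeated on a temperature-modified σ(T) field (the heated annulus raises
the exterior field).  A uniform ~20% lower effective tissue voltage would
reconcile all four groups simultaneously; no printed model input produces
it, so the baseline-field calibration is reported as computed.  Values
calibrated here should be compared across geometries, not used as absolute
device constants.

## Thermal model

Transient conduction ρC_p ∂T/∂t = ∇·(k∇T) + Q_e with the duty-cycled
Joule source Q_e = R(t)·10⁻⁶ · (J·E), where R(t) is the delivery rate in
µs of pulse-on time per second.  ρ = 1079 kg/m³, C_p = 3540 J/(kg·K),
k = 0.52 W/(m·K) are liver values from the same public tissue-property
database as σ (implementer defaults; the study prints none of them).  No
perfusion term, matching the stated heat equation (a Pennes option
exists, off by default).  Note that the published end-of-treatment
iso-volumes (0.17–3.92 cm³ above 45 °C) are far smaller than a
conduction-only model can yield at the delivered average power, implying
an unprinted heat sink; accordingly only the qualitative thermal findings
(iso-volumes growing with exposure, hottest tissue at the uncooled tip,
cooled sheath along the shaft) are treated as reproducible, and all hold
here.

Boundary conditions: far boundary and pad face fixed at the 33 °C baseline
(probe-consistent, see below); the cooled shaft wall — everything proximal
of the uncooled distal 0.5 cm — carries either a fixed-temperature or,
by default, a convective film condition at the 22 °C coolant.  The default
film coefficient 1300 W/(m²K) is a laminar pipe-flow estimate for the
10 mL/min water loop (Nu = 3.66 in the 0.0228 cm channel, rescaled to the
outer wall); it replaces the conjugate CFD of the coolant loop.
Treatments start from the steady cooled state, which puts the probe
baseline near 24 °C, matching the ~25 °C observed at treatment start
(tissue at core temperature would contradict that probe reading; 33 °C
baseline + 22 °C coolant reproduces it without asserting an unphysical
bulk temperature).

Time stepping is implicit Euler with a lumped mass matrix (and a
row-lumped film matrix, keeping the discrete operator monotone): the
operator is factorised once per step size, so a treatment costs one sparse
back-substitution per 0.1 s step.  Against the slab Fourier-series
solution the transient is within 0.5%; with no source the scheme obeys the
discrete maximum principle, and uniform heating of an insulated domain
raises temperature by exactly Q_e·Δt/ρC_p per step.

## Delivery controller

Dose is accounted as summed pulse-on time: the 0.02 s prescription is
20,000 × 1000 ns pulses in 10,000 bipolar waveforms.  The device's control
algorithm is unpublished; delivery is represented by the rate R(t) with a
proportional-band throttle

    R(T) = max_rate · clamp((setpoint − T)/band, floor, 1)

(defaults: setpoint 45 °C, max_rate 100 µs/s, band 1 °C, floor 0.05,
control interval 0.5 s) — the simplest law that ramps at full rate from
baseline, settles into a stable plateau within 1 °C of the setpoint, and
can never stall (floor > 0 guarantees dose completion; termination trims
the final interval so the delivered dose equals the prescription exactly).

The temperature the controller sees is read 0.24 cm up the cooled wall
from the insulation–electrode junction.  This probe offset is the one
fitted constant of the delivery model: the physical fiberoptic sensor is
mounted within the cooled applicator body at the interface, so it reads a
coolant-moderated interface temperature, whereas the tissue node exactly
at the junction sits on the corner field singularity and would saturate
the controller at its floor.  The offset was set once so the simulated
0.5 cm treatment lands inside the observed 473 ± 83 s and then frozen;
with it, durations fall strictly with exposure length (494, 298, 256,
230 s at the resolutions of `analysis/04`) — the same mechanism the study
reports: the farther the sensor from the hot tip, the higher the sustained
rate — and every run holds 45 ± 1 °C with zero overshoot.

## Synthetic cohort

Replicate ablation volumes and treatment times are drawn per group from
truncated-normal distributions with exactly the published n / mean / SD
(9, 6, 7, 5 replicates).  Truncation at zero is deliberate: the 0.5 cm
volume group (7.95 ± 3.74) has ~1.7% plain-normal mass below zero; the
induced mean shift (+0.16 cm³ for that group, negligible elsewhere) is
computable via `truncation_bias` and accounted for in the recovery tests.
Volumes and times are independent by default (no joint distribution is
published); a correlation knob uses jointly truncated bivariate normals.
The generator emulates between-replicate scatter only — it does not model
CT segmentation error separately (absorbed in the SD) nor the study's
exclusion of ablations crossing lobe boundaries, which would induce
informative censoring not recoverable from summaries.  Passing recovery
tests therefore demonstrate the calibration pipeline's statistical
behaviour, not in-vivo fidelity.

Per-replicate threshold recovery is unbiased up to a convexity term: the
volume→threshold map is convex, so group-mean thresholds averaged over
seeds sit slightly above the threshold implied by the mean volume, the
more so the larger the group's volume CV (≈46% for the 1.0 cm group).

## Problem sizes and numerical settings

Threshold calibrations (and `scripts/acceptance.py`) run the full study
meshing: 100 µm near size, 5.14 mm far size, two 250 V/cm refinement
passes (~110k–265k elements, ~20 s total for all four geometries).
Analysis scripts 01–03 use a 200 µm near size (thresholds agree within
1%); treatment simulations (script 04, tests) use 400 µm with one
refinement pass and dt = 0.1 s — durations and iso-volumes there are
stated at those resolutions.  Tie-breaks and degenerate inputs: volumes
outside a curve's range are flagged with the nearest endpoint rather than
extrapolated; zero-SD cohort groups return the mean exactly; a zero
prescribed dose is zero pulses and an immediate no-op treatment.

## Known limitations

- Absolute lethal thresholds carry the ~0.8 field-scale offset discussed
  above; orderings and ratios are the robust outputs.
- Thermal iso-volume magnitudes assume conduction only; with the true (but
  unpublished) perfusion and dielectric details they would shrink
  substantially.
- The controller is behaviourally, not numerically, matched to the device:
  gains, update interval and any hysteresis of the real algorithm are
  unpublished.
- The trocar tip is a flat disc; tip curvature controls the local field
  singularity, though its effect on ≥400 V/cm iso-volumes is small.
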