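# brainmbm

Fast estimation of brain deformation from head rotational kinematics,
for injury biomechanics research, helmet design iteration, and
interpretation of wearable head-sensor data.

Finite element head models predict intracranial strain well but need
hours per impact.  `brainmbm` implements the rapid alternative: a planar
multibody model (MBM) — ~20 point masses per anatomic plane connected by
springs and stiffness-proportional dampers, driven by a rigid skull
rotation about the mass centroid — plus a machine-learning correction
layer that maps the MBM output and the peak loading kinematics onto
reference-quality strain.  A full single-plane simulation takes a
fraction of a second.

The pipeline, per plane:

1. **Mesh** (`geometry`): grid of point masses clipped to an outline,
   4-neighbour springs, skull drive ring, triangular strain elements.
2. **Loading** (`kinematics`): haversine pulses
   a(t) = α_p sin²(πt/T), T = 2Δω/α_p, or measured 3-axis CSV traces
   (truncated at 60 ms).
3. **Dynamics** (`dynamics`): M·a = F_elastic + F_damping with
   F = Σᵢ Kᵢδᵢêᵢ + β Σᵢ Kᵢδ̇ᵢêᵢ, integrated by Dormand–Prince RK5(4).
4. **Strain** (`strain`): per-element Green strain from side-length
   changes (ds² − ds₀² = 2E_ij da_i da_j), Hencky strain
   E_H = ½ log(I + 2E_G), maximum principal strain (MPS) as the larger
   eigenvalue; summarised as the 95th percentile over elements of the
   per-element time peak (MPS95); multi-axis loading combined as
   MPS_res = √(MPS_x² + MPS_y² + MPS_z²).
5. **Calibration** (`calibration`): per-subdomain random search of
   spring stiffness (250 draws over 2–70 kN/m, best-decile average,
   15 loading conditions) against reference displacements, then a
   damping-factor sweep (0–1 %).
6. **Correction** (`ml_correction`): LSBoost — 30 gradient-boosted
   regression trees — mapping (MBM MPS95, peak angular velocity, peak
   angular acceleration) to reference MPS95, whole-plane and
   per-element, with a seeded 60/40 split and fivefold CV.

Because the original reference data come from a proprietary FE head
model, the `surrogate` module generates structurally equivalent
reference datasets (a refined, heterogeneous-stiffness mesh on the same
outline) so calibration and correction are fully testable; see
`docs/methods.md` for what the surrogate does and does not emulate.

## Worked example

```python
import numpy as np
from brainmbm import (build_mesh, DEFAULT_PLANE_SPECS, generate_haversine,
                      simulate, SimulationConfig, mps_field, percentile_mps)

mesh = build_mesh(DEFAULT_PLANE_SPECS["coronal"])
print(f"coronal mesh: {mesh.n_brain} brain nodes, "
      f"{len(mesh.springs)} springs, {len(mesh.triangles)} triangles")

# A 5 krad/s^2, 30 rad/s haversine impact (12 ms pulse, 60 ms window).
trace = generate_haversine(peak_accel=5000.0, delta_velocity=30.0, pad_to=0.060)

result = simulate(mesh, trace, SimulationConfig(damping_factor=0.0015))
field = mps_field(result, mesh)
print(f"95th-percentile MPS: {percentile_mps(field):.4f}")
print(f"max element MPS:     {field.peak_mps.max():.4f} "
      f"at t = {field.time_of_peak[np.argmax(field.peak_mps)]*1000:.1f} ms")
```

prints

```
coronal mesh: 20 brain nodes, 38 springs, 25 triangles
95th-percentile MPS: 0.3165
max element MPS:     0.3165 at t = 44.0 ms
```

A 30 rad/s rotation is a severe (potentially concussive) exposure, and
the ~0.32 peak true strain the uncalibrated model reports is in the
right physical regime; peak strain occurs well after the 12 ms pulse,
during the ring-down.  The `brainmbm` command-line tool wraps the same
steps (`brainmbm build-mesh`, `make-surrogate`, `calibrate`, `simulate`,
`strain`, `train-ml`, `predict`, `evaluate`) with JSON manifests for
reproducibility; run `brainmbm --help`.

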