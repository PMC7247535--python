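# Methods

## The model

`brainmbm` estimates brain deformation during head impact from rotational
kinematics alone, in seconds rather than the hours a finite element (FE)
head model needs.  The brain's cross-section in one anatomic plane
(coronal, sagittal or axial) is lumped into ~20 point masses on a square
grid clipped to a closed outline.  Neighbouring masses are connected by
linear springs with stiffness-proportional dampers; a ring of massless
skull nodes on the outline is kinematically driven through a rigid
rotation about the mass centroid and drags the interior along through
one spring per skull node.  For a spring with stiffness K (N/m),
elongation δ and elongation rate δ̇, the force on each endpoint is

    F = K δ ê + β K δ̇ ê ,

so the damping factor β carries units of seconds; the shipped default
β = 0.0015 is the "0.15 %" convention.  Newton's second law per brain
node gives a small ODE system integrated with the Dormand–Prince
embedded Runge–Kutta 5(4) scheme (`scipy.integrate.solve_ivp`,
`RK45`), from the reference configuration at rest, with relative/absolute
tolerances 1e-6/1e-9 and solutions sampled on a 0.5 ms output grid.

Rotation is applied about the mass centroid because the lumped network,
lacking a skull boundary contact, would otherwise translate freely under
linear acceleration — motion the brain does not actually exhibit.

### Spring directions: two conventions

The force direction ê is ambiguous in a lumped model and both readings
are implemented:

* `deformed` (default): δ = |current separation| − rest length, ê along
  the current separation.  This is geometrically exact; in particular a
  rigid rotation of the whole mesh is an equilibrium, which matters
  because study-range pulses rotate the head by up to ~3 rad
  (θ = Δω²/α for a haversine pulse).  A linearised model cannot follow
  such rotations and would report O(1) spurious strain.
* `reference`: fully linearised about the reference configuration —
  ê fixed at its reference orientation and δ the projection of the
  relative displacement onto it.  This is the constant-matrix
  small-displacement form; the response is exactly linear in the
  prescribed skull-displacement input, which the verification suite
  exploits (superposition, analytic oscillator checks).

### Strain

Triads of adjacent brain nodes form triangular elements.  For each
element the Green strain follows from the squared side-length changes
(equivalently E = (FᵀF − I)/2 with F the triangle's affine deformation
gradient — the implementation computes both and requires agreement), the
Hencky (true) strain is E_H = ½ log(I + 2E_G) via eigendecomposition, and
the maximum principal strain (MPS) is the larger Hencky eigenvalue, i.e.
the log of the larger principal stretch.  A plane-level summary takes,
per element, the peak MPS over time, then the 95th percentile over
elements (linear-interpolation percentile), the common injury-risk
metric.  Simultaneous 3-axis loading is handled per plane and combined
as the Euclidean resultant √(MPS_x² + MPS_y² + MPS_z²); relative errors
between predictions are |pred − ref|/ref × 100 %.

Strain is evaluated on the fixed output grid, not on the integrator's
adaptive steps, so results do not depend on step selection.

## Loading

Idealised impacts are haversine pulses a(t) = α_p sin²(πt/T) with
duration T = 2Δω/α_p, spanning peak accelerations 0.1–15 krad/s² and
velocity changes 1–100 rad/s.  The study grid takes 17 log-spaced values
per variable (the ranges span two decades; spacing is a package choice);
pairs whose duration exceeds the 60 ms analysis window are flagged
excluded rather than dropped so exclusion counts can be reported.
Measured 3-axis traces arrive as CSV (`time_s` plus `wx_rads…` or
`ax_rads2…` columns; the unit suffix is mandatory), are resampled to a
uniform grid, differentiated/integrated as needed, and truncated at
60 ms before simulation.

## Surrogate reference data

The stiffness calibration and the ML correction both require a richer
ground truth than the coarse model.  The original reference — a
proprietary 3-D FE head model — cannot be shipped, so the `surrogate`
module generates a structurally analogous stand-in: the same outline
meshed at 1/`refinement` of the coarse spacing, with spring stiffnesses
sampled from a smooth heterogeneous field (three seeded radial bumps on
a 15 kN/m base, clipped to 2–70 kN/m).  Fine displacement solutions are
interpolated to the coarse node positions (inverse-distance over the 3
nearest fine nodes) and perturbed with seeded Gaussian noise (default
1e-4 m, about 1 % of typical excursions).  What this surrogate preserves
is the *relationship* the downstream methods consume: a reference that
shares the coarse model's physics but has finer resolution and
heterogeneous properties, producing a systematic, kinematics-dependent
discrepancy.  What it does not emulate: real anatomy, CSF and
ventricles, nonlinear viscoelastic tissue, or 3-D coupling between
planes — so passing tests demonstrate that the algorithms work as
designed, not that the shipped defaults reproduce any particular FE
model's strains.

With `refinement = 1`, zero noise and a shared stiffness field the
surrogate reproduces the coarse model exactly; this self-consistent mode
underpins the parameter-recovery experiments.

## Calibration

Each brain node defines a subdomain: its incident springs (1–4) are free
while all adjacent nodes are position-driven along reference
trajectories (skull neighbours are reconstructed analytically from the
condition label).  Per loading condition, 250 stiffness vectors are
drawn uniformly over 2000–70000 N/m per spring (seeded), the central
node is integrated for each draw — all 250 draws as one batched ODE
system — and scored by position RMSE pooled over both components and all
samples.  The estimate is the mean over the best decile (25 draws; ties
broken by draw index).  Springs shared by two subdomains average their
two estimates; the final stiffness averages over 15 loading conditions
(5 velocity values × 3 acceleration values linearly spanning 10–50 rad/s
and 0.5–7.9 krad/s²).  Some of these pulses last up to 0.2 s, so
calibration references are simulated over the full pulse plus a 20 ms
settle margin rather than the 60 ms cap used for measured traces.

Damping is selected afterwards by sweeping β over 0–1 % in 0.05 % steps
with full-mesh simulations of every reference condition, taking the β
minimising the median pooled RMSE, and reporting the plateau of βs
within 5 % of that minimum (the equivalence band).

Recovery behaviour is verified on a self-consistent reference (12-node
plane, known smooth stiffness field): the suite checks that the median
per-spring stiffness error stays within 15 % noiseless and 25 % with
1e-4 m displacement noise, and that the damping sweep returns the β
used to generate the reference to within one grid step.  Top-decile
averaging over a 4-D uniform search is intrinsically dispersed —
individual springs can sit on flat directions of the RMSE landscape —
which is why the 15-condition averaging matters.

## ML correction

The correction layer is least-squares gradient boosting
(`sklearn.ensemble.GradientBoostingRegressor`) with exactly 30 trees,
learning rate 0.1, maximum depth 4 and minimum leaf size 3 (fixed,
recorded in model metadata).  Features are the coarse-model MPS95, peak
angular velocity and peak angular acceleration, per plane, in seven
canonical combinations (one to three base features × up to three
planes, three to nine columns).  Training uses a seeded random 60/40
train/test split; validation metrics come from fivefold cross-validation
on the training portion; RMSE, MAE and R² are reported per split.

Tree ensembles cannot predict outside the span of their training
targets, so inputs outside the training feature range are *flagged*,
never altered or refused — the characteristic "floor" at the low end of
the training targets is left visible.  Regional prediction trains one
model per triangular element with the same whole-plane features and the
element's neighbourhood reference MPS as target (mean fine-element peak
MPS within a disc capturing 10 % of the element's area); elements are
excluded when no fine element falls in the disc or when the element
centroid lies in a declared nonbrain region (none exist for the default
ellipse; the rule is exercised with synthetic holes).

On the shipped benchmark (141 conditions after the 60 ms cap,
refinement-2 heterogeneous reference, default noise), the raw coarse
model's held-out mean relative error is a few tens of percent and the
corrected model's a few percent — the correction removes most of the
systematic discrepancy, as `scripts/acceptance.py` recomputes.

## Numerical and design choices

* Node masses are Voronoi-cell areas clipped to the outline, scaled to
  the plane's total mass (default 1 kg, configurable) — Voronoi cells
  tile the outline, so mass is conserved exactly.  Brain nodes sit at
  grid-cell centres; default spacings put 19–20 nodes in each default
  ellipse (coronal 0.070×0.065 m, sagittal 0.085×0.065 m, axial
  0.085×0.070 m — parametric placeholders, not anatomy).
* Eight skull nodes per plane, equally spaced by arc length; rest
  lengths equal reference separations (zero pre-strain); no diagonal
  springs (four springs per interior node).
* Uncalibrated springs default to 12 kN/m, near the log-midpoint of the
  search range.
* Degenerate inputs raise typed errors: coincident spring endpoints in
  deformed mode, non-positive-definite deformations, empty strain
  fields, non-monotone time vectors, sub-resolved pulses (dt ≥ T/20).
* All stochastic steps (stiffness field, noise, stiffness draws, ML
  splits) key a `numpy` Generator on explicit seeds; same seed, same
  bytes.

## Known limitations

* A 4-neighbour axial-spring lattice has zero-energy shear modes: shear
  stiffness is geometric (tension-limited), so even infinitely stiff
  springs leave a residual shear response — the model's deformation
  under rotation is partly carried by these soft modes.  This is a
  property of the spring topology itself, shared with the formulation
  the model implements.
* Planes are independent; multi-axis loading is combined only through
  the resultant, ignoring inter-plane mechanical coupling.
* Linear springs and dampers: no nonlinear or viscoelastic tissue
  behaviour.
* The ML layer is only trustworthy inside its training range; the
  out-of-range flags exist precisely because the floor behaviour
  otherwise masks extrapolation failure.

## Problem sizes

The test suite and acceptance script size their experiments for a
single-CPU desk run: a 12-node reduced plane for calibration recovery
(15 conditions × 250 draws per node), a 14×14 pulse grid (141 retained
conditions) with a refinement-2 reference (~80 fine nodes) for the ML
benchmark, and the full 21-point damping sweep.  These sizes are the
package's defaults for its own verification; all are parameters.
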