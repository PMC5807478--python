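# Methods

This note documents the models, numerical choices and limitations of the
`brainshift` package in one place. Empirical numbers quoted here are the
ones the test suite and `scripts/acceptance.py` compute.

## Constitutive model

The gel skeleton is a one-term Ogden solid in principal stretches with a
volumetric penalty `(1/D)(J-1)^2`; `D = 3(1-2ν)/(μ0(1+ν)) = 2/K` links
the compressibility parameter to the Poisson ratio of the drained solid
matrix (ν = 0.35 for the biphasic cards, giving D = 0.84e-3 1/Pa at
μ0 = 794.36 Pa). `D = 0` denotes the incompressible solid of the
monophasic HVE card.

Viscoelasticity is quasi-linear: the deviatoric elastic stress history
is convolved with the normalized Prony relaxation function
`g_R(t) = 1 - Σ g_i (1 - exp(-t/τ_i))`. The hereditary integral is
evaluated with one exponential internal variable per Prony term,

    h_i(t+Δ) = e^{-Δ/τ_i} h_i(t) + (τ_i/Δ)(1 - e^{-Δ/τ_i}) Δx,

which is exact for histories that are piecewise linear between samples;
a nonzero initial value is treated as a step at t = 0. The O(N²) direct
convolution exists only as a test oracle. With the published series
(g = 0.13, 0.32; τ = 14, 333 s) the long-term shear modulus is
0.55 μ0 = 436.9 Pa.

Sign conventions: tension positive, compression negative (α < 0 for the
gel, so compression stiffens); z increases upward from the column base;
excess pore pressure is measured relative to the external fluid column.

## Characterization fits

`simulate_compression_test` reproduces the unconfined ramp-and-hold
protocol (12 mm × 7 mm cylinder, 8.3 mm/s to 30% of height = 0.356 true
strain, 500 s hold) assuming ideal lubrication and a fully drained,
incompressible uniaxial-stress state; the stress is the quasi-linear
viscoelastic scaling of the Ogden uniaxial response. Nominal stress
(force over undeformed area) versus true strain is the fitted measure —
the standard choice for unconfined gel tests; the hold phase relaxes
toward `(1 - Σ g_i)` of the peak deviatoric stress.

Fitting is sequential, as in the experiment: `fit_ogden` least-squares
(μ0, α) on the loading ramp over a fixed multi-start grid of α values
(the small-strain response fixes only E = 3 μ0, so |true strain| below
0.05 flags α as unidentifiable); `fit_prony` then fits `g_R` to the
hold stress normalized by its peak, removing the μ0 coupling, under the
constraints g_i ≥ 0, Σ g_i < 1, τ_i > 0 (box-bounded least squares with
an SLSQP fallback when the simplex constraint activates; τ returned
ascending). Because the ramp (0.25 s) is much shorter than min τ
(14 s), the viscous stiffening absorbed into the "instantaneous" μ0 is
below 0.1% for the published parameters; recovery on noiseless
synthetic data is within 0.05% (μ0), 0.15% (α), ±0.001 (g) and well
inside the 1%/2%/±0.01/5% acceptance tolerances, and stays inside
5%/10% tolerances with 75 µN force noise.

## Reduced shift geometry

The published study solves a 94k-element 3D contact problem; here the
smallest setting in which all three formulations and the drainage
schedule are distinguishable is used: a vertical column (default 10 cm,
41 nodes) on a rigid impermeable base, loaded by its own buoyant
weight. The fluid level maps linearly from the remaining CSF volume
(level fraction v/220). Submerged material weighs (ρ_s − ρ_w)g =
147.2 N/m³; emerged material weighs ρ_s g = 9959 N/m³ (ρ_s = 1015,
ρ_w = 1000 kg/m³, g = 9.812 m/s²).

Two lateral confinement modes:

* **oedometer** (λ_lateral = 1) for the Terzaghi benchmark;
* **uniaxial_stress** for the shift model: each slice is laterally
  free, and the element lateral stretch solves the zero total lateral
  traction condition `dU/dλ_l = p·J/λ_l`. Including the pore pressure
  in this condition is essential: in the undrained limit it recovers the
  isochoric response instead of locking. The Prony scaling is applied
  to the axial deviatoric stress after the lateral elimination, not
  inside it — a deliberate reduced-model simplification (the lateral
  kinematics use the rate-independent stress). With g_i = 0 the PHVE
  path is bit-identical to PHE by construction.

Drainage steps follow the protocol: per level, 0.1 s of gravity /
buoyancy equilibration (loads ramped linearly across the sub-step's
increments), 10 s with p = 0 imposed at emerged nodes (free drainage),
then a 60 s hold. Nodes once drained stay drained (the bath never
rises; `run_shift` rejects non-monotone schedules). Loss percentages
are computed exactly — 18.2, 31.8, 45.5, 59.1% — rather than forcing
the commonly quoted 18/32/46/60% rounding, which is inconsistent for
the last two steps.

## Coupled solver numerics

Linear finite elements for both displacement and pressure on the 1D
column; backward Euler in time; monolithic Newton with an analytically
assembled Jacobian whose element tangents (dP/dλ, dP/dp, dJ/dλ, dJ/dp)
come from central differences of the vectorized element response.
Convergence demands a residual below 1e-8 of the load/storage scale per
step; a non-convergent step is bisected, up to 10 times, before a hard
error. Fluid and solid constituents are incompressible, so skeleton
volume change equals fluid efflux; the cumulative drained outflow is
accounted via the reaction of the pressure rows at Dirichlet nodes and
matches the column volume change to ~1e-10 relative (discrete
conservation).

Two numerical caveats are intentional and documented:

* at the published permeability (k = 1.57e-9 m/s) the storage term
  (J − J_prev)/Δt cannot be resolved below the roundoff of J ≈ 1 in
  double precision, so the Newton tolerance carries an explicit
  machine-epsilon floor (~1e3·eps·h/Δt);
* equal-order interpolation leaves a pressure checkerboard mode in the
  *strictly* undrained oedometer limit (k → 0 with a drained node);
  element-mean pressures remain correct, and the uniaxial-stress mode
  used by the shift model is free of it (its storage term depends on
  pressure through the lateral kinematics).

Validation: against the Terzaghi series (c_v = kM/γ_w, constrained
modulus M = K + 4μ0/3 = 3442 Pa) the 100-node oedometer run keeps the
pore-pressure error below 0.3% of the initial excess pressure at
dimensionless times 0.05–0.5; the series itself agrees with an
independent finite-difference solve to <0.5%. Halving Δt and element
size changes the settlement of a two-level drainage run by ~0.1%; the
default 41-node, five-level run still carries ≈1% discretization error
at the deepest drainage level (acceptable for the formulation
comparison, which shows differences an order of magnitude larger).

The emergent Poisson behaviour of the biphasic cards spans the stated
0.5 → 0.35 range: instantaneous (undrained) response is isochoric,
ν_eff ≈ 0.5, while the drained state reflects the solid-matrix
ν = 0.35 — this is a consequence of the model, not an imposed drift.

## Synthetic data

The generators state the instruments, not tunable noise dials: the
compression rig quantizes force to 75 µN (with Gaussian noise at that
scale added first) and displacement to 0.1 µm; marker observations are
snapped to the 1 mm isotropic voxel grid and then perturbed uniformly
within ±0.5 mm per axis (the stated uncertainty read as a bound; a
Gaussian mode of the same scale sits behind a flag). Observed
displacements are referenced to the first (100% fluid) acquisition, as
in the scans. The default layout reduces the 18 phantom markers (8
superficial, internal rows of 3/4/3) to column elevations chosen to
span superficial and deep positions proportionally; the true 3D marker
coordinates are not reproduced (geometry out of scope).

A green end-to-end test therefore establishes that the pipeline's
statistics respect the stated instrument error structure on a 1D
trajectory — not that the reduced model reproduces the phantom's 3D
deformation field, which would require the non-public MRI data and the
full contact model.

## Error metrics

EPE is the Euclidean norm of the vector difference; AE the plain 3D
angle (undefined at zero displacement — flagged, excluded from
averages and counted; the optical-flow "augmented" variant, appending a
unit component, is available behind a flag); ME the signed magnitude
difference |u_meas| − |u_sim|, with the signed mean as headline and
min/max taken on absolute values in the step tables. Summaries report
avg, sem = sd/√n, and min/max with marker ids (ties to the lowest id).
Model comparison uses the standard unpaired pooled-variance two-sample
t test (paired variant available).

## Known limitations

* 1D kinematics: no falx/skull contact, no friction, no lateral marker
  displacement components — AE across formulations degenerates because
  all simulated vectors are collinear.
* The lateral-traction elimination uses the rate-independent stress;
  lateral creep is not modelled.
* Permeability is constant (no void-ratio dependence), consistent with
  the single published k.
* Fits assume ideal lubrication (no barreling) and isothermal
  conditions.
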