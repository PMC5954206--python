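# Methods

## Problem

After a Stanford type-B aortic dissection, an intimal flap separates the
aorta into a true lumen (TL) and a false lumen (FL). Endovascular repair
presses the flap back against the FL wall ("re-apposition") with a balloon or
stent. The quantity this package computes is the *re-apposition pressure*:
the average radial contact pressure a rigid expansion member must exert, in
excess of the static aortic pressure, to achieve full flap re-apposition —
as a function of aortic pressure (70–140 mmHg) and region (mid vs distal
descending thoracic aorta), for porcine tissue.

## Constitutive model

Each tissue layer (intimal flap, FL wall, TL wall) is a Gasser–Ogden–
Holzapfel (GOH) material: an incompressible neo-Hookean matrix plus two
symmetric dispersed collagen-fiber families at ±α to the circumferential
axis,

    Ψ = C10 (I1 − 3) + k1/(2 k2) Σ_{±α} [exp(k2 E²) − 1],
    E = κ (I1 − 3) + (1 − 3κ)(I4 − 1),

with dispersion κ ∈ [0, 1/3] (κ = 1/3 isotropic) and a tension-only fiber
switch (E > 0). α is measured from the circumferential axis — the convention
is a single switch in the code, since published parameter tables do not
always state it. Parameters for nine per-pig flap samples and the three wall
layers are shipped as CSV tables (`reappose.load_flap_parameters()`,
`load_wall_parameters()`).

Three evaluation paths share the same scalar fiber response:

* **plane-stress biaxial** (incompressible, σ_rr = 0) — the quantity measured
  in planar biaxial testing and used as the fitting target;
* **plane-strain point kernel** — compressible form with a `−2 C10 ln J`
  correction (stress-free reference) plus a volumetric penalty
  U = K/2 (J−1)², K = 10⁴·C10 by default; used by the finite-element solver
  with an analytically derived consistent tangent (verified against finite
  differences to 1e−4 relative);
* **energy density** for work/energy audits.

## Parameter estimation

`fit_goh` minimizes the unweighted sum of squared Cauchy-stress residuals
over both in-plane components by Nelder–Mead (the method used for the
original characterization), with

* bounds enforced by smooth reparameterization (log for C10, k1, k2; scaled
  logistic for α and κ), since plain Nelder–Mead is unconstrained;
* multi-start (default 8 restarts: one data-informed start from the
  low-stretch secant stiffness plus Latin-hypercube points, seeded);
* repeated Nelder–Mead polish at the incumbent until stagnation.

Joint identifiability of (α, κ) from two-axis data is weak; the contract is
recovery in *stress space* (noise-free round trips reach SSE/record ≈ 1e−16
Pa²). At 2 % multiplicative noise, medians of the c10 and k1 relative errors
over 20 replicates are ~1 % and ~6 %.

## Synthetic biaxial data

The generator emulates displacement-controlled two-axis ramps: three
stretch-ratio protocols (1:1, 1:0.75, 0.75:1), 15 levels each up to stretch
1.30, stresses = model stresses × (1 + cv·z) with seeded standard-normal z.
Multiplicative noise is used because stress magnitudes span orders of
magnitude along a ramp. It does *not* emulate preconditioning, shear, rate
effects, or mounting artifacts — so fit tests show estimator correctness
under the model's own assumptions, not robustness to real experimental
artifacts.

## Geometry

The unloaded cross-section is an annulus (inner radius R) whose wall is
split over the dissected sector (flap fraction f = 0.55 of the circumference
by default, configurable within the 50–60 % band) into an inner flap layer
and an outer FL-wall layer; the remainder is the TL wall. The flap lies on
its original mural arc in zero-gap apposition with the FL wall; all layers
merge at the tear edges. Layer thicknesses come from the material tables.
R is *not* a measured quantity: defaults are 9 mm (mid) and 7 mm (distal)
inner radius, typical porcine descending-thoracic values, and every result
record carries the value used.

Meshing is structured polar with bilinear quadrilaterals: at least two
element rows through the flap (bending), duplicated interface nodes across
the flap/FL-wall contact pair, oriented boundary-edge sets, and a short
geometric transition where the wall thickness changes at the tear edges.

## Cross-section solver

The paper-scale 3D prismatic model with axially constrained ends is reduced
to a 2D plane-strain cross-section (out-of-plane stretch 1): all reported
outputs (radial pressure, diameter) are cross-sectional. Elements use a
mean-dilatation (element-averaged J) treatment of the volumetric penalty to
avoid locking. Loads are follower pressures; contact is frictionless penalty
contact on three pairs (member–flap, member–TL wall, flap–FL wall) with a
C1-regularized penalty law (quadratic below a 0.5 µm smoothing depth) and
penalty stiffness 100 × (stiffest μ)/h. Contact forces use deformed
tributary lengths so nodal penalty forces are traction-consistent on the
stretched surface. The half model fixes u_x on the symmetry plane; the
remaining in-plane rigid translation is removed by a mean-u_y Lagrange
multiplier, which also carries the net member force the way the 3D vessel's
axial supports would.

### Two-step protocol

1. **Pressurize** to the target static pressure, applied to the TL *and* FL
   luminal surfaces (the bench applied static pressure to the whole vessel;
   the FL communicates through the entry/re-entry tears). A TL-only mode is
   retained as a configuration switch — under TL-only pressure the flap
   self-apposes in step 1 and the re-apposition pressure degenerates to ~0.
2. **Expand** the rigid member until every flap outer node is within
   g_tol = 1 % of the flap thickness from the FL wall ("full re-apposition"),
   then report the tributary-weighted average member contact pressure in
   mmHg and the final mean luminal diameter.

### Numerical choices that matter

* **Drape bias.** With balanced lumen pressures the slack flap's position is
  indeterminate (many bending equilibria). A small inward bias pressure
  (default 0.5 mmHg) on the flap's FL face selects the taut drape branch and
  makes results path- and mesh-consistent. The bias is part of the defined
  loading of every reported state; it contributes of order 1 % of the
  measured pressures. Setting `flap_drape_bias_mmhg = 0` recovers the
  unbiased (multi-stable) problem.
* **Damped continuation.** Member-radius increments are solved with small
  grounded springs toward the previous state (1e−5 × contact penalty,
  escalated through snap-through radii), then *measured* states are polished
  free of damping. A tight trust region (50 µm Newton-step cap) lets the
  polish grind through contact-transition cascades.
* **Terminal interpolation.** Near closure dq/dr ≈ 150 mmHg/mm, so the
  reported pressure/diameter are interpolated to gap = g_tol between the two
  polished bracket states instead of being read at a bisected radius; this
  removed most of the mesh-to-mesh noise (mesh convergence ≈ 1 % between
  0.3 mm and 0.2 mm elements at 100 mmHg, mid region).
* **Acceptance of chatter.** Penalty contact with ~10² active nodes has a
  practical residual floor; measured equilibria are accepted at relative
  force residual ≤ 5e−3 and flagged unconverged above it.
* Newton tolerance 1e−6 relative (projected residual), follower-load and
  contact stiffness included in the tangent, adaptive substepping on
  divergence, deterministic throughout (identical inputs → identical
  results).

## Studies

`run_sweep` runs the 8-point pressure ladder warm-started: each point's
fully apposed terminal state is carried to the next pressure (ramp with the
member held, short member adjustment). `run_sensitivity` mirrors the bench
design: Sample #1 baseline, wall variants (seeded ±20 % perturbations of c10
and k1 of the TL and FL walls, the bench study's appendix variant tables not
being available in the main text), and a flap arm that swaps in the other
pigs' flap parameters, at 70/100/140 mmHg. `run_mesh_convergence` compares
element sizes {h, h/1.5, h/2}.

### Problem sizes used by the test suite

The shipped tests run desk-scale versions of the studies: mid-region sweeps
at 0.6 mm elements with 0.45 mm member increments (row 1 on the full
8-point ladder, rows 2–5 on {70,100,140}), distal sweeps at 0.45 mm
elements with 0.3 mm increments on reduced ladders (row 1 at {70,90},
rows 2–4 at {70} only), wall-variant arms at a single pressure point per
region, and the mesh-convergence check at 0.6 vs 0.45 mm. The
acceptance script (`scripts/acceptance.py`) runs the mesh-convergence study
at the full 0.3 vs 0.2 mm sizes.

## Known limitations

* **Distal region at high pressure.** The distal FL wall parameters give
  almost no circumferential fiber recruitment at out-of-plane stretch 1
  (fibers at 66.5°, κ = 0), so its thin-wall inflation limit
  p_max ≈ 2·C10·t/R is only ~180–215 mmHg at the default 14 mm distal
  diameter. Above ~90–110 mmHg the distal model dilates toward that limit:
  the closure radius moves ~1 mm per 10 mmHg, results become
  ill-conditioned, and the very stiff distal flap #2 cannot stretch to the
  dilated wall at all (flagged unconverged). In this regime the model also
  predicts distal re-apposition pressures *above* mid ones — opposite to the
  bench observation — which we attribute to the unknown true distal geometry
  (vessel radius, per-pig flap geometry) rather than to the method.
* **No diameter-curve flattening.** With near-axial fiber angles (TL wall
  87.1°) and out-of-plane stretch fixed at 1, hoop-direction collagen
  recruitment is minimal, so the computed pressure–diameter curve does not
  flatten above ~110 mmHg; axial prestretch (not modeled) would engage these
  fibers in reality.
* Flap residual stress/post-dissection shortening is not modeled (stress-free
  reference configuration); no viscoelasticity, no fluid dynamics, no 3D
  spiral or multi-re-entry anatomies; the expansion member is a rigid circle
  (no folded-balloon kinematics).
* The measured radial pressure includes the 0.5 mmHg drape-bias load and a
  ≤ 0.5 % force-residual tolerance; magnitudes are also sensitive to the
  strictness of the 1 %-of-thickness full-apposition criterion (an
  ultrasound-confirmed bench criterion is far looser).
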