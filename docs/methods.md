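# Methods

## Scope and model idea

`thromboflow` predicts where and how fast thrombus forms in 2-D idealised
aortic-dissection phantoms and in a backward-facing-step (BFS) channel.
The model is hemodynamics-based: the coagulation cascade is collapsed into
a single lumped coagulant species, and growth is gated on three local
quantities that are cheap to compute from the flow — the cycle-averaged
shear rate, the relative residence time (RRT), and the activated-platelet
level.  The process is deliberately accelerated so that a thrombus that
would take weeks in vivo develops within 20 cardiac cycles (phantoms) or
50 s (BFS); the *location and extent* of thrombus, not its physical growth
rate, are the predictions of interest.

## Governing equations

Flow: incompressible Navier–Stokes with variable viscosity and the clot
momentum sink `S_M = k_M sat(BP; BP_t) u`, `k_M = 1e7 kg/m^3/s`, where
`sat(x; x_t) = x^2/(x^2+x_t^2)`.  Viscosity is Quemada shear-thinning,
amplified by `(1 + 100 sat(BP; BP_t))` inside clots.

Species (per fluid cell):

* `RT`: advected age tracer with unit source, `D_RT = 1.14e-11 m^2/s`,
  zero at the inlet.  `RRT = (window increase of RT)/window`.
* `RP`, `AP`: platelet transport with `D_p = D_pt + alpha*gdot`
  (`D_pt = 1.6e-13 m^2/s`, `alpha = 7e-13 m^2`), activation pair
  `r1 = k1 [AP][RP]` (`k1 = 0.5 1/s`) and `r2 = k2_eff [RP] RRT`.
* `C`: no advection; diffusion with `phi_g D_c` and source
  `k_c sat(BP;BP_t) phi_g` (`k_c = 200 nmol/L/s`); Dirichlet
  `C = 100 nmol/L` at wall faces whose window-averaged shear rate is below
  the wall threshold, `C = 0` at other walls, zero-flux on the aortic arch.
* `BP`: immobile, `dBP/dt = k_BP sat(C;C_t) sat(RRT;RRT_t) phi_g [AP]`
  with `k_BP = 10 nmol/L/s`, `C_t = 10`, `BP_t = 20` (both nmol/L,
  interpreted from the printed "nmol"), `RRT_t = 0.9`.

`phi_g = g_t^2/(gbar^2+g_t^2)` with the bulk threshold `g_t = 100 1/s`
(pulsatile phantoms) or `10 1/s` (steady BFS); the wall threshold is
`90 1/s` and `1 1/s` respectively.  The 10,000 1/s activation shear rate is
reported as a diagnostic flag (peak tear shear exceeding it), not a runtime
switch, since the 5 % background activation is applied in all scenarios.

### Parameter interpretation decided here

* **k2.** The printed `k2 = 1.2e-8 mL/platelets/s` multiplies normalised
  concentrations in this code as `k2_eff = k2 * AP_ref = 0.15 1/s`
  (`AP_ref = 1.25e7 plt/mL`), mirroring the normalisation convention that
  the source uses for `k_BP`.  Config-exposed.
* **Platelet conservation.** With RP and AP normalised by different
  references (2.5e8 and 1.25e7 plt/mL), conservation of physical platelet
  number requires `S_AP = +20 (r1+r2)` against `S_RP = -(r1+r2)`.  The
  reaction update is semi-implicit in RP and transfers exactly
  `20 x (RP loss)` to AP, so the linear invariant `RP + AP/20` holds to
  machine precision in closed domains.  A consequence worth knowing: full
  conversion drives normalised AP toward 21 in stagnant pockets, which
  (by design of the accelerated kinetics) makes saturated regions clot
  within seconds once gated on.
* **D_c (calibrated).** The coagulant base diffusivity is not a printed
  constant; it controls how fast the clot front spreads (a reaction-
  diffusion front, speed ~ sqrt(D_c * k)).  The default `D_c = 1e-8 m^2/s`
  was calibrated once so that the BFS thrombus approaches its asymptotic
  length within the 50 s window; it is reported in every run log.
* **Adhesion flux.** The first-order platelet adhesion coefficient at
  low-shear walls is not printed; the default `5e-5 m/s` keeps wall
  depletion below ~5 % of bulk concentration per cycle.
* **Quemada coefficients** are not printed in the source material; the
  defaults (`k0 = 4.33`, `kinf = 2.07`, `gamma_c = 1.88 1/s`) are a
  published-parameter-set shape with the plasma viscosity calibrated to
  `1.1124e-3 Pa s` so that `mu(1e4 1/s) * 1e4 = 40 Pa` at 45 % hematocrit
  (the stated stress equivalence at the activation threshold).  The 30 %
  hematocrit benchmark keeps the same coefficients, which places its curve
  strictly below the 45 % curve.  A `gamma_floor = 1 1/s` caps the
  low-shear singularity in stagnant zones.
* **Windkessel defaults** (`Rc = 1.81e5`, `Rp = 5.90e6 Pa s/m^2`,
  `Cw = 3.62e-7 m^2/Pa`, per-unit-depth units) were fitted by
  `fit_windkessel` against a synthetic 120/80 mmHg trace driven by the
  default waveform through a 20 mm bore (examples/02 reproduces the fit).
  With rigid walls and a prescribed inflow, the outlet pressure shifts the
  pressure gauge but not the velocity field; the Windkessel is retained for
  pressure reporting.

## Geometry

Phantoms: the true lumen (default 20 mm wide) runs the full 300 mm vessel;
the false lumen (15 mm) is a blind pocket along the dissected segment
(60–260 mm) separated by a 2 mm flap with 1–2 tear openings.  Only tear
diameters are printed in the source; every other dimension is a
reconstruction, config-exposed, and labelled as such.  Canonical tear
layouts: C1 proximal 10 mm; C2 distal 10 mm; C3 10/5 with the re-entry
tear mid-section; C4 10/5 distal; C5 10/10; C6 20/10.  Walls whose face
lies within the first 45 mm are tagged "arch" and take zero-flux species
conditions (avoiding artificial clotting at the truncated arch).

BFS: a 10 mm upstream bore expands over a 2.5 mm step (15 mm downstream
bore).  The axisymmetric mode is the default benchmark: the grid spans the
radius, all finite-volume face areas and cell volumes carry the radius
factor, the radial momentum equation carries the `-mu v/r^2` curvature
term, and the axis is a symmetry boundary.  At 0.76 L/min the step
Reynolds number is ~120–160 (upstream mean velocity 0.161 m/s), giving a
laminar recirculation zone of 10–18 step heights depending on inflow
development — the substrate on which the benchmark thrombus grows.

## Numerics

Cartesian cell-centred grid with stair-stepped walls (at least 4 cells
across the smallest tear is enforced).  Flow: incremental pressure-
correction projection; the predictor treats advection (first-order upwind),
diffusion and the momentum sink implicitly — the sink coefficient reaches
`1e7 kg/m^3/s` so explicit treatment would be unstable — and includes the
old pressure gradient; the Poisson solve (prefactorised, geometry-only)
returns a correction that leaves the face velocities discretely
divergence-free (~1e-12 1/s in practice) and vanishes at steady state.
Because momentum advection is implicit, the advective CFL may exceed 1 at
the paper-scale time steps (0.005 s phantom, 0.01 s BFS); species
transport instead sub-cycles explicit positivity-preserving upwind
advection to CFL <= 0.9.  The coagulant's implicit diffusion operator is
refactorised once per averaging window (its coefficients change only when
the shear gates update).  Operator order per step: flow -> shear/metric
accumulation -> RT -> platelets -> coagulant -> BP -> sink/viscosity.

Window averaging: one cardiac period (phantoms) or 1 s (BFS).  Gating uses
the last *completed* window; during the first coupled window a running mean
(and running RRT) substitutes.  Phantom runs integrate 2 flow-only cycles
before switching the thrombosis model on (cycles 3–20); the BFS runs 2 s of
flow spin-up before its 50 s coupled window.

Degenerate inputs: disconnected fluid regions, overlapping or off-flap
tears, under-resolved tears and nonpositive dimensions raise
`GeometryError`; closed domains (test boxes) pin the pressure gauge.

## What the synthetic scenarios do and do not establish

The phantoms are *reconstructions*: tear diameters and thresholds follow
the printed values, but absolute lumen widths, tear positions and the
waveform shape are plausible defaults, so phantom outputs are checked only
qualitatively (which regions clot, monotone trends of flow split with tear
size) — matching printed WSS tables is out of reach without the exact
geometry.  The BFS benchmark is quantitative at the scale of its coarse
grid (~4 cells/mm, first-order upwind): the height plateau is resolved to
one cell (0.25 mm) and the reported lengths inherit a few-mm discretisation
uncertainty.  A green suite establishes internal consistency (conservation,
positivity, gating logic, solver accuracy on analytic flows) and the
benchmark-scale growth behaviour; it does not validate against patient
anatomy, compliant walls, 3-D secondary flow, or real growth time scales,
all of which are outside the model.

## Known limitations

* First-order upwind advection is diffusive; recirculation lengths on the
  coarse benchmark grid carry O(20 %) uncertainty, which propagates into
  the thrombus length.
* The thrombus front advances wherever a low-shear wall band exists; as the
  clot streamlines the step, the reattachment region migrates downstream
  and can seed slow secondary growth — visible as a small late-time creep
  in the benchmark length.
* The RRT gate is weak near walls during start-up transients (RT grows
  everywhere until advection establishes a steady age field), so early
  nucleation is slightly more permissive than the converged state.
* Yield-stress rheology, platelet shear-history activation and the
  high-shear (vWF) aggregation pathway are not modelled.
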