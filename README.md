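# thromboflow

A 2-D coupled flow/transport simulator of **false-lumen thrombosis in aortic
dissection**, for researchers in computational hemodynamics who want a
desk-scale, hemodynamics-based thrombosis model: instead of resolving the
coagulation cascade, the likelihood and growth of thrombus are driven by
local shear rates, fluid residence time and platelet distribution.

## The model

Blood is an incompressible, laminar, shear-thinning (Quemada) fluid:

    rho du/dt + rho u.grad(u) = -grad p + div(mu (grad u + grad u^T)) - S_M

with a clot momentum sink `S_M = k_M BP^2/(BP^2+BP_t^2) u` and viscosity
amplified up to 101x where bound platelets accumulate.  Five scalar fields
ride on the flow:

| field | meaning | dynamics |
|-------|---------|----------|
| RT    | residence time | `dRT/dt + v.grad RT = D_RT lap RT + 1`; its per-cycle increase / period is the relative residence time RRT |
| RP/AP | resting/activated platelets (normalised) | convection-diffusion-reaction, `D_p = D_pt + alpha*gdot`, activation `r1 = k1[AP][RP]`, `r2 = k2_eff [RP] RRT` |
| C     | lumped coagulant | formed at walls where the cycle-averaged wall shear rate is below a threshold; spreads by a shear-gated diffusivity `phi_g D_c` with source `k_c phi_C(BP) phi_g` |
| BP    | bound platelets (thrombus) | `dBP/dt = k_BP phi_BP(C,RRT) phi_g [AP]`, immobile and monotone |

All switches are smooth saturations `x^2/(x^2+x_t^2)`; the shear gate
`phi_g = g_t^2/(gbar^2+g_t^2)` uses *cycle-averaged* shear so that thrombus
never forms in fast, washed-out regions.  A three-element Windkessel sets
the outlet pressure of the pulsatile runs.

Two scenario families are built in: six idealised dissection phantoms
(C1–C6: one or two flap tears of 5–20 mm) under a 1.02 Hz aortic waveform
with 0.51 m/s peak, and the backward-facing-step (BFS) benchmark channel
(10 mm bore, 2.5 mm step, steady 0.76 L/min) in which a thrombus grows in
the recirculation zone behind the step.

## Worked example

```bash
python examples/04_bfs_thrombosis.py
```

runs a coarse, shortened step benchmark and prints (abridged):

```
 t [s]   length [mm]   height [mm]   max BP [nmol/L]
   4.0          3.00          0.50          94.9
   7.0          6.50          1.00         325.8
  10.0         12.00          1.00         510.8
  13.0         16.00          1.00         648.6
```

The clot nucleates at the step corner, grows radially until it reaches the
step height (2.5 mm in the full-resolution 50 s benchmark — this shortened
coarse run reaches 1 mm), and creeps axially along the recirculation zone
(`length`); `max BP` is the peak
bound-platelet concentration, far above the 20 nmol/L momentum-sink
threshold, so the clot interior is effectively solid.  The other examples
cover the Quemada rheology (`01`), fitting the Windkessel outlet (`02`),
solver validation on Poiseuille flow (`03`), false-lumen thrombosis in a
dissection phantom (`05`), and the tear-size/flow-split sweep (`06`).

## Acceptance script

`scripts/acceptance.py` re-runs the full 50 s BFS benchmark from scratch on
a coarse axisymmetric grid (~4 cells/mm) and writes the three benchmark
quantities — the thrombus height plateau (mm), the maximum thrombus length
at 50 s (mm), and the length at the growth-rate knee in step heights — as
JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The pipeline is deterministic; the seed only feeds any future stochastic
extensions.  Runtime is roughly 10 minutes on one CPU.

## Layout

- `src/thromboflow/grid.py` — phantom/step geometry builders, wall classification
- `src/thromboflow/rheology.py` — shear rate, Quemada viscosity, clot amplification
- `src/thromboflow/flow.py` — incremental-projection Navier–Stokes with momentum sink
- `src/thromboflow/windkessel.py`, `waveform.py` — outlet model and inlet waveform
- `src/thromboflow/transport.py` — RT/RP/AP/C/BP transport and kinetics
- `src/thromboflow/metrics.py` — WSS/TAWSS/RRT windows, flow split, thrombus extent
- `src/thromboflow/scenarios.py` — scenario configs, orchestration, outputs, sensitivity
- `docs/methods.md` — model assumptions, parameters, numerical choices, limitations
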