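# Backward-facing-step thrombosis benchmark — annotated scenario config.
# Load with:  thromboflow.load_config("examples/configs/bfs_benchmark.yaml")
name: bfs
mode: steady_bfs            # steady inflow, 1 s averaging windows
resolution: 4.0             # cells per mm
phantom: null
step:                       # geometry in mm
  channel_height_upstream: 10.0   # upstream tube bore (diameter)
  step_height: 2.5                # radial step -> 15 mm downstream bore
  upstream_length: 20.0
  downstream_length: 60.0
axisymmetric: true          # tube of circular cross-section
rho: 1060.0                 # blood density, kg/m^3
rheology:
  plasma_viscosity: 0.0011124   # Pa s; calibrated so mu(1e4/s)*1e4 = 40 Pa at 45% Hct
  hematocrit: 0.3               # benchmark blood analogue
  quemada_k0: 4.33
  quemada_kinf: 2.07
  quemada_gamma_c: 1.88         # 1/s
  gamma_floor: 1.0              # 1/s, low-shear cap of the Quemada law
  amplification_factor: 100.0   # clot viscosity boost
  bp_threshold: 20.0            # nmol/L
kinetics:
  k1: 0.5                   # 1/s, platelet-platelet activation
  k2: 1.2e-08               # mL/platelets/s (dimensional form)
  k2_eff: 0.15              # 1/s, = k2 * ap_ref (normalised form actually used)
  k_c: 200.0                # nmol/L/s, coagulant source
  k_bp: 10.0                # nmol/L/s, bound-platelet formation
  k_m: 10000000.0           # kg/m^3/s, momentum sink
  d_rt: 1.14e-11            # m^2/s, blood self-diffusivity (residence time)
  d_pt: 1.6e-13             # m^2/s, platelet thermal diffusivity
  alpha: 7.0e-13            # m^2, shear-enhanced diffusivity coefficient
  d_c: 1.0e-08              # m^2/s, coagulant diffusivity (calibrated default)
  rrt_t: 0.9                # RRT switching threshold
  c_t: 10.0                 # nmol/L
  bp_t: 20.0                # nmol/L
  gamma_bulk_t: 10.0        # 1/s, bulk shear gate (steady-flow value)
  gamma_wall_t: 1.0         # 1/s, wall coagulant/adhesion gate (steady-flow value)
  gamma_activation_t: 10000.0   # 1/s, activation diagnostic threshold
  c_wall: 100.0             # nmol/L, low-shear wall coagulant level
  background_activation: 0.05   # AP background = 5% of inlet RP
  rp_inlet: 250000000.0     # platelets/mL
  ap_ref: 12500000.0        # platelets/mL (AP normalisation)
  adhesion_rate: 5.0e-05    # m/s, first-order wall adhesion
waveform: null              # steady mode: constant inflow instead
windkessel: null            # outlet pressure fixed at zero in this mode
numerics:
  dt: 0.01                  # s (phantom runs use 0.005)
  cycles_flow_init: 2
  cycles_total: 20
  scalar_cfl: 0.9           # species sub-cycling limit
  pressure_tol: 1.0e-10
bfs_flow_lpm: 0.76          # fixed volumetric inflow, L/min
spinup_time: 2.0            # flow-only spin-up before coupling, s
coupled_time: 50.0          # coupled simulation time, s
window: 1.0                 # averaging window, s
thrombosis_enabled: true
flow_feedback_enabled: true # momentum sink + viscosity amplification
snapshot_every: null        # e.g. 5.0 to dump VTK fields every 5 s
step_type: step
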