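# Fully-commented run configuration for the peri-implant blood-flow
# scenario (load with `implantflow run --config scenario_config.yaml`
# or `implantflow.load_config`).  Every omitted key takes the
# physiological default shown here; only boundary.contact_angle is
# mandatory (it is the study's control variable).

geometry:
  domain_height: 10.0        # mm, channel height
  domain_width: 1.5          # mm, bone-to-implant gap
  n_threads: 10              # thread count on the implant wall
  thread_height: 1.0         # mm per thread
  thread_depth: 0.5          # mm, thread depth into the channel
  thread_profile: triangular # triangular | rectangular | trapezoidal
  cell_size: 0.05            # mm; 0.05 = coarse preset, 0.025 = full

properties:
  rho_plasma: 1025.0         # kg/m^3, fibrinogen-free plasma
  rho_fibrinogen: 1400.0     # kg/m^3
  rho_rbc: 1125.0            # kg/m^3, red-blood-cell phase
  mu_rbc: 0.0050             # Pa.s
  sigma: 0.021               # N/m, plasma-RBC interfacial tension
  D_fib: 0.23e-10            # m^2/s, fibrinogen diffusion coefficient

boundary:
  contact_angle: 5           # deg, implant wettability (REQUIRED):
                             # 5 superhydrophilic ... 100 hydrorepellent
  inlet_speed: 0.01          # m/s at both velocity inlets
  inlet_hematocrit: 0.45     # RBC volume fraction of the inflow
  inlet_Y0: 0.0029           # fibrinogen mass fraction in inlet plasma
  left_boundary: inlet       # alveolar bone wall: inlet | wall
  bottom_boundary: inlet     # blood inlet: inlet | wall
  top_boundary: outlet       # blood outlet: outlet | wall
  slug_wavelength: 0.5       # mm, inlet slug-train spatial period
  slug_period: 0.05          # s, temporal period (0 = premixed inflow)

solver:
  dt: 1.0e-4                 # s, outer time step
  t_end: 3.0                 # s, simulated horizon
  inner_tolerance: 1.0e-9    # kg, fibrinogen-mass convergence monitor
  max_inner_iterations: 1    # Picard property-coupling sweeps per step
  cfl_safety: 0.4            # advective CFL fraction for sub-stepping
  capillary_safety: 1.8      # fraction of the Brackbill capillary limit
  alpha_compression: 1.0     # interface-compression coefficient
  sample_stride: 1           # outer steps between infiltration samples
  pressure_rtol: 1.0e-6      # relative residual of the Poisson solve
  snapshot_times: [1.0, 3.0] # s, field snapshots to keep

output:
  outdir: runs/cais5
  export_csv: true           # infiltration time series
  export_vtk: false          # legacy-VTK field snapshots
  export_png: false          # fibrinogen/plasma heatmaps
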