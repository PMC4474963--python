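geometry:
  equivalent_radius: 4.0
  dimensionless_pseudopod_length: 1.9
  pseudopod_width: 0.45
  cell_steric_layer: 0.175
  mesh_resolution: 96
kinetics:
  kf2D0: 10.0
  sigma: 250000.0
  lb: 0.08
  gamma_f: 3.9e-05
  kN_off0: 9.0
  kI_off0: 0.33
  yI: 0.00024
  phi0: 90.01
  gamma_prime: 8.16e-07
  temperature: 310.0
  slip_velocity_scale: 0.0
shear_rate: 1000.0
viscosity: 1.0
initial_gap: 0.5
initial_orientation:
- 0.0
- 0.0
- 0.0
initial_centroid_height: null
wall_steric_layer: 0.35
reactive_distance: 0.58
steric_f0: 10000.0
steric_lambda: 0.01
total_receptors: 25100
max_bonds: 40
dt: 5.0e-06
max_steps: 80000
x_stop: 150.0
substep_threshold: 0.1
coarse_dt_factor: 4
coarse_gap_threshold: 0.5
regularization: 0.15
adhesion_enabled: true
firm_fraction: 0.5
stall_speed_fraction: 0.01
stall_time: 0.01
seed: 0
record_every: 20
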