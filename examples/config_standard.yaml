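# Standard sasmd configuration (see sasmd.config for the schema).
# Units: energies kJ/mol, lengths nm, times ps, angles rad;
#        forces in pN only where the key says so (f0_pN).
# landscape: the anisotropic binding funnel (well, barrier shell with
#            escape channels, cleft guide wall). channels[].guide_open
#            marks approach channels; closed channels are cryptic exits.
# controller: spring k (kJ/mol/nm^2), speed v (nm/ps), force window T,
#            trigger (t0, f0_pN), termination (cutoff_separation, max_time),
#            engine (dt, friction, temperature).
# ga:        the embedded direction optimizer's budget (m populations x
#            pop_size x n_generations trial segments per optimization).
landscape:
  well_depth: 30.0
  well_width: 0.3
  well_center:
  - 0.0
  - 0.0
  - 0.0
  background_barrier: 100.0
  barrier_radius: 0.8
  barrier_width: 0.15
  channels:
  - direction:
    - 0.0
    - 0.0
    - 1.0
    barrier_height: 70.0
    width: 0.3
    guide_open: true
  - direction:
    - 0.7071067811865475
    - 0.0
    - 0.7071067811865475
    barrier_height: 8.0
    width: 0.2
    guide_open: false
  envelope_radius: null
  background_stiffness: 0.0
  core_softening: 0.01
  guide_amp: 35.0
  guide_on: 0.25
  guide_off: 1.1
  direction_jitter: 0.0
  barrier_jitter: 0.0
controller:
  k: 200.0
  v: 0.002
  T: 1.0
  t0: 5.0
  cutoff_separation: 0.6
  max_time: 6000.0
  n0:
  - 0.0
  - 0.0
  - 1.0
  engine:
    dt: 0.002
    friction: 50.0
    temperature: 300.0
  equil_time: 100.0
  traj_stride: 50
  recenter_hemisphere: false
  f0_pN: 250.0
ga:
  m: 16
  pop_size: 4
  n_generations: 3
  crossover_rate: 0.9
  mutation_rate: 0.15
  mutation_sigma: 0.1
  entropy_weights:
  - 1.0
  - 0.1
  narrowing_enabled: true
  narrow_on_global_best: false
  p_strategy: softmax
  softmax_temperature: 0.25
  early_stop_tol: 0.0001
  early_stop_patience: 5
  seed: null
experiment:
  n_seeds: 5
  f0_values_pN:
  - 400
  - 350
  - 300
  - 250
  - 200
  pulling_rates:
  - 0.002
  - 0.005
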