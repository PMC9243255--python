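# Demo pipeline configuration: two synthetic states x 5 subjects x 100 nodes.
# Run:  neuroturb all --config examples/demo.yaml --out demo_run
seed: 7
geometry:
  n_nodes: 100
  layout: uniform_ball
  radius_mm: 70.0
  n_networks: 4
  lambda_c: 0.18
cohort:
  regime: hopf_forward
  tr: 2.0
  duration_volumes: 200
  states:
    - {label: rest, n_subjects: 5, G: 2.0}
    - {label: sleep, n_subjects: 5, G: 0.5}
signal:
  low_hz: 0.008
  high_hz: 0.08
  order: 2
  edge_discard: 10
turbulence:
  lambda_min: 0.01
  lambda_max: 0.30
  lambda_step: 0.03
  dt_steps: 1
  r_min_mm: 8.0
  r_max_mm: 34.0
  n_bins: 20
hopf:
  a: -0.02
  noise_sd: 0.01
  dt: 0.1
  g_min: 0.0
  g_max: 3.0
  g_step: 0.25
  n_reps: 5
  duration_volumes: 200
perturbation:
  kind: periodic_force
  F0: 0.0005
  n_trials: 10
  lambda_s: 0.12
stats:
  q: 0.05
  top_q: 0.15
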