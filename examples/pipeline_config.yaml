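# Example configuration for `hemiflow run --config examples/pipeline_config.yaml`
# Any omitted block falls back to the documented defaults.
seed: 11
paradigm:
  n_blocks_per_condition: 4
  block_duration_s: 30.0
  tr_s: 3.0
  n_dummy: 5
simulation:
  coupling: 0.35
  bold_noise_sd: 0.5
  groups:
    - label: LH
      n_subjects: 6
      asymmetry_ratio: 1.0
      edge_deltas: [[MOG_R, INS_L, 0.35], [MOG_R, INS_R, 0.35]]
    - label: RH
      n_subjects: 6
      asymmetry_ratio: 3.0
activation:
  q: 0.01
  min_cluster: 10
  connectivity: 26
connectivity:
  n_reps: 100
  alpha: 0.05
comparison:
  alpha_fwe: 0.01
  count_alpha: 0.01
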