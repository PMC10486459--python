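# Example configuration for `cysurv run-all --config ... --out runs/full`.
# Omit `sim` and set `data_dir` to run on an existing cohort directory.
seed: 5
sim:
  n_patients: 120
  seed: 5
  shrinkage_effect: 0.4
  texture_effect: 6.0
  clinical_effect: 2.5
split_fractions: [0.56, 0.04, 0.40]
mi_k_features: 12
roi:
  stride: 6
  max_hybrids_per_case: 8
  intensity_window: [-50.0, 150.0]
cnn:
  conv_channels: [6, 12]
  local_channels: [12]
  epochs: 4
  learning_rate: 0.02
bpnn:
  hidden_nodes: 13
  max_iter: 100
combinations: [C, R, D, CR, CD, CRD]
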