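# Full shipped example: 51 crossbred sires (8 x 50%HF, 12 x 62.5%HF,
# 31 x 75%HF), 4,319 half-sib daughter records with family sizes 7..628,
# eight production/reproduction traits.  Run with:
#   sireval all -c examples/crossbred.yaml -o crossbred_out
seed: 1
output_dir: crossbred_out
n_sires: 51
total_daughters: 4319
traits: [BWT, AFC, SPC, DMY, PMY, LL, DO, CI]
apply_filter: true
filter_group: grade
fixed_factors: [grade, parity, location]
lsmeans_factor: grade
reml_tol: 1.0e-7
reml_max_iter: 5000
correlation_pairs:
  - [DMY, PMY]
  - [DO, CI]
  - [AFC, DMY]
index_weights:
  BWT: -8.93
  AFC: -12.61
  SPC: -30.91
  DMY: -20.36
  PMY: -4.03
  LL: -0.98
  DO: 0.44
  CI: 29.86
selection_fraction: 0.2
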