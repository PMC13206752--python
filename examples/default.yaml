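# Default desk-scale configuration for `marsa run`.
# Every key shown here matches the built-in defaults; delete any block to
# inherit it unchanged.  All randomness derives from `seed`.
seed: 0

synthetic:
  n_items: 30
  n_dims: 3
  n_categories: 4
  cat_separation: 2.0
  within_sd: 1.0
  n_subjects: 12
  shared_w: 1.0
  unique_visual_w: 0.3
  unique_linguistic_w: 0.3
  noise_sd: 0.1
  brain:
    n_subjects: 8
    mask_shape: [10, 10, 10]
    noise_sd: 0.5
    regions:
      - {center: [3, 3, 3], radius: 2.0, source: shared, amplitude: 1.0}
      - {center: [7, 7, 7], radius: 2.0, source: unique_linguistic, amplitude: 1.0}

ma:
  enabled: true
  subset_size: 8
  evidence_threshold: 0.5
  max_trials: 10
  placement_noise: 0.05
  arena_radius: 1.0

searchlight:
  radius: 2.0
  min_voxels: 10

reweight:
  train_frac: 0.7
  n_folds: 10

rsa:
  n_perm: 500

stats:
  q: 0.05
  sidedness: one

io:
  write_nifti: true
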