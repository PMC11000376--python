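# Example configuration for the `dynrad` CLI.
#
#   dynrad all --config examples/pipeline_config.yaml --out scratch/demo --seed 1
#
# Omit `manifest` to run on a simulated phantom cohort; point it at a CSV
# with columns patient_id, label, {plain,arterial,portal,equilibrium}_image
# and ..._mask to run on real NIfTI/NRRD data.
seed: 1
out_dir: scratch/demo
simulate:
  n_patients: 12
  prevalence: 0.4
  volume_shape: [28, 28, 28]
  lesion_radius_range: [5.0, 7.0]
  noise_sigma: 5.0
preprocess:
  region: whole-volume      # statistics region for z-normalisation
  n_levels: 64              # gray-level quantisation 1..64
  target_spacing: [1.0, 1.0, 1.0]
  time_grid: [1.0, 2.0, 3.0, 4.0]
dynamic:
  racr_denominator: series-mean
  corrected_curvature: false
model:
  alpha: 0.05
  cv_folds: 5
  cv_repeats: 5
  icc_threshold: 0.8
  icc_jitter_mm: 0.4        # 0 disables the two-reader ICC filter
  icc_n_patients: 6
  validation_fraction: 0.3
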