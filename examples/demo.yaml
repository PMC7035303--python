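# Demo pipeline configuration: `flowpulse run --config examples/demo.yaml --out runs/demo`
# All keys are optional; unknown keys are rejected.  Values shown are the defaults.

seed: 1
log_level: INFO
stages: [simulate_flow, metrics, simulate_cohort, analyze]

waveform:              # parametric cardiac flow waveform (ICA-like)
  mean_flow: 4.4       # ml/s
  pulse_amplitude: 5.5 # ml/s peak-to-trough -> dense PI = 5.5/4.4 = 1.25
  systolic_peak_time: 0.16
  peak_width: 0.16     # FWHM, fraction of cycle
  dicrotic_amplitude: 0.0
  rr_interval: 0.9     # s
  rr_jitter_sd: 0.0
  noise_sd: 0.0

phantom:               # voxelized Poiseuille tube + gated acquisition
  shape: straight      # or curved
  radius: 2.5          # mm
  voxel_size: 0.5      # mm
  length: 8.0          # mm of centerline
  venc: 110.0          # cm/s velocity-encoding limit
  n_phases: 20
  n_cycles: 30
  samples_per_cycle: 200
  start_voxel: 2       # first of the six averaged centerline voxels

cohort:
  n_subjects: 400

models:
  terms: [ICA_PI, M1_PI, ICA_FVP, M1_FVP]
  include_extended: true
  include_subgroup: true
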