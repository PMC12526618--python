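# Default synthetic-cohort configuration.
#
# velocity_params: per (condition, phase) [mean, sd] of phase velocity in m/s.
# coherence_targets: per (condition, phase, muscle pair, band) target
# band-averaged magnitude-squared coherence. Targets above clamp_coherence_max
# are clamped at generation time (magnitude-squared coherence cannot exceed 1,
# and 1 is unattainable in the presence of independent noise).
n_participants: 30
fs: 1000
conditions: [sham, m1_tdcs, dlpfc_tdcs]
phases: [p0_30, p30_60, p60_100]
phase_distances_m:
  p0_30: 30
  p30_60: 30
  p60_100: 40
velocity_params:
  sham:
    p0_30: [9.26, 0.44]
    p30_60: [11.12, 0.60]
    p60_100: [10.08, 0.32]
  m1_tdcs:
    p0_30: [9.35, 0.40]
    p30_60: [11.59, 0.67]
    p60_100: [9.88, 0.34]
  dlpfc_tdcs:
    p0_30: [8.97, 0.49]
    p30_60: [11.32, 0.59]
    p60_100: [9.85, 0.40]
coherence_targets:
  sham:
    p0_30:
      RA-BF: {alpha: 0.20, beta: 0.41, gamma: 0.88}
      TA-GL: {alpha: 0.12, beta: 0.25, gamma: 0.68}
    p30_60:
      RA-BF: {alpha: 0.24, beta: 0.44, gamma: 0.55}
      TA-GL: {alpha: 0.09, beta: 0.08, gamma: 0.34}
    p60_100:
      RA-BF: {alpha: 0.23, beta: 0.53, gamma: 0.15}
      TA-GL: {alpha: 0.22, beta: 0.51, gamma: 0.98}
  m1_tdcs:
    p0_30:
      RA-BF: {alpha: 0.25, beta: 0.48, gamma: 0.95}
      TA-GL: {alpha: 0.15, beta: 0.30, gamma: 0.75}
    p30_60:
      RA-BF: {alpha: 0.32, beta: 0.55, gamma: 0.70}
      TA-GL: {alpha: 0.12, beta: 0.11, gamma: 0.45}
    p60_100:
      RA-BF: {alpha: 0.20, beta: 0.60, gamma: 0.12}
      TA-GL: {alpha: 0.25, beta: 0.58, gamma: 1.10}
  dlpfc_tdcs:
    p0_30:
      RA-BF: {alpha: 0.18, beta: 0.39, gamma: 0.82}
      TA-GL: {alpha: 0.10, beta: 0.22, gamma: 0.65}
    p30_60:
      RA-BF: {alpha: 0.20, beta: 0.40, gamma: 0.50}
      TA-GL: {alpha: 0.08, beta: 0.07, gamma: 0.30}
    p60_100:
      RA-BF: {alpha: 0.25, beta: 0.50, gamma: 0.16}
      TA-GL: {alpha: 0.20, beta: 0.48, gamma: 0.90}
clamp_coherence_max: 0.95
noise_sd_velocity: 0.15     # m/s; Gaussian noise added in formula velocity mode
participant_sd: 0.2         # m/s; participant-level random intercept (table mode)
broadband_noise_sd: 0.3     # relative amplitude of 20-450 Hz background noise
gain_jitter_sigma: 0.1      # lognormal sigma of per-trial per-channel gain
seed: 42
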