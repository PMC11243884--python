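# Full pipeline configuration with package defaults.
# Any key may be omitted; CLI flags override individual values.

seed: 0

synth:                        # synthetic grasp generator
  grid_rows: 32
  grid_cols: 32
  n_active_sensors: 548       # physical taxels on the 32x32 grid
  sampling_rate: 32.0         # Hz
  duration: 8.0               # s per trial
  onset_time: 1.5             # s; grasp spans [onset, offset] (~5 s)
  offset_time: 6.5
  peak_pressure: 600.0        # ADC counts (10-bit scale)
  n_blobs: 3                  # contact regions per grasp
  blob_width: 2.0             # spatial Gaussian sigma, taxels
  temporal_smoothness: 0.4    # rise/fall time constant, s
  noise_sd: 2.0               # sensor noise, ADC counts
  bit_depth: 10
  n_trials: 10
  jitter:                     # trial-to-trial variability
    onset_sd: 0.2             # s
    amplitude_sd: 0.1         # fraction of peak
    center_sd: 1.0            # taxels

denoise:
  enabled: true
  order: 2                    # IIR order (Butterworth)
  cutoff_fraction: 0.14285714285714285   # pass-band edge = fs/7
  causal: false               # false = zero-phase forward-backward

transform:
  wavelet: sym4
  dimensionality: 1           # 1 = per-taxel time series, 2 = per frame, 3 = volume
  level: max                  # floor(log2(L)) rule; or an explicit integer
  extension_mode: periodization   # coefficient count == sample count

sparsify:
  targets: [0.01, 0.0043, 0.0015, 0.0001]   # survey NMSE targets
  tolerance_factor: 1.0e-4    # convergence: |achieved - target| <= factor * target
  max_iterations: 60
  normalization: mean         # NMSE denominator (the survey definition)

survey:
  wavelets: all               # or an explicit list of registry names
  dimensionalities: [1, 2, 3]
  include_dct: true

diagnostics:
  recording_index: 0
  wavelet: sym4
  dimensionality: 1
  k_values: [0, 16, 64, 256, 1024, 4096]
  scaling_iterations: 5       # cascade-algorithm depth
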