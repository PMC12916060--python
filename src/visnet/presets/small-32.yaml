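version: 1
preset: small-32
input_size: 256
input_channels: 32
base_wavelength: 16.0
layers:
  - {grid: 32, n_connections: 340, radius: 15.0, sparseness: 0.01, beta: 10.0, max_weight: null}
  - {grid: 32, n_connections: 200, radius: 7.0, sparseness: 0.01, beta: 10.0, max_weight: null}
  - {grid: 32, n_connections: 200, radius: 7.0, sparseness: 0.01, beta: 10.0, max_weight: null}
  - {grid: 32, n_connections: 200, radius: 7.0, sparseness: 0.01, beta: 10.0, max_weight: null}
learning:
  rule: competitive_standard
  learning_rate: 0.5
  eta: 0.8
  use_previous_trace_only: true
  reset_trace_per_object: true
schedule:
  epochs_per_layer: 50
  rng_seed: 0
stimuli:
  kind: synthetic
  n_objects: 9
  n_views: 9
  seed: 0
network_seed: 0
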