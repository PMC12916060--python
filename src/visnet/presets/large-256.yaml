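version: 1
preset: large-256
input_size: 256
input_channels: 32
base_wavelength: 16.0
layers:
  - {grid: 256, n_connections: 1000, radius: 15.0, sparseness: 0.0025, beta: 100.0, max_weight: 0.06}
  - {grid: 256, n_connections: 1000, radius: 56.0, sparseness: 0.0025, beta: 100.0, max_weight: 0.06}
  - {grid: 256, n_connections: 1000, radius: 56.0, sparseness: 0.0025, beta: 100.0, max_weight: 0.06}
  - {grid: 256, n_connections: 1000, radius: 56.0, sparseness: 0.0025, beta: 100.0, max_weight: null}
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
  kind: directory
  path: stimuli/
  layout: nested
network_seed: 0
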