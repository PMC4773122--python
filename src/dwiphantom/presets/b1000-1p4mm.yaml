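# 3T single-shell acquisition reconstructed at 1.4 mm (factor-2 k-space
# truncation of the native 0.7 mm simulation); 66 volumes.
substrate:
  recipe:
    grid_shape: [64, 64, 64]
    voxel_size_mm: 0.7
    rng_seed: 0
relaxometry:
  field_strength: "3T"
  te_ms: 57
  tr_ms: 8800
protocol:
  delta_ms: 12.9
  Delta_ms: 21.8
  n_directions: 60
  n_b0: 6
  bvalues: [1000]
  resolution_factor: 2
  filter: none
  snr: inf
  seed: 0
output:
  basename: dwi
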