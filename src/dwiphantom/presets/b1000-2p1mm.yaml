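# 3T single-shell acquisition reconstructed at 2.1 mm (factor-3 k-space
# truncation); 66x66x66 native grid so the matrix divides evenly by 3.
substrate:
  recipe:
    grid_shape: [66, 66, 66]
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
  resolution_factor: 3
  filter: none
  snr: inf
  seed: 0
output:
  basename: dwi
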