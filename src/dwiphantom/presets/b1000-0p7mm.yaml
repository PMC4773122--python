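# 3T single-shell acquisition at the native 0.7 mm resolution:
# TR/TE 8800/57 ms, delta 12.9 ms, Delta 21.8 ms,
# 6 x b=0 plus 60 directions at b = 1000 s/mm^2 (66 volumes).
# Swap protocol.bvalues to [2500] or [10000] for the other shells.
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
  resolution_factor: 1
  filter: none
  snr: inf
  seed: 0
output:
  basename: dwi
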