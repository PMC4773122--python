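# Single-shell protocol used for connectivity experiments: 6 x b=0 plus
# 60 directions at b = 1000 s/mm^2, reconstructed at 1.4 mm.  Set
# protocol.snr to one of {30, 25, 20, 15} (or pass --snr) for the noisy
# realizations; use resolution_factor 3 with the 66^3 grid for 2.1 mm.
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
  snr: 30
  seed: 0
output:
  basename: dwi
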