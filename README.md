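# dwiphantom

A ground-truth diffusion-MRI brain phantom simulator.  It converts a 4-class
tissue volume-fraction map (white matter, cortical grey matter, deep grey
matter, CSF) plus a white-matter streamline tractogram into realistic
multi-shell diffusion-weighted MR image volumes, with a physically modeled
2D multislice spin-echo acquisition:

* **Microstructure** — per-tissue analytic attenuation models: isotropic
  tensors for CSF/CGM, a cylinder (GPD restricted diffusion) + zeppelin
  mixture for WM, and a WM/CGM mixture for deep GM, with the standard
  in-vivo parameter values built in.
* **Fiber geometry** — each streamline segment is assigned to the voxel
  containing its midpoint; the WM attenuation of a voxel is the mean of the
  single-fiber model over its segment directions.
* **Relaxometry** — proton-density / T1 / T2 spin-echo signal equations with
  1.5 T and 3 T constant presets; per-voxel volume-fraction mixing.
* **Acquisition** — native high-resolution simulation degraded through
  per-slice k-space: complex Gaussian noise, central truncation (Gibbs
  ringing + partial volume), optional Fermi/Hamming apodization, magnitude
  reconstruction (Rician statistics), and an ideal rectangular slice profile
  for through-plane downsampling.
* **Analysis** — log-linear DTI fitting (FA/MD), mixture-weight recovery,
  and streamline-count connectivity matrices, used to close the loop on
  simulated data.
* **Synthetic substrate** — a parametric generator of brain-like inputs
  (crossing / arc / kissing bundles, GM rim, CSF cavity, deep-GM blobs) so
  the whole pipeline runs without any external data.  Real inputs are read
  from NIfTI (fractions) and TCK/TRK (streamlines).

## Test

```sh
python -m pytest -q tests/
```

The suite includes independent numerical oracles (a Monte-Carlo random walk
in a reflecting cylinder, a direct Dirichlet-kernel truncation sum, and a
multi-start electrostatic-energy search); the full run takes a few minutes.

## CLI

```sh
# list shipped acquisition presets (3T, TR/TE 8800/57 ms, delta/Delta
# 12.9/21.8 ms, 6 x b=0 + 60 directions; 0.7 / 1.4 / 2.1 mm)
dwiphantom presets

# simulate an acquisition from a config (YAML); every stage is seeded and a
# reproducibility manifest is written next to the NIfTI + bval/bvec outputs
dwiphantom simulate src/dwiphantom/presets/b1000-1p4mm.yaml --out out/ --snr 20

# generate and save a synthetic substrate
dwiphantom make-substrate --grid 48 --seed 1 --out substrate/

# fit tensors / build a connectome from outputs
dwiphantom fit-dti out/dwi.nii.gz out/dwi.bval out/dwi.bvec --out fit/
dwiphantom connectome substrate/tractogram.tck parcels.nii.gz --out cm.tsv
```

A config file mirrors the module boundaries:

```yaml
substrate:
  recipe: {grid_shape: [64, 64, 64], voxel_size_mm: 0.7, rng_seed: 0}
  # or: fraction_map: vf.nii.gz  /  tractogram: tracks.tck
relaxometry: {field_strength: "3T", te_ms: 57, tr_ms: 8800}
protocol:
  delta_ms: 12.9
  Delta_ms: 21.8
  n_directions: 60
  n_b0: 6
  bvalues: [1000]
  resolution_factor: 2      # k-space downsampling (0.7 mm -> 1.4 mm)
  filter: none              # none | fermi | hamming
  snr: 20                   # or "inf"
  seed: 0
```

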