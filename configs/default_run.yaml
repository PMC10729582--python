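# Bundled synthetic two-group dataset: normotensive-like vs hypertensive-like
# fields of view (higher vascular-associated-microglia fraction and leakage).
seed: 0
mode: rodent-3D
groups:
  - name: control
    n_fovs: 2
    fov:
      vam_fraction: 0.1
      leakage_fraction: 0.05
  - name: hypertensive
    n_fovs: 2
    fov:
      vam_fraction: 0.5
      leakage_fraction: 0.15
fov:
  shape: [16, 128, 128]
  voxel_size: [1.0, 1.25, 1.25]
  n_vessels: 3
  n_cells: 6
clustering:
  k: 4
  n_neighbors: 10
  seed: 42
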