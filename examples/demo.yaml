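scenario: dying-cell-demo
seed: 42
output_dir: out
stages:
  - name: rms
  - name: spatial
    params:
      density_per_um2: 100
      n_reps: 5
  - name: series
    params:
      preset: dying
      n_frames: 10
      grid_shape: [16, 16]
  - name: fluor
    params:
      preset: untreated_width
      n_cells: 40
      shape: [1024, 1024]
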