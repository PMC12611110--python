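# Full-pipeline demo on synthetic study data (440 regions, 2013-2022).
simulation:
  seed: 7
  n_rows: 20
  n_cols: 22
lisa:
  seed: 11
  n_perm: 999
hmr:
  bandwidth: auto
  fallback_bandwidth: 470.0
  n_cells: 200
output_dir: out/synthetic_demo
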