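# Virtual 8-week lineage tracing in the small intestine, then fit k_r/k_d.
preset: SI
seed: 42
outdir: out/si_trace
geometry:
  n_rows: 8
  cells_per_row: 5
experiment:
  type: trace
  times: [48h, 8w]
  n: 500
  start_rows: [0, 1, 2, 3]
inference:
  n_boot: 1000
  n_g: 5
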