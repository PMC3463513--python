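# full pipeline on a simulated study (resevol run --config run.yaml)
outdir: out/demo
seed: 1
simulate:
  seed: 1
  n_proteins_per_cell: 50
  residue_range: [130, 170]
grouping_fraction: 0.3333333333333333
bin_edges: [0, 15, 30, 45, 60, 80, 100]
bootstrap_B: 100
bootstrap_method: full
rates_mode: per_bin
analyses: [dnds, dn, ds, cai]
comparisons: [core, expression, four_cell]
cai_reference: study
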