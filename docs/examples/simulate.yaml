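# synthetic four-cell study (resevol simulate --config simulate.yaml --out study/)
seed: 1
n_proteins_per_cell: 50
residue_range: [130, 170]
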