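kind: expression
n_samples: 120
n_genes: 800
n_programs: 3
markers_per_program: 60
marker_effect: 2.0
noise_sd: 0.6
baseline_mean: 3.0
baseline_gene_sd: 1.0
dropout_rate: 0.05
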