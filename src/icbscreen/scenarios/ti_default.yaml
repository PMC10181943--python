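# tumor-intrinsic reference cohort: four lineage-like programs
# (adeno-like, squamous-like, neuroendocrine-like, dedifferentiated-like)
kind: expression
n_samples: 220
n_genes: 1000
n_programs: 4
markers_per_program: 60
marker_effect: 2.0
noise_sd: 0.6
baseline_mean: 3.0
baseline_gene_sd: 1.0
dropout_rate: 0.05
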