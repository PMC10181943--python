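kind: signature
n_samples: 200
min_mutations: 500
max_mutations: 2000
concentration: 1.0
max_active_signatures: 4
reference:
  synthetic: true
  n_signatures: 7
  seed: 20240001
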