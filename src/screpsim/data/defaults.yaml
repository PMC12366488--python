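# Hierarchy hyper-parameter defaults for datasets lacking
# paired/multi-sample structure. Regenerate with
# scripts/derive_defaults.py.
mu_a: -1.7379
sigma_a: 0.5852
mu_b: -2.6669
sigma_b: 0.6521
provenance: 're-estimated from synthetic reference seed=20240901, design={''n_genes'':
  3000, ''n_subjects'': 10, ''n_timepoints'': 2, ''cells_per_sample'': 150}, generating
  truth={''mu_a'': -2.0, ''sigma_a'': 0.5, ''mu_b'': -2.5, ''sigma_b'': 0.5}; scripts/derive_defaults.py'
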