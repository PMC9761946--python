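# Reduced benchmark grid: a fast sanity-scale version of the full factorial
# design (the full grid spans 2-20 variables, proportions 0.1-0.6, three
# mechanisms, three sample sizes and 100 replicates = 102,600 datasets).
n_vars: [5, 15]
proportions: [0.3, 0.5]
mechanisms: [MCAR, MNAR]
n_rows: [1000]
replicates: 5
master_seed: 0
max_in_degree: 3
n_levels: 3
dirichlet:
  alpha_with_parents: 0.5
  alpha_root: 5.0
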