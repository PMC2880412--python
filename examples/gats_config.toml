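# Run configuration for `abfold fold --config examples/gats_config.toml`.
# All keys mirror GATSConfig fields; command-line flags override them.
[gats]
pop_min = 100
pop_max = 500
crossover_rate = 0.88
mutation_rate = 0.025
tabu_min = 7
tabu_max = 14
neighborhood_size = 30
candidate_size = 5
tsm_iterations = 80
explore_epochs = 3
explore_frac = 0.5
polish_frac = 0.1
stagnation_limit = 100
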