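# SER randomization sweep on the 60-node modular graph.
# Run with: netdyn sweep --config examples/experiment.yaml --out results/
# (reduced ensemble sizes; raise n_runs to 10000 and n_graph_seeds to 10
# for the full-scale experiment)
dynamics: ser
axis: randomization
grid: [0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0]
n_graph_seeds: 5
swaps_per_level: 50
master_seed: 0
graph:
  model: modular
  parameters:
    n_cliques: 4
    clique_size: 15
    rewire_p: 0.23
params:
  p: 0.1
  f: 0.001
  t_max: 10
  n_runs: 1000
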