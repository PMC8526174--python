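"""Build the graph zoo used by the dynamics experiments.

Each generator emits a binary symmetric adjacency matrix of a simple
undirected graph.  The printed node/edge counts are the fixed design
values of each ensemble: the modular and ring graphs have 420 edges, the
preferential-attachment graph 416, and the deterministic hierarchical
graph exactly 64 nodes and 174 edges.
"""

import netdyn as nd

specs = {
    "modular (4 cliques of 15, p=0.23)": nd.make_modular(4, 15, 0.23, seed=1),
    "Erdos-Renyi (n=60, p=0.23)": nd.make_standard("erdos_renyi", 60, seed=1, p=0.23),
    "Barabasi-Albert (n=60, m=8)": nd.make_standard("barabasi_albert", 60, seed=1, m=8),
    "ring lattice (n=60, k=14)": nd.make_standard("watts_strogatz", 60, seed=1,
                                                  ring_neighbors=14),
    "hierarchical (3 levels)": nd.make_hierarchical(3),
}

for name, A in specs.items():
    n, m = A.shape[0], int(A.sum()) // 2
    density = 2 * m / (n * (n - 1))
    print(f"{name:38s} {n:3d} nodes {m:4d} edges  density {density:.3f}")

# degree-preserving randomization scrambles topology but not degrees
A = specs["modular (4 cliques of 15, p=0.23)"]
B = nd.randomize_degree_preserving(A, 500, seed=2)
print("\nafter 500 double-edge swaps: degrees preserved:",
      (A.sum(axis=1) == B.sum(axis=1)).all(),
      "| edges changed:", int((A != B).sum()) // 2)
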