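"""Two classes of functional connectivity in the SER excitable model.

Runs the susceptible-excited-refractory automaton on a modular graph and
on its degree-preserving randomization, accumulates co-activation (FCsim)
and sequential-activation (FCseq) count matrices over 1000 runs, and
correlates each with the structural adjacency matrix.

On the modular graph both correlations are positive (structure is visible
in both same-step and one-step-lagged excitations); full randomization
destroys the co-activation correlation while the sequential one survives
— the signature distinguishing the two FC classes.
"""

import numpy as np

import netdyn as nd

params = nd.SERParams(p=0.1, f=0.001, t_max=10, n_runs=1000)

A = nd.make_modular(4, 15, 0.23, seed=1)
A_rand = nd.randomize_degree_preserving(A, 500, seed=2)

for label, G in [("modular", A), ("fully randomized", A_rand)]:
    fc = nd.ser_ensemble_fc(G, params, np.random.default_rng(0))
    r_sim = nd.scfc_correlation(G, fc.C.astype(float))
    r_seq = nd.scfc_correlation(G, fc.Sm.astype(float))
    print(f"{label:18s} SC/FCsim r = {r_sim.r:+.3f}   SC/FCseq r = {r_seq.r:+.3f}")
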