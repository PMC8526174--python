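"""Lag structure of effective-frequency FC for coupled phase oscillators.

Simulates noisy Kuramoto oscillators (k=10, sigma=0.25) on a modular
graph, computes the windowed effective-frequency series of each node, and
correlates SC with the lagged-correlation FC for a range of lags.

Lags 0 and 1 share part of the averaging window and capture co-activity;
lag 2 is the first disjoint-window lag (sequential activation); larger
lags progressively decouple from the structure.
"""

import warnings

import numpy as np

import netdyn as nd
from netdyn.kuramoto import _simulate_batch, effective_frequency, lagged_correlation_fc

warnings.simplefilter("ignore")

A = nd.make_modular(4, 15, 0.23, seed=1)
params = nd.KuramotoParams(k=10.0, sigma=0.25, n_runs=20)

runs = _simulate_batch(A, params, np.random.default_rng(0), params.n_runs)
stride = params.effective_stride

print("lag (series steps)   SC/FC correlation")
for lag in range(6):
    F_sum = np.zeros_like(A, dtype=float)
    for r in range(params.n_runs):
        om = effective_frequency(runs[r], params.window)[:, ::stride]
        F = lagged_correlation_fc(om, lag)
        F_sum += np.where(np.isnan(F), 0.0, F)
    r_val = nd.scfc_correlation(A, F_sum).r
    marker = " <- co-activation" if lag == 0 else (
        " <- sequential activation" if lag == 2 else "")
    print(f"  {lag}                  {r_val:+.3f}{marker}")
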