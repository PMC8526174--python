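# Methods

`netdyn` probes how much of a network's structural connectivity (SC) is
visible in the functional connectivity (FC) inferred from dynamics
simulated on it. Two FC classes are distinguished throughout:
**co-activation** (FCsim), built from simultaneous activity, and
**sequential activation** (FCseq), built from one-step- or
one-window-lagged activity. The central statistic is the Pearson
correlation between the flattened off-diagonal entries of the binary
adjacency matrix and an FC matrix.

## Structural substrates

All dynamics run on simple undirected binary graphs (numpy `int8`
adjacency matrices, zero diagonal, validated on every entry point).

- **Modular** (default experiment substrate): `n_cliques` = 4 cliques of
  `clique_size` = 15 nodes; every edge independently selected with
  probability `rewire_p` = 0.23 keeps one uniformly chosen endpoint and
  redraws the other among that endpoint's non-neighbours. Edge count is
  conserved exactly (420 edges, density 0.237). The rewiring target may be
  any non-neighbour, inside or outside the original clique; forcing
  inter-clique targets was considered and rejected as a stronger
  assumption than the conserved-edge-count reading.
- **Erdős–Rényi** (n = 60, p = 0.23), **Barabási–Albert** (n = 60,
  m = 8, hence (60−8)·8 = 416 edges) and the **ring lattice** used as the
  Watts–Strogatz substrate, all via networkx. A ring with "15 nearest
  neighbours" is symmetrically infeasible for an undirected simple graph;
  we use k = 14 (7 per side, 420 edges), which also matches the
  moves-per-10%-randomization ratio of ≈ 0.11 used by the sweep defaults
  (50/420 ≈ 0.119).
- **Hierarchical scale-free modular graph** (deterministic). Level 1 is a
  complete 4-node module. Each further level takes four copies of the
  previous graph and connects, to the root hub, (a) the outermost
  peripheral nodes of the three replica copies and (b) each replica's own
  central node. Edge recursion E_k = 4·E_{k−1} + 3^k + 3: levels 1, 2, 3
  give 4/16/64 nodes and 6/36/174 edges. Among the recursive 4-module
  constructions in circulation (which give 159 or 168 edges at 64 nodes,
  depending on whether only the outermost or all non-central replica
  nodes attach to the hub), this is the variant that reproduces the
  64-node / 174-edge graph, and the 20-swaps-per-10% randomization ratio
  20/174 ≈ 0.115; it keeps both the heavy-tailed degree sequence (root
  hub degree 45) and nested modules.
- **Builders from data**: a metabolite-centric graph from an SBML model's
  stoichiometric matrix S (edge wherever (S·Sᵀ)_ij ≠ 0, i ≠ j; SBML
  parsed with python-libsbml), and thresholding + symmetrization of a
  weighted connectivity matrix (edge if either direction passes the
  threshold, optionally after a decimal-log transform).

**Randomization.** Degree-preserving randomization uses Markov-chain
double-edge swaps: two random edges (a,b), (c,d) are replaced by (a,d),
(c,b) unless a self-loop or multi-edge would arise. Progress is counted
in *successful* swaps; a proposal budget of 100× the requested swaps
guards against graphs with no legal swap (e.g. a triangle) and raises a
diagnostic error when exhausted. Ring lattices are instead rewired one
endpoint at a time (edge deleted, one endpoint kept at random, new
partner drawn among non-neighbours), which conserves edge count but not
degrees and passes through a small-world regime.

Sweep substrates must be connected (synchronization and excitation
spreading are uninterpretable across components); disconnected draws are
resampled with deterministically derived child seeds.

## Dynamics and their FC estimators

### SER cellular automaton
Three states per node (susceptible / excited / refractory), synchronous
updates: S→E if any neighbour is excited or spontaneously with
probability f (default 0.001, applies to S nodes only); E→R always;
R→S with probability p (default 0.1). Runs last t_max = 10 steps from
random initial conditions with 6% of nodes excited (round-half-up,
minimum one) and the rest S or R equiprobably. Activity is binarized as
c_i(t) = 1 iff excited; FCsim and FCseq are the parameter-free counting
matrices C_ij = Σ_t c_i(t)c_j(t) and S_ij = Σ_t c_i(t)c_j(t−1),
summed over time and then over an ensemble of independent runs (default
10 000; the trend tests use 1000). The initial-condition column enters
both sums (the formulas sum over all available steps); a flag excludes
it. Counts are kept raw — the SC/FC statistic is invariant under
positive rescaling, so normalization is cosmetic and off by default.

### Noisy Kuramoto oscillators
dθ_i/dt = ω_i + (k/N) Σ_j A_ij sin(θ_j − θ_i) + σu, integrated by
Euler–Maruyama with dt = 0.1 up to t_max = 50; ω_i uniform on (0, 1),
redrawn per run; initial phases uniform on (−π, π); k = 10, σ = 0.25.
Noise enters with √dt scaling by default (the consistent
stochastic-integration reading of "Gaussian noise scaled by σ" under
Euler); a literal σ·u·dt mode exists for sensitivity checks. Phases
accumulate unwrapped — wrapping before differencing would corrupt the
frequency estimate.

The FC signal is the **effective frequency**
Ω_i(t) = (1/2Δt) Σ_{t′=t−Δt}^{t+Δt−1} [θ_i(t′+1) − θ_i(t′)], a centred
moving average of phase increments with half-window Δt = 20 steps.
FC(δt) is the Pearson correlation of Ω_i(t) with Ω_j(t+δt); lag 0 is
co-activation, and a small positive lag is sequential activation.

**Ω-series stride.** Before correlating, the Ω series is subsampled with
a stride equal to the window (configurable; stride 1 keeps the raw
grid). On the raw grid, series points one or two steps apart share 39 or
38 of their 40 averaged increments, so small lags are numerically
indistinguishable from lag 0 (measured SC/FC by lag on a modular graph:
0.62, 0.63, 0.63, 0.64 …) and no co-activation/sequential distinction
exists. With stride = Δt, consecutive points share half a window: lags 0
and 1 both capture co-activity, lag 2 is the first disjoint-window lag —
the sequential-activation default — and larger lags decouple (measured:
modular 0.49, 0.50, 0.27, 0.14, 0.09; Erdős–Rényi 0.28, 0.26, −0.01, ~0).
FC matrices are summed over runs (default 100; trend tests use 20);
zero-variance entries (fully synchronized, noiseless series) are treated
as missing, excluded pairwise and reported, never silently zeroed.

### Coupled logistic maps
x_i(t+1) = R_i x_i(t)(1 − x_i(t)) + (k/N) Σ_j A_ij (x_j(t) − x_i(t)),
hard-clipped to [0, 1] after each synchronous update (the simplest
contract enforcing the bounded state space; exercised by a dedicated
arithmetic test). R_i is uniform on (3.7, 3.9) — chaotic regime — and
redrawn per run; k = 2, t_max = 500, initial states uniform on (0, 1),
no transient discard by default (a `transient` option exists). FCsim and
FCseq are the lag-0 and lag-1 Pearson correlations of the state series,
with S_ij = corr(x_i(t), x_j(t+1)). Aggregation differs from the other
models by design: the SC/FC correlation is computed **per run** and then
averaged (sd over runs as the error), rather than summing FC first.

### FitzHugh–Nagumo
τx dx_i/dt = γx_i − x_i³/3 − y_i + (k/⟨d⟩) Σ_j A_ij (x_j − x_i) + σv_x,
τy dy_i/dt = x_i − βy_i + a, with γ = 1, β = 0.6, τx = 1 ms, τy = 0.1 s,
σ = 0.15 (membrane equation only — the recovery equation is
noise-free), coupling prefactor k/⟨d⟩ = 0.044 with ⟨d⟩ computed from the
substrate at run time. a = 0.8 places the rest state on the stable left
branch (excitable; the fixed point solves x³ + 2x + 4 = 0, x* ≈ −1.18);
a = 0 yields sustained relaxation oscillations. Explicit Euler at
dt = 0.1 ms, traces downsampled to 1 ms; initial conditions uniform in a
±0.5 box around the fixed point; integration aborts with a diagnostic
naming the step if |x| exceeds a blow-up bound.

Two per-step noise scalings are implemented: the default `dt_over_tau`
(σ·(dt/τx)·v, amplitude 0.015/step) and `sqrt_dt_over_tau`
(σ·√(dt/τx)·v, 0.047/step — Euler–Maruyama in τx-normalized time).
Under the default the excitable rest state's stationary fluctuation
(std ≈ 0.06) sits ≈ 6σ below the escape barrier, so spiking beyond the
initial transient is essentially absent; the √ scaling makes an isolated
node spike at ~2/s while diffusive coupling still stabilizes the
network. Both are exposed because the regime phenomenology depends
sharply on this choice.

**Spike FC.** Spikes are detected as threshold crossings of x (threshold
1.0) on the 1 ms grid. `binarize_spikes` marks level-exceedance per bin
by default; FC counting uses **onset-only** marking (a bin counts only if
it contains an upward crossing), because a supra-threshold plateau lasts
40–80 ms (set by τy) and would otherwise contribute one count per
millisecond, swamping coincidence counts and forcing
FCseq ≈ −(11/12)·FCsim identically. FCsim is the co-activation count
matrix of the 1 ms onset raster; FCseq is the count matrix of the
12 ms-coarsened raster (disjoint windows) minus FCsim — joint spikes
within a window but not within the same millisecond. Entries can be
negative (several same-window spikes) and are preserved. Both matrices
are symmetric by construction, unlike the SER sequential matrix.

## The SC/FC statistic and sweeps

`scfc_correlation` correlates SC and FC over **all ordered off-diagonal
pairs** for every model (the asymmetric SER sequential matrix therefore
contributes both orientations; an S + Sᵀ symmetrization helper exists
for sensitivity analysis). Missing FC entries are excluded pairwise;
zero variance in either flattened vector yields an explicit
"degenerate" status, never a silent 0. The diagonal is always excluded.

Sweep axes: **randomization** (fraction of the full schedule; 10% = 50
moves for the 420-edge graphs, 20 for the hierarchical graph, both
configurable), **coupling** (k grids for oscillators and maps; the SER
automaton has no coupling parameter and rejects this axis), and
**intrinsic** (SER recovery probability p; width of the Kuramoto ω
interval, widened symmetrically about its midpoint; midpoint of the
logistic R interval at fixed width 0.2). Each grid point regenerates the
graph for `n_graph_seeds` independent seeds (default 10; trend tests use
5) and aggregates mean ± sd across graph seeds (SER, Kuramoto, FHN) or
across runs pooled over graph seeds (logistic maps).

**Seeding.** A master seed spawns one `numpy.random.SeedSequence` child
per (grid value, graph seed) cell, keyed by a CRC-32 hash of the grid
value rather than its position. Any cell therefore reproduces
identically whether computed inside a full sweep, alone, serially or in
parallel, and two sweeps with equal master seeds are bit-identical.

## What the synthetic setup does and does not show

The generators and dynamics above *are* the study system — there is no
external data; every quantitative statement in the test suite is about
these ensembles at the stated sizes. Reduced ensemble sizes (SER 1000
runs instead of 10 000, 20 oscillator/map runs instead of 100/50, FHN 3
runs of 20 s instead of 10 of 180 s, 5 graph seeds instead of 10) keep
the suite fast; directional trend tests compare means across seeds with
margins, not pixel-level curves. Two caveats:

- The FHN **excitable-regime** sequential dominance on randomized graphs
  is a weak, slowly accumulating signal: at 3 × 20 s per graph the
  excitable network carries roughly one spike wave per run and the
  co-activation/sequential comparison is at noise level (measured
  r_sim ≈ +0.03 vs r_seq ≈ 0.00 over 5 graph seeds under the default
  noise scaling; similar under the √ scaling). A single 180 s run does
  show the sequential class ahead (+0.08 vs +0.06, √ scaling). The
  corresponding trend test is kept at the reduced scale and currently
  fails; treat it as a statement about data volume, not about the
  implementation. The oscillatory-regime counterpart (co-activation
  dominant) is robust at the same scale.
- Excitation propagates between FHN neighbours in under a millisecond
  (set by τx), so nearly all structured coincidences land in the same
  1 ms bin; the 12 ms sequential window mostly captures noise-gated,
  multi-hop recruitment, which needs long horizons to estimate.

## Numerical and interface choices

- Euler (maps: exact iteration) everywhere, first-order convergence
  asserted for FHN by dt-halving; Kuramoto free rotation is exact to
  machine precision and the two-oscillator phase-locking matches the
  closed-form sine ODE solution within Euler error.
- Degenerate inputs fail loudly: empty graphs, complete graphs (no legal
  rewire), short series, non-finite parameters, blow-ups.
- Node indexing is 0-based; 1-based edge lists are detected on read and
  restorable on write. Graphs travel as edge-list TSV, adjacency CSV or
  GraphML; rasters and FC matrices as CSV.
- The CLI is a thin wrapper (`netdyn graph make/randomize`, `netdyn
  ser/kuramoto/logistic/fhn`, `netdyn sweep --config experiment.yaml`,
  `netdyn matrices`); every flag overrides the YAML config.

## Known limitations

- No directed or weighted substrates, multilayer graphs, delayed or
  phase-shifted coupling, continuous chaotic flows, or
  information-theoretic FC estimators (transfer entropy, Granger) — the
  framework is deliberately limited to the four probe dynamics and
  correlation/count FC.
- SER ensemble batching changes the RNG draw order relative to
  one-run-at-a-time simulation; results are exchangeable in distribution
  but bit-reproducibility is guaranteed only at fixed batch size
  (default 2000).
- The hierarchical generator is deterministic; "graph seeds" leave it
  unchanged and only the randomization stage varies across seeds.
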