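"""Susceptible–excited–refractory (SER) cellular automaton on a graph.

A minimal stochastic model of excitable dynamics in discrete time with
synchronous updates:

1. S → E if at least one neighbour is excited, or spontaneously with
   probability ``f`` per step;
2. E → R deterministically;
3. R → S with recovery probability ``p`` per step.

Because states and time are discrete, co-activation and sequential
activation are parameter-free counting matrices over the binarized
activity ``c_i(t) = 1`` iff node i is excited at step t:

    C_ij = Σ_t c_i(t) c_j(t)          (co-activation, symmetric)
    S_ij = Σ_t c_i(t) c_j(t-1)        (sequential activation, asymmetric)

Counts are accumulated over time within a run and then summed over an
ensemble of runs with independent random initial conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graphs import validate_adjacency

__all__ = [
    "SERParams",
    "FCPair",
    "S",
    "E",
    "R",
    "ser_init",
    "ser_step",
    "ser_run",
    "coactivation_matrix",
    "sequential_matrix",
    "ser_ensemble_fc",
]

# state codes
S, E, R = 0, 1, 2


@dataclass
class SERParams:
    """Parameters of the SER automaton.

    f
        Spontaneous excitation probability per susceptible node per step
        (default 0.001).
    p
        Recovery probability per refractory node per step (default 0.1).
    t_max
        Number of synchronous updates per run; the raster has
        ``t_max + 1`` columns including the initial condition (default 10).
    n_runs
        Ensemble size for FC accumulation (default 10_000).
    frac_excited_init
        Fraction of nodes excited in the initial condition (default 0.06);
        the rest are S or R with equal probability.
    include_initial
        Whether column 0 enters the C and S sums (default True).
    normalized
        Divide accumulated counts by ``n_runs`` (off by default: raw
        counts; the SC/FC correlation is scale-invariant either way).
    """

    f: float = 0.001
    p: float = 0.1
    t_max: int = 10
    n_runs: int = 10_000
    frac_excited_init: float = 0.06
    include_initial: bool = True
    normalized: bool = False

    def __post_init__(self):
        if not (0.0 <= self.f <= 1.0 and 0.0 <= self.p <= 1.0):
            raise ValueError("f and p must be probabilities in [0, 1]")
        if self.t_max < 1 or self.n_runs < 1:
            raise ValueError("t_max and n_runs must be >= 1")
        if not 0.0 < self.frac_excited_init < 1.0:
            raise ValueError("frac_excited_init must be in (0, 1)")


@dataclass
class FCPair:
    """Co-activation and sequential-activation matrices of one ensemble."""

    C: np.ndarray  # symmetric co-activation counts (or sums of correlations)
    Sm: np.ndarray  # sequential-activation counts, generally asymmetric
    normalized: bool = False


def _init_batch(n: int, n_runs: int, frac_excited: float, rng) -> np.ndarray:
    if n < 1:
        raise ValueError("need at least one node")
    if not 0.0 < frac_excited < 1.0:
        raise ValueError("frac_excited must be in (0, 1)")
    # round-half-up with a floor of one excited node
    n_exc = max(1, int(np.floor(frac_excited * n + 0.5)))
    states = np.where(
        rng.random((n_runs, n)) < 0.5, np.int8(S), np.int8(R)
    )
    for r in range(n_runs):
        exc = rng.choice(n, size=n_exc, replace=False)
        states[r, exc] = E
    return states


def ser_init(n: int, frac_excited: float, rng: np.random.Generator) -> np.ndarray:
    """Random initial state vector.

    ``round(frac_excited * n)`` nodes (at least one) are excited; each
    remaining node is independently S or R with probability 1/2.
    """
    return _init_batch(n, 1, frac_excited, rng)[0]


def _step_batch(states: np.ndarray, A: np.ndarray, f: float, p: float, rng):
    """One synchronous update of a (n_runs, n) batch of state vectors."""
    excited = states == E
    # neighbour drive evaluated on the time-t state for every node
    drive = excited.astype(np.int32) @ A > 0
    spont = rng.random(states.shape) < f if f > 0 else False
    recover = rng.random(states.shape) < p if p < 1 else True
    out = states.copy()
    out[(states == S) & (drive | spont)] = E
    out[excited] = R
    out[(states == R) & recover] = S
    return out


def ser_step(
    x: np.ndarray, A: np.ndarray, params: SERParams, rng: np.random.Generator
) -> np.ndarray:
    """Synchronous update of a single state vector (rules 1–3 above)."""
    A = validate_adjacency(A)
    x = np.asarray(x, dtype=np.int8)
    if x.shape != (A.shape[0],):
        raise ValueError("state vector length must match adjacency size")
    return _step_batch(x[None, :], A, params.f, params.p, rng)[0]


def _run_batch(A, params: SERParams, n_runs: int, rng) -> np.ndarray:
    """Simulate a batch of runs; returns raster (n_runs, n, t_max+1) in {0,1}."""
    n = A.shape[0]
    states = _init_batch(n, n_runs, params.frac_excited_init, rng)
    raster = np.empty((n_runs, n, params.t_max + 1), dtype=np.int8)
    raster[:, :, 0] = states == E
    for t in range(1, params.t_max + 1):
        states = _step_batch(states, A, params.f, params.p, rng)
        raster[:, :, t] = states == E
    return raster


def ser_run(
    A: np.ndarray, params: SERParams, rng: np.random.Generator
) -> np.ndarray:
    """One run from a random initial condition.

    Returns the binary activity raster, shape ``(n, t_max + 1)``; column 0
    is the initial condition.
    """
    A = validate_adjacency(A, require_edges=True)
    return _run_batch(A, params, 1, rng)[0]


def coactivation_matrix(raster: np.ndarray) -> np.ndarray:
    """C_ij = Σ_t c_i(t) c_j(t).  Symmetric; C_ii is node i's excitation count."""
    c = np.asarray(raster, dtype=np.int64)
    if c.ndim != 2 or c.shape[1] < 1:
        raise ValueError("raster must be a non-empty (n, T) matrix")
    return c @ c.T


def sequential_matrix(raster: np.ndarray) -> np.ndarray:
    """S_ij = Σ_t c_i(t) c_j(t−1): j fired one step before i.  Asymmetric."""
    c = np.asarray(raster, dtype=np.int64)
    if c.ndim != 2 or c.shape[1] < 2:
        raise ValueError("raster needs at least two time columns")
    return c[:, 1:] @ c[:, :-1].T


def ser_ensemble_fc(
    A: np.ndarray,
    params: SERParams,
    rng: np.random.Generator,
    batch_size: int = 2000,
) -> FCPair:
    """Accumulate C and S over ``params.n_runs`` independent runs.

    Each run starts from a fresh random initial condition; counts are
    summed over time within a run, then over runs.  Runs are simulated in
    vectorized batches (identical statistics, single RNG stream).
    """
    A = validate_adjacency(A, require_edges=True)
    n = A.shape[0]
    C = np.zeros((n, n), dtype=np.int64)
    Sm = np.zeros((n, n), dtype=np.int64)
    left = params.n_runs
    while left > 0:
        b = min(batch_size, left)
        raster = _run_batch(A, params, b, rng)
        if not params.include_initial:
            raster = raster[:, :, 1:]
        C += np.einsum("rit,rjt->ij", raster, raster, dtype=np.int64)
        Sm += np.einsum("rit,rjt->ij", raster[:, :, 1:], raster[:, :, :-1],
                        dtype=np.int64)
        left -= b
    if params.normalized:
        return FCPair(C / params.n_runs, Sm / params.n_runs, normalized=True)
    return FCPair(C, Sm, normalized=False)
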