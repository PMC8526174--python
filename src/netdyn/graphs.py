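"""Structural-connectivity graphs: generators, randomization and builders.

All functions in this module produce or transform binary, symmetric
adjacency matrices of simple undirected graphs (numpy ``int8`` arrays with
zero diagonal).  These matrices are the common substrate on which every
dynamics module (:mod:`netdyn.ser`, :mod:`netdyn.kuramoto`,
:mod:`netdyn.logistic`, :mod:`netdyn.fhn`) runs.

Generators
----------
``make_modular``
    Four (or more) cliques with stochastic edge rewiring between them.
``make_standard``
    Erdős–Rényi, Barabási–Albert and ring-lattice (Watts–Strogatz
    substrate) ensembles, via networkx.
``make_hierarchical``
    A deterministic hierarchical scale-free modular graph (64 nodes and
    174 edges at three levels).

Randomization
-------------
``randomize_degree_preserving``
    Markov-chain double-edge swaps (degree sequence preserved).
``rewire_one_endpoint``
    Watts–Strogatz-style single-endpoint rewiring (edge count preserved,
    degrees not).

Builders from data
------------------
``graph_from_stoichiometry``
    Metabolite-centric projection of a stoichiometric matrix: an edge
    wherever two metabolites share a reaction (non-zero entry of S·Sᵀ).
``graph_from_weights``
    Thresholding + symmetrization of a real weighted connectivity matrix.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

__all__ = [
    "validate_adjacency",
    "degree_sequence",
    "is_connected",
    "to_networkx",
    "from_networkx",
    "make_modular",
    "make_standard",
    "make_hierarchical",
    "randomize_degree_preserving",
    "rewire_one_endpoint",
    "graph_from_stoichiometry",
    "graph_from_weights",
    "ensure_connected",
]


class GraphParameterError(ValueError):
    """Raised when generator or randomizer parameters are infeasible."""


class RandomizationError(RuntimeError):
    """Raised when a randomizer cannot perform the requested moves."""


# ---------------------------------------------------------------------------
# validation / conversion helpers
# ---------------------------------------------------------------------------

def validate_adjacency(A: np.ndarray, require_edges: bool = False) -> np.ndarray:
    """Check that ``A`` is a binary symmetric zero-diagonal matrix.

    Returns the matrix as a C-contiguous ``int8`` array.  Raises
    :class:`GraphParameterError` on violation.
    """
    A = np.asarray(A)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise GraphParameterError(f"adjacency must be square, got shape {A.shape}")
    if not np.isin(A, (0, 1)).all():
        raise GraphParameterError("adjacency entries must be 0 or 1")
    if np.any(np.diag(A) != 0):
        raise GraphParameterError("adjacency must have zero diagonal (no self-loops)")
    if not np.array_equal(A, A.T):
        raise GraphParameterError("adjacency must be symmetric (undirected graph)")
    if require_edges and A.sum() == 0:
        raise GraphParameterError("graph has no edges")
    return np.ascontiguousarray(A, dtype=np.int8)


def degree_sequence(A: np.ndarray) -> np.ndarray:
    """Row sums of the adjacency matrix (node degrees)."""
    return np.asarray(A).sum(axis=1).astype(int)


def edge_count(A: np.ndarray) -> int:
    """Number of undirected edges."""
    return int(np.asarray(A).sum()) // 2


def is_connected(A: np.ndarray) -> bool:
    return nx.is_connected(to_networkx(A))


def to_networkx(A: np.ndarray) -> nx.Graph:
    return nx.from_numpy_array(np.asarray(A))


def from_networkx(G: nx.Graph) -> np.ndarray:
    A = nx.to_numpy_array(G, dtype=np.int8, nodelist=sorted(G.nodes()))
    np.fill_diagonal(A, 0)
    A[A != 0] = 1
    return validate_adjacency(A)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def make_modular(
    n_cliques: int = 4,
    clique_size: int = 15,
    rewire_p: float = 0.23,
    seed=None,
) -> np.ndarray:
    """Modular graph: disjoint cliques with inter-clique rewiring.

    Starts from ``n_cliques`` cliques of ``clique_size`` nodes each.  Every
    edge is then independently selected with probability ``rewire_p``; a
    selected edge keeps one uniformly chosen endpoint and its other
    endpoint is redrawn uniformly from the non-neighbours of the kept
    endpoint.  Rewiring moves endpoints but never creates or destroys
    edges, so the edge count stays ``n_cliques * C(clique_size, 2)``.

    With the defaults (4 cliques of 15, p = 0.23) this yields the 60-node,
    420-edge modular substrate (density 0.23) used throughout the
    experiment drivers.
    """
    if n_cliques < 2 or clique_size < 2:
        raise GraphParameterError("need n_cliques >= 2 and clique_size >= 2")
    if not 0.0 <= rewire_p <= 1.0:
        raise GraphParameterError(f"rewire_p must be in [0, 1], got {rewire_p}")
    rng = _as_rng(seed)
    n = n_cliques * clique_size
    A = np.zeros((n, n), dtype=np.int8)
    for c in range(n_cliques):
        lo, hi = c * clique_size, (c + 1) * clique_size
        A[lo:hi, lo:hi] = 1
    np.fill_diagonal(A, 0)

    edges = [(i, j) for i in range(n) for j in range(i + 1, n) if A[i, j]]
    for (u, v) in edges:
        if rng.random() >= rewire_p:
            continue
        keep = u if rng.random() < 0.5 else v
        # candidates: non-neighbours of the kept endpoint (self excluded)
        cand = np.flatnonzero(A[keep] == 0)
        cand = cand[cand != keep]
        if cand.size == 0:
            continue  # kept endpoint saturated; edge stays
        new = int(rng.choice(cand))
        A[u, v] = A[v, u] = 0
        A[keep, new] = A[new, keep] = 1
    return validate_adjacency(A)


def make_standard(model: str, n: int, seed=None, **params) -> np.ndarray:
    """Standard random-graph ensembles on ``n`` nodes.

    Parameters
    ----------
    model
        ``"erdos_renyi"`` (param ``p``, default 0.23),
        ``"barabasi_albert"`` (param ``m``, default 8), or
        ``"watts_strogatz"`` (params ``ring_neighbors`` — total neighbours
        per node, default 14 — and optional ``rewire_p``, default 0: the
        pristine ring lattice, to be rewired separately with
        :func:`rewire_one_endpoint`).
    """
    rng = _as_rng(seed)
    nx_seed = int(rng.integers(2**31))
    if n < 1:
        raise GraphParameterError("n must be positive")
    if model == "erdos_renyi":
        p = params.pop("p", 0.23)
        if not 0 <= p <= 1:
            raise GraphParameterError(f"edge probability must be in [0,1], got {p}")
        G = nx.erdos_renyi_graph(n, p, seed=nx_seed)
    elif model == "barabasi_albert":
        m = params.pop("m", 8)
        if not 1 <= m < n:
            raise GraphParameterError(f"need 1 <= m < n, got m={m}, n={n}")
        G = nx.barabasi_albert_graph(n, m, seed=nx_seed)
    elif model == "watts_strogatz":
        k = params.pop("ring_neighbors", 14)
        rp = params.pop("rewire_p", 0.0)
        if k % 2 or not 0 < k < n:
            raise GraphParameterError(
                f"ring_neighbors must be even and in (0, n); got {k}"
            )
        G = nx.watts_strogatz_graph(n, k, rp, seed=nx_seed)
    else:
        raise GraphParameterError(f"unknown model {model!r}")
    if params:
        raise GraphParameterError(f"unused parameters for {model}: {sorted(params)}")
    return from_networkx(G)


def make_hierarchical(levels: int = 3) -> np.ndarray:
    """Deterministic hierarchical scale-free modular graph.

    Level 1 is a fully connected 4-node module (hub = node 0).  Each
    further level takes four copies of the previous graph and wires, into
    the root hub of the first copy, (a) the outermost peripheral nodes of
    the three replicas and (b) each replica's own central node.  The edge
    count recursion is ``E_k = 4 E_{k-1} + 3^k + 3``, i.e. 6, 36, 174
    edges at levels 1, 2, 3 on 4, 16, 64 nodes.

    The result combines a heavy-tailed (scale-free-like) degree sequence —
    the root hub at level 3 has degree 45 — with nested modular structure.
    """
    if levels < 1:
        raise GraphParameterError("levels must be >= 1")
    G = nx.complete_graph(4)
    peripheral = [1, 2, 3]
    for level in range(2, levels + 1):
        n = G.number_of_nodes()
        H = nx.Graph()
        new_peripheral = []
        for c in range(4):
            H.add_edges_from((u + c * n, v + c * n) for u, v in G.edges())
            if c > 0:
                new_peripheral.extend(p + c * n for p in peripheral)
        for c in range(1, 4):
            for p in peripheral:
                H.add_edge(0, p + c * n)
            H.add_edge(0, c * n)
        G = H
        peripheral = new_peripheral
    return from_networkx(G)


# ---------------------------------------------------------------------------
# randomization / rewiring
# ---------------------------------------------------------------------------

def randomize_degree_preserving(
    A: np.ndarray,
    n_swaps: int,
    seed=None,
    max_tries_per_swap: int = 100,
) -> np.ndarray:
    """Degree-preserving randomization by double-edge swaps.

    Repeatedly picks two distinct edges (a, b), (c, d) and replaces them
    with (a, d), (c, b) provided no self-loop or multi-edge would result.
    Exactly ``n_swaps`` *successful* swaps are performed; rejected
    proposals do not count.  The degree of every node, and hence the edge
    count, is preserved.  The input matrix is not modified.

    Raises
    ------
    RandomizationError
        If the graph has fewer than two edges, or the proposal budget
        (``max_tries_per_swap * n_swaps``) is exhausted — e.g. on a
        triangle, where no legal swap exists.
    """
    if n_swaps < 0:
        raise GraphParameterError("n_swaps must be >= 0")
    A = validate_adjacency(A).copy()
    if n_swaps == 0:
        return A
    rng = _as_rng(seed)
    ii, jj = np.nonzero(np.triu(A, 1))
    edges = list(zip(ii.tolist(), jj.tolist()))
    if len(edges) < 2:
        raise RandomizationError("need at least two edges to swap")
    done = 0
    budget = max_tries_per_swap * n_swaps
    while done < n_swaps:
        if budget <= 0:
            raise RandomizationError(
                f"exhausted proposal budget after {done}/{n_swaps} swaps; "
                "the graph may admit no further legal double-edge swaps"
            )
        budget -= 1
        e1, e2 = rng.integers(len(edges)), rng.integers(len(edges))
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if rng.random() < 0.5:
            c, d = d, c
        # propose (a, b), (c, d) -> (a, d), (c, b)
        if a == d or c == b or A[a, d] or A[c, b]:
            continue
        A[a, b] = A[b, a] = 0
        A[c, d] = A[d, c] = 0
        A[a, d] = A[d, a] = 1
        A[c, b] = A[b, c] = 1
        edges[e1] = (min(a, d), max(a, d))
        edges[e2] = (min(c, b), max(c, b))
        done += 1
    return A


def rewire_one_endpoint(A: np.ndarray, n_rewires: int, seed=None) -> np.ndarray:
    """Single-endpoint rewiring (Watts–Strogatz scheme).

    Each move destroys a randomly selected edge and creates a new edge
    between one of its two endpoints (chosen at random) and a node drawn
    uniformly from the non-neighbours of that endpoint.  Edge count and
    simplicity are preserved; the degree sequence generally is not.
    Starting from a ring lattice, increasing ``n_rewires`` takes the graph
    through a small-world regime toward an Erdős–Rényi-like topology.
    """
    if n_rewires < 0:
        raise GraphParameterError("n_rewires must be >= 0")
    A = validate_adjacency(A).copy()
    n = A.shape[0]
    rng = _as_rng(seed)
    if n_rewires and edge_count(A) >= n * (n - 1) // 2:
        raise RandomizationError("complete graph: no legal new edge exists")
    for _ in range(n_rewires):
        ii, jj = np.nonzero(np.triu(A, 1))
        if ii.size == 0:
            raise RandomizationError("graph has no edges to rewire")
        e = rng.integers(ii.size)
        u, v = int(ii[e]), int(jj[e])
        keep, drop = (u, v) if rng.random() < 0.5 else (v, u)
        cand = np.flatnonzero(A[keep] == 0)
        cand = cand[cand != keep]
        if cand.size == 0:
            # kept endpoint saturated: keep the other endpoint instead
            keep, drop = drop, keep
            cand = np.flatnonzero(A[keep] == 0)
            cand = cand[cand != keep]
            if cand.size == 0:
                continue
        new = int(rng.choice(cand))
        A[u, v] = A[v, u] = 0
        A[keep, new] = A[new, keep] = 1
    return validate_adjacency(A)


# ---------------------------------------------------------------------------
# builders from data
# ---------------------------------------------------------------------------

def graph_from_stoichiometry(S: np.ndarray) -> np.ndarray:
    """Metabolite-centric graph from a stoichiometric matrix.

    ``S`` is metabolites × reactions.  Two metabolites are adjacent iff
    they participate in at least one common reaction, i.e. iff the
    corresponding off-diagonal entry of S·Sᵀ is non-zero.
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.size == 0:
        raise GraphParameterError("stoichiometric matrix must be non-empty 2-D")
    if not np.isfinite(S).all():
        raise GraphParameterError("stoichiometric matrix must be finite numeric")
    M = S @ S.T
    A = (M != 0).astype(np.int8)
    np.fill_diagonal(A, 0)
    return validate_adjacency(A)


def graph_from_weights(
    W: np.ndarray,
    threshold: float,
    log10_transform: bool = False,
) -> np.ndarray:
    """Binary graph from a real weighted connectivity matrix.

    An edge i–j is accepted if the (optionally log10-transformed) weight
    passes ``threshold`` in *either* direction — thresholding followed by
    symmetrization.  Non-positive weights under the log transform, and
    NaNs, never pass.  The diagonal is discarded.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise GraphParameterError(f"weight matrix must be square, got {W.shape}")
    if log10_transform:
        with np.errstate(divide="ignore", invalid="ignore"):
            T = np.where(W > 0, np.log10(np.where(W > 0, W, 1.0)), -np.inf)
    else:
        T = np.where(np.isnan(W), -np.inf, W)
    passes = T > threshold
    A = (passes | passes.T).astype(np.int8)
    np.fill_diagonal(A, 0)
    return validate_adjacency(A)


# ---------------------------------------------------------------------------
# connectivity guard
# ---------------------------------------------------------------------------

def ensure_connected(factory, seed, max_resamples: int = 50) -> np.ndarray:
    """Draw graphs from ``factory(seed)`` until one is connected.

    Dynamics sweeps require a connected substrate (synchronization and
    excitation spreading are uninterpretable on disconnected components).
    Resampling derives new seeds deterministically from the original.
    """
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(max_resamples):
        A = factory(np.random.default_rng(child))
        if is_connected(A):
            return A
    raise RandomizationError(
        f"no connected graph found in {max_resamples} resamples"
    )
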