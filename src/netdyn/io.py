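"""Readers and writers for graphs, rasters and FC matrices.

Graphs travel as edge-list TSV (two integer columns, optional header),
square adjacency CSV, or GraphML.  Stoichiometric matrices are extracted
from SBML Level 2/3 files.  Node indexing is 0-based internally; 1-based
edge lists are detected on read (no node 0 present) and restored on write
via the ``one_based`` flag.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from . import graphs

__all__ = [
    "read_graph",
    "write_graph",
    "read_edgelist_tsv",
    "write_edgelist_tsv",
    "read_adjacency_csv",
    "write_adjacency_csv",
    "read_graphml",
    "write_graphml",
    "read_weight_matrix_csv",
    "stoichiometric_matrix_from_sbml",
    "write_raster_csv",
    "write_fc_csv",
    "read_fc_csv",
]


def read_edgelist_tsv(path) -> np.ndarray:
    """Two-column integer TSV; a non-numeric first row is treated as header."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    first = df.iloc[0]
    if not all(s.lstrip("-").isdigit() for s in first):
        df = df.iloc[1:]
    edges = df.iloc[:, :2].astype(int).to_numpy()
    if edges.size == 0:
        raise ValueError(f"no edges in {path}")
    offset = 1 if edges.min() >= 1 else 0
    edges -= offset
    n = int(edges.max()) + 1
    A = np.zeros((n, n), dtype=np.int8)
    A[edges[:, 0], edges[:, 1]] = 1
    A[edges[:, 1], edges[:, 0]] = 1
    np.fill_diagonal(A, 0)
    return graphs.validate_adjacency(A)


def write_edgelist_tsv(A: np.ndarray, path, one_based: bool = False) -> None:
    A = graphs.validate_adjacency(A)
    ii, jj = np.nonzero(np.triu(A, 1))
    off = 1 if one_based else 0
    pd.DataFrame({"source": ii + off, "target": jj + off}).to_csv(
        path, sep="\t", index=False
    )


def read_adjacency_csv(path) -> np.ndarray:
    M = pd.read_csv(path, header=None).to_numpy(dtype=float)
    if not np.isin(M, (0, 1)).all():
        raise ValueError("adjacency CSV must contain only 0/1 entries")
    return graphs.validate_adjacency(M.astype(np.int8))


def write_adjacency_csv(A: np.ndarray, path) -> None:
    A = graphs.validate_adjacency(A)
    pd.DataFrame(A).to_csv(path, header=False, index=False)


def read_graphml(path) -> np.ndarray:
    import networkx as nx

    try:
        G = nx.read_graphml(path, node_type=int)
    except (ValueError, TypeError):
        # non-numeric node ids: fall back to label-sorted integer relabeling
        G = nx.read_graphml(path)
        G = nx.convert_node_labels_to_integers(G, ordering="sorted")
    return graphs.from_networkx(nx.Graph(G))


def write_graphml(A: np.ndarray, path) -> None:
    import networkx as nx

    nx.write_graphml(graphs.to_networkx(graphs.validate_adjacency(A)), path)


_READERS = {
    ".tsv": read_edgelist_tsv,
    ".txt": read_edgelist_tsv,
    ".csv": read_adjacency_csv,
    ".graphml": read_graphml,
}
_WRITERS = {
    ".tsv": write_edgelist_tsv,
    ".txt": write_edgelist_tsv,
    ".csv": write_adjacency_csv,
    ".graphml": write_graphml,
}


def read_graph(path) -> np.ndarray:
    """Dispatch on file extension (.tsv/.txt edge list, .csv adjacency, .graphml)."""
    ext = os.path.splitext(str(path))[1].lower()
    try:
        return _READERS[ext](path)
    except KeyError:
        raise ValueError(f"unsupported graph format {ext!r}") from None


def write_graph(A: np.ndarray, path) -> None:
    ext = os.path.splitext(str(path))[1].lower()
    try:
        _WRITERS[ext](A, path)
    except KeyError:
        raise ValueError(f"unsupported graph format {ext!r}") from None


def read_weight_matrix_csv(path) -> np.ndarray:
    """Square real-valued matrix for :func:`netdyn.graphs.graph_from_weights`."""
    W = pd.read_csv(path, header=None).to_numpy(dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(f"weight matrix must be square, got {W.shape}")
    return W


def stoichiometric_matrix_from_sbml(path) -> tuple[np.ndarray, list[str]]:
    """Extract the metabolites × reactions stoichiometric matrix from SBML.

    Reactant coefficients enter with negative sign, products positive.
    Returns the matrix and the list of species (metabolite) identifiers in
    row order.
    """
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR):
        raise ValueError(f"SBML parse error in {path}")
    model = doc.getModel()
    if model is None:
        raise ValueError(f"no model in {path}")
    species = [model.getSpecies(i).getId() for i in range(model.getNumSpecies())]
    index = {s: i for i, s in enumerate(species)}
    S = np.zeros((len(species), model.getNumReactions()))
    for j in range(model.getNumReactions()):
        rxn = model.getReaction(j)
        for k in range(rxn.getNumReactants()):
            ref = rxn.getReactant(k)
            S[index[ref.getSpecies()], j] -= ref.getStoichiometry()
        for k in range(rxn.getNumProducts()):
            ref = rxn.getProduct(k)
            S[index[ref.getSpecies()], j] += ref.getStoichiometry()
    return S, species


def write_raster_csv(raster: np.ndarray, path) -> None:
    """Node × time raster (binary activity or real states) as CSV."""
    pd.DataFrame(np.asarray(raster)).to_csv(path, header=False, index=False)


def write_fc_csv(F: np.ndarray, path, labels=None) -> None:
    """Square FC matrix as CSV with a header row of node labels."""
    F = np.asarray(F)
    if labels is None:
        labels = [str(i) for i in range(F.shape[0])]
    pd.DataFrame(F, columns=labels).to_csv(path, index=False)


def read_fc_csv(path) -> np.ndarray:
    return pd.read_csv(path).to_numpy(dtype=float)
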