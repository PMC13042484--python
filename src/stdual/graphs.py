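"""Dual adjacency graph construction.

Two binary, symmetric, zero-diagonal views over the same spots:

* SAG (spatial adjacency graph): a symmetrized k-NN graph in coordinate
  space, pruned by removing edges whose consensus co-assignment frequency
  C_ij falls below a confidence threshold tau (default 0.2);
* FAG (feature adjacency graph): candidate neighbor pairs drawn from the
  intersection of each spot's consensus neighborhood (C_ij = 1, padded by
  next-highest consensus) and its top cosine-similarity neighborhood in
  topic-activity space, inserted while both endpoints stay under a
  per-node cap of newly added edges.

The FAG is the long-range mechanism: spatially disjoint regions sharing a
transcriptional program can be linked even though the SAG never connects
them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.neighbors import kneighbors_graph

__all__ = ["DualGraph", "build_spatial_graph", "build_feature_graph"]


@dataclass
class DualGraph:
    A_coord: sp.csr_matrix
    A_feat: sp.csr_matrix
    k: int = 6
    tau: float = 0.2
    n_neighbors: int = 6


def build_spatial_graph(
    coords: np.ndarray, k: int = 6, C: np.ndarray | None = None, tau: float = 0.2
) -> sp.csr_matrix:
    """Symmetrized spatial k-NN graph with consensus pruning.

    Edges (i, j) with C_ij < tau are removed after symmetrization; with
    ``C=None`` no pruning is applied.
    """
    n = coords.shape[0]
    if k >= n:
        raise ValueError("k-too-large: need k < number of spots")
    A = kneighbors_graph(coords, n_neighbors=k, include_self=False)
    A = A.maximum(A.T)  # element-wise max with transpose -> undirected
    if C is not None:
        A = A.tocoo()
        keep = C[A.row, A.col] >= tau
        A = sp.coo_matrix(
            (A.data[keep], (A.row[keep], A.col[keep])), shape=(n, n)
        )
    A = sp.csr_matrix(A)
    A.setdiag(0)
    A.eliminate_zeros()
    A.data = np.ones_like(A.data)
    return A


def _consensus_neighbors(C: np.ndarray, i: int, n_neighbors: int) -> set:
    """Spots with C_ij = 1, padded with next-highest consensus scores until the
    set reaches n_neighbors; ties break by score descending then index."""
    row = C[i].copy()
    row[i] = -np.inf
    members = set(np.flatnonzero(row == 1.0).tolist())
    if len(members) < n_neighbors:
        order = np.lexsort((np.arange(row.size), -row))
        for j in order:
            if len(members) >= n_neighbors:
                break
            if j != i and row[j] < 1.0 and row[j] > 0:
                members.add(int(j))
    return members


def build_feature_graph(
    topic_features: np.ndarray, C: np.ndarray, n_neighbors: int = 6
) -> sp.csr_matrix:
    """FAG from consensus + cosine neighborhoods with a per-node degree cap.

    Candidate pairs are visited in ascending spot order, then by cosine
    similarity rank, and inserted symmetrically only while both endpoints
    have added fewer than ``n_neighbors`` edges.
    """
    X = np.asarray(topic_features, dtype=float)
    n = X.shape[0]
    norms = np.linalg.norm(X, axis=1)
    zero = norms == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} spots have zero-norm feature rows; "
            "excluded from cosine ranking"
        )
    Xn = np.where(zero[:, None], 0.0, X / np.where(norms == 0, 1.0, norms)[:, None])
    S = Xn @ Xn.T
    np.fill_diagonal(S, -np.inf)
    S[:, zero] = -np.inf
    S[zero, :] = -np.inf

    deg_add = np.zeros(n, dtype=int)
    rows, cols = [], []
    added = set()
    kk = min(n_neighbors, n - 1)
    for i in range(n):
        if zero[i]:
            continue
        cons = _consensus_neighbors(C, i, n_neighbors)
        # top-n cosine neighbors, ties by index ascending
        order = np.lexsort((np.arange(n), -S[i]))
        feat = [int(j) for j in order[:kk] if np.isfinite(S[i, j])]
        for j in feat:  # iterate in similarity-rank order
            if j not in cons:
                continue
            key = (min(i, j), max(i, j))
            if key in added:
                continue
            if deg_add[i] < n_neighbors and deg_add[j] < n_neighbors:
                added.add(key)
                rows += [i, j]
                cols += [j, i]
                deg_add[i] += 1
                deg_add[j] += 1
    A = sp.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    ).tocsr()
    A.data = np.ones_like(A.data)
    return A
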