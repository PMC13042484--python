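"""Multi-resolution consensus clustering.

Repeated clustering of the PCA features (Leiden over a resolution sweep, or a
Gaussian mixture over a sweep of component counts) is condensed into a
co-assignment consensus matrix

    C_ij = (1/r) * sum_t 1[l_i(t) = l_j(t)],

and preliminary domain labels L_init are obtained by Leiden community
detection on the graph whose edge weights are the C_ij.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
from sklearn.mixture import GaussianMixture
from sklearn.neighbors import kneighbors_graph

__all__ = [
    "ClusteringRun",
    "ConsensusResult",
    "run_multiresolution_clustering",
    "build_consensus_matrix",
    "derive_initial_labels",
    "leiden_on_graph",
]

DEFAULT_LEIDEN_RESOLUTIONS = tuple(np.round(np.arange(0.1, 1.01, 0.1), 2))


@dataclass
class ClusteringRun:
    labels: np.ndarray
    method: str
    resolution_or_k: float

    def __post_init__(self):
        # relabel to 0-based contiguous ids
        _, self.labels = np.unique(np.asarray(self.labels), return_inverse=True)


@dataclass
class ConsensusResult:
    C: np.ndarray
    runs: list
    L_init: np.ndarray
    n_cluster: int = field(default=0)


def _knn_igraph(features: np.ndarray, k: int = 15) -> ig.Graph:
    A = kneighbors_graph(features, n_neighbors=min(k, len(features) - 1))
    A = A.maximum(A.T).tocoo()
    edges = [(int(i), int(j)) for i, j in zip(A.row, A.col) if i < j]
    g = ig.Graph(n=features.shape[0], edges=edges)
    return g


def leiden_on_graph(
    graph: ig.Graph,
    resolution: float = 1.0,
    seed: int = 0,
    weights=None,
) -> np.ndarray:
    """Leiden (RB-configuration modularity) labels on an igraph graph."""
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        weights=weights,
        seed=seed,
        n_iterations=2,
    )
    return np.asarray(part.membership)


def run_multiresolution_clustering(
    features: np.ndarray,
    method: str = "leiden",
    settings=None,
    seed: int = 0,
    knn: int = 15,
    target_k: int | None = None,
) -> list:
    """One :class:`ClusteringRun` per setting.

    ``settings`` are Leiden resolutions (default 0.1..1.0 step 0.1) or GMM
    component counts (default a small band {K-2, ..., K+2} around a user
    target ``target_k``).  All runs are reproducible under ``seed``.
    """
    if settings is None and method == "leiden":
        settings = DEFAULT_LEIDEN_RESOLUTIONS
    if settings is None and method == "gmm" and target_k is not None:
        settings = [k for k in range(target_k - 2, target_k + 3) if k >= 2]
    if settings is None or len(settings) == 0:
        raise ValueError("no-runs: settings must be non-empty")
    runs = []
    if method == "leiden":
        g = _knn_igraph(features, k=knn)
        for res in settings:
            labels = leiden_on_graph(g, resolution=float(res), seed=seed)
            runs.append(ClusteringRun(labels, "leiden", float(res)))
    elif method == "gmm":
        for k in settings:
            best, best_ll = None, -np.inf
            for restart in range(10):
                gm = GaussianMixture(
                    n_components=int(k),
                    covariance_type="tied",  # EEE, stable on wide embeddings
                    random_state=seed * 1000 + restart,
                    n_init=1,
                    reg_covar=1e-4,
                )
                lab = gm.fit_predict(features)
                ll = gm.score(features)
                if ll > best_ll:
                    best, best_ll = lab, ll
            runs.append(ClusteringRun(best, "gmm", float(k)))
    else:
        raise ValueError(f"unknown method {method!r}")
    return runs


def build_consensus_matrix(runs: list) -> np.ndarray:
    """Co-assignment frequency matrix C (N x N, entries multiples of 1/r)."""
    if not runs:
        raise ValueError("no-runs")
    n = runs[0].labels.size
    if any(r.labels.size != n for r in runs):
        raise ValueError("run-mismatch: label vectors differ in length")
    C = np.zeros((n, n))
    for r in runs:
        lab = r.labels
        C += (lab[:, None] == lab[None, :]).astype(float)
    C /= len(runs)
    return C


def derive_initial_labels(
    C: np.ndarray, resolution: float = 1.0, seed: int = 0
) -> tuple[np.ndarray, int]:
    """Leiden communities on the consensus-weighted graph -> (L_init, n_cluster).

    Edges are all pairs with C_ij > 0 (self-loops excluded), weighted by C_ij.
    """
    n = C.shape[0]
    iu = np.triu_indices(n, k=1)
    w = C[iu]
    nz = w > 0
    if not nz.any():
        raise ValueError("degenerate-consensus: no positive off-diagonal entries")
    edges = list(zip(iu[0][nz].tolist(), iu[1][nz].tolist()))
    g = ig.Graph(n=n, edges=edges)
    labels = leiden_on_graph(g, resolution=resolution, seed=seed, weights=w[nz])
    _, labels = np.unique(labels, return_inverse=True)
    return labels, int(labels.max() + 1)
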