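"""Spatial domain calling from the fused embedding.

With a known target cluster count the embedding is clustered by a Gaussian
mixture (best of 10 seeded restarts); otherwise Leiden resolution is chosen
by a Calinski-Harabasz grid search over [0.1, 2.5].  An optional single-pass
local refinement reassigns spots whose label disagrees with the modal label
of their 25 nearest spatial neighbors — recommended only for coarse
spot-based platforms, since it can over-smooth fine structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import calinski_harabasz_score
from sklearn.mixture import GaussianMixture
from sklearn.neighbors import NearestNeighbors

from .consensus import _knn_igraph, leiden_on_graph

__all__ = [
    "DomainResult",
    "cluster_embeddings",
    "search_resolution",
    "refine_labels_local",
]


@dataclass
class DomainResult:
    labels: np.ndarray
    method: str
    resolution: float | None = None
    ch_score: float | None = None
    refined: bool = False


def _contiguous(labels: np.ndarray) -> np.ndarray:
    _, lab = np.unique(labels, return_inverse=True)
    return lab


def cluster_embeddings(
    E_att: np.ndarray,
    n_clusters: int | None = None,
    method: str = "gmm",
    seed: int = 0,
    knn: int = 15,
) -> DomainResult:
    """GMM with a fixed K when the domain count is known, else a CH-searched
    Leiden clustering."""
    E = np.asarray(E_att, dtype=float)
    if not np.all(np.isfinite(E)):
        raise ValueError("E_att must be finite")
    if n_clusters is not None and method == "gmm":
        if n_clusters > E.shape[0]:
            raise ValueError("invalid-k: more clusters than spots")
        if n_clusters == 1:
            return DomainResult(np.zeros(E.shape[0], dtype=int), "gmm")
        best, best_ll = None, -np.inf
        for restart in range(10):
            gm = GaussianMixture(
                n_components=n_clusters,
                covariance_type="tied",  # the EEE model Mclust defaults to
                random_state=seed * 1000 + restart,
                n_init=1,
                reg_covar=1e-4,
            )
            lab = gm.fit_predict(E)
            ll = gm.score(E)
            if ll > best_ll:
                best, best_ll = lab, ll
        return DomainResult(_contiguous(best), "gmm")
    res, result = search_resolution(E, seed=seed, knn=knn)
    return result


def search_resolution(
    E_att: np.ndarray,
    lo: float = 0.1,
    hi: float = 2.5,
    step: float = 0.001,
    seed: int = 0,
    knn: int = 15,
) -> tuple[float, DomainResult]:
    """Grid search for the Leiden resolution maximizing the CH score on the
    embedding.  Resolutions yielding a single cluster are skipped; ties break
    toward the lowest resolution."""
    if not (lo < hi and step > 0):
        raise ValueError("need lo < hi and step > 0")
    E = np.asarray(E_att, dtype=float)
    g = _knn_igraph(E, k=knn)
    best_res, best_ch, best_lab = None, -np.inf, None
    for res in np.arange(lo, hi + step / 2, step):
        lab = leiden_on_graph(g, resolution=float(res), seed=seed)
        if np.unique(lab).size < 2:
            continue
        ch = calinski_harabasz_score(E, lab)
        if ch > best_ch:
            best_res, best_ch, best_lab = float(res), float(ch), lab
    if best_lab is None:
        raise ValueError("no-partition-found: every resolution gave one cluster")
    return best_res, DomainResult(
        _contiguous(best_lab), "leiden", resolution=best_res, ch_score=best_ch
    )


def refine_labels_local(
    labels: np.ndarray,
    coords: np.ndarray,
    n: int = 25,
    enabled: bool = True,
) -> np.ndarray:
    """Single-pass modal reassignment over the n nearest spatial neighbors.

    A spot keeps its label on a modal tie.  Never increases the number of
    distinct labels.  Disabled (identity) when ``enabled`` is False.
    """
    labels = np.asarray(labels)
    if not enabled:
        return labels.copy()
    N = labels.size
    if n >= N:
        raise ValueError("n must be < number of spots")
    nn = NearestNeighbors(n_neighbors=n + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    idx = idx[:, 1:]  # drop self
    out = labels.copy()
    n_lab = int(labels.max()) + 1
    for i in range(N):
        counts = np.bincount(labels[idx[i]], minlength=n_lab)
        top = counts.max()
        modal = np.flatnonzero(counts == top)
        if labels[i] in modal:
            continue  # ties involving the original label keep it
        if modal.size == 1:
            out[i] = modal[0]
        # ambiguous tie between other labels: keep original
    return out
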