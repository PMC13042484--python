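"""NMF topic modeling of log expression, with spatial and supervised filtering.

The log-expression matrix is factorized as X ~ Z Hᵀ with non-negative
spot-topic weights Z (N x K) and gene-topic weights H (G x K), NNDSVD
initialization.  Topics are then filtered twice:

1. spatially — topics whose Moran's I falls below a threshold (default 0.2)
   are discarded as spatially unstructured;
2. by discriminative power — a random forest trained to predict the
   preliminary consensus labels from the surviving topics scores each topic
   by its mean Gini-impurity reduction, and the bottom fraction p (default
   0.2) is dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import NMF
from sklearn.ensemble import RandomForestClassifier

from .spatial import SpatialWeights, morans_i_batch

__all__ = [
    "TopicModel",
    "fit_nmf",
    "filter_topics_by_mri",
    "score_topic_importance",
    "select_informative_topics",
]


@dataclass
class TopicModel:
    Z: np.ndarray  # N x K, column min-max normalized to [0, 1]
    H: np.ndarray  # G x K, original scale
    mri: np.ndarray | None = None
    importances: np.ndarray | None = None
    filtered: np.ndarray | None = None  # indices surviving the spatial filter
    selected: np.ndarray | None = None  # final topic index set T (into 0..K-1)
    reconstruction_err: float = 0.0

    @property
    def n_topics(self) -> int:
        return self.Z.shape[1]

    @property
    def Z_final(self) -> np.ndarray:
        if self.selected is None:
            raise ValueError("topics not selected yet")
        return self.Z[:, self.selected]


def _minmax_columns(Z: np.ndarray) -> np.ndarray:
    """Column-wise min-max to [0, 1]; constant columns map to all zeros."""
    lo = Z.min(axis=0)
    rng = Z.max(axis=0) - lo
    out = np.zeros_like(Z, dtype=float)
    ok = rng > 0
    out[:, ok] = (Z[:, ok] - lo[ok]) / rng[ok]
    return out


def fit_nmf(
    loggered: np.ndarray,
    n_topics: int = 30,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-4,
) -> TopicModel:
    """Frobenius NMF with NNDSVD init; Z min-max normalized per column."""
    X = np.asarray(loggered, dtype=float)
    if np.any(X < 0):
        raise ValueError("negative-input: NMF requires a non-negative matrix")
    if n_topics >= min(X.shape):
        raise ValueError("n_topics must be < min(N, G)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = NMF(
            n_components=n_topics,
            init="nndsvd",
            solver="cd",
            max_iter=max_iter,
            tol=tol,
            random_state=seed,
        )
        W = model.fit_transform(X)
    return TopicModel(
        Z=_minmax_columns(W),
        H=model.components_.T.copy(),
        reconstruction_err=float(model.reconstruction_err_),
    )


def filter_topics_by_mri(
    tm: TopicModel, weights: SpatialWeights, threshold: float = 0.2
) -> TopicModel:
    """Keep topics with Moran's I >= threshold (inclusive boundary)."""
    tm.mri = morans_i_batch(tm.Z, weights)
    keep = np.flatnonzero(tm.mri >= threshold)
    if keep.size == 0:
        raise ValueError("no-spatial-topics: every topic fails the Moran's I filter")
    tm.filtered = keep
    return tm


def score_topic_importance(
    Z_filtered: np.ndarray,
    L_init: np.ndarray,
    n_trees: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Random-forest Gini importances of topics for the preliminary labels.

    Trained on all spots (no split); importances are normalized to sum to 1,
    which leaves the ranking untouched.
    """
    L_init = np.asarray(L_init)
    if np.unique(L_init).size < 2:
        raise ValueError("degenerate-labels: need >= 2 classes")
    rf = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1
    )
    rf.fit(Z_filtered, L_init)
    imp = rf.feature_importances_
    s = imp.sum()
    return imp / s if s > 0 else np.full_like(imp, 1.0 / imp.size)


def select_informative_topics(
    tm: TopicModel, importances: np.ndarray, p: float = 0.2
) -> TopicModel:
    """Keep the top floor((1 - p) * N_filt) topics by importance.

    Ties at the cut break by topic index ascending.
    """
    if not 0 <= p < 1:
        raise ValueError("p must satisfy 0 <= p < 1")
    if tm.filtered is None:
        raise ValueError("run filter_topics_by_mri first")
    n_filt = tm.filtered.size
    n_keep = int(np.floor((1 - p) * n_filt))
    if n_keep == 0:
        raise ValueError("no-topics-selected")
    tm.importances = np.asarray(importances, dtype=float)
    order = np.argsort(-tm.importances, kind="stable")[:n_keep]
    tm.selected = np.sort(tm.filtered[order])
    return tm
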