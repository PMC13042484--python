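"""Benchmark metrics and rank-based aggregation.

Accuracy (NMI, homogeneity, completeness, ARI) compares predicted domains to
annotations; continuity (CHAOS, PAS, ASW) measures spatial coherence; marker
quality uses Moran's I and Geary's C of marker expression.  For cross-method
comparison, per-dataset scores are converted to fractional ranks, normalized
to [0, 1] (best method 1, worst 0), averaged over datasets, and aggregated
into Overall_accuracy / Overall_continuity / Overall_marker and their sum,
the Total score.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import (
    adjusted_rand_score,
    completeness_score,
    homogeneity_score,
    normalized_mutual_info_score,
    silhouette_score,
)
from sklearn.neighbors import NearestNeighbors

from .spatial import SpatialWeights, gearys_c, morans_i

__all__ = [
    "accuracy_metrics",
    "continuity_metrics",
    "marker_metrics",
    "rank_based_scores",
    "overall_scores",
    "relative_improvement",
]


def accuracy_metrics(pred, truth) -> tuple[float, float, float, float]:
    """(NMI, HOM, COM, ARI) of predicted vs reference labels.

    For a single-cluster prediction against a multi-class reference the
    degenerate sklearn conventions apply: HOM = 0, COM = 1.
    """
    pred, truth = np.asarray(pred), np.asarray(truth)
    if pred.size != truth.size:
        raise ValueError("alignment-error: label vectors differ in length")
    return (
        float(normalized_mutual_info_score(truth, pred)),
        float(homogeneity_score(truth, pred)),
        float(completeness_score(truth, pred)),
        float(adjusted_rand_score(truth, pred)),
    )


def continuity_metrics(
    labels,
    coords,
    pas_neighbors: int = 10,
    pas_threshold: int = 6,
) -> tuple[float, float, float]:
    """(CHAOS, PAS, ASW) spatial-continuity scores.

    CHAOS: mean within-cluster 1-NN edge length on z-scaled coordinates
    (lower = more coherent; singleton clusters skipped with a warning).
    PAS: fraction of spots disagreeing with more than ``pas_threshold`` of
    their ``pas_neighbors`` nearest spatial neighbors.  ASW: mean silhouette
    width of the labels on the coordinates.
    """
    labels = np.asarray(labels)
    coords = np.asarray(coords, float)
    zc = (coords - coords.mean(axis=0)) / coords.std(axis=0)

    dists = []
    for lab in np.unique(labels):
        pts = zc[labels == lab]
        if pts.shape[0] < 2:
            warnings.warn(f"cluster {lab} has a single spot; skipped in CHAOS")
            continue
        nn = NearestNeighbors(n_neighbors=2).fit(pts)
        d, _ = nn.kneighbors(pts)
        dists.append(d[:, 1])
    chaos = float(np.concatenate(dists).mean()) if dists else float("nan")

    k = min(pas_neighbors, labels.size - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    disagree = (labels[idx[:, 1:]] != labels[:, None]).sum(axis=1)
    pas = float((disagree > pas_threshold).mean())

    asw = (
        float(silhouette_score(coords, labels))
        if np.unique(labels).size > 1
        else float("nan")
    )
    return chaos, pas, asw


def marker_metrics(expr, weights: SpatialWeights) -> tuple[float, float]:
    """(Moran's I, Geary's C) of a marker expression vector."""
    return morans_i(expr, weights), gearys_c(expr, weights)


def rank_based_scores(
    V: np.ndarray, higher_is_better: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized rank scores per Eqs. of the unified benchmark index.

    ``V`` is datasets x methods.  Per dataset, methods get fractional ranks
    (1 = best); normalized scores are (N_method - R)/(N_method - 1), so the
    best method scores 1 and the worst 0.  Returns (R_tilde, rank_m) with
    ``rank_m`` the per-method mean across datasets.
    """
    V = np.atleast_2d(np.asarray(V, float))
    n_methods = V.shape[1]
    if n_methods < 2:
        raise ValueError("undefined-normalization: need >= 2 methods")
    R = np.vstack(
        [rankdata(-row if higher_is_better else row, method="average") for row in V]
    )
    R_tilde = (n_methods - R) / (n_methods - 1)
    return R_tilde, R_tilde.mean(axis=0)


def overall_scores(rank_scores: dict) -> tuple[float, float, float, float]:
    """Aggregate the eight metric rank-scores into the three overall scores
    and the Total (their sum).

    ``rank_scores`` maps metric name -> rank score, with keys NMI, HOM, COM,
    CHAOS, PAS, ASW, MoranI, GearyC.
    """
    needed = ["NMI", "HOM", "COM", "CHAOS", "PAS", "ASW", "MoranI", "GearyC"]
    missing = [k for k in needed if k not in rank_scores]
    if missing:
        raise ValueError(f"incomplete-report: missing metrics {missing}")
    acc = float(np.mean([rank_scores[k] for k in ("NMI", "HOM", "COM")]))
    cont = float(np.mean([rank_scores[k] for k in ("CHAOS", "PAS", "ASW")]))
    mark = float(np.mean([rank_scores[k] for k in ("MoranI", "GearyC")]))
    return acc, cont, mark, acc + cont + mark


def relative_improvement(a: float, b: float, higher_is_better: bool = True) -> float:
    """Percent improvement of value ``a`` over baseline ``b``.

    ``100 (a - b)/b`` for higher-is-better metrics; for lower-is-better ones
    (e.g. the Davies-Bouldin index) ``100 (b - a)/b``.
    """
    if b <= 0:
        raise ValueError("invalid-baseline: baseline must be positive")
    return 100.0 * ((a - b) / b if higher_is_better else (b - a) / b)
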