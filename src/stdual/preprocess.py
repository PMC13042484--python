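"""QC filtering, library-size normalization, HVG selection and PCA.

Genes detected in fewer than ``min_locations`` spots or with total counts not
exceeding ``min_counts`` are removed; expression is normalized to a fixed
library size per spot (10 000) and natural-log transformed.  Highly variable
genes use the Seurat-v3 variance-stabilizing statistic computed on raw counts
(lowess trend of log10 variance against log10 mean, then the variance of
clipped standardized counts).
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.decomposition import PCA
from sklearn.utils.extmath import randomized_svd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .data import ExpressionLayers, STDataset

__all__ = [
    "filter_genes",
    "normalize_log1p",
    "seurat_v3_dispersion",
    "select_hvgs",
    "reduce_pca",
]


def filter_genes(
    ds: STDataset, min_locations: int = 5, min_counts: int = 20
) -> STDataset:
    """Drop genes seen in fewer than ``min_locations`` spots or with total
    counts <= ``min_counts``.  Retention is strict: a total of exactly
    ``min_counts`` is removed, ``min_counts + 1`` is kept.  Idempotent."""
    n_loc = (ds.counts > 0).sum(axis=0)
    totals = ds.counts.sum(axis=0)
    keep = (n_loc >= min_locations) & (totals > min_counts)
    if not keep.any():
        raise ValueError("empty-after-filter: no genes pass the QC thresholds")
    if keep.all():
        return ds
    return ds.subset_genes(keep)


def normalize_log1p(ds: STDataset, target_sum: float = 10_000.0):
    """Counts-per-``target_sum`` normalization followed by ln(x + 1).

    Spots with zero total counts are dropped with a warning.  Returns
    ``(layers, ds)`` where ``ds`` is the (possibly spot-filtered) dataset.
    """
    if np.any(ds.counts < 0):
        raise ValueError("invalid-counts: negative entries")
    row_sums = ds.counts.sum(axis=1).astype(float)
    if np.any(row_sums == 0):
        warnings.warn(
            f"dropping {int((row_sums == 0).sum())} spots with zero total counts"
        )
        ds = ds.subset_spots(row_sums > 0)
        row_sums = ds.counts.sum(axis=1).astype(float)
    normalized = ds.counts / row_sums[:, None] * target_sum
    layers = ExpressionLayers(
        normalized=normalized,
        loggered=np.log1p(normalized),
        gene_ids=list(ds.gene_ids),
        spot_ids=list(ds.spot_ids),
    )
    return layers, ds


def seurat_v3_dispersion(counts: np.ndarray, span: float = 0.3) -> np.ndarray:
    """Seurat-v3 variance-stabilized dispersion per gene, on raw counts.

    A lowess trend of log10(variance) on log10(mean) predicts the expected
    standard deviation per gene; counts are standardized against it, clipped
    at sqrt(N), and the variance of the clipped values is the statistic.
    Constant genes get statistic 0.
    """
    X = np.asarray(counts, dtype=float)
    n = X.shape[0]
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1) if n > 1 else np.zeros(X.shape[1])
    stat = np.zeros(X.shape[1])
    usable = (mean > 0) & (var > 0)
    if usable.sum() >= 3:
        lx, ly = np.log10(mean[usable]), np.log10(var[usable])
        fitted = lowess(ly, lx, frac=span, return_sorted=False)
        reg_std = np.sqrt(10.0**fitted)
        Xu = X[:, usable]
        clip = np.sqrt(n)
        zs = np.clip((Xu - mean[usable]) / reg_std, -clip, clip)
        # variance of clipped z-scores, expanded form as in Seurat v3
        stat[usable] = (
            (zs**2).sum(axis=0) - n * zs.mean(axis=0) ** 2
        ) / (n - 1)
    elif usable.any():  # too few genes for a trend: fall back to raw variance
        stat[usable] = var[usable]
    return stat


def select_hvgs(
    layers: ExpressionLayers, counts: np.ndarray, n_top: int = 3000
) -> np.ndarray:
    """Flag the ``min(n_top, G)`` most variable genes.

    Ranking follows the variance-stabilized dispersion statistic; ties break
    by gene index ascending for determinism.  Sets ``layers.hvg_mask`` and
    returns it.
    """
    if n_top <= 0:
        raise ValueError("invalid-parameter: n_top must be >= 1")
    stat = seurat_v3_dispersion(counts)
    G = stat.size
    k = min(n_top, G)
    # stable sort on (-stat, index): argsort of -stat with kind="stable"
    order = np.argsort(-stat, kind="stable")
    mask = np.zeros(G, dtype=bool)
    mask[order[:k]] = True
    layers.hvg_mask = mask
    return mask


def reduce_pca(
    layers: ExpressionLayers, n_comps: int = 200, seed: int = 0
) -> np.ndarray:
    """Centered PCA scores of the HVG-restricted log layer (N x n_comps).

    ``n_comps`` is clipped to min(N, #HVGs) with a warning when too large.
    Exact SVD for small problems, seeded randomized SVD otherwise.
    """
    X = layers.loggered
    if layers.hvg_mask is not None:
        X = X[:, layers.hvg_mask]
    n, g = X.shape
    max_comps = min(n, g)
    if n_comps > max_comps:
        warnings.warn(f"n_comps clipped from {n_comps} to {max_comps}")
        n_comps = max_comps
    Xc = X - X.mean(axis=0)
    if n * g > 5_000_000 and n_comps < max_comps:
        U, S, _ = randomized_svd(Xc, n_components=n_comps, random_state=seed)
        pcs = U * S
    else:
        pca = PCA(n_components=n_comps, svd_solver="full")
        pcs = pca.fit_transform(Xc)
    layers.pcs = pcs
    return pcs
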