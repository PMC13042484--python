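"""Marker and differentially expressed gene discovery.

Three routes to interpretable gene lists:

* per-topic z-score markers (genes whose topic weight z-score exceeds the
  1.96 two-sided normal cutoff);
* domain -> topic -> gene Pearson-correlation markers: each domain is mapped
  to the topic whose activity best correlates with its binary membership
  vector, then genes correlating with that topic's activity above r = 0.3
  are ranked;
* Wilcoxon rank-sum differential expression with Benjamini-Hochberg control
  (default FDR < 0.001, |log2FC| >= 1).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .gene_select import GeneSelection

__all__ = [
    "topic_marker_table",
    "domain_topic_correlation_markers",
    "differential_expression",
    "cluster_specific_degs",
]


def topic_marker_table(
    sel: GeneSelection, gene_ids=None, theta: float | None = None
) -> pd.DataFrame:
    """Genes with topic z-score strictly above theta, per topic, descending."""
    theta = sel.theta if theta is None else theta
    Z = sel.zscores
    G, T = Z.shape
    gene_ids = list(gene_ids) if gene_ids is not None else [f"gene_{g}" for g in range(G)]
    rows = []
    for t in range(T):
        hits = np.flatnonzero(Z[:, t] > theta)
        if hits.size == 0:
            warnings.warn(f"no gene passes theta={theta} for topic {t}")
            continue
        order = hits[np.argsort(-Z[hits, t], kind="stable")]
        for rank, g in enumerate(order, start=1):
            rows.append((gene_ids[g], t, float(Z[g, t]), rank))
    return pd.DataFrame(rows, columns=["gene_id", "scope", "score", "rank"])


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc, yc = x - x.mean(), y - y.mean()
    den = np.sqrt((xc @ xc) * (yc @ yc))
    return float(xc @ yc / den) if den > 0 else np.nan


def domain_topic_correlation_markers(
    labels: np.ndarray,
    Z_final: np.ndarray,
    loggered: np.ndarray,
    gene_ids=None,
    r_min: float = 0.3,
) -> pd.DataFrame:
    """Correlation-based domain markers (see module docstring).

    Constant topic activities or gene vectors are skipped.  Returns one row
    per (domain, gene) with the topic-gene Pearson r as score.
    """
    labels = np.asarray(labels)
    Z = np.asarray(Z_final, float)
    X = np.asarray(loggered, float)
    G = X.shape[1]
    gene_ids = list(gene_ids) if gene_ids is not None else [f"gene_{g}" for g in range(G)]
    rows = []
    for dom in np.unique(labels):
        ind = (labels == dom).astype(float)
        cors = np.array([_pearson(ind, Z[:, t]) for t in range(Z.shape[1])])
        if np.all(np.isnan(cors)):
            continue
        best_t = int(np.nanargmax(cors))
        act = Z[:, best_t]
        gene_r = np.array([_pearson(act, X[:, g]) for g in range(G)])
        hits = np.flatnonzero(gene_r > r_min)
        order = hits[np.argsort(-gene_r[hits], kind="stable")]
        for rank, g in enumerate(order, start=1):
            rows.append((gene_ids[g], int(dom), best_t, float(gene_r[g]), rank))
    return pd.DataFrame(
        rows, columns=["gene_id", "scope", "topic", "score", "rank"]
    )


def differential_expression(
    loggered: np.ndarray,
    labels: np.ndarray,
    group_a,
    group_b=None,
    gene_ids=None,
    fdr: float = 0.001,
    min_abs_l2fc: float = 1.0,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum DEGs of group A versus group B.

    ``group_b=None`` compares against all other spots.  Fold change is
    computed on de-logged means: log2((mean(expm1 xA) + eps) /
    (mean(expm1 xB) + eps)).  Rows are filtered to padj < fdr and
    |log2FC| >= min_abs_l2fc.
    """
    labels = np.asarray(labels)
    X = np.asarray(loggered, float)
    in_a = labels == group_a
    in_b = ~in_a if group_b is None else labels == group_b
    if in_a.sum() == 0 or in_b.sum() == 0:
        raise ValueError("both groups must be non-empty")
    if in_a.sum() < 3 or in_b.sum() < 3:
        warnings.warn("a group has fewer than 3 spots; test validity is limited")
    G = X.shape[1]
    gene_ids = list(gene_ids) if gene_ids is not None else [f"gene_{g}" for g in range(G)]
    XA, XB = X[in_a], X[in_b]
    eps = 1e-9
    mean_a = np.expm1(XA).mean(axis=0)
    mean_b = np.expm1(XB).mean(axis=0)
    l2fc = np.log2((mean_a + eps) / (mean_b + eps))
    pvals = np.ones(G)
    for g in range(G):
        a, b = XA[:, g], XB[:, g]
        if np.ptp(np.concatenate([a, b])) == 0:
            continue  # identical constant distributions: p = 1
        pvals[g] = mannwhitneyu(a, b, alternative="two-sided").pvalue
    _, padj, _, _ = multipletests(pvals, method="fdr_bh")
    keep = (padj < fdr) & (np.abs(l2fc) >= min_abs_l2fc)
    df = pd.DataFrame(
        {
            "gene_id": np.asarray(gene_ids, dtype=object)[keep],
            "group": group_a,
            "log2fc": l2fc[keep],
            "p_adj": padj[keep],
            "direction": np.where(l2fc[keep] > 0, "up", "down"),
        }
    )
    return df.sort_values("p_adj", kind="stable").reset_index(drop=True)


def cluster_specific_degs(
    loggered: np.ndarray,
    labels: np.ndarray,
    group,
    gene_ids=None,
    fdr: float = 0.001,
    min_abs_l2fc: float = 1.0,
) -> pd.DataFrame:
    """Genes up-regulated in ``group`` versus *every* other cluster.

    A gene qualifies only if it passes the one-vs-one test (positive fold
    change, padj < fdr, log2FC >= threshold) against each remaining cluster
    separately; the reported statistics are the weakest (largest padj,
    smallest fold change) across the comparisons.
    """
    labels = np.asarray(labels)
    others = [g for g in np.unique(labels) if g != group]
    if not others:
        raise ValueError("need at least two clusters")
    surviving: dict | None = None
    for other in others:
        tab = differential_expression(
            loggered, labels, group, other,
            gene_ids=gene_ids, fdr=fdr, min_abs_l2fc=min_abs_l2fc,
        )
        up = tab[tab.log2fc > 0].set_index("gene_id")
        if surviving is None:
            surviving = {
                g: (row.log2fc, row.p_adj) for g, row in up.iterrows()
            }
        else:
            surviving = {
                g: (min(surviving[g][0], row.log2fc),
                    max(surviving[g][1], row.p_adj))
                for g, row in up.iterrows()
                if g in surviving
            }
        if not surviving:
            break
    rows = [
        (g, group, l2fc, padj, "up")
        for g, (l2fc, padj) in (surviving or {}).items()
    ]
    df = pd.DataFrame(
        rows, columns=["gene_id", "group", "log2fc", "p_adj", "direction"]
    )
    return df.sort_values("p_adj", kind="stable").reset_index(drop=True)
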