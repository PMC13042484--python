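"""High spatial-specificity gene (HSG) selection.

Starting from the gene-topic weight matrix restricted to the selected topics,
the module ranks genes within each topic, finds cumulative-contribution rank
thresholds, z-scores topic weights, and assembles the feature gene set:

* TSGs (topic-specific genes): genes ranked within the head of some topic
  (rank <= r_t^(l)) whose topic z-score exceeds theta (1.96, the two-sided
  95% normal cutoff).
* Non-TSGs: HVGs ranked below the bulk threshold r_t^(u) in every topic,
  minus a rescue set of genes with high per-gene Moran's I.
* HSGs: (HVG u TSG) minus at most |TSG \\ HVG| of the least topic-relevant
  HVG-and-Non-TSG genes, guaranteeing a net gain over the HVG list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .spatial import SpatialWeights, morans_i_batch

__all__ = [
    "GeneSelection",
    "two_sided_z_cutoff",
    "normalize_gene_topic_weights",
    "compute_rank_matrix",
    "cumulative_rank_thresholds",
    "topic_zscores",
    "select_tsgs",
    "initial_non_tsgs",
    "rescue_spatial_genes",
    "assemble_hsgs",
    "select_hsg_set",
]


def two_sided_z_cutoff(alpha: float = 0.05) -> float:
    """Two-sided standard-normal cutoff; alpha=0.05 gives 1.959964."""
    return float(norm.ppf(1 - alpha / 2))


@dataclass
class GeneSelection:
    """State of the gene-selection algebra (all index sets are 0-based gene
    indices into the filtered gene panel)."""

    H_T: np.ndarray  # G x T, unnormalized topic weights of selected topics
    H_norm: np.ndarray | None = None
    R: np.ndarray | None = None
    zscores: np.ndarray | None = None
    r_low: np.ndarray | None = None
    r_high: np.ndarray | None = None
    tau_low: float = 0.3
    tau_high: float = 0.8
    theta: float = 1.96
    theta_mri: float | None = None
    theta_s: float | None = None
    gene_mri: np.ndarray | None = None
    rank_sum: np.ndarray | None = None
    sets: dict = field(default_factory=dict)


def normalize_gene_topic_weights(H: np.ndarray, T=None) -> np.ndarray:
    """Column-normalize (selected columns of) H so each topic sums to 1."""
    H_T = np.asarray(H, dtype=float)
    if T is not None:
        H_T = H_T[:, np.asarray(T)]
    sums = H_T.sum(axis=0)
    if np.any(sums <= 0):
        raise ValueError("empty-topic: a selected topic has zero total weight")
    return H_T / sums


def compute_rank_matrix(H_norm: np.ndarray) -> np.ndarray:
    """Within-topic ranks: 1 = largest contribution; ties by gene index."""
    G, T = H_norm.shape
    R = np.empty((G, T), dtype=int)
    ranks = np.arange(1, G + 1)
    for t in range(T):
        order = np.argsort(-H_norm[:, t], kind="stable")
        R[order, t] = ranks
    return R


def cumulative_rank_thresholds(
    H_norm: np.ndarray, tau_low: float = 0.3, tau_high: float = 0.8
) -> tuple[np.ndarray, np.ndarray]:
    """Smallest rank r per topic whose rank-ordered cumulative contribution
    reaches tau_low / tau_high (inclusive >=)."""
    if not 0 < tau_low < tau_high <= 1:
        raise ValueError("invalid-quantiles: need 0 < tau_low < tau_high <= 1")
    G, T = H_norm.shape
    r_low = np.empty(T, dtype=int)
    r_high = np.empty(T, dtype=int)
    for t in range(T):
        csum = np.cumsum(np.sort(H_norm[:, t])[::-1])
        # guard against float round-off at the tail
        csum[-1] = max(csum[-1], 1.0)
        r_low[t] = int(np.searchsorted(csum, tau_low - 1e-12) + 1)
        r_high[t] = int(np.searchsorted(csum, tau_high - 1e-12) + 1)
    return r_low, r_high


def topic_zscores(H_T: np.ndarray) -> np.ndarray:
    """Column z-scores of the unnormalized topic weights, population sigma."""
    mu = H_T.mean(axis=0)
    sigma = H_T.std(axis=0)  # population convention (divide by G)
    if np.any(sigma == 0):
        raise ValueError("constant-topic: zero standard deviation")
    return (H_T - mu) / sigma


def select_tsgs(sel: GeneSelection, theta: float | None = None) -> set:
    """Genes in the head of some topic with z strictly above theta."""
    theta = sel.theta if theta is None else theta
    hit = (sel.R <= sel.r_low[None, :]) & (sel.zscores > theta)
    tsg = set(np.flatnonzero(hit.any(axis=1)).tolist())
    if not tsg:
        warnings.warn("no topic-specific genes found")
    sel.sets["TSG"] = tsg
    return tsg


def initial_non_tsgs(sel: GeneSelection, hvg: set) -> set:
    """HVGs ranked below r_t^(u) in every selected topic."""
    below = (sel.R > sel.r_high[None, :]).all(axis=1)
    out = set(np.flatnonzero(below).tolist()) & set(hvg)
    sel.sets["NonTSG_init"] = out
    return out


def rescue_spatial_genes(
    sel: GeneSelection,
    weights: SpatialWeights | None = None,
    loggered: np.ndarray | None = None,
    theta_mri: float | None = None,
    theta_s: float | None = None,
) -> set:
    """Remove genes with high spatial autocorrelation from the Non-TSG set.

    Rescue condition: gene Moran's I (on log expression) above theta_mri and
    topic rank sum S_g below theta_s.  Default thresholds are the 75th
    percentile of Moran's I and the median rank sum over the preliminary
    Non-TSG set.
    """
    init = sel.sets["NonTSG_init"]
    if sel.gene_mri is None:
        if weights is None or loggered is None:
            raise ValueError("need spatial weights and expression for gene MRI")
        sel.gene_mri = morans_i_batch(loggered, weights)
    sel.rank_sum = sel.R.sum(axis=1).astype(float)
    if init:
        idx = np.fromiter(init, dtype=int)
        if theta_mri is None:
            theta_mri = float(np.percentile(sel.gene_mri[idx], 75))
        if theta_s is None:
            theta_s = float(np.median(sel.rank_sum[idx]))
    else:
        theta_mri = np.inf if theta_mri is None else theta_mri
        theta_s = -np.inf if theta_s is None else theta_s
    sel.theta_mri, sel.theta_s = theta_mri, theta_s
    rescued = {
        g
        for g in init
        if sel.gene_mri[g] > theta_mri and sel.rank_sum[g] < theta_s
    }
    sel.sets["NonTSG_del"] = rescued
    sel.sets["NonTSG"] = init - rescued
    return sel.sets["NonTSG"]


def assemble_hsgs(sel: GeneSelection, hvg: set) -> set:
    """Final HSG assembly with the net-gain cap on deletions.

    Candidates for deletion (HVG n Non-TSG) are ordered by minimum topic rank
    descending (least topic-relevant first) and truncated so that at most
    |Add| - |HVG| genes are removed.
    """
    hvg = set(hvg)
    tsg = sel.sets.get("TSG", set())
    add = hvg | tsg
    pool = sorted(hvg & sel.sets.get("NonTSG", set()))
    cap = len(add) - len(hvg)
    if pool and cap > 0:
        min_rank = sel.R.min(axis=1)
        # least topic-relevant first; ties by gene index ascending
        pool.sort(key=lambda g: (-min_rank[g], g))
        del_star = set(pool[:cap])
    else:
        del_star = set()
    sel.sets["HVG"] = hvg
    sel.sets["Add"] = add
    sel.sets["Del_star"] = del_star
    sel.sets["HSG"] = add - del_star
    return sel.sets["HSG"]


def select_hsg_set(
    H: np.ndarray,
    T: np.ndarray,
    hvg_mask: np.ndarray,
    weights: SpatialWeights,
    loggered: np.ndarray,
    tau_low: float = 0.3,
    tau_high: float = 0.8,
    theta: float = 1.96,
    theta_mri: float | None = None,
    theta_s: float | None = None,
) -> GeneSelection:
    """Run the whole selection pipeline; the result's ``sets['HSG']`` holds
    the final gene index set."""
    sel = GeneSelection(
        H_T=np.asarray(H, dtype=float)[:, np.asarray(T)],
        tau_low=tau_low,
        tau_high=tau_high,
        theta=theta,
    )
    sel.H_norm = normalize_gene_topic_weights(sel.H_T)
    sel.R = compute_rank_matrix(sel.H_norm)
    sel.r_low, sel.r_high = cumulative_rank_thresholds(sel.H_norm, tau_low, tau_high)
    sel.zscores = topic_zscores(sel.H_T)
    hvg = set(np.flatnonzero(hvg_mask).tolist())
    select_tsgs(sel, theta)
    initial_non_tsgs(sel, hvg)
    rescue_spatial_genes(sel, weights, loggered, theta_mri, theta_s)
    assemble_hsgs(sel, hvg)
    return sel
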