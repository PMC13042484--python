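"""Synthetic spatial transcriptomics with known domain structure.

Spots lie on an ``n_side x n_side`` grid partitioned into contiguous
rectangular domain tiles.  Each domain is driven by its own gene program: a
set of planted marker genes with elevated negative-binomial means inside the
domain.  Half of each domain's markers are "strong" (high baseline, 6-fold
enrichment) and half "subtle" (low baseline, 3-fold enrichment) — the subtle
half emulates real markers whose raw variance is unremarkable even though
their expression is spatially coherent.  A block of spatially unstructured
high-dispersion "noise" genes competes with markers for variance-based
rankings, and a background of housekeeping-like genes sits on the
mean-variance trend.  Counts are gamma-Poisson (negative binomial,
dispersion 0.3 for structured genes) with lognormal library-size variation
and optional Bernoulli dropout.

The ``split_domain`` variant places domain 0 on two spatially disjoint tiles
(opposite edges of the grid) sharing one program, to exercise the long-range
feature-graph mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import STDataset

__all__ = ["SyntheticTruth", "generate_synthetic_st", "generate_label_fixture"]


@dataclass
class SyntheticTruth:
    domain_labels: np.ndarray
    topic_loadings: np.ndarray  # N x K domain-indicator loadings
    gene_programs: np.ndarray  # G x K fold-enrichment matrix
    planted_markers: dict  # domain -> list of gene ids
    params: dict = field(default_factory=dict)

    @property
    def all_markers(self) -> list:
        out = []
        for d in sorted(self.planted_markers):
            out.extend(self.planted_markers[d])
        return out


def _domain_layout(
    n_side: int, n_domains: int, split_domain: bool
) -> np.ndarray:
    """Assign each grid spot a domain; tiles are contiguous rectangles."""
    rows, cols = np.divmod(np.arange(n_side * n_side), n_side)
    if split_domain:
        # n_domains + 1 vertical bands; the two outermost both carry domain 0
        bands = np.minimum(
            (cols * (n_domains + 1)) // n_side, n_domains
        )
        labels = np.where(bands == n_domains, 0, bands)
        return labels
    nr = int(np.floor(np.sqrt(n_domains)))
    while n_domains % nr:
        nr -= 1
    nc = n_domains // nr
    tile_r = np.minimum((rows * nr) // n_side, nr - 1)
    tile_c = np.minimum((cols * nc) // n_side, nc - 1)
    return tile_r * nc + tile_c


def generate_synthetic_st(
    n_side: int = 20,
    n_domains: int = 4,
    n_genes: int = 300,
    n_markers_per_domain: int = 10,
    dropout: float = 0.3,
    seed: int = 0,
    split_domain: bool = False,
    dispersion: float = 0.3,
    strong_fold: float = 6.0,
    subtle_fold: float = 3.0,
    library_sd: float = 0.25,
    n_program_genes: int = 40,
    program_fold_range: tuple = (2.0, 4.0),
) -> tuple[STDataset, SyntheticTruth]:
    """Generate a grid dataset with planted domains and markers.

    Returns ``(dataset, truth)``; regeneration with identical parameters is
    bitwise identical.
    """
    if n_domains < 2:
        raise ValueError("layout-error: need n_domains >= 2")
    if n_side * n_side < 4 * n_domains:
        raise ValueError("layout-error: grid too small for the domain count")
    n_marker_total = n_domains * n_markers_per_domain
    n_noise = n_genes // 5
    if n_marker_total + n_noise >= n_genes:
        raise ValueError("layout-error: gene panel too small for marker count")

    rng = np.random.default_rng(seed)
    n = n_side * n_side
    rows, cols = np.divmod(np.arange(n), n_side)
    coords = np.column_stack([cols, rows]).astype(float) * 100.0
    labels = _domain_layout(n_side, n_domains, split_domain)

    # gene panel: [markers | noise | background]
    base = np.empty(n_genes)
    disp = np.full(n_genes, dispersion)
    folds = np.zeros((n_genes, n_domains))
    planted: dict = {d: [] for d in range(n_domains)}
    g = 0
    n_strong = n_markers_per_domain // 2
    for d in range(n_domains):
        for m in range(n_markers_per_domain):
            if m < n_strong:
                base[g], folds[g, d] = 1.5, strong_fold
            else:
                base[g], folds[g, d] = 0.4, subtle_fold
            planted[d].append(f"gene_{g}")
            g += 1
    noise_idx = np.arange(g, g + n_noise)
    base[noise_idx] = rng.lognormal(np.log(4.0), 0.4, n_noise)
    disp[noise_idx] = rng.uniform(2.0, 4.0, n_noise)  # heavy, unstructured
    g += n_noise
    bg_idx = np.arange(g, n_genes)
    base[bg_idx] = rng.lognormal(np.log(1.0), 0.8, bg_idx.size)
    disp[bg_idx] = rng.uniform(0.2, 0.6, bg_idx.size)

    # each domain additionally modulates a disjoint block of background
    # genes with moderate folds — the broad transcriptional program that
    # distinguishes tissue domains beyond their headline markers
    n_prog = min(n_program_genes, bg_idx.size // n_domains)
    prog_pool = rng.permutation(bg_idx)
    lo_f, hi_f = program_fold_range
    for d in range(n_domains):
        block = prog_pool[d * n_prog : (d + 1) * n_prog]
        folds[block, d] = rng.uniform(lo_f, hi_f, block.size)

    # per-spot mean matrix
    mu = np.tile(base, (n, 1))
    for d in range(n_domains):
        in_d = labels == d
        enriched = folds[:, d] > 0
        mu[np.ix_(in_d, enriched)] *= folds[enriched, d]
    lib = rng.lognormal(0.0, library_sd, n)
    mu *= lib[:, None]

    # gamma-Poisson counts
    shape = 1.0 / disp
    lam = rng.gamma(shape[None, :], mu * disp[None, :])
    counts = rng.poisson(lam).astype(np.int64)
    if dropout > 0:
        counts[rng.random((n, n_genes)) < dropout] = 0

    ds = STDataset(
        counts=counts,
        coords=coords,
        gene_ids=[f"gene_{j}" for j in range(n_genes)],
        spot_ids=[f"spot_{i}" for i in range(n)],
    )
    loadings = np.zeros((n, n_domains))
    loadings[np.arange(n), labels] = 1.0
    truth = SyntheticTruth(
        domain_labels=labels,
        topic_loadings=loadings,
        gene_programs=folds,
        planted_markers=planted,
        params=dict(
            n_side=n_side,
            n_domains=n_domains,
            n_genes=n_genes,
            n_markers_per_domain=n_markers_per_domain,
            dropout=dropout,
            seed=seed,
            split_domain=split_domain,
            dispersion=dispersion,
        ),
    )
    return ds, truth


def generate_label_fixture(
    n: int, n_classes: int, agreement: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """A (truth, pred) label pair agreeing on an ``agreement`` fraction."""
    if not 0 <= agreement <= 1:
        raise ValueError("agreement must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    truth = rng.integers(0, n_classes, n)
    pred = truth.copy()
    flip = rng.random(n) >= agreement
    pred[flip] = rng.integers(0, n_classes, int(flip.sum()))
    return truth, pred
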