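"""Canonical data containers and readers/writers for spatial expression data.

The package operates on a spot-by-gene UMI count matrix ``X`` (N x G) together
with a 2-D coordinate matrix ``S`` (N x 2).  Three on-disk layouts are
supported: a 10x-Genomics-style MTX directory with a tissue-positions table,
an H5AD container, and plain delimited matrices.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = ["STDataset", "ExpressionLayers", "load_dataset", "save_dataset"]


class STDataError(ValueError):
    """Raised on malformed or inconsistent spatial expression input."""


@dataclass
class STDataset:
    """A spot x gene count matrix with aligned 2-D spatial coordinates.

    Attributes
    ----------
    counts : ndarray of shape (n_spots, n_genes)
        Non-negative integer UMI counts.
    coords : ndarray of shape (n_spots, 2)
        Spatial positions in platform units.
    gene_ids, spot_ids : list of str
        Unique identifiers aligned with the matrix axes.
    """

    counts: np.ndarray
    coords: np.ndarray
    gene_ids: list = field(default_factory=list)
    spot_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if sp.issparse(self.counts):  # pragma: no cover - defensive
            self.counts = self.counts.toarray()
        self.coords = np.asarray(self.coords, dtype=float)
        n, g = self.counts.shape
        if not self.gene_ids:
            self.gene_ids = [f"gene_{j}" for j in range(g)]
        if not self.spot_ids:
            self.spot_ids = [f"spot_{i}" for i in range(n)]
        if self.coords.shape != (n, 2):
            raise STDataError(
                f"alignment-error: coords shape {self.coords.shape} does not match "
                f"{n} spots"
            )
        if np.any(self.counts < 0):
            raise STDataError("invalid-counts: negative entries in count matrix")
        if len(self.gene_ids) != g or len(set(self.gene_ids)) != g:
            raise STDataError("gene_ids must be unique and match the gene axis")
        if len(self.spot_ids) != n or len(set(self.spot_ids)) != n:
            raise STDataError("spot_ids must be unique and match the spot axis")

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset_genes(self, mask: np.ndarray) -> "STDataset":
        mask = np.asarray(mask)
        return STDataset(
            counts=self.counts[:, mask],
            coords=self.coords.copy(),
            gene_ids=[g for g, m in zip(self.gene_ids, mask) if m],
            spot_ids=list(self.spot_ids),
        )

    def subset_spots(self, mask: np.ndarray) -> "STDataset":
        mask = np.asarray(mask)
        return STDataset(
            counts=self.counts[mask, :],
            coords=self.coords[mask, :],
            gene_ids=list(self.gene_ids),
            spot_ids=[s for s, m in zip(self.spot_ids, mask) if m],
        )

    def to_anndata(self) -> ad.AnnData:
        adata = ad.AnnData(
            X=sp.csr_matrix(self.counts.astype(np.float32)),
            obs=pd.DataFrame(index=pd.Index(self.spot_ids, name="spot_id")),
            var=pd.DataFrame(index=pd.Index(self.gene_ids, name="gene_id")),
        )
        adata.obsm["spatial"] = self.coords.copy()
        return adata

    @classmethod
    def from_anndata(cls, adata: ad.AnnData) -> "STDataset":
        if "spatial" not in adata.obsm:
            raise STDataError("coords-missing: AnnData has no obsm['spatial']")
        X = adata.X
        X = X.toarray() if sp.issparse(X) else np.asarray(X)
        return cls(
            counts=np.asarray(X),
            coords=np.asarray(adata.obsm["spatial"])[:, :2],
            gene_ids=list(map(str, adata.var_names)),
            spot_ids=list(map(str, adata.obs_names)),
        )


@dataclass
class ExpressionLayers:
    """Derived expression layers: library-size normalized, log1p, HVG mask, PCs.

    ``loggered`` is ln(normalized + 1) elementwise; rows of ``normalized`` sum
    to the target library size (10 000 by default) whenever the raw row sum is
    positive.
    """

    normalized: np.ndarray
    loggered: np.ndarray
    hvg_mask: np.ndarray | None = None
    pcs: np.ndarray | None = None
    gene_ids: list = field(default_factory=list)
    spot_ids: list = field(default_factory=list)


def _read_mtx_dir(path: str) -> STDataset:
    mtx_path = None
    for cand in ("matrix.mtx", "matrix.mtx.gz"):
        p = os.path.join(path, cand)
        if os.path.exists(p):
            mtx_path = p
            break
    if mtx_path is None:
        raise STDataError(f"no matrix.mtx found in {path}")
    M = scipy.io.mmread(mtx_path)  # genes x spots, 10x convention
    counts = np.asarray(M.todense()).T if sp.issparse(M) else np.asarray(M).T

    def _first_existing(names):
        for nm in names:
            p = os.path.join(path, nm)
            if os.path.exists(p):
                return p
        return None

    feat = _first_existing(["features.tsv", "genes.tsv"])
    barc = _first_existing(["barcodes.tsv"])
    gene_ids = (
        pd.read_csv(feat, sep="\t", header=None).iloc[:, 0].astype(str).tolist()
        if feat
        else []
    )
    spot_ids = (
        pd.read_csv(barc, sep="\t", header=None).iloc[:, 0].astype(str).tolist()
        if barc
        else []
    )
    pos = _first_existing(["tissue_positions.csv", "tissue_positions_list.csv"])
    if pos is None:
        raise STDataError("coords-missing: no tissue_positions table in MTX directory")
    postab = pd.read_csv(pos)
    if "barcode" in postab.columns:
        postab = postab.set_index("barcode")
        if spot_ids:
            missing = [s for s in spot_ids if s not in postab.index]
            if missing:
                raise STDataError(
                    f"alignment-error: {len(missing)} barcodes missing coordinates"
                )
            postab = postab.loc[spot_ids]
    coords = postab[["x", "y"]].to_numpy(dtype=float) if {"x", "y"} <= set(
        postab.columns
    ) else postab.iloc[:, -2:].to_numpy(dtype=float)
    if coords.shape[0] != counts.shape[0]:
        raise STDataError(
            f"alignment-error: positions rows ({coords.shape[0]}) != spots "
            f"({counts.shape[0]})"
        )
    return STDataset(counts=counts, coords=coords, gene_ids=gene_ids, spot_ids=spot_ids)


def _read_delimited(path: str) -> STDataset:
    """`path` is a directory containing matrix.tsv (spots x genes) + coords.tsv."""
    mat_p = os.path.join(path, "matrix.tsv")
    coord_p = os.path.join(path, "coords.tsv")
    if not os.path.exists(mat_p):
        raise STDataError(f"no matrix.tsv in {path}")
    if not os.path.exists(coord_p):
        raise STDataError("coords-missing: no coords.tsv next to matrix.tsv")
    mat = pd.read_csv(mat_p, sep="\t", index_col=0)
    coords = pd.read_csv(coord_p, sep="\t", index_col=0)
    if mat.shape[0] != coords.shape[0]:
        raise STDataError(
            f"alignment-error: matrix has {mat.shape[0]} spots, coords has "
            f"{coords.shape[0]} rows"
        )
    return STDataset(
        counts=mat.to_numpy(),
        coords=coords.iloc[:, :2].to_numpy(dtype=float),
        gene_ids=list(map(str, mat.columns)),
        spot_ids=list(map(str, mat.index)),
    )


def load_dataset(path: str, format: str = "h5ad") -> STDataset:
    """Load an on-disk dataset into an :class:`STDataset`.

    Parameters
    ----------
    path
        File (h5ad) or directory (mtx_dir, delimited) to read.
    format
        One of ``"mtx_dir"``, ``"h5ad"``, ``"delimited"``.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format == "h5ad":
        return STDataset.from_anndata(ad.read_h5ad(path))
    if format == "mtx_dir":
        return _read_mtx_dir(path)
    if format == "delimited":
        return _read_delimited(path)
    raise ValueError(f"unknown format {format!r}")


def save_dataset(ds: STDataset, path: str, format: str = "h5ad") -> None:
    """Write a dataset in any of the formats :func:`load_dataset` reads."""
    if format == "h5ad":
        ds.to_anndata().write_h5ad(path)
    elif format == "delimited":
        os.makedirs(path, exist_ok=True)
        pd.DataFrame(ds.counts, index=ds.spot_ids, columns=ds.gene_ids).to_csv(
            os.path.join(path, "matrix.tsv"), sep="\t"
        )
        pd.DataFrame(ds.coords, index=ds.spot_ids, columns=["x", "y"]).to_csv(
            os.path.join(path, "coords.tsv"), sep="\t"
        )
    elif format == "mtx_dir":
        os.makedirs(path, exist_ok=True)
        scipy.io.mmwrite(
            os.path.join(path, "matrix.mtx"), sp.coo_matrix(ds.counts.T)
        )
        pd.Series(ds.gene_ids).to_csv(
            os.path.join(path, "features.tsv"), sep="\t", index=False, header=False
        )
        pd.Series(ds.spot_ids).to_csv(
            os.path.join(path, "barcodes.tsv"), sep="\t", index=False, header=False
        )
        pd.DataFrame(
            {"barcode": ds.spot_ids, "x": ds.coords[:, 0], "y": ds.coords[:, 1]}
        ).to_csv(os.path.join(path, "tissue_positions.csv"), index=False)
    else:
        raise ValueError(f"unknown format {format!r}")
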