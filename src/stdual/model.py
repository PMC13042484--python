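"""Model/Results interface orchestrating the full workflow.

``SpatialDomainModel`` holds a dataset plus configuration; ``fit`` runs
preprocessing, consensus clustering, topic modeling, HSG selection, dual
graph construction, autoencoder training and domain calling, returning a
``SpatialDomainResults`` carrying labels, embeddings, gene sets, loss
history and diagnostics.

Ablation switches mirror the framework's component analysis: ``use_hsg``
(topic-driven gene selection vs plain HVGs) and ``dual_view`` (spatial +
feature views vs the spatial view alone).
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import consensus as cons
from . import domains as dom
from . import gene_select as gsel
from . import graphs as gb
from . import markers as mk
from . import metrics as ev
from . import network as net
from . import preprocess as pp
from .data import STDataset
from .spatial import knn_spatial_weights

__all__ = ["PipelineConfig", "SpatialDomainModel", "SpatialDomainResults"]


@dataclass
class PipelineConfig:
    """All tunable parameters, with the framework's published defaults."""

    # preprocessing
    min_locations: int = 5
    min_counts: int = 20
    target_sum: float = 10_000.0
    n_hvg: int = 3000
    n_pcs: int = 200
    # consensus
    leiden_resolutions: tuple = cons.DEFAULT_LEIDEN_RESOLUTIONS
    consensus_method: str = "leiden"
    init_resolution: float = 1.0
    knn_features: int = 15
    # topics
    n_topics: int = 30
    mri_threshold: float = 0.2
    rf_trees: int = 100
    topic_drop_frac: float = 0.2
    spatial_k: int = 6
    # gene selection
    tau_low: float = 0.3
    tau_high: float = 0.8
    theta: float = 1.96
    theta_mri: float | None = None
    theta_s: float | None = None
    # graphs
    graph_k: int = 6
    prune_tau: float = 0.2
    fag_neighbors: int = 6
    # network
    d_hid: int = 256
    d_out: int = 64
    epochs: int = 600
    lr: float = 1e-3
    lambdas: tuple = (10.0, 10.0, 5.0, 1.0)
    warmup_frac: float = 0.2
    n_prototypes: int | None = None
    temperature: float = 0.1
    sinkhorn_iters: int = 3
    prototype_refresh: int = 20
    # domain calling
    cluster_method: str = "gmm"
    refine: bool = False
    refine_n: int = 25
    resolution_grid: tuple = (0.1, 2.5, 0.001)
    # ablations
    use_hsg: bool = True
    dual_view: bool = True

    @classmethod
    def fixture(cls, **overrides) -> "PipelineConfig":
        """Scaled profile for the bundled synthetic grid fixtures: half the
        gene panel as HVGs, 15 topics, a lighter hidden layer."""
        base = dict(n_hvg=150, n_pcs=50, n_topics=15, d_hid=128, epochs=600)
        base.update(overrides)
        return cls(**base)


@dataclass
class SpatialDomainResults:
    """Fitted artifacts of one run."""

    model: "SpatialDomainModel"
    labels: np.ndarray
    embeddings: net.Embeddings
    loss_history: list
    gene_selection: gsel.GeneSelection | None
    hsg_ids: list
    topic_model: object
    consensus: cons.ConsensusResult
    domain_result: dom.DomainResult
    layers: object
    dataset: STDataset
    seed: int
    config: PipelineConfig

    # ---- evaluation ----------------------------------------------------
    def evaluate(self, truth) -> dict:
        nmi, hom, com, ari = ev.accuracy_metrics(self.labels, np.asarray(truth))
        chaos, pas, asw = ev.continuity_metrics(self.labels, self.dataset.coords)
        return dict(
            NMI=nmi, HOM=hom, COM=com, ARI=ari, CHAOS=chaos, PAS=pas, ASW=asw
        )

    def topic_markers(self) -> pd.DataFrame:
        return mk.topic_marker_table(self.gene_selection, self.layers.gene_ids)

    def domain_markers(self, r_min: float = 0.3) -> pd.DataFrame:
        return mk.domain_topic_correlation_markers(
            self.labels,
            self.topic_model.Z_final,
            self.layers.loggered,
            self.layers.gene_ids,
            r_min=r_min,
        )

    def differential_expression(self, group_a, group_b=None, **kw) -> pd.DataFrame:
        return mk.differential_expression(
            self.layers.loggered, self.labels, group_a, group_b,
            gene_ids=self.layers.gene_ids, **kw
        )

    def summary(self) -> str:
        ds = self.dataset
        s = self.gene_selection
        last = self.loss_history[-1] if self.loss_history else None
        lines = [
            "Spatial domain identification results",
            "=" * 45,
            f"spots: {ds.n_spots}    genes (post-QC): {ds.n_genes}",
            f"seed: {self.seed}    dual view: {self.config.dual_view}"
            f"    HSG selection: {self.config.use_hsg}",
        ]
        if s is not None:
            lines += [
                f"HVG: {len(s.sets['HVG'])}  TSG: {len(s.sets['TSG'])}  "
                f"Non-TSG: {len(s.sets['NonTSG'])}  removed: "
                f"{len(s.sets['Del_star'])}  HSG: {len(s.sets['HSG'])}",
            ]
        if self.topic_model is not None and self.topic_model.selected is not None:
            lines += [
                f"topics: {self.topic_model.n_topics} fitted, "
                f"{self.topic_model.filtered.size} spatial, "
                f"{self.topic_model.selected.size} selected",
            ]
        lines += [
            f"domains called: {int(self.labels.max()) + 1} "
            f"({self.domain_result.method})",
        ]
        if last is not None:
            lines += [
                f"final losses  recon: {last.recon:.4f}  graph: {last.graph:.4f}"
                f"  swav: {last.swav:.4f}  att: {last.att:.4f}"
                f"  total: {last.total:.4f}",
                f"mean attention (spatial, feature): "
                f"({self.embeddings.alpha[:, 0].mean():.3f}, "
                f"{self.embeddings.alpha[:, 1].mean():.3f})",
            ]
        return "\n".join(lines)

    # ---- persistence ---------------------------------------------------
    def save(self, run_dir: str) -> None:
        os.makedirs(run_dir, exist_ok=True)
        pd.DataFrame(
            {"spot_id": self.dataset.spot_ids, "domain": self.labels}
        ).to_csv(os.path.join(run_dir, "labels.tsv"), sep="\t", index=False)
        np.savetxt(
            os.path.join(run_dir, "embedding_att.tsv"),
            self.embeddings.E_att,
            delimiter="\t",
        )
        pd.DataFrame(
            [asdict(h) for h in self.loss_history]
        ).to_csv(os.path.join(run_dir, "loss_history.csv"), index=False)
        manifest = {
            "seed": self.seed,
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(self.config).items()
            },
            "n_spots": self.dataset.n_spots,
            "n_genes": self.dataset.n_genes,
            "n_domains": int(self.labels.max()) + 1,
            "n_hsg": len(self.hsg_ids),
        }
        if self.gene_selection is not None:
            manifest["thresholds"] = {
                "tau_low": self.gene_selection.tau_low,
                "tau_high": self.gene_selection.tau_high,
                "theta": self.gene_selection.theta,
                "theta_mri": self.gene_selection.theta_mri,
                "theta_s": self.gene_selection.theta_s,
            }
            for name, idx in self.gene_selection.sets.items():
                pd.Series(
                    sorted(self.layers.gene_ids[g] for g in idx)
                ).to_csv(
                    os.path.join(run_dir, f"genes_{name}.tsv"),
                    sep="\t", index=False, header=False,
                )
        with open(os.path.join(run_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)


class SpatialDomainModel:
    """Dual-view domain-identification model over a spatial dataset.

    Parameters
    ----------
    dataset
        Raw counts + coordinates.
    n_domains
        Target number of domains (GMM clustering); ``None`` triggers the
        Calinski-Harabasz resolution search with Leiden.
    config
        :class:`PipelineConfig`; defaults follow the published settings.
    """

    def __init__(
        self,
        dataset: STDataset,
        n_domains: int | None = None,
        config: PipelineConfig | None = None,
    ):
        self.dataset = dataset
        self.n_domains = n_domains
        self.config = config or PipelineConfig()

    @classmethod
    def from_anndata(cls, adata, **kw) -> "SpatialDomainModel":
        return cls(STDataset.from_anndata(adata), **kw)

    def fit(self, seed: int = 0) -> SpatialDomainResults:
        cfg = self.config
        # --- preprocessing ---
        ds = pp.filter_genes(self.dataset, cfg.min_locations, cfg.min_counts)
        layers, ds = pp.normalize_log1p(ds, cfg.target_sum)
        pp.select_hvgs(layers, ds.counts, cfg.n_hvg)
        pcs = pp.reduce_pca(layers, cfg.n_pcs, seed=seed)

        # --- consensus clustering ---
        runs = cons.run_multiresolution_clustering(
            pcs, cfg.consensus_method,
            settings=cfg.leiden_resolutions if cfg.consensus_method == "leiden"
            else None,
            seed=seed, knn=cfg.knn_features, target_k=self.n_domains,
        )
        C = cons.build_consensus_matrix(runs)
        L_init, n_cluster = cons.derive_initial_labels(
            C, cfg.init_resolution, seed=seed
        )
        consensus_res = cons.ConsensusResult(C=C, runs=runs, L_init=L_init,
                                             n_cluster=n_cluster)

        # --- topics ---
        from . import topics as tp

        weights = knn_spatial_weights(ds.coords, k=cfg.spatial_k)
        n_topics = min(cfg.n_topics, min(ds.n_spots, ds.n_genes) - 1)
        tm = tp.fit_nmf(layers.loggered, n_topics=n_topics, seed=seed)
        tp.filter_topics_by_mri(tm, weights, cfg.mri_threshold)
        imp = tp.score_topic_importance(
            tm.Z[:, tm.filtered], L_init, n_trees=cfg.rf_trees, seed=seed
        )
        tp.select_informative_topics(tm, imp, cfg.topic_drop_frac)

        # --- gene selection ---
        hvg_idx = np.flatnonzero(layers.hvg_mask)
        if cfg.use_hsg:
            sel = gsel.select_hsg_set(
                tm.H, tm.selected, layers.hvg_mask, weights, layers.loggered,
                tau_low=cfg.tau_low, tau_high=cfg.tau_high, theta=cfg.theta,
                theta_mri=cfg.theta_mri, theta_s=cfg.theta_s,
            )
            feat_idx = np.fromiter(sorted(sel.sets["HSG"]), dtype=int)
        else:
            sel = None
            feat_idx = hvg_idx
        hsg_ids = [layers.gene_ids[g] for g in feat_idx]
        X_feat = layers.loggered[:, feat_idx]

        # --- graphs ---
        A_coord = gb.build_spatial_graph(
            ds.coords, k=cfg.graph_k, C=C, tau=cfg.prune_tau
        )
        A_feat = (
            gb.build_feature_graph(tm.Z_final, C, n_neighbors=cfg.fag_neighbors)
            if cfg.dual_view
            else None
        )

        # --- autoencoder ---
        tcfg = net.TrainConfig(
            d_hid=cfg.d_hid, d_out=cfg.d_out, epochs=cfg.epochs, lr=cfg.lr,
            seed=seed, lambdas=cfg.lambdas, warmup_frac=cfg.warmup_frac,
            n_prototypes=cfg.n_prototypes, temperature=cfg.temperature,
            sinkhorn_iters=cfg.sinkhorn_iters,
            prototype_refresh=cfg.prototype_refresh, dual_view=cfg.dual_view,
        )
        params, emb, history = net.train_model(
            X_feat, A_coord, A_feat, tcfg, n_clusters=self.n_domains
        )

        # --- domain calling ---
        if self.n_domains is not None:
            dres = dom.cluster_embeddings(
                emb.E_att, self.n_domains, cfg.cluster_method, seed=seed
            )
        else:
            lo, hi, step = cfg.resolution_grid
            _, dres = dom.search_resolution(
                emb.E_att, lo, hi, step, seed=seed
            )
        labels = dom.refine_labels_local(
            dres.labels, ds.coords, n=min(cfg.refine_n, ds.n_spots - 1),
            enabled=cfg.refine,
        )
        dres.refined = cfg.refine

        return SpatialDomainResults(
            model=self,
            labels=labels,
            embeddings=emb,
            loss_history=history,
            gene_selection=sel,
            hsg_ids=hsg_ids,
            topic_model=tm,
            consensus=consensus_res,
            domain_result=dres,
            layers=layers,
            dataset=ds,
            seed=seed,
            config=cfg,
        )
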