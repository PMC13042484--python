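# stdual

Spatial-transcriptomics domain identification through a **dual-view graph
autoencoder** with **topic-driven gene selection**.

Sequencing- and imaging-based spatial transcriptomics measure a spot x gene
count matrix `X` (N x G) alongside 2-D coordinates `S`. The analysis goal is
to segment the tissue into *spatial domains* — regions sharing a
transcriptional program — and to explain each domain by its driving topics
and marker genes. Purely spatial methods over-smooth and cannot connect
functionally identical regions that are far apart (e.g. the dorsal and
ventral hippocampus in a sagittal section); purely expression-based
clustering fragments coherent tissue. `stdual` is written for
computational biologists who want both: a spatial view and a feature view
of the same spots, learned jointly and fused by attention.

## Model

1. **Consensus clustering.** Leiden over a resolution sweep on PCA scores
   gives runs `l^(t)`; the consensus matrix `C_ij = (1/r) Σ_t 1[l_i^(t) =
   l_j^(t)]` and preliminary labels `L_init` (Leiden on the C-weighted
   graph) summarize them.
2. **Topics.** NMF with NNDSVD init factorizes log expression into
   spot-topic `Z` and gene-topic `H`; topics are kept if spatially coherent
   (Moran's I ≥ 0.2) and discriminative (top 80% by random-forest Gini
   importance against `L_init`).
3. **High spatial-specificity genes (HSGs).** Within each kept topic, genes
   are ranked by normalized weight; topic-specific genes (TSGs) have rank
   within the head of some topic and z-score > 1.96. HSG = (HVG ∪ TSG)
   minus at most |TSG \ HVG| of the least topic-relevant, non-spatial HVGs
   — a strict net gain over the HVG list.
4. **Dual graphs.** SAG: spatial 6-NN pruned where consensus < 0.2. FAG:
   consensus neighborhoods ∩ cosine neighborhoods of topic activity, with a
   per-node cap on added edges — the long-range link between distant
   same-program regions.
5. **Autoencoder.** Shared-weight GCN encoders per view
   (`E = ReLU(Ã X W1) W2 + b2`), tanh/softmax attention fusion, decoders on
   transposed weights, trained under
   `L = λ1 L_recon + λ2 L_graph + λ3 L_swav + λ4 L_att`
   with λ initialized to (10, 10, 5, 1), a SwAV term (Sinkhorn-normalized
   prototype assignments, symmetric KL across views) and a staged weighting
   schedule. Domains come from a tied-covariance Gaussian mixture (known K)
   or a Calinski-Harabasz-searched Leiden clustering of the fused embedding.

## Worked example

```python
from stdual import generate_synthetic_st
from stdual.model import SpatialDomainModel, PipelineConfig

ds, truth = generate_synthetic_st(seed=1)          # 20x20 grid, 4 domains
model = SpatialDomainModel(ds, n_domains=4, config=PipelineConfig.fixture())
res = model.fit(seed=1)
print(res.summary())
print(res.evaluate(truth.domain_labels))
```

prints

```
Spatial domain identification results
=============================================
spots: 400    genes (post-QC): 300
seed: 1    dual view: True    HSG selection: True
HVG: 150  TSG: 52  Non-TSG: 50  removed: 27  HSG: 150
topics: 15 fitted, 4 spatial, 3 selected
domains called: 4 (gmm)
final losses  recon: 9.7537  graph: 8.8956  swav: 0.3292  att: 0.0127  total: 108.0913
mean attention (spatial, feature): (0.519, 0.481)
{'NMI': 0.962, 'HOM': 0.962, 'COM': 0.962, 'ARI': 0.973, 'CHAOS': 0.176, 'PAS': 0.013, 'ASW': 0.388}
```

Reading the output: of 15 fitted topics, 4 were spatially coherent and 3
survived importance filtering — matching the four planted domain programs.
The HSG set swapped 27 non-spatial HVGs for 52 topic-specific genes. The
attention split (0.52/0.48) shows both views contribute, and the called
domains agree with the planted ones at ARI 0.97 with near-zero PAS (almost
no spatially aberrant spots). `res.domain_markers()` then lists, per
domain, the genes correlating above r = 0.3 with the domain's best-matching
topic — on this fixture the top entries are the planted markers of that
domain's program.

The same workflow is scriptable from a shell:

```bash
stdual simulate --preset default --out sim && \
stdual run --input sim --format delimited --n-domains 4 --seed 0 --out run0 && \
stdual eval --pred run0/labels.tsv --truth sim/truth.tsv
```

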