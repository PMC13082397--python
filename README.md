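# duast

Dual-branch representation learning for spatial transcriptomics:
spatial domain identification, gene-expression reconstruction,
multi-omics integration, and spatially-variable-gene (SVG) scoring.

## Who this is for

Computational biologists analyzing array-based spatial transcriptomics
(10x Visium, Stereo-seq, ...) or spatial multi-omics (CITE-seq-style
protein + RNA, epigenome + transcriptome) who want a single model that
combines a *spatial* view of the tissue with a *non-spatial* (or
second-modality) view of the same spots.

## The model in brief

Given an expression matrix `X1 ∈ R^{N×d1}`, spot coordinates, and an
optional second modality `X2 ∈ R^{N×d2}` (a copy of `X1` in
single-omics mode), the package trains two encoders jointly:

- a **spatial-aware branch**: a variational graph auto-encoder over the
  binary symmetric KNN graph of spot coordinates — GCN encoder,
  posterior `N(μ, σ²)` per spot, inner-product adjacency decoder,
  negative-ELBO loss (adjacency BCE + KL);
- a **non-spatial branch**: a two-layer batch-normalized MLP on `X2`.

Three couplings tie the branches together: a Deep-Graph-Infomax-style
**local–global contrastive loss** (shared bilinear discriminator,
neighborhood summaries, permuted negatives), **adversarial alignment**
through a gradient-reversal layer and an MLP modality discriminator,
and **attention fusion** — a per-spot softmax convex combination
`Z_att = α₁ Z_sa + α₂ Z_ns` decoded back to expression under MSE.

Domain mode minimizes `λ₁ L_SAB + λ₂ L_LGCM + λ₃ L_AAM + λ₄ L_AFM`;
spatial domains are the tied-covariance Gaussian-mixture (mclust-EEE
style) clusters of `Z_att`.  SVG mode swaps the fusion term for a
linear reconstruction from the concatenated latent
`Z_con = [Z_sa, Z_ns]`; after training, each gene's **spatial relevance
score** is the min-max-normalized ratio of mean absolute decoder
weights in the spatial vs non-spatial latent subspace, after
reweighting by the latent column norms.  See `docs/methods.md` for the
full treatment.

## Worked example

```python
import duast

# simulate a 900-spot slice: 3 contiguous domains, 20 planted SVGs
dataset, truth = duast.generate_st(seed=1)
prep, kept = duast.preprocess_dataset(dataset)
graph = duast.build_knn_adjacency(prep.coords, 6)

# spatial domain identification
model = duast.train(prep, graph, duast.ModelConfig(mode="domain", seed=1))
res = duast.cluster_embeddings(model.Z_att, 3, seed=0)
print(duast.supervised_metrics(res.labels, truth.domain_labels)["ARI"])
# 0.9904521579873833

# spatially-variable-gene scoring (restart-averaged ranking)
scores, runs = duast.score_spatial_genes(prep, graph,
                                         duast.ModelConfig.for_svg(seed=1))
print(scores.ranking[:10])
# [  9  31  81  59  40 113 139  35 177  42]
```

The adjusted Rand index of 0.99 means the mixture clustering of the
fused embedding reproduces the three planted domains nearly perfectly
(1.0 is exact agreement, 0 is chance).  The ten top-ranked genes are
all planted spatially variable genes — `truth.svg_flags` marks which
gene indices carry a spatial program, so you can check the ranking
against the ground truth directly.

The same workflow is available from the shell:

```bash
duast simulate --out sim --seed 1
duast preprocess --input sim/data.h5ad --out prep.h5ad
duast train --input prep.h5ad --out run --mode domain --seed 1
duast cluster --run run --n-clusters 3 --out labels.csv
duast train --input prep.h5ad --out svgrun --mode svg --seed 1
duast svg --run svgrun --top 50 --out svgs.tsv
duast evaluate --labels labels.csv --truth sim/data.h5ad --out metrics.json
```

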