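# Methods

This note records the modelling assumptions, parameter defaults and
numerical conventions behind `sthet`, and what the synthetic studies in
the test suite do and do not establish.

## Data model and preprocessing

A dataset is a nonnegative genes × spots count matrix with per-spot 2-D
coordinates, an integer histological-region label per spot (validated to
a contiguous 1..K range; non-contiguous codes are remapped with a logged
table), and optionally a per-spot histology feature matrix standing in
for image-derived features (image processing itself is outside this
package's scope — any upstream feature extractor can supply the matrix).
Counts are scaled per spot to the median library size and log1p
transformed; this is a monotone per-spot transform, so within-spot gene
rankings are preserved.  Highly variable genes are ranked by a
variance-stabilizing dispersion: each gene's raw counts are standardized
by the standard deviation *expected* for its mean under a log-log
polynomial mean–variance trend fitted across genes, clipped at √n, and
scored by the variance of the standardized values.  Genes sitting above
the trend rank first; constant genes score zero.

Spots are summarized by the 50-dimensional bottleneck of a symmetric
two-hidden-layer autoencoder (hidden width 128, relu, linear output)
trained to reconstruct the normalized HVG matrix under mean squared
error with Adam (lr 1e-3), early-stopped like every other trainer here.
MSE on log-normalized data is the simplest objective consistent with the
encoder's role as a spot feature extractor; the operation is isolated so
a count-likelihood (e.g. NB/VAE) variant could replace it without
touching anything downstream.

## Graphs

* **Cell heterogeneous graph**: each spot links to its top-m HVGs
  (default m = 30) ranked by expression-to-gene-mean ratio — large
  enough to characterize a state, small enough to keep the graph
  sparse.  Zero-expression genes are never linked; ties at the m-th
  rank go to the lower gene index so the construction is
  bit-reproducible.  Each spot has exactly one region edge.  Node
  encodings: autoencoder latent for spots, one-hot for genes and
  regions.
* **Semantic graphs**: 6-nearest-neighbor graphs from Euclidean
  distance on coordinates (SLG), cosine similarity of histology
  features (HSG) and of the spot encodings (TSG).  All kNN searches are
  exact with ties broken by ascending index.  Without histology
  features the HSG is omitted and the fusion attention runs over two
  graphs.
* **Gene heterogeneous graph**: candidates are the union of all states'
  SVGs; each links to its top-m expressing spots (the express rule
  transposed) and to every state that called it.
* **Communication neighborhoods**: one shared spatial K-nearest-neighbor
  set per spot (default K = 6, matching the semantic graphs) reused by
  all retained ligand–receptor pairs; pairs whose ligand or receptor is
  absent from the dataset are skipped with a logged list.  Gene matching
  is case-sensitive throughout.

## Encoders and objectives

The hierarchical and semantic encoders and their attention mechanisms
are described in the README.  Numerical conventions: LeakyReLU slope
0.2 in all attention logits; ELU between graph-attention layers; heads
are averaged, not concatenated; graph attention aggregates over
neighbors only (no self-loops) — a node's own signal reaches it through
the other encoder via the contrastive coupling.  The view weight β is
global (computed from the average over all spots), while the fusion
weight γ is per-spot.  Softmaxes subtract a detached row maximum;
attention rows over empty sets are all-zero rather than NaN, and such
anchors are excluded from losses.

Common embedding dimension d = 32 (so R is 64-d), gene embedding b = 50,
communication projection 32.  Contrastive balance λ = 0.5 and
temperature τ = 0.5; both exposed.  Positives are each spot's spatial
6-NN restricted to its own region; a spot with no same-region neighbor
falls back to its single nearest same-region spot dataset-wide, and a
spot alone in its region is dropped from the loss with a warning
(preventing −log 0 while honoring the region constraint).  Losses
average over spots with at least one positive.  Gene-module positives
additionally require co-expression: joint nonzero fraction ≥ ρ = 0.1
(the threshold is logged together with how many knowledge-base pairs
pass).  GRN edges are treated as undirected for the symmetric
contrastive similarity; direction is retained in outputs.

All trainers use full-batch Adam (lr 1e-3) with early stopping when the
loss fails to improve by 1e-4 for 10 epochs, capped at 500 epochs.  The
two cell-module encoders are optimized jointly on the total loss by
default; an `alternating` flag optimizes them on alternating epochs.
For datasets above a few thousand spots the all-spots negative sets
dominate memory; the intended extension is per-epoch negative
subsampling, which is not needed at the problem sizes this package
targets in its tests (≤ a few hundred spots) and is therefore not
implemented.

Everything differentiable runs on a small reverse-mode autodiff core
(`sthet/_autodiff.py`) over float64 numpy arrays.  Gradients are
validated against central finite differences in the test suite, and all
graph/matrix entry points force C-contiguous inputs where BLAS
summation order could otherwise perturb the last bits — with one seed,
every stage reproduces its outputs byte-for-byte.

## Clustering and evaluation

Embeddings are clustered Seurat-style: exact kNN (k = 20, including
self), shared-neighbor Jaccard weights pruned below 1/15, Louvain
communities (igraph `community_multilevel`, seeded).  Because the
contrastive positives are deliberately local, the learned embedding
preserves sub-state structure *within* regions, and a fixed Louvain
resolution tends to over-partition annotated domains.  The package
therefore follows the standard benchmarking convention for spatial
domain detection: when an annotated cluster count is available (the
pipeline uses the number of histological regions K), the resolution is
chosen by bisection so the community count matches it
(`cluster_spots(target_clusters=...)`); a fixed `resolution` remains
available for exploratory sub-state analysis.

Silhouette widths use Euclidean distances on the supplied embedding;
d(i) is the mean distance to own-cluster co-members, c(i) the minimum
over other clusters of the mean distance to that cluster ("nearest
cluster" is only defined through these means, so the minimum-of-means
reading is used and documented).  Singleton-cluster spots and coincident
duplicated points (d = c = 0) score 0.  Denoising averages each spot
with its k = 3 nearest neighbors *plus itself* (mean over 4 values),
by default in embedding space with a `space="physical"` option.  SVGs
and differential LRPs use one-vs-rest Wilcoxon rank-sum (normal
approximation) with Benjamini–Hochberg control, log2 fold-change floor
0.25 on expm1 means, FDR 0.05; clusters under 3 spots are excluded with
a warning.  LRP specificity uses the mean-absolute-difference Gini over
cluster-mean strengths, Σᵢⱼ|μᵢ−μⱼ| / (2 C Σμ) ∈ [0, (C−1)/C], without
small-sample correction; the 0.4 "specific" flag is a reporting default
only.

## Synthetic studies

The generator plants every structure the learning stages are asked to
recover: axis-aligned domain blocks on a spot grid (a scattered-island
option gives two distant blocks the same expression program but
distinct region labels), per-domain 20-gene programs at marker
fold-change 5 over a baseline negative-binomial rate of 0.3 with
dispersion 0.5 (Var = μ + 0.5μ²) and 10% independent dropout — the
baseline rate is set so the zero fraction (~75–80%) matches typical
spot-level HVG matrices; per-region histology mean shifts with isotropic
noise; within-module PPI/GRN edges with an equal number of cross-module
decoys (so positive-pair enrichment is a meaningful test); and
ligand–receptor pairs whose ligand decays as a Gaussian (width 3 grid
units) from the sender-domain centroid while the receptor is expressed
in the receiver domain, plus a spatially uniform decoy pair.  The
standard study is a 20×15 grid, 3 domains, 200 genes, seed 1.

What passing these studies shows: the encoders, objectives and
downstream statistics recover exactly the structure they model, at
realistic sparsity and noise, from a cold start.  What it does not
show: robustness to segmentation errors in region labels, to spatial
covariates that violate the block-domain geometry, to batch effects, or
to the far larger spot counts and gene panels of real platforms —
real-data behavior must be established separately.

## Known limitations

* Histology enters only as precomputed feature vectors; no image
  processing.
* Full-batch training with all-spot negative sets bounds practical
  problem sizes to a few thousand spots.
* Multi-subunit ligand/receptor complexes must be expanded to gene
  pairs upstream; the loader treats each row as one ordered pair.
* The Gini specificity is the standard mean-absolute-difference
  coefficient over cluster means; other inequality-based variants would
  need their own calibration.
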