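# sthet

Heterogeneous-graph attention and contrastive learning for spatially
resolved transcriptomics (SRT).

Array- and imaging-based SRT platforms measure a gene expression matrix
**X** ∈ R^(m×n) at n spots/cells with preserved tissue coordinates
**S** ∈ R^(n×2), alongside histological-region labels y_i ∈ {1..K} and,
optionally, image-derived feature vectors per spot.  Dissecting a tumor
microenvironment (or any heterogeneous tissue) from these data means
answering three linked questions: which *cell-modules* (spatial domains
and sub-states) are present, which *gene-modules* underlie them, and
which *ligand–receptor pairs* (LRPs) carry communication between
neighboring cells.  `sthet` answers all three with one family of
heterogeneous-graph attention encoders trained by contrastive
self-supervision, using protein–protein interactions (PPI), regulatory
relations (GRN) and ligand–receptor tables as priors.

## The model

**Cell modules.**  Each spot gets two representations that supervise
each other.  The *hierarchical* embedding comes from a spot-centered
heterogeneous graph with "expresses gene" edges (top-m genes per spot by
expression-to-mean ratio) and a "belongs to region" edge: node encodings
are projected to a common space, d_i = relu(W_∅ l_i + b_∅), aggregated
per view with attention α_ij = softmax_j LeakyReLU(a_Ωᵀ[d_i ‖ d_j]), and
the gene and region views are mixed with a global view weight β learned
from the |V|-average of a_Hᵀ tanh(W_H d_i + b_H), giving
R¹_i = Σ_m β_Ωm d_i^Ωm.  The *semantic* embedding runs a multi-head
graph-attention encoder (heads averaged) over three 6-nearest-neighbor
graphs — spatial location (SLG), histology similarity (HSG, optional)
and transcriptional similarity (TSG) — and fuses the per-graph outputs
p_i^m with attention γ_i^m = softmax_m(a_m · p_i^C):
R²_i = Σ_m γ_i^m p_i^m.  Training minimizes a mutual InfoNCE objective

L_total = (1/|V|) Σ_i [ λ·L_i^H + (1−λ)·L_i^S ],
L_i^H = −log Σ_{j∈P_i} exp(sim(R²_i, R¹_j)/τ) / Σ_{k∈P_i∪N_i} exp(sim(R²_i, R¹_k)/τ),

with cosine similarity, positives P_i = spatial neighbors sharing the
spot's region, negatives N_i = all other spots, and L^S the symmetric
term.  The final representation R = R¹‖R² feeds shared-nearest-neighbor
Louvain clustering, silhouette evaluation SW(i) = (c(i)−d(i))/max{c,d},
kNN expression denoising, and one-vs-rest Wilcoxon calling of spatially
variable genes (SVGs).

**Gene modules.**  SVGs become candidate genes of a gene-centered graph
("expressed by" spots, "over-expressed by" cell-states) encoded with the
same two-level attention; contrastive positives are PPI/GRN partners
that are also co-expressed (jointly nonzero in ≥ ρ of spots), so
embeddings place interacting, co-expressed genes adjacently before
Louvain clustering into modules.

**Cell–cell communication.**  For LRP k (ligand o, receptor p) the
receptor sits on the central spot and the ligand on its K spatial
neighbors: α_i,z = softmax_z LeakyReLU(a_kᵀ[x_i,p ‖ x_z,o]),
LR_i,k = Σ_z α_i,z x_z,o, and the interaction strength is
LRP_i,k = LR_i,k · x_i,p.  The per-spot strength vector H_i is projected
to K_i = W H_i and trained with the same InfoNCE positives so
communication profiles respect cell-state structure.  Downstream, each
pair's cluster specificity is scored with a Gini coefficient over
cluster-mean strengths and differential pairs are called one-vs-rest.

All attention encoders and objectives run on a small reverse-mode
autodiff core over numpy (`sthet/_autodiff.py`), gradient-checked
against finite differences in the test suite.

## Worked example

```python
import sthet as st
from sklearn.metrics import adjusted_rand_score

# a synthetic study with known truth: 20x15 spot grid, 3 domains,
# 200 genes (20-gene program per domain at fold-change 5), planted
# PPI/GRN modules and a sender->receiver ligand gradient
cfg = st.SimConfig(seed=1)
ds, kb, truth = st.simulate_dataset(cfg)
ds, hvgs = st.normalize_and_select_hvgs(ds, n_hvg=200)
latent = st.encode_cells(ds, dim=50, seed=1)

g1 = st.build_cell_hetero_graph(ds, latent, m=30)
graphs = st.build_semantic_graphs(ds, latent, k=6)
result = st.CellModuleModel(ds, g1, graphs).fit(seed=1)
print(result.summary())
labels = st.cluster_spots(result.R, seed=1, target_clusters=ds.n_regions)
print(f"ARI vs planted domains: {adjusted_rand_score(truth.domains, labels):.3f}")
print(f"ASW: {st.silhouette(result.R, labels).asw:.3f}")
```

prints

```
Cell-module fit
==============================================
spots: 300   embedding: 64-d (R1||R2)
epochs run: 500   final loss: 3.054290
view weights beta (region, gene): (0.6411, 0.3589)
mean graph attention gamma:
  slg: 0.4383
  hsg: 0.2451
  tsg: 0.3166
ARI vs planted domains: 1.000
ASW: 0.854
```

The view weights say the region edge carries somewhat more of the
hierarchical signal than the gene edges on this fixture; the fusion
attention γ favors the spatial graph.  Clustering the concatenated
embedding recovers the three planted domains exactly (ARI 1.0) with a
tight silhouette (0.854).  `GeneModuleModel` and `CCCModel` continue the
workflow from `labels`; the `sthet` CLI (`simulate`, `cell-module`,
`gene-module`, `ccc`, `evaluate`, `run`) wires the same stages together
with resumable, seeded outputs.

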