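"""Gene-module learning: SVG calling, gene-centered attention encoding,
and PPI/GRN-anchored contrastive training.

Spatially variable genes (SVGs) are called per cell-state by one-vs-rest
Wilcoxon rank-sum on the normalized expression with a log2 fold-change
floor and Benjamini-Hochberg control.  The union of all states' SVGs
forms the candidate genes of a gene-centered heterogeneous graph whose
two views (expressing spots, over-expressing states) are aggregated by
the same two-level attention as the cell module.  Contrastive training
pulls together candidate pairs that are both (a) linked in the PPI or
GRN priors and (b) co-expressed in at least a fraction ``rho`` of
spots; all other candidates act as negatives.  The embeddings are
finally clustered into gene modules with SNN + Louvain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._autodiff import Adam, EarlyStopper, Tensor, cosine_similarity_matrix
from .cell import (HierarchicalEncoder, PositiveNegativeSets,
                   info_nce_per_anchor)
from .datasets import InteractionKB, SpatialDataset, ValidationError
from .evaluate import _louvain, snn_graph
from .graphs import GeneHeteroGraph, build_gene_hetero_graph

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# SVG calling
# ---------------------------------------------------------------------------

def call_svgs(ds: SpatialDataset, cluster_labels: np.ndarray,
              lfc_min: float = 0.25, fdr_max: float = 0.05,
              min_cluster_size: int = 3) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum over HVGs per cluster.

    Keeps genes with log2 fold-change >= ``lfc_min`` and BH-adjusted
    p <= ``fdr_max``; returns a table of (gene, cluster, lfc, p_adj).
    """
    labels = np.asarray(cluster_labels)
    clusters = np.unique(labels)
    if clusters.size < 2:
        raise ValidationError("SVG calling requires at least 2 clusters")
    X = ds.normalized_matrix()
    genes = list(ds.gene_ids)
    if ds.hvgs is not None:
        cols = ds.hvg_indices()
        X = X[:, cols]
        genes = list(ds.hvgs)
    expr = np.expm1(X)
    eps = 1e-9
    rows = []
    for c in clusters:
        inside = labels == c
        if inside.sum() < min_cluster_size:
            logger.warning("cluster %s has <%d spots; excluded from SVG calling",
                           c, min_cluster_size)
            continue
        pvals = np.ones(len(genes))
        lfcs = np.zeros(len(genes))
        for gi in range(len(genes)):
            a = X[inside, gi]
            b = X[~inside, gi]
            if np.ptp(np.concatenate([a, b])) == 0:
                pvals[gi] = 1.0
            else:
                pvals[gi] = stats.ranksums(a, b).pvalue
            lfcs[gi] = np.log2((expr[inside, gi].mean() + eps)
                               / (expr[~inside, gi].mean() + eps))
        p_adj = multipletests(pvals, method="fdr_bh")[1]
        keep = (lfcs >= lfc_min) & (p_adj <= fdr_max)
        for gi in np.where(keep)[0]:
            rows.append((genes[gi], int(c), float(lfcs[gi]), float(p_adj[gi])))
    return pd.DataFrame(rows, columns=["gene", "cluster", "lfc", "p_adj"])


# ---------------------------------------------------------------------------
# gene encoder and contrastive training
# ---------------------------------------------------------------------------

@dataclass
class GeneContrastiveConfig:
    """Positive rule and temperature for the gene contrastive objective."""

    tau: float = 0.5
    rho: float = 0.1     # minimum joint-nonzero spot fraction for co-expression

    def __post_init__(self):
        if self.tau <= 0:
            raise ValidationError("temperature tau must be > 0")
        if not 0.0 <= self.rho <= 1.0:
            raise ValidationError("rho must be in [0, 1]")


def gene_positive_pairs(ds: SpatialDataset, kb: InteractionKB,
                        candidates: list[str], rho: float
                        ) -> tuple[np.ndarray, int]:
    """Boolean candidates x candidates positive mask.

    A pair is positive when it appears in PPI or (undirected) GRN and the
    two genes are jointly nonzero in at least ``rho`` of spots.
    """
    pos_index = {g: i for i, g in enumerate(candidates)}
    cand = set(candidates)
    linked = np.zeros((len(candidates), len(candidates)), dtype=bool)
    edges = [tuple(p) for p in kb.ppi] + list(kb.grn)
    for a, b in edges:
        if a in cand and b in cand:
            linked[pos_index[a], pos_index[b]] = True
            linked[pos_index[b], pos_index[a]] = True
    kb_pairs = int(linked.sum() // 2)   # distinct undirected pairs
    gene_index = {g: i for i, g in enumerate(ds.gene_ids)}
    X = ds.normalized_matrix()[:, [gene_index[g] for g in candidates]] > 0
    joint = X.T.astype(np.float64) @ X.astype(np.float64) / X.shape[0]
    mask = linked & (joint >= rho)
    np.fill_diagonal(mask, False)
    return mask, kb_pairs


class GeneEncoder(HierarchicalEncoder):
    """Two-level attention over a gene's expressing spots and its states.

    Structurally identical to the cell hierarchical encoder with the
    views {spots, cell-states} in place of {region, genes}.
    """

    def __init__(self, g2: GeneHeteroGraph, b: int = 50,
                 rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        n_spots_feat = g2.spot_encodings.shape[1]
        super().__init__(n_latent=len(g2.candidate_genes),
                         n_genes=n_spots_feat,
                         n_regions=len(g2.states), d=b, rng=rng)
        self.g2 = g2

    def forward_genes(self) -> tuple[Tensor, dict[str, np.ndarray]]:
        g2 = self.g2
        d_gene = (Tensor(g2.gene_encodings) @ self.W_spot.T + self.b_spot).relu()
        d_spot = (Tensor(g2.spot_encodings) @ self.W_gene.T + self.b_gene).relu()
        d_state = (Tensor(g2.state_encodings) @ self.W_region.T
                   + self.b_region).relu()

        alpha_spot = self._node_attention(d_gene, d_spot, g2.expressed_by_mask,
                                          self.a_gene)
        view_spot = (alpha_spot @ d_spot).relu()
        has_state = g2.state_mask.any(axis=1)
        alpha_state = self._node_attention(d_gene, d_state, g2.state_mask,
                                           self.a_region)
        view_state = (alpha_state @ d_state).relu()
        # genes not over-expressed anywhere fall back to the spot view only
        state_w = Tensor(has_state.astype(np.float64).reshape(-1, 1))

        if self.beta_override is not None:
            beta = Tensor(np.asarray(self.beta_override, dtype=np.float64))
        else:
            from ._autodiff import concat, masked_softmax
            w = concat([((dv @ self.W_view.T + self.b_view).tanh()
                         @ self.a_view).mean().reshape(1)
                        for dv in (view_spot, view_state)], axis=0)
            beta = masked_softmax(w, np.ones(2, dtype=bool), axis=0)
        G = beta[0] * view_spot + beta[1] * view_state * state_w
        tables = {"alpha_spot": alpha_spot.data, "alpha_state": alpha_state.data,
                  "beta": beta.data}
        return G, tables


def gene_forward(g2: GeneHeteroGraph, enc: GeneEncoder
                 ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    G, tables = enc.forward_genes()
    return G.data, tables


@dataclass
class GeneModuleResults:
    """Fitted gene embeddings with the positive-pair audit."""

    G: np.ndarray
    candidate_genes: list[str]
    beta: np.ndarray
    loss_curve: list[float]
    n_epochs: int
    n_kb_pairs: int
    n_positive_pairs: int
    module_labels: np.ndarray | None = None
    config: dict = field(default_factory=dict)

    def cluster(self, resolution: float = 1.0, k: int = 20, seed: int = 0
                ) -> np.ndarray:
        self.module_labels = cluster_gene_modules(self.G, resolution=resolution,
                                                  k=k, seed=seed)
        return self.module_labels

    def summary(self) -> str:
        lines = [
            "Gene-module fit",
            "=" * 46,
            f"candidate genes: {len(self.candidate_genes)}   "
            f"embedding: {self.G.shape[1]}-d",
            f"epochs run: {self.n_epochs}   final loss: {self.loss_curve[-1]:.6f}",
            f"KB pairs among candidates: {self.n_kb_pairs}; "
            f"positives after co-expression filter: {self.n_positive_pairs}",
        ]
        if self.module_labels is not None:
            lines.append(f"gene modules found: {self.module_labels.max()}")
        return "\n".join(lines)


class GeneModuleModel:
    """Contrastive trainer for gene embeddings anchored on PPI/GRN priors."""

    def __init__(self, ds: SpatialDataset, kb: InteractionKB,
                 g2: GeneHeteroGraph | None = None,
                 cluster_labels: np.ndarray | None = None,
                 latent_cell: np.ndarray | None = None,
                 svg_table: pd.DataFrame | None = None,
                 b: int = 50, tau: float = 0.5, rho: float = 0.1,
                 m: int = 30, lr: float = 1e-3, max_epochs: int = 500,
                 min_delta: float = 1e-4, patience: int = 10):
        if g2 is None:
            if svg_table is None:
                if cluster_labels is None:
                    raise ValidationError(
                        "need a gene graph, an SVG table, or cluster labels")
                svg_table = call_svgs(ds, cluster_labels)
            if latent_cell is None:
                raise ValidationError("latent_cell required to build the gene graph")
            g2 = build_gene_hetero_graph(ds, latent_cell, svg_table, m=m)
        self.ds = ds
        self.kb = kb
        self.g2 = g2
        self.cfg = GeneContrastiveConfig(tau=tau, rho=rho)
        self.b = b
        self.lr = lr
        self.max_epochs = max_epochs
        self.min_delta = min_delta
        self.patience = patience

    def fit(self, seed: int = 0) -> GeneModuleResults:
        rng = np.random.default_rng(seed)
        enc = GeneEncoder(self.g2, b=self.b, rng=rng)
        pos_mask, kb_pairs = gene_positive_pairs(
            self.ds, self.kb, self.g2.candidate_genes, self.cfg.rho)
        n_pos = int(pos_mask.sum() // 2)
        if n_pos == 0:
            if kb_pairs > 0:
                raise ValidationError(
                    f"all {kb_pairs} KB pairs were filtered by the co-expression "
                    f"threshold rho={self.cfg.rho}; lower rho")
            raise ValidationError("no positive gene pair among candidates")
        logger.info("%d KB pairs among candidates, %d pass co-expression",
                    kb_pairs, n_pos)
        neg_mask = ~pos_mask
        np.fill_diagonal(neg_mask, False)
        anchor = pos_mask.any(axis=1)
        neg_mask[~anchor] = False
        sets = PositiveNegativeSets(pos_mask=pos_mask, neg_mask=neg_mask,
                                    anchor_mask=anchor)
        w = anchor.astype(np.float64)
        w = (w / w.sum()).reshape(-1, 1)

        opt = Adam(enc.parameters(), lr=self.lr)
        stopper = EarlyStopper(min_delta=self.min_delta, patience=self.patience)
        curve: list[float] = []
        epoch = 0
        for epoch in range(self.max_epochs):
            opt.zero_grad()
            G, _ = enc.forward_genes()
            sim = cosine_similarity_matrix(G, G) * (1.0 / self.cfg.tau)
            loss = (info_nce_per_anchor(sim, sets) * w).sum()
            value = float(loss.data)
            if not np.isfinite(value):
                raise FloatingPointError(f"training diverged at epoch {epoch}")
            loss.backward()
            opt.step()
            curve.append(value)
            if stopper.update(value):
                break
        G, tables = enc.forward_genes()
        return GeneModuleResults(
            G=G.data, candidate_genes=list(self.g2.candidate_genes),
            beta=tables["beta"], loss_curve=curve, n_epochs=epoch + 1,
            n_kb_pairs=kb_pairs, n_positive_pairs=n_pos,
            config={"b": self.b, "tau": self.cfg.tau, "rho": self.cfg.rho,
                    "seed": seed})


def gene_contrastive_train(ds: SpatialDataset, kb: InteractionKB,
                           g2: GeneHeteroGraph, seed: int = 0,
                           **kwargs) -> GeneModuleResults:
    """Functional wrapper around :class:`GeneModuleModel`."""
    return GeneModuleModel(ds, kb, g2=g2, **kwargs).fit(seed=seed)


def cluster_gene_modules(G: np.ndarray, resolution: float = 1.0,
                         k: int = 20, seed: int = 0) -> np.ndarray:
    """SNN + Louvain on gene embeddings; labels 1..n_modules."""
    G = np.asarray(G, dtype=np.float64)
    if G.shape[0] < 2:
        raise ValidationError("too few genes to cluster")
    if np.allclose(G.var(axis=0), 0):
        raise ValidationError("degenerate embeddings: zero variance")
    n = G.shape[0]
    k = min(k, n)
    src, dst, w = snn_graph(G, k=k)
    return _louvain(src, dst, w, n, resolution, seed)


__all__ = [
    "call_svgs", "GeneContrastiveConfig", "GeneEncoder", "gene_forward",
    "gene_positive_pairs", "GeneModuleModel", "GeneModuleResults",
    "gene_contrastive_train", "cluster_gene_modules",
]
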