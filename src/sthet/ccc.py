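"""Ligand-receptor communication inference by spatial neighbor attention.

For ligand-receptor pair k the receptor lives on the central spot and
the ligand on its spatial K nearest neighbors.  A per-pair attention
vector a_k scores each neighbor from the (receptor, ligand) expression
pair through a LeakyReLU, the softmax-normalized weights aggregate the
neighborhood ligand signal LR_ik, and the interaction strength is
LRP_ik = LR_ik * x_ receptor.  The strengths of all retained pairs form
the per-spot vector H_i; a linear projection K_i = W H_i is trained
contrastively (same positives/negatives as the cell module) so that
spots in the same state carry comparable communication profiles.
Downstream, each pair's cluster specificity is scored with a Gini
coefficient over cluster-mean strengths, and differential pairs are
called one-vs-rest as for SVGs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._autodiff import (Adam, EarlyStopper, Parameter, Tensor,
                        cosine_similarity_matrix, glorot, masked_logsumexp,
                        masked_softmax)
from .cell import PositiveNegativeSets, info_nce_per_anchor
from .datasets import SpatialDataset, ValidationError
from .graphs import LRPNeighborGraph

logger = logging.getLogger(__name__)

LEAKY_SLOPE = 0.2


@dataclass
class CCCResult:
    """Per-spot x per-LRP interaction strengths with attention diagnostics."""

    H: np.ndarray                 # spots x M, nonnegative
    attention: np.ndarray         # spots x K x M neighbor weights
    LR: np.ndarray                # spots x M aggregated ligand signal
    a: np.ndarray                 # M x 2 attention vectors
    spot_ids: list[str]
    lrp_names: list[str]
    W: np.ndarray | None = None   # projection for the latent K_i
    latent: np.ndarray | None = None
    loss_curve: list[float] = field(default_factory=list)
    n_epochs: int = 0
    config: dict = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.H, index=self.spot_ids, columns=self.lrp_names)

    def top_attention_frame(self, neighbors: np.ndarray) -> pd.DataFrame:
        """Audit table: per spot and LRP, the neighbor receiving the most
        attention and its weight."""
        rows = []
        for j, name in enumerate(self.lrp_names):
            best = np.argmax(self.attention[:, :, j], axis=1)
            for i, spot in enumerate(self.spot_ids):
                rows.append((spot, name,
                             self.spot_ids[neighbors[i, best[i]]],
                             float(self.attention[i, best[i], j])))
        return pd.DataFrame(rows, columns=["spot_id", "lrp",
                                           "top_neighbor", "weight"])

    def summary(self) -> str:
        lines = [
            "Cell-cell communication fit",
            "=" * 46,
            f"spots: {len(self.spot_ids)}   LRPs retained: {len(self.lrp_names)}",
        ]
        if self.loss_curve:
            lines.append(f"epochs run: {self.n_epochs}   "
                         f"final loss: {self.loss_curve[-1]:.6f}")
        top = np.argsort(-self.H.mean(axis=0))[:5]
        lines.append("strongest pairs (mean strength):")
        for j in top:
            lines.append(f"  {self.lrp_names[j]}: {self.H[:, j].mean():.4f}")
        return "\n".join(lines)


def _strength_forward(expr: np.ndarray, graph: LRPNeighborGraph, a: Tensor
                      ) -> tuple[Tensor, Tensor, Tensor]:
    """Vectorized neighbor-attention strengths for all retained pairs.

    ``expr`` is the spots x genes normalized expression; ``a`` is (M, 2).
    Returns (H, LR, attention) with attention of shape spots x K x M.
    """
    nbrs = graph.neighbors                           # n x K
    rec = expr[:, [r.receptor_col for r in graph.retained]]      # n x M
    lig = expr[:, [r.ligand_col for r in graph.retained]]        # n x M
    lig_nbr = lig[nbrs]                              # n x K x M
    if not np.all(np.isfinite(expr)):
        raise ValidationError("non-finite expression values")
    n, K = nbrs.shape
    M = len(graph.retained)
    logits = (a[:, 0].reshape(1, 1, M) * rec[:, None, :]
              + a[:, 1].reshape(1, 1, M) * lig_nbr).leaky_relu(LEAKY_SLOPE)
    alpha = masked_softmax(logits, np.ones((n, K, M), dtype=bool), axis=1)
    LR = (alpha * lig_nbr).sum(axis=1)               # n x M
    H = LR * rec
    return H, LR, alpha


def infer_lrp_strength(ds: SpatialDataset, graph: LRPNeighborGraph,
                       a: np.ndarray | None = None, seed: int = 0) -> CCCResult:
    """Interaction strengths with fixed (or freshly initialized) attention.

    Expression enters as the normalized log1p values, so strengths are
    comparable across spots.  With receptor expression zero the strength
    is exactly zero for any attention vector.
    """
    M = graph.M
    if a is None:
        rng = np.random.default_rng(seed)
        a = rng.uniform(-0.1, 0.1, size=(M, 2))
    a = np.asarray(a, dtype=np.float64)
    if a.shape != (M, 2):
        raise ValidationError(f"attention array must be ({M}, 2), got {a.shape}")
    expr = ds.normalized_matrix()
    H, LR, alpha = _strength_forward(expr, graph, Tensor(a))
    names = [f"{r.ligand}->{r.receptor}" for r in graph.retained]
    return CCCResult(H=H.data, attention=alpha.data, LR=LR.data, a=a,
                     spot_ids=list(ds.spot_ids), lrp_names=names)


class CCCModel:
    """Trains the per-pair attention vectors and the latent projection
    contrastively against the cell-module positive/negative sets."""

    def __init__(self, ds: SpatialDataset, graph: LRPNeighborGraph,
                 sets: PositiveNegativeSets, tau: float = 0.5,
                 proj_dim: int = 32, lr: float = 1e-3, max_epochs: int = 500,
                 min_delta: float = 1e-4, patience: int = 10):
        if graph.M == 0:
            raise ValidationError("no retained ligand-receptor pairs")
        if tau <= 0:
            raise ValidationError("temperature tau must be > 0")
        self.ds = ds
        self.graph = graph
        self.sets = sets
        self.tau = tau
        self.proj_dim = proj_dim
        self.lr = lr
        self.max_epochs = max_epochs
        self.min_delta = min_delta
        self.patience = patience

    def fit(self, seed: int = 0) -> CCCResult:
        rng = np.random.default_rng(seed)
        M = self.graph.M
        a = Parameter(rng.uniform(-0.1, 0.1, size=(M, 2)))
        W = glorot(rng, M, self.proj_dim)
        expr = self.ds.normalized_matrix()
        wgt = self.sets.anchor_mask.astype(np.float64)
        wgt = (wgt / wgt.sum()).reshape(-1, 1)

        opt = Adam([a, W], lr=self.lr)
        stopper = EarlyStopper(min_delta=self.min_delta, patience=self.patience)
        curve: list[float] = []
        epoch = 0
        for epoch in range(self.max_epochs):
            opt.zero_grad()
            H, _, _ = _strength_forward(expr, self.graph, a)
            K_lat = H @ W.T
            sim = cosine_similarity_matrix(K_lat, K_lat) * (1.0 / self.tau)
            loss = (info_nce_per_anchor(sim, self.sets) * wgt).sum()
            value = float(loss.data)
            if not np.isfinite(value):
                raise FloatingPointError(f"training diverged at epoch {epoch}")
            loss.backward()
            opt.step()
            curve.append(value)
            if stopper.update(value):
                break

        H, LR, alpha = _strength_forward(expr, self.graph, a)
        latent = H.data @ W.data.T
        names = [f"{r.ligand}->{r.receptor}" for r in self.graph.retained]
        return CCCResult(H=H.data, attention=alpha.data, LR=LR.data,
                         a=a.data, spot_ids=list(self.ds.spot_ids),
                         lrp_names=names, W=W.data, latent=latent,
                         loss_curve=curve, n_epochs=epoch + 1,
                         config={"tau": self.tau, "proj_dim": self.proj_dim,
                                 "K": self.graph.K, "seed": seed})


def ccc_contrastive_train(ds: SpatialDataset, graph: LRPNeighborGraph,
                          sets: PositiveNegativeSets, seed: int = 0,
                          **kwargs) -> CCCResult:
    """Functional wrapper around :class:`CCCModel`."""
    return CCCModel(ds, graph, sets, **kwargs).fit(seed=seed)


# ---------------------------------------------------------------------------
# downstream scoring of H
# ---------------------------------------------------------------------------

def lrp_specificity_gini(H: np.ndarray, cluster_labels: np.ndarray,
                         specific_threshold: float = 0.4) -> pd.DataFrame:
    """Gini coefficient of each pair's cluster-mean strengths.

    Gini = sum_ij |mu_i - mu_j| / (2 C sum_i mu_i) over the C cluster
    means; 0 for perfectly even strengths, (C-1)/C when one cluster
    carries everything.  Pairs with all-zero strength score 0 with a
    warning.
    """
    H = np.asarray(H, dtype=np.float64)
    labels = np.asarray(cluster_labels)
    clusters = np.unique(labels)
    if clusters.size < 2:
        raise ValidationError("Gini specificity requires at least 2 clusters")
    C = clusters.size
    means = np.vstack([H[labels == c].mean(axis=0) for c in clusters])  # C x M
    totals = means.sum(axis=0)
    gini = np.zeros(H.shape[1])
    for j in range(H.shape[1]):
        if totals[j] == 0:
            logger.warning("LRP column %d has all-zero strengths; Gini set to 0", j)
            continue
        mu = means[:, j]
        gini[j] = np.abs(mu[:, None] - mu[None, :]).sum() / (2 * C * totals[j])
    return pd.DataFrame({"gini": gini, "specific": gini >= specific_threshold})


def differential_lrp(H: np.ndarray, cluster_labels: np.ndarray,
                     lrp_names: list[str] | None = None,
                     lfc_min: float = 0.25, fdr_max: float = 0.05,
                     min_cluster_size: int = 3) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum on strength columns per cluster."""
    H = np.asarray(H, dtype=np.float64)
    labels = np.asarray(cluster_labels)
    clusters = np.unique(labels)
    if clusters.size < 2:
        raise ValidationError("differential analysis requires at least 2 clusters")
    names = lrp_names if lrp_names is not None else [
        f"lrp_{j + 1}" for j in range(H.shape[1])]
    eps = 1e-9
    rows = []
    for c in clusters:
        inside = labels == c
        if inside.sum() < min_cluster_size:
            logger.warning("cluster %s has <%d spots; excluded", c, min_cluster_size)
            continue
        pvals = np.ones(H.shape[1])
        lfcs = np.zeros(H.shape[1])
        for j in range(H.shape[1]):
            a = H[inside, j]
            b = H[~inside, j]
            if np.ptp(np.concatenate([a, b])) == 0:
                pvals[j] = 1.0
            else:
                pvals[j] = stats.ranksums(a, b).pvalue
            lfcs[j] = np.log2((a.mean() + eps) / (b.mean() + eps))
        p_adj = multipletests(pvals, method="fdr_bh")[1]
        for j in range(H.shape[1]):
            rows.append((names[j], int(c), float(lfcs[j]), float(pvals[j]),
                         float(p_adj[j])))
    df = pd.DataFrame(rows, columns=["lrp", "cluster", "lfc", "p", "p_adj"])
    return df.sort_values(["cluster", "p_adj", "lrp"]).reset_index(drop=True)


__all__ = [
    "CCCResult", "CCCModel", "infer_lrp_strength", "ccc_contrastive_train",
    "lrp_specificity_gini", "differential_lrp",
]
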