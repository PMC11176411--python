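"""Cell-module learning: hierarchical and semantic attention encoders
trained collaboratively with a mutual InfoNCE objective.

Two per-spot representations are learned.  The *hierarchical* embedding
R1 aggregates, in a common d-space, the spot's linked genes (gene-level
attention) and its histological region, with a global view-level
attention deciding how much each node type contributes.  The *semantic*
embedding R2 runs a multi-head graph-attention encoder over each
semantic kNN graph (spatial / histological / transcriptional) and fuses
the per-graph embeddings with a learned per-spot graph attention.  The
two embeddings supervise each other: each spot's positives are its
spatial neighbors from the same histological region, all other spots
are negatives, and the symmetric InfoNCE losses are balanced by
``lambda`` at temperature ``tau``.  The final representation is the
concatenation R = R1 || R2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._autodiff import (Adam, EarlyStopper, Parameter, Tensor, concat,
                        cosine_similarity_matrix, glorot, masked_logsumexp,
                        masked_softmax)
from .datasets import EmbeddingSet, SpatialDataset, ValidationError
from .graphs import CellHeteroGraph, SemanticGraphSet, pairwise_euclidean

logger = logging.getLogger(__name__)

LEAKY_SLOPE = 0.2


# ---------------------------------------------------------------------------
# hierarchical encoder (local view: genes + region)
# ---------------------------------------------------------------------------

class HierarchicalEncoder:
    """Projects spot/gene/region encodings to a common d-space and
    aggregates them with node-level and view-level attention."""

    def __init__(self, n_latent: int, n_genes: int, n_regions: int,
                 d: int = 32, rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.d = d
        self.W_spot = glorot(rng, n_latent, d)
        self.b_spot = Parameter(np.zeros(d))
        self.W_gene = glorot(rng, n_genes, d)
        self.b_gene = Parameter(np.zeros(d))
        self.W_region = glorot(rng, n_regions, d)
        self.b_region = Parameter(np.zeros(d))
        self.a_gene = Parameter(rng.uniform(-0.1, 0.1, size=2 * d))
        self.a_region = Parameter(rng.uniform(-0.1, 0.1, size=2 * d))
        self.a_view = Parameter(rng.uniform(-0.1, 0.1, size=d))
        self.W_view = glorot(rng, d, d)
        self.b_view = Parameter(np.zeros(d))
        # view-weight override for endpoint checks; None = learned
        self.beta_override: np.ndarray | None = None

    def parameters(self) -> list[Parameter]:
        return [self.W_spot, self.b_spot, self.W_gene, self.b_gene,
                self.W_region, self.b_region, self.a_gene, self.a_region,
                self.a_view, self.W_view, self.b_view]

    def _node_attention(self, d_center: Tensor, d_nbr: Tensor,
                        mask: np.ndarray, a: Parameter) -> Tensor:
        dd = self.d
        u = d_center @ a[:dd]                    # (n,)
        v = d_nbr @ a[dd:]                       # (h,)
        n, h = mask.shape
        logits = (u.reshape(n, 1) + v.reshape(1, h)).leaky_relu(LEAKY_SLOPE)
        return masked_softmax(logits, mask, axis=1)

    def forward(self, g1: CellHeteroGraph
                ) -> tuple[Tensor, dict[str, np.ndarray]]:
        """Return R1 and the attention tables (alpha per view, beta)."""
        d_spot = (Tensor(g1.spot_encodings) @ self.W_spot.T + self.b_spot).relu()
        d_gene = (Tensor(g1.gene_encodings) @ self.W_gene.T + self.b_gene).relu()
        d_region = (Tensor(g1.region_encodings) @ self.W_region.T
                    + self.b_region).relu()

        alpha_region = self._node_attention(d_spot, d_region,
                                            g1.region_onehot.astype(bool),
                                            self.a_region)
        d_view1 = (alpha_region @ d_region).relu()
        alpha_gene = self._node_attention(d_spot, d_gene, g1.express_mask,
                                          self.a_gene)
        d_view2 = (alpha_gene @ d_gene).relu()

        if self.beta_override is not None:
            beta = Tensor(np.asarray(self.beta_override, dtype=np.float64))
        else:
            views = [d_view1, d_view2]
            w = concat([((dv @ self.W_view.T + self.b_view).tanh()
                         @ self.a_view).mean().reshape(1) for dv in views], axis=0)
            beta = masked_softmax(w, np.ones(2, dtype=bool), axis=0)
        R1 = beta[0] * d_view1 + beta[1] * d_view2
        tables = {"alpha_gene": alpha_gene.data, "alpha_region": alpha_region.data,
                  "beta": beta.data}
        return R1, tables


def hierarchical_forward(g1: CellHeteroGraph, enc: HierarchicalEncoder
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Functional wrapper: returns (R1, gene attention, view weights)."""
    R1, tables = enc.forward(g1)
    return R1.data, tables["alpha_gene"], tables["beta"]


# ---------------------------------------------------------------------------
# semantic encoder (global view: GAT per graph + fusion attention)
# ---------------------------------------------------------------------------

class GATLayer:
    """One multi-head graph-attention layer; head outputs are averaged."""

    def __init__(self, in_dim: int, out_dim: int, heads: int,
                 rng: np.random.Generator, activation: str = "elu"):
        self.heads = heads
        self.activation = activation
        self.W = [glorot(rng, in_dim, out_dim) for _ in range(heads)]
        self.a = [Parameter(rng.uniform(-0.1, 0.1, size=2 * out_dim))
                  for _ in range(heads)]
        self.out_dim = out_dim

    def parameters(self) -> list[Parameter]:
        return [*self.W, *self.a]

    def forward(self, h: Tensor, adj: np.ndarray
                ) -> tuple[Tensor, list[np.ndarray]]:
        n = adj.shape[0]
        out: Tensor | None = None
        alphas: list[np.ndarray] = []
        for q in range(self.heads):
            Wh = h @ self.W[q].T
            u = Wh @ self.a[q][:self.out_dim]
            v = Wh @ self.a[q][self.out_dim:]
            logits = (u.reshape(n, 1) + v.reshape(1, n)).leaky_relu(LEAKY_SLOPE)
            alpha = masked_softmax(logits, adj, axis=1)
            alphas.append(alpha.data)
            head = alpha @ Wh
            out = head if out is None else out + head
        out = out * (1.0 / self.heads)
        if self.activation == "elu":
            out = out.elu()
        elif self.activation == "relu":
            out = out.relu()
        elif self.activation != "linear":
            raise ValueError(f"unknown activation {self.activation!r}")
        if not np.all(np.isfinite(out.data)):
            raise FloatingPointError("NaN in graph attention layer output")
        return out, alphas


class SemanticEncoder:
    """A stack of GAT layers per semantic graph plus fusion attention."""

    def __init__(self, in_dim: int, n_graphs: int, d: int = 32,
                 n_layers: int = 2, heads: int = 2,
                 activation: str = "elu",
                 rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.d = d
        self.n_graphs = n_graphs
        self.layers: list[list[GATLayer]] = []
        for _ in range(n_graphs):
            dims = [in_dim] + [d] * n_layers
            self.layers.append([
                GATLayer(dims[l], dims[l + 1], heads, rng, activation)
                for l in range(n_layers)])
        self.fusion = Parameter(rng.uniform(-0.1, 0.1, size=(n_graphs, n_graphs * d)))

    def parameters(self) -> list[Parameter]:
        out = [self.fusion]
        for graph_layers in self.layers:
            for layer in graph_layers:
                out.extend(layer.parameters())
        return out

    def forward(self, adjacencies: list[np.ndarray], h0: np.ndarray
                ) -> tuple[Tensor, dict]:
        if len(adjacencies) != self.n_graphs:
            raise ValidationError(
                f"encoder built for {self.n_graphs} graphs, got {len(adjacencies)}")
        P: list[Tensor] = []
        all_alphas: list[list[np.ndarray]] = []
        for g, adj in enumerate(adjacencies):
            h = Tensor(np.asarray(h0, dtype=np.float64))
            layer_alphas: list[np.ndarray] = []
            for li, layer in enumerate(self.layers[g]):
                try:
                    h, alphas = layer.forward(h, adj)
                except FloatingPointError as err:
                    raise FloatingPointError(
                        f"graph {g} layer {li}: {err}") from err
                layer_alphas.extend(alphas)
            P.append(h)
            all_alphas.append(layer_alphas)
        p_concat = concat(P, axis=1)                       # n x (M*d)
        logits = p_concat @ self.fusion.T                  # n x M
        n = logits.shape[0]
        gamma = masked_softmax(logits, np.ones((n, self.n_graphs), dtype=bool),
                               axis=1)
        R2: Tensor | None = None
        for m, Pm in enumerate(P):
            term = gamma[:, m].reshape(n, 1) * Pm
            R2 = term if R2 is None else R2 + term
        tables = {"gamma": gamma.data, "P": [p.data for p in P],
                  "gat_alpha": all_alphas}
        return R2, tables


def semantic_forward(graphs: SemanticGraphSet, latent_cell: np.ndarray,
                     enc: SemanticEncoder
                     ) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Functional wrapper: returns (R2, gamma, per-graph embeddings)."""
    R2, tables = enc.forward(graphs.matrices(), latent_cell)
    return R2.data, tables["gamma"], tables["P"]


# ---------------------------------------------------------------------------
# positive / negative sampling and the contrastive objective
# ---------------------------------------------------------------------------

@dataclass
class PositiveNegativeSets:
    pos_mask: np.ndarray        # n x n bool
    neg_mask: np.ndarray        # n x n bool
    anchor_mask: np.ndarray     # n bool; False = excluded from the loss

    def __post_init__(self):
        if np.any(self.pos_mask & self.neg_mask):
            raise ValidationError("positive and negative sets overlap")
        if np.any(np.diag(self.pos_mask)) or np.any(np.diag(self.neg_mask)):
            raise ValidationError("a spot cannot be its own positive/negative")


def sample_positives_negatives(ds: SpatialDataset, graphs: SemanticGraphSet
                               ) -> PositiveNegativeSets:
    """Positives: spatial (SLG) neighbors sharing the spot's region.

    A spot whose SLG neighborhood contains no same-region spot falls back
    to its single nearest same-region spot dataset-wide; a spot whose
    region has no other member is excluded from the loss with a warning.
    Negatives are all remaining spots.
    """
    slg = graphs.adjacencies["slg"]
    n = ds.n_spots
    same_region = ds.regions[:, None] == ds.regions[None, :]
    pos = slg & same_region
    anchor = np.ones(n, dtype=bool)
    empties = np.where(pos.sum(axis=1) == 0)[0]
    if empties.size:
        dist = pairwise_euclidean(ds.coords)
        np.fill_diagonal(dist, np.inf)
        for i in empties:
            candidates = np.where(same_region[i] & (np.arange(n) != i))[0]
            if candidates.size == 0:
                logger.warning("spot %s is alone in its region; excluded from loss",
                               ds.spot_ids[i])
                anchor[i] = False
                continue
            pos[i, candidates[np.argmin(dist[i, candidates])]] = True
    neg = ~pos
    np.fill_diagonal(neg, False)
    neg[~anchor] = False
    pos[~anchor] = False
    return PositiveNegativeSets(pos_mask=pos, neg_mask=neg, anchor_mask=anchor)


@dataclass
class ContrastiveConfig:
    """Balance and temperature of the mutual InfoNCE objective."""

    lam: float = 0.5
    tau: float = 0.5

    def __post_init__(self):
        if self.tau <= 0:
            raise ValidationError(f"temperature tau must be > 0, got {self.tau}")
        if not 0.0 <= self.lam <= 1.0:
            raise ValidationError(f"lambda must be in [0, 1], got {self.lam}")


def info_nce_per_anchor(sim: Tensor, sets: PositiveNegativeSets) -> Tensor:
    """-log( sum_pos e^s / sum_(pos+neg) e^s ) per anchor row of ``sim``.

    Rows excluded from the loss (no positives) contribute exactly zero.
    """
    pos = sets.pos_mask
    both = pos | sets.neg_mask
    invalid = ~pos.any(axis=1)
    if invalid.any():
        # dummy singleton sets keep the row finite; the difference cancels
        pos = pos.copy()
        both = both.copy()
        pos[invalid, :] = False
        both[invalid, :] = False
        pos[invalid, 0] = True
        both[invalid, 0] = True
    lse_all = masked_logsumexp(sim, both, axis=1)
    lse_pos = masked_logsumexp(sim, pos, axis=1)
    return lse_all - lse_pos


def contrastive_loss(R1: Tensor | np.ndarray, R2: Tensor | np.ndarray,
                     sets: PositiveNegativeSets,
                     cfg: ContrastiveConfig = ContrastiveConfig()
                     ) -> tuple[Tensor, Tensor, Tensor]:
    """Mutual InfoNCE between the two representations.

    Returns (L_total, L_H, L_S) where L_H scores hierarchical embeddings
    of candidates against each spot's semantic anchor and L_S swaps the
    roles; each is the mean per-anchor loss over spots with at least one
    positive, and L_total = lam * L_H + (1 - lam) * L_S.
    """
    R1 = R1 if isinstance(R1, Tensor) else Tensor(R1)
    R2 = R2 if isinstance(R2, Tensor) else Tensor(R2)
    w = sets.anchor_mask.astype(np.float64)
    w = (w / w.sum()).reshape(-1, 1)
    sim_h = cosine_similarity_matrix(R2, R1) * (1.0 / cfg.tau)
    sim_s = cosine_similarity_matrix(R1, R2) * (1.0 / cfg.tau)
    L_H = (info_nce_per_anchor(sim_h, sets) * w).sum()
    L_S = (info_nce_per_anchor(sim_s, sets) * w).sum()
    L_total = cfg.lam * L_H + (1.0 - cfg.lam) * L_S
    return L_total, L_H, L_S


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

@dataclass
class CellModuleResults:
    """Fitted cell-module embeddings with attention diagnostics."""

    R1: np.ndarray
    R2: np.ndarray
    spot_ids: list[str]
    beta: np.ndarray                       # view weights (region, gene)
    gamma: np.ndarray                      # spots x graphs fusion weights
    alpha_gene: np.ndarray                 # spots x HVGs gene attention
    graph_names: list[str]
    loss_curve: list[float]
    n_epochs: int
    config: dict = field(default_factory=dict)

    @property
    def R(self) -> np.ndarray:
        return np.hstack([self.R1, self.R2])

    def embeddings(self, latent_cell: np.ndarray | None = None) -> EmbeddingSet:
        return EmbeddingSet(R1=self.R1, R2=self.R2, spot_ids=self.spot_ids,
                            latent_cell=latent_cell)

    def summary(self) -> str:
        lines = [
            "Cell-module fit",
            "=" * 46,
            f"spots: {len(self.spot_ids)}   embedding: {self.R.shape[1]}-d (R1||R2)",
            f"epochs run: {self.n_epochs}   final loss: {self.loss_curve[-1]:.6f}",
            f"view weights beta (region, gene): "
            f"({self.beta[0]:.4f}, {self.beta[1]:.4f})",
            "mean graph attention gamma:",
        ]
        for name, g in zip(self.graph_names, self.gamma.mean(axis=0)):
            lines.append(f"  {name}: {g:.4f}")
        return "\n".join(lines)


class CellModuleModel:
    """Joint trainer for the hierarchical and semantic encoders.

    Parameters
    ----------
    g1, graphs : prebuilt heterogeneous and semantic graphs.
    ds : the dataset providing region labels and coordinates for the
        positive/negative sampling.
    d : common embedding dimension (R is 2d).
    lam, tau : contrastive balance and temperature.
    alternating : if True, the two encoders are optimized on alternating
        epochs instead of jointly.
    """

    def __init__(self, ds: SpatialDataset, g1: CellHeteroGraph,
                 graphs: SemanticGraphSet, d: int = 32,
                 lam: float = 0.5, tau: float = 0.5,
                 heads: int = 2, n_layers: int = 2,
                 lr: float = 1e-3, max_epochs: int = 500,
                 min_delta: float = 1e-4, patience: int = 10,
                 alternating: bool = False):
        self.ds = ds
        self.g1 = g1
        self.graphs = graphs
        self.d = d
        self.cfg = ContrastiveConfig(lam=lam, tau=tau)
        self.heads = heads
        self.n_layers = n_layers
        self.lr = lr
        self.max_epochs = max_epochs
        self.min_delta = min_delta
        self.patience = patience
        self.alternating = alternating

    def fit(self, seed: int = 0) -> CellModuleResults:
        rng = np.random.default_rng(seed)
        hier = HierarchicalEncoder(
            n_latent=self.g1.spot_encodings.shape[1],
            n_genes=self.g1.gene_encodings.shape[0],
            n_regions=self.g1.region_encodings.shape[0],
            d=self.d, rng=rng)
        sem = SemanticEncoder(
            in_dim=self.g1.spot_encodings.shape[1],
            n_graphs=len(self.graphs.matrices()), d=self.d,
            n_layers=self.n_layers, heads=self.heads, rng=rng)
        sets = sample_positives_negatives(self.ds, self.graphs)
        adjacencies = self.graphs.matrices()
        latent = self.g1.spot_encodings

        if self.alternating:
            optimizers = [Adam(hier.parameters(), lr=self.lr),
                          Adam(sem.parameters(), lr=self.lr)]
        else:
            optimizers = [Adam(hier.parameters() + sem.parameters(), lr=self.lr)]
        stopper = EarlyStopper(min_delta=self.min_delta, patience=self.patience)
        curve: list[float] = []
        epoch = 0
        for epoch in range(self.max_epochs):
            opt = optimizers[epoch % len(optimizers)]
            opt.zero_grad()
            R1, _ = hier.forward(self.g1)
            R2, _ = sem.forward(adjacencies, latent)
            loss, _, _ = contrastive_loss(R1, R2, sets, self.cfg)
            value = float(loss.data)
            if not np.isfinite(value):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch} (lr={self.lr})")
            loss.backward()
            opt.step()
            curve.append(value)
            if stopper.update(value):
                break

        R1, hier_tables = hier.forward(self.g1)
        R2, sem_tables = sem.forward(adjacencies, latent)
        return CellModuleResults(
            R1=R1.data, R2=R2.data, spot_ids=list(self.ds.spot_ids),
            beta=hier_tables["beta"], gamma=sem_tables["gamma"],
            alpha_gene=hier_tables["alpha_gene"],
            graph_names=self.graphs.names,
            loss_curve=curve, n_epochs=epoch + 1,
            config={"d": self.d, "lam": self.cfg.lam, "tau": self.cfg.tau,
                    "heads": self.heads, "n_layers": self.n_layers,
                    "lr": self.lr, "seed": seed})


def train_cell_module(ds: SpatialDataset, g1: CellHeteroGraph,
                      graphs: SemanticGraphSet, seed: int = 0,
                      **kwargs) -> CellModuleResults:
    """Functional wrapper around :class:`CellModuleModel`."""
    return CellModuleModel(ds, g1, graphs, **kwargs).fit(seed=seed)


__all__ = [
    "HierarchicalEncoder", "SemanticEncoder", "GATLayer",
    "ContrastiveConfig", "PositiveNegativeSets",
    "hierarchical_forward", "semantic_forward",
    "sample_positives_negatives", "contrastive_loss", "info_nce_per_anchor",
    "CellModuleModel", "CellModuleResults", "train_cell_module",
]
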