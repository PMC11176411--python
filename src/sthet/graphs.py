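"""Graph construction: heterogeneous cell/gene graphs, semantic kNN graphs,
and the spatial neighborhoods used for communication inference.

All nearest-neighbor searches here are exact (full pairwise distances)
with a deterministic tie-break by ascending node index, so every
adjacency is bit-reproducible and can be checked against a brute-force
oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import InteractionKB, SpatialDataset, ValidationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# kNN primitives
# ---------------------------------------------------------------------------

def knn_from_distance(dist: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k smallest entries per row, self excluded.

    Ties are broken by ascending column index (stable sort).  Returns an
    (n, k) integer array.
    """
    n = dist.shape[0]
    if n <= k:
        raise ValidationError(f"need more than k={k} nodes, got {n}")
    d = dist.copy()
    np.fill_diagonal(d, np.inf)
    order = np.argsort(d, axis=1, kind="stable")
    return order[:, :k]


def knn_from_similarity(sim: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest entries per row, self excluded, ties by index."""
    n = sim.shape[0]
    if n <= k:
        raise ValidationError(f"need more than k={k} nodes, got {n}")
    s = sim.copy()
    np.fill_diagonal(s, -np.inf)
    order = np.argsort(-s, axis=1, kind="stable")
    return order[:, :k]


def neighbors_to_adjacency(nbrs: np.ndarray, n: int) -> np.ndarray:
    adj = np.zeros((n, n), dtype=bool)
    rows = np.repeat(np.arange(nbrs.shape[0]), nbrs.shape[1])
    adj[rows, nbrs.ravel()] = True
    return adj


def pairwise_euclidean(x: np.ndarray) -> np.ndarray:
    sq = (x ** 2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
    return np.sqrt(np.maximum(d2, 0.0))


def pairwise_cosine(x: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    norms = np.sqrt((x ** 2).sum(axis=1, keepdims=True))
    xn = x / np.maximum(norms, eps)
    return xn @ xn.T


# ---------------------------------------------------------------------------
# cell-centered heterogeneous graph
# ---------------------------------------------------------------------------

@dataclass
class CellHeteroGraph:
    """Spot-centered graph with 'express' (spot->gene) and 'belongs to'
    (spot->region) relations, plus per-node-type encodings."""

    express_mask: np.ndarray        # spots x HVGs, bool
    region_onehot: np.ndarray       # spots x K
    spot_encodings: np.ndarray      # spots x latent dim
    gene_encodings: np.ndarray      # HVGs x HVGs (one-hot)
    region_encodings: np.ndarray    # K x K (one-hot)
    hvgs: list[str]
    m: int

    def __post_init__(self):
        degrees = self.express_mask.sum(axis=1)
        if np.any(degrees == 0):
            raise ValidationError("spot with zero express edges")
        if not np.all(self.region_onehot.sum(axis=1) == 1):
            raise ValidationError("each spot must belong to exactly one region")


def build_cell_hetero_graph(ds: SpatialDataset, latent_cell: np.ndarray,
                            hvgs: list[str] | None = None, m: int = 30
                            ) -> CellHeteroGraph:
    """Link each spot to the top-m HVGs by expression-to-mean ratio.

    The ranking score for gene j in spot i is the normalized expression
    x_ij divided by gene j's mean expression over all spots; genes with
    zero expression in the spot are never linked, and ties at the m-th
    rank go to the lower gene index.
    """
    hvgs = hvgs if hvgs is not None else ds.hvgs
    if hvgs is None:
        raise ValidationError("no HVG list available")
    if m < 1:
        raise ValidationError("m must be >= 1")
    if m > len(hvgs):
        logger.warning("m=%d clipped to %d HVGs", m, len(hvgs))
        m = len(hvgs)
    gene_index = {g: i for i, g in enumerate(ds.gene_ids)}
    cols = np.array([gene_index[g] for g in hvgs])
    expr = ds.normalized_matrix()[:, cols]       # spots x HVGs
    gene_mean = expr.mean(axis=0)
    ratio = expr / np.where(gene_mean == 0, 1.0, gene_mean)[None, :]
    ratio = np.where(expr > 0, ratio, -np.inf)

    order = np.argsort(-ratio, axis=1, kind="stable")
    n = ds.n_spots
    mask = np.zeros((n, len(hvgs)), dtype=bool)
    for i in range(n):
        top = order[i, :m]
        top = top[np.isfinite(ratio[i, top])]
        mask[i, top] = True

    K = ds.n_regions
    region_onehot = np.eye(K)[ds.regions - 1]
    return CellHeteroGraph(express_mask=mask, region_onehot=region_onehot,
                           spot_encodings=np.asarray(latent_cell, dtype=np.float64),
                           gene_encodings=np.eye(len(hvgs)),
                           region_encodings=np.eye(K), hvgs=list(hvgs), m=m)


# ---------------------------------------------------------------------------
# semantic kNN graphs
# ---------------------------------------------------------------------------

@dataclass
class SemanticGraphSet:
    """Spatial (SLG), histological (HSG) and transcriptional (TSG) kNN graphs
    over the same spots; HSG is absent when no histology features exist."""

    adjacencies: dict[str, np.ndarray]  # name -> spots x spots bool
    k: int

    @property
    def names(self) -> list[str]:
        return list(self.adjacencies)

    def matrices(self) -> list[np.ndarray]:
        return [self.adjacencies[n] for n in self.adjacencies]

    def __post_init__(self):
        for name, adj in self.adjacencies.items():
            if np.any(np.diag(adj)):
                raise ValidationError(f"{name} has self-edges")
            if not np.all(adj.sum(axis=1) == self.k):
                raise ValidationError(f"{name} row degree != {self.k}")


def build_semantic_graphs(ds: SpatialDataset, latent_cell: np.ndarray,
                          k: int = 6) -> SemanticGraphSet:
    """Six-nearest-neighbor graphs from location (Euclidean), histology and
    transcription (cosine on the spot encodings)."""
    n = ds.n_spots
    if n <= k:
        raise ValidationError(f"{n} spots <= k={k}; use a smaller k")
    adj: dict[str, np.ndarray] = {}
    slg_nbrs = knn_from_distance(pairwise_euclidean(ds.coords), k)
    adj["slg"] = neighbors_to_adjacency(slg_nbrs, n)
    if ds.histo_features is not None:
        hsg_nbrs = knn_from_similarity(pairwise_cosine(ds.histo_features), k)
        adj["hsg"] = neighbors_to_adjacency(hsg_nbrs, n)
    else:
        logger.info("no histology features: semantic set has 2 graphs")
    tsg_nbrs = knn_from_similarity(pairwise_cosine(np.asarray(latent_cell)), k)
    adj["tsg"] = neighbors_to_adjacency(tsg_nbrs, n)
    return SemanticGraphSet(adjacencies=adj, k=k)


# ---------------------------------------------------------------------------
# gene-centered heterogeneous graph
# ---------------------------------------------------------------------------

@dataclass
class GeneHeteroGraph:
    """Gene-centered graph: 'expressed by' (gene->spot) and 'over-expressed
    by' (gene->cell-state) relations over SVG candidate genes."""

    candidate_genes: list[str]
    expressed_by_mask: np.ndarray    # candidates x spots, bool
    state_mask: np.ndarray           # candidates x states, bool
    spot_encodings: np.ndarray
    gene_encodings: np.ndarray       # candidates x candidates one-hot
    state_encodings: np.ndarray      # states x states one-hot
    states: list[int]

    def __post_init__(self):
        if np.any(self.expressed_by_mask.sum(axis=1) == 0):
            raise ValidationError("candidate gene with zero expressed_by edges")


def build_gene_hetero_graph(ds: SpatialDataset, latent_cell: np.ndarray,
                            svg_table: pd.DataFrame, m: int = 30
                            ) -> GeneHeteroGraph:
    """Candidates are the union of all states' SVGs; each links to its top-m
    expressing spots (the express rule transposed) and to every state that
    called it an SVG."""
    if svg_table.empty:
        raise ValidationError("no candidate genes: SVG table is empty")
    candidates = sorted(svg_table["gene"].unique(),
                        key=lambda g: ds.gene_ids.index(g))
    states = sorted(int(c) for c in svg_table["cluster"].unique())
    state_pos = {s: i for i, s in enumerate(states)}
    gene_index = {g: i for i, g in enumerate(ds.gene_ids)}
    cols = np.array([gene_index[g] for g in candidates])
    expr = ds.normalized_matrix()[:, cols]    # spots x candidates
    n_spots = ds.n_spots
    m_eff = min(m, n_spots)

    scored = np.where(expr > 0, expr, -np.inf).T     # candidates x spots
    order = np.argsort(-scored, axis=1, kind="stable")
    expressed_by = np.zeros((len(candidates), n_spots), dtype=bool)
    for gi in range(len(candidates)):
        top = order[gi, :m_eff]
        top = top[np.isfinite(scored[gi, top])]
        expressed_by[gi, top] = True

    state_mask = np.zeros((len(candidates), len(states)), dtype=bool)
    cand_pos = {g: i for i, g in enumerate(candidates)}
    for _, row in svg_table.iterrows():
        state_mask[cand_pos[row["gene"]], state_pos[int(row["cluster"])]] = True
    empty_states = [s for s in states if not state_mask[:, state_pos[s]].any()]
    if empty_states:
        logger.warning("states with zero SVGs kept as isolated nodes: %s", empty_states)
    return GeneHeteroGraph(candidate_genes=candidates,
                           expressed_by_mask=expressed_by,
                           state_mask=state_mask,
                           spot_encodings=np.asarray(latent_cell, dtype=np.float64),
                           gene_encodings=np.eye(len(candidates)),
                           state_encodings=np.eye(len(states)),
                           states=states)


# ---------------------------------------------------------------------------
# per-LRP spatial neighborhoods
# ---------------------------------------------------------------------------

@dataclass
class RetainedLRP:
    index: int          # 1-based index in the KB list (stable across a run)
    ligand: str
    receptor: str
    ligand_col: int     # column in the dataset gene axis
    receptor_col: int


@dataclass
class LRPNeighborGraph:
    """Spatial K-nearest-neighbor sets, shared by all retained LRPs."""

    neighbors: np.ndarray            # spots x K int
    retained: list[RetainedLRP]
    skipped: list[tuple[str, str]] = field(default_factory=list)

    @property
    def K(self) -> int:
        return self.neighbors.shape[1]

    @property
    def M(self) -> int:
        return len(self.retained)


def build_lrp_graphs(ds: SpatialDataset, kb: InteractionKB, K: int = 6
                     ) -> LRPNeighborGraph:
    """Retain LRPs whose ligand and receptor both occur in the dataset and
    attach the shared spatial K-nearest-neighbor sets."""
    gene_index = {g: i for i, g in enumerate(ds.gene_ids)}
    retained: list[RetainedLRP] = []
    skipped: list[tuple[str, str]] = []
    for idx, (lig, rec) in enumerate(kb.lrp, start=1):
        if lig in gene_index and rec in gene_index:
            retained.append(RetainedLRP(index=idx, ligand=lig, receptor=rec,
                                        ligand_col=gene_index[lig],
                                        receptor_col=gene_index[rec]))
        else:
            skipped.append((lig, rec))
    if skipped:
        logger.info("skipped %d LRPs with genes absent from dataset: %s",
                    len(skipped), skipped)
    if not retained:
        raise ValidationError("no ligand-receptor pair has both genes in the dataset")
    nbrs = knn_from_distance(pairwise_euclidean(ds.coords), K)
    return LRPNeighborGraph(neighbors=nbrs, retained=retained, skipped=skipped)


def write_edge_list(graph: CellHeteroGraph, ds: SpatialDataset,
                    path: str | Path) -> None:
    """Serialize a cell heterogeneous graph as (type, id, type, id) TSV rows."""
    rows = []
    for i, spot in enumerate(ds.spot_ids):
        for j in np.where(graph.express_mask[i])[0]:
            rows.append(("spot", spot, "gene", graph.hvgs[j]))
        region = int(np.argmax(graph.region_onehot[i]) + 1)
        rows.append(("spot", spot, "region", str(region)))
    pd.DataFrame(rows, columns=["src_type", "src_id", "dst_type", "dst_id"]).to_csv(
        path, sep="\t", index=False)


__all__ = [
    "CellHeteroGraph", "SemanticGraphSet", "GeneHeteroGraph",
    "LRPNeighborGraph", "RetainedLRP",
    "build_cell_hetero_graph", "build_semantic_graphs",
    "build_gene_hetero_graph", "build_lrp_graphs",
    "knn_from_distance", "knn_from_similarity", "neighbors_to_adjacency",
    "pairwise_euclidean", "pairwise_cosine", "write_edge_list",
]
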