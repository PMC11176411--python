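"""Clustering, evaluation metrics, and denoising on learned embeddings.

Spot and gene embeddings are clustered the conventional way for this
field: a k-nearest-neighbor graph is reweighted by shared-neighbor
(Jaccard) overlap and communities are found with the Louvain algorithm.
Clusterings are scored with the average silhouette width on Euclidean
distances, SW(i) = (c(i) - d(i)) / max{c(i), d(i)}, where d(i) is the
mean distance to the spot's own cluster and c(i) the mean distance to
the nearest other cluster.
"""

from __future__ import annotations

import logging
import random as _random
from dataclasses import dataclass

import igraph as ig
import numpy as np
from scipy import stats
from sklearn.neighbors import NearestNeighbors

from .datasets import SpatialDataset, ValidationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# shared-nearest-neighbor Louvain clustering
# ---------------------------------------------------------------------------

def snn_graph(X: np.ndarray, k: int = 20, prune: float = 1 / 15
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """kNN graph with Jaccard shared-neighbor weights, pruned below ``prune``.

    Returns (sources, targets, weights) for edges with source < target.
    Each point's neighbor set includes itself, as is conventional.
    """
    n = X.shape[0]
    k = min(k, n)
    nn = NearestNeighbors(n_neighbors=k).fit(X)
    _, idx = nn.kneighbors(X)
    member = np.zeros((n, n), dtype=bool)
    rows = np.repeat(np.arange(n), k)
    member[rows, idx.ravel()] = True
    member[np.arange(n), np.arange(n)] = True
    shared = member.astype(np.float64) @ member.T.astype(np.float64)
    sizes = member.sum(axis=1).astype(np.float64)
    union = sizes[:, None] + sizes[None, :] - shared
    jaccard = shared / union
    # edges only between kNN-linked pairs
    linked = member | member.T
    np.fill_diagonal(linked, False)
    src, dst = np.where(np.triu(linked, 1))
    w = jaccard[src, dst]
    keep = w >= prune
    return src[keep], dst[keep], w[keep]


def _louvain(src: np.ndarray, dst: np.ndarray, w: np.ndarray, n: int,
             resolution: float, seed: int) -> np.ndarray:
    g = ig.Graph(n=n, edges=list(zip(src.tolist(), dst.tolist())))
    state = _random.getstate()
    try:
        _random.seed(seed)
        ig.set_random_number_generator(_random)
        part = g.community_multilevel(weights=w.tolist(), resolution=resolution)
    finally:
        _random.setstate(state)
    labels = np.asarray(part.membership)
    # relabel to 1..C in order of first appearance, for determinism
    remap: dict[int, int] = {}
    out = np.empty(n, dtype=np.int64)
    for i, lab in enumerate(labels):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        out[i] = remap[lab]
    return out


def cluster_spots(R: np.ndarray, resolution: float = 0.8, k: int = 20,
                  seed: int = 0, target_clusters: int | None = None
                  ) -> np.ndarray:
    """Louvain communities on the SNN graph of embedding rows; labels 1..C.

    With ``target_clusters`` set, the resolution is chosen by bisection so
    the community count matches the target (the usual practice when the
    number of annotated regions is known); ``resolution`` is then ignored.
    """
    R = np.ascontiguousarray(R, dtype=np.float64)
    if not np.all(np.isfinite(R)):
        raise ValidationError("non-finite entries in embedding")
    n = R.shape[0]
    if n < k:
        logger.warning("k=%d clipped to n=%d", k, n)
        k = n
    src, dst, w = snn_graph(R, k=k)
    if target_clusters is None:
        return _louvain(src, dst, w, n, resolution, seed)

    def labels_at(res: float) -> np.ndarray:
        return _louvain(src, dst, w, n, res, seed)

    lo, hi = 1e-4, 2.0
    lab_hi = labels_at(hi)
    while lab_hi.max() < target_clusters and hi < 64:
        hi *= 2
        lab_hi = labels_at(hi)
    best = lab_hi
    for _ in range(25):
        mid = 0.5 * (lo + hi)
        lab = labels_at(mid)
        c = lab.max()
        if c == target_clusters:
            return lab
        if abs(c - target_clusters) < abs(best.max() - target_clusters):
            best = lab
        if c < target_clusters:
            lo = mid
        else:
            hi = mid
    logger.warning("no resolution yielded exactly %d clusters; returning %d",
                   target_clusters, best.max())
    return best


# ---------------------------------------------------------------------------
# silhouette (average silhouette width)
# ---------------------------------------------------------------------------

@dataclass
class SilhouetteReport:
    sw: np.ndarray          # per-spot silhouette width
    d_own: np.ndarray       # mean distance to own cluster
    c_nearest: np.ndarray   # mean distance to nearest other cluster
    asw: float


def silhouette(R: np.ndarray, labels: np.ndarray) -> SilhouetteReport:
    """Silhouette widths on Euclidean distances in the embedding.

    Degenerate cases follow the usual conventions: spots in singleton
    clusters get SW = 0, and coincident points split across clusters
    (d = c = 0) also score 0.
    """
    # C-contiguity pins the BLAS summation order, so results match to the
    # last bit whether the embedding comes from memory or from a TSV
    R = np.ascontiguousarray(R, dtype=np.float64)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValidationError("silhouette requires at least 2 clusters")
    n = R.shape[0]
    sq = (R ** 2).sum(axis=1)
    dist = np.sqrt(np.maximum(sq[:, None] + sq[None, :] - 2 * R @ R.T, 0.0))
    sw = np.zeros(n)
    d_own = np.zeros(n)
    c_near = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        n_own = own.sum() - 1
        if n_own == 0:
            sw[i] = 0.0
            c_near[i] = np.nan
            continue
        d_own[i] = dist[i, own].sum() / n_own
        c_near[i] = min(dist[i, labels == c].mean() for c in uniq if c != labels[i])
        denom = max(c_near[i], d_own[i])
        sw[i] = 0.0 if denom == 0 else (c_near[i] - d_own[i]) / denom
    return SilhouetteReport(sw=sw, d_own=d_own, c_nearest=c_near,
                            asw=float(sw.mean()))


# ---------------------------------------------------------------------------
# denoising
# ---------------------------------------------------------------------------

def knn_smooth(ds: SpatialDataset, R: np.ndarray, k: int = 3,
               space: str = "embedding") -> np.ndarray:
    """Average each spot's normalized expression with its k nearest
    neighbors (plus itself) in embedding or physical space."""
    X = ds.normalized_matrix()
    n = X.shape[0]
    if k >= n:
        raise ValidationError(f"k={k} must be smaller than n={n}")
    if space == "embedding":
        feats = np.asarray(R, dtype=np.float64)
    elif space == "physical":
        feats = ds.coords
    else:
        raise ValueError(f"unknown space {space!r}")
    from .graphs import knn_from_distance, pairwise_euclidean
    nbrs = knn_from_distance(pairwise_euclidean(feats), k)
    idx = np.hstack([np.arange(n)[:, None], nbrs])   # self + k neighbors
    return X[idx].mean(axis=1)


# ---------------------------------------------------------------------------
# module pair distance test
# ---------------------------------------------------------------------------

@dataclass
class DistanceTestReport:
    statistic: float
    pvalue: float
    module_distances: np.ndarray
    random_distances: np.ndarray


def module_distance_test(G: np.ndarray, gene_ids: list[str],
                         module_pairs: list[tuple[str, str]],
                         n_random: int = 1000, seed: int = 0,
                         alternative: str = "less") -> DistanceTestReport:
    """Wilcoxon rank-sum comparing embedding distances of known-module gene
    pairs against random candidate pairs.

    ``alternative='less'`` tests whether module pairs sit closer than
    random pairs (the expected direction when the embedding respects the
    priors).  Random pairs are sampled without replacement when possible,
    with replacement (flagged) otherwise.
    """
    G = np.asarray(G, dtype=np.float64)
    pos = {g: i for i, g in enumerate(gene_ids)}
    pairs = [(pos[a], pos[b]) for a, b in module_pairs if a in pos and b in pos]
    if not pairs:
        raise ValidationError("no module pair maps into the embedding")
    mod_d = np.array([np.linalg.norm(G[a] - G[b]) for a, b in pairs])

    rng = np.random.default_rng(seed)
    n = G.shape[0]
    n_possible = n * (n - 1) // 2
    replace = n_random > n_possible
    if replace:
        logger.warning("n_random=%d exceeds available pairs; sampling with "
                       "replacement", n_random)
    seen: set[tuple[int, int]] = set()
    rand_pairs: list[tuple[int, int]] = []
    while len(rand_pairs) < n_random:
        a, b = rng.integers(n), rng.integers(n)
        if a == b:
            continue
        key = (min(a, b), max(a, b))
        if not replace and key in seen:
            continue
        seen.add(key)
        rand_pairs.append(key)
    rand_d = np.array([np.linalg.norm(G[a] - G[b]) for a, b in rand_pairs])
    stat, p = stats.ranksums(mod_d, rand_d, alternative=alternative)
    return DistanceTestReport(statistic=float(stat), pvalue=float(p),
                              module_distances=mod_d, random_distances=rand_d)


__all__ = [
    "snn_graph", "cluster_spots", "silhouette", "SilhouetteReport",
    "knn_smooth", "module_distance_test", "DistanceTestReport",
]
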