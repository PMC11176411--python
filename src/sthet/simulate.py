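"""Synthetic multimodal SRT fixtures with planted ground truth.

The generator emulates the statistical structure the learning modules
assume: a spot grid partitioned into spatially contiguous expression
domains, per-domain gene programs with a marker fold-change, a
negative-binomial count law with multiplicative dropout, per-domain
histology feature shifts, an interaction knowledge base with planted
within-module edges plus an equal number of cross-module decoys, and
ligand-receptor pairs whose ligand decays spatially from a sender
domain toward a receiver domain.  Every planted quantity is recorded in
:class:`GroundTruth` so recovery can be scored without external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datasets import InteractionKB, SpatialDataset


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe the standard fixture: a 20 x 15 grid (300 spots),
    3 domains, 200 genes of which each domain owns a 20-gene program at
    fold-change 5 over a baseline negative-binomial rate of 0.3 (chosen
    so the zero fraction matches typical spot-level data) with
    dispersion 0.5 and 10% dropout.
    """

    grid_shape: tuple[int, int] = (20, 15)   # columns x rows
    n_domains: int = 3
    n_genes: int = 200
    genes_per_program: int = 20
    baseline_rate: float = 0.3
    marker_fold_change: float = 5.0
    dispersion: float = 0.5
    dropout_rate: float = 0.1
    histo_dim: int = 10
    histo_shift: float = 2.0
    histo_noise: float = 1.0
    n_planted_lrps: int = 1
    n_decoy_lrps: int = 1
    lrp_amplitude: float = 5.0
    lrp_gradient_width: float = 3.0
    scattered_islands: bool = False
    seed: int = 1

    def __post_init__(self):
        for name in ("baseline_rate", "marker_fold_change", "dropout_rate",
                     "dispersion", "lrp_amplitude", "lrp_gradient_width"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.grid_shape[0] < self.n_domains:
            raise ValueError(
                f"grid with {self.grid_shape[0]} columns cannot hold "
                f"{self.n_domains} contiguous domains")
        n_lrp_genes = 2 * (self.n_planted_lrps + self.n_decoy_lrps)
        if self.n_genes < self.n_domains * self.genes_per_program + n_lrp_genes:
            raise ValueError("n_genes too small for the requested programs and LRPs")


@dataclass
class LRPTruth:
    index: int            # 1-based position in the KB LRP list
    ligand: str
    receptor: str
    kind: str             # "planted" or "decoy"
    sender_domain: int | None = None
    receiver_domain: int | None = None


@dataclass
class GroundTruth:
    """Everything the generator planted, for scoring recovery."""

    domains: np.ndarray                       # per-spot program label, 1..D
    modules: dict[int, list[str]]             # program id -> gene ids
    planted_ppi: list[tuple[str, str]]
    decoy_ppi: list[tuple[str, str]]
    planted_grn: list[tuple[str, str]]
    decoy_grn: list[tuple[str, str]]
    lrps: list[LRPTruth]
    sender_centroids: dict[int, tuple[float, float]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "domains": self.domains.tolist(),
            "modules": {str(k): v for k, v in self.modules.items()},
            "planted_ppi": self.planted_ppi,
            "decoy_ppi": self.decoy_ppi,
            "planted_grn": self.planted_grn,
            "decoy_grn": self.decoy_grn,
            "lrps": [vars(l) for l in self.lrps],
            "sender_centroids": {str(k): list(v) for k, v in self.sender_centroids.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _negative_binomial(rng: np.random.Generator, mean: np.ndarray,
                       dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with Var = mu + dispersion * mu^2."""
    if dispersion == 0:
        return rng.poisson(mean).astype(np.float64)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam).astype(np.float64)


def simulate_dataset(cfg: SimConfig) -> tuple[SpatialDataset, InteractionKB, GroundTruth]:
    """Generate one dataset, its knowledge base, and the planted truth."""
    rng = np.random.default_rng(cfg.seed)
    cols, rows = cfg.grid_shape
    n_spots = cols * rows
    xs, ys = np.meshgrid(np.arange(cols), np.arange(rows), indexing="ij")
    coords = np.column_stack([xs.ravel(), ys.ravel()]).astype(np.float64)
    spot_ids = [f"spot_{i:04d}" for i in range(n_spots)]

    # contiguous vertical strips of columns per domain
    edges = np.linspace(0, cols, cfg.n_domains + 1)
    domains = np.digitize(coords[:, 0], edges[1:-1]) + 1  # 1..D
    regions = domains.copy()
    if cfg.scattered_islands:
        # split domain 1 spatially: its right half keeps the same expression
        # program but becomes a separate histological region
        d1_cols = coords[domains == 1][:, 0]
        mid = np.median(d1_cols)
        island = (domains == 1) & (coords[:, 0] > mid)
        regions = regions.copy()
        regions[island] = cfg.n_domains + 1

    # gene roster: program genes, then LRP genes, then background
    gene_ids: list[str] = []
    modules: dict[int, list[str]] = {}
    for d in range(1, cfg.n_domains + 1):
        members = [f"prog{d}_g{j:02d}" for j in range(cfg.genes_per_program)]
        modules[d] = members
        gene_ids.extend(members)
    lrp_truths: list[LRPTruth] = []
    lrp_gene_ids: list[str] = []
    for k in range(cfg.n_planted_lrps):
        lrp_gene_ids.extend([f"LIG{k + 1}", f"REC{k + 1}"])
    for k in range(cfg.n_decoy_lrps):
        lrp_gene_ids.extend([f"DLIG{k + 1}", f"DREC{k + 1}"])
    gene_ids.extend(lrp_gene_ids)
    n_bg = cfg.n_genes - len(gene_ids)
    gene_ids.extend(f"bg_g{j:03d}" for j in range(n_bg))

    # mean matrix, genes x spots
    mean = np.full((cfg.n_genes, n_spots), cfg.baseline_rate)
    gidx = {g: i for i, g in enumerate(gene_ids)}
    for d, members in modules.items():
        in_domain = domains == d
        for g in members:
            mean[gidx[g], in_domain] = cfg.baseline_rate * cfg.marker_fold_change

    sender_centroids: dict[int, tuple[float, float]] = {}
    kb_lrps: list[tuple[str, str]] = []
    floor = 0.05
    for k in range(cfg.n_planted_lrps):
        sender = 1 + k % cfg.n_domains
        receiver = 1 + (k + 1) % cfg.n_domains
        lig, rec = f"LIG{k + 1}", f"REC{k + 1}"
        centroid = coords[domains == sender].mean(axis=0)
        sender_centroids[sender] = (float(centroid[0]), float(centroid[1]))
        dist = np.linalg.norm(coords - centroid, axis=1)
        mean[gidx[lig]] = floor + cfg.lrp_amplitude * np.exp(
            -dist ** 2 / (2 * cfg.lrp_gradient_width ** 2))
        mean[gidx[rec]] = np.where(domains == receiver, cfg.lrp_amplitude, floor)
        kb_lrps.append((lig, rec))
        lrp_truths.append(LRPTruth(index=len(kb_lrps), ligand=lig, receptor=rec,
                                   kind="planted", sender_domain=sender,
                                   receiver_domain=receiver))
    for k in range(cfg.n_decoy_lrps):
        lig, rec = f"DLIG{k + 1}", f"DREC{k + 1}"
        mean[gidx[lig]] = 0.5 * cfg.lrp_amplitude
        mean[gidx[rec]] = 0.5 * cfg.lrp_amplitude
        kb_lrps.append((lig, rec))
        lrp_truths.append(LRPTruth(index=len(kb_lrps), ligand=lig, receptor=rec,
                                   kind="decoy"))

    counts = _negative_binomial(rng, mean, cfg.dispersion)
    if cfg.dropout_rate > 0:
        keep = rng.random(counts.shape) >= cfg.dropout_rate
        counts = counts * keep

    # histology features: per-region mean shift plus isotropic noise
    histo_means = rng.normal(size=(int(regions.max()), cfg.histo_dim))
    histo_means *= cfg.histo_shift / np.linalg.norm(histo_means, axis=1, keepdims=True)
    histo = histo_means[regions - 1] + cfg.histo_noise * rng.normal(
        size=(n_spots, cfg.histo_dim))

    # knowledge base: chain + random edges inside each module, 1:1 decoys across
    planted_ppi: list[tuple[str, str]] = []
    planted_grn: list[tuple[str, str]] = []
    for d, members in modules.items():
        for a, b in zip(members[:-1], members[1:]):
            planted_ppi.append((a, b))
        regulator = members[0]
        for target in members[1:]:
            planted_grn.append((regulator, target))

    def _cross_module_pairs(n_pairs: int) -> list[tuple[str, str]]:
        pairs: list[tuple[str, str]] = []
        seen: set[tuple[str, str]] = set()
        all_modules = list(modules)
        while len(pairs) < n_pairs:
            d1, d2 = rng.choice(all_modules, size=2, replace=False)
            a = modules[d1][rng.integers(len(modules[d1]))]
            b = modules[d2][rng.integers(len(modules[d2]))]
            if (a, b) not in seen and (b, a) not in seen:
                seen.add((a, b))
                pairs.append((a, b))
        return pairs

    decoy_ppi = _cross_module_pairs(len(planted_ppi))
    decoy_grn = _cross_module_pairs(len(planted_grn))

    ds = SpatialDataset(counts=counts, gene_ids=gene_ids, spot_ids=spot_ids,
                        coords=coords, regions=regions, histo_features=histo)
    kb = InteractionKB(
        ppi={frozenset(p) for p in planted_ppi + decoy_ppi},
        grn=set(planted_grn + decoy_grn),
        lrp=kb_lrps)
    gt = GroundTruth(domains=domains, modules=modules,
                     planted_ppi=planted_ppi, decoy_ppi=decoy_ppi,
                     planted_grn=planted_grn, decoy_grn=decoy_grn,
                     lrps=lrp_truths, sender_centroids=sender_centroids)
    return ds, kb, gt


def receiver_border_interior(ds: SpatialDataset, gt: GroundTruth, lrp: LRPTruth,
                             border_width: float = 2.0, interior_min: float = 4.0
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Split receiver-domain spots into border (near the sender) and interior.

    Border spots lie within ``border_width`` of the closest sender-domain
    spot; interior spots lie at least ``interior_min`` away.
    """
    if lrp.kind != "planted":
        raise ValueError("border/interior split is defined for planted LRPs only")
    sender_xy = ds.coords[gt.domains == lrp.sender_domain]
    receiver = np.where(gt.domains == lrp.receiver_domain)[0]
    d_to_sender = np.array([
        np.min(np.linalg.norm(sender_xy - ds.coords[i], axis=1)) for i in receiver])
    border = receiver[d_to_sender <= border_width]
    interior = receiver[d_to_sender >= interior_min]
    return border, interior


__all__ = ["SimConfig", "GroundTruth", "LRPTruth", "simulate_dataset",
           "receiver_border_interior"]
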