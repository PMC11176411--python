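"""Expression preprocessing: library normalization, HVG selection, spot encoding.

Counts are scaled per spot to the median library size and log1p
transformed; highly variable genes are ranked by a variance-stabilizing
dispersion (variance of the standardized, clipped log values, in the
spirit of the common 'vst' selection).  Spots are then summarized by a
50-dimensional bottleneck of a symmetric autoencoder trained to
reconstruct the normalized HVG matrix under mean-squared error.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np

from ._autodiff import Adam, EarlyStopper, Parameter, Tensor, glorot
from .datasets import SpatialDataset, ValidationError

logger = logging.getLogger(__name__)


def normalize_and_select_hvgs(ds: SpatialDataset, n_hvg: int = 3000
                              ) -> tuple[SpatialDataset, list[str]]:
    """Normalize counts per spot and rank highly variable genes.

    Returns a new dataset carrying ``normalized`` (spots x genes log1p
    matrix) and ``hvgs`` (gene ids, most variable first), and the HVG
    list itself.  ``n_hvg`` is clipped to the gene count with a warning.
    """
    counts = ds.counts  # genes x spots
    totals = counts.sum(axis=0)
    zero = np.where(totals == 0)[0]
    if zero.size:
        ids = [ds.spot_ids[i] for i in zero]
        raise ValidationError(f"all-zero spots cannot be normalized: {ids}")
    target = np.median(totals)
    scaled = counts * (target / totals)[None, :]
    lognorm = np.log1p(scaled)  # genes x spots

    # variance-stabilizing dispersion: standardize raw counts by the SD a
    # gene of that mean is *expected* to have (log-log polynomial trend over
    # genes), clip at sqrt(n), and rank by the variance of the standardized
    # values -- genes above the mean-variance trend rank first
    n = counts.shape[1]
    mu = counts.mean(axis=1)
    var = counts.var(axis=1, ddof=1) if n > 1 else np.zeros_like(mu)
    informative = (mu > 0) & (var > 0)
    exp_var = var.copy()
    if informative.sum() >= 2:
        deg = min(2, informative.sum() - 1)
        coef = np.polyfit(np.log10(mu[informative]),
                          np.log10(var[informative]), deg)
        exp_var = np.where(mu > 0, 10 ** np.polyval(coef, np.log10(
            np.where(mu > 0, mu, 1.0))), 1.0)
    sd_exp = np.sqrt(np.maximum(exp_var, 1e-12))
    z = (counts - mu[:, None]) / sd_exp[:, None]
    z = np.clip(z, -np.sqrt(n), np.sqrt(n))
    dispersion = z.var(axis=1, ddof=1) if n > 1 else z.var(axis=1)
    dispersion = np.where(var > 0, dispersion, 0.0)

    if n_hvg > ds.n_genes:
        logger.warning("n_hvg=%d clipped to %d genes", n_hvg, ds.n_genes)
        n_hvg = ds.n_genes
    order = np.lexsort((np.arange(ds.n_genes), -dispersion))
    hvgs = [ds.gene_ids[i] for i in order[:n_hvg]]

    out = replace(ds, normalized=lognorm.T.copy(), hvgs=hvgs)
    return out, hvgs


class Autoencoder:
    """Two-hidden-layer symmetric autoencoder with an MSE reconstruction loss."""

    def __init__(self, n_features: int, latent: int = 50, hidden: int = 128,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.W1 = glorot(rng, n_features, hidden)
        self.b1 = Parameter(np.zeros(hidden))
        self.W2 = glorot(rng, hidden, latent)
        self.b2 = Parameter(np.zeros(latent))
        self.W3 = glorot(rng, latent, hidden)
        self.b3 = Parameter(np.zeros(hidden))
        self.W4 = glorot(rng, hidden, n_features)
        self.b4 = Parameter(np.zeros(n_features))

    def parameters(self) -> list[Parameter]:
        return [self.W1, self.b1, self.W2, self.b2,
                self.W3, self.b3, self.W4, self.b4]

    def encode(self, x: Tensor) -> Tensor:
        h = (x @ self.W1.T + self.b1).relu()
        return h @ self.W2.T + self.b2

    def decode(self, z: Tensor) -> Tensor:
        h = (z @ self.W3.T + self.b3).relu()
        return h @ self.W4.T + self.b4

    def loss(self, x: Tensor) -> Tensor:
        recon = self.decode(self.encode(x))
        diff = recon - x
        return (diff * diff).mean()


def encode_cells(ds: SpatialDataset, dim: int = 50, seed: int = 0,
                 hidden: int = 128, lr: float = 1e-3, max_epochs: int = 300,
                 min_delta: float = 1e-4, patience: int = 10) -> np.ndarray:
    """Train the spot autoencoder and return spots x ``dim`` encodings.

    Deterministic given ``seed``: identical inputs and seed reproduce the
    encodings bit for bit.
    """
    if ds.n_spots < dim:
        raise ValidationError(
            f"{ds.n_spots} spots < latent dim {dim}; use a smaller dim")
    X = ds.normalized_matrix()
    if ds.hvgs is not None:
        X = X[:, ds.hvg_indices()]
    Xt = Tensor(X)
    model = Autoencoder(X.shape[1], latent=dim, hidden=hidden, seed=seed)
    opt = Adam(model.parameters(), lr=lr)
    stopper = EarlyStopper(min_delta=min_delta, patience=patience)
    for epoch in range(max_epochs):
        opt.zero_grad()
        loss = model.loss(Xt)
        loss.backward()
        opt.step()
        if stopper.update(float(loss.data)):
            logger.debug("autoencoder early stop at epoch %d", epoch)
            break
    return model.encode(Tensor(X)).data


__all__ = ["normalize_and_select_hvgs", "encode_cells", "Autoencoder"]
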