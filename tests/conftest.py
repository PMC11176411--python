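"""Shared fixtures: the standard synthetic study and its fitted models.

Everything is generated programmatically; the expensive fits are
session-scoped so recovery tests across modules reuse one training run.
"""

from __future__ import annotations

import numpy as np
import pytest

import sthet as st
from sthet.cell import sample_positives_negatives
from sthet.datasets import SpatialDataset
from sthet.simulate import SimConfig, simulate_dataset


def make_dataset(X: np.ndarray, coords: np.ndarray | None = None,
                 regions: np.ndarray | None = None,
                 gene_ids: list[str] | None = None,
                 histo: np.ndarray | None = None) -> SpatialDataset:
    """Build a dataset around a given spots x genes *normalized* matrix."""
    X = np.asarray(X, dtype=np.float64)
    n, g = X.shape
    gene_ids = gene_ids or [f"g{j}" for j in range(g)]
    coords = coords if coords is not None else np.column_stack(
        [np.arange(n), np.zeros(n)])
    regions = regions if regions is not None else np.ones(n, dtype=int)
    ds = SpatialDataset(counts=X.T.copy(), gene_ids=gene_ids,
                        spot_ids=[f"s{i}" for i in range(n)],
                        coords=coords, regions=regions, histo_features=histo)
    ds.normalized = X.copy()
    ds.hvgs = list(gene_ids)
    return ds


@pytest.fixture(scope="session")
def standard_fixture():
    """The default study: 20x15 grid, 3 domains, 200 genes, fold-change 5."""
    ds, kb, gt = simulate_dataset(SimConfig(seed=1))
    ds, hvgs = st.normalize_and_select_hvgs(ds, n_hvg=200)
    latent = st.encode_cells(ds, dim=50, seed=1)
    return {"ds": ds, "kb": kb, "gt": gt, "hvgs": hvgs, "latent": latent}


@pytest.fixture(scope="session")
def standard_graphs(standard_fixture):
    f = standard_fixture
    g1 = st.build_cell_hetero_graph(f["ds"], f["latent"], m=30)
    graphs = st.build_semantic_graphs(f["ds"], f["latent"], k=6)
    return {"g1": g1, "semantic": graphs}


@pytest.fixture(scope="session")
def cell_fit(standard_fixture, standard_graphs):
    """Cell-module training on the standard study, seed 1."""
    model = st.CellModuleModel(standard_fixture["ds"], standard_graphs["g1"],
                               standard_graphs["semantic"])
    return model.fit(seed=1)


@pytest.fixture(scope="session")
def cell_labels(standard_fixture, cell_fit):
    return st.cluster_spots(cell_fit.R, seed=1,
                            target_clusters=standard_fixture["ds"].n_regions)


@pytest.fixture(scope="session")
def svg_table(standard_fixture, cell_labels):
    return st.call_svgs(standard_fixture["ds"], cell_labels)


@pytest.fixture(scope="session")
def gene_fit(standard_fixture, svg_table):
    model = st.GeneModuleModel(standard_fixture["ds"], standard_fixture["kb"],
                               svg_table=svg_table,
                               latent_cell=standard_fixture["latent"])
    return model.fit(seed=1)


@pytest.fixture(scope="session")
def ccc_fit(standard_fixture, standard_graphs):
    f = standard_fixture
    graph = st.build_lrp_graphs(f["ds"], f["kb"], K=6)
    sets = sample_positives_negatives(f["ds"], standard_graphs["semantic"])
    return st.CCCModel(f["ds"], graph, sets).fit(seed=1)
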