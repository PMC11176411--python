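"""SVG calling, gene encoder, contrastive training and module clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.metrics import adjusted_rand_score

from conftest import make_dataset
from sthet.datasets import InteractionKB, ValidationError
from sthet.genes import (GeneEncoder, GeneModuleModel, call_svgs,
                         cluster_gene_modules, gene_forward,
                         gene_positive_pairs)
from sthet.graphs import build_gene_hetero_graph


# ---------------------------------------------------------------------------
# SVG calling
# ---------------------------------------------------------------------------

def _two_cluster_dataset(rng, n_per=12, n_genes=20, n_markers=5, shift=3.0):
    base = rng.lognormal(0.0, 0.3, size=(2 * n_per, n_genes))
    labels = np.repeat([1, 2], n_per)
    markers = list(range(n_markers))
    base[labels == 1][:, :n_markers]  # noqa: B018 - clarity
    base[np.ix_(labels == 1, markers)] += shift
    return make_dataset(base), labels, [f"g{j}" for j in markers]


def test_exclusively_expressed_gene_called():
    X = np.zeros((12, 3))
    X[:6, 0] = 5.0         # gene 0 only in cluster 1
    X[:, 1] = 1.0
    X[:, 2] = np.linspace(1, 2, 12)
    ds = make_dataset(X)
    table = call_svgs(ds, np.repeat([1, 2], 6))
    called = table[(table.gene == "g0") & (table.cluster == 1)]
    assert len(called) == 1


def test_constant_gene_never_called():
    rng = np.random.default_rng(0)
    X = rng.lognormal(size=(14, 4))
    X[:, 2] = 3.0
    ds = make_dataset(X)
    table = call_svgs(ds, np.repeat([1, 2], 7))
    assert "g2" not in set(table.gene)


def test_svg_caller_matches_direct_wilcoxon_bh_enumeration():
    """Planted 2-cluster toy: recompute rank-sum p-values and BH adjustment
    from scratch and compare the called set exactly."""
    rng = np.random.default_rng(42)
    ds, labels, markers = _two_cluster_dataset(rng)
    table = call_svgs(ds, labels, lfc_min=0.25, fdr_max=0.05)

    X = ds.normalized
    expr = np.expm1(X)
    for c in (1, 2):
        inside = labels == c
        pvals, lfcs = [], []
        for gi in range(X.shape[1]):
            a, b = X[inside, gi], X[~inside, gi]
            # normal-approximation rank-sum statistic, from first principles
            n1, n2 = len(a), len(b)
            ranks = sps.rankdata(np.concatenate([a, b]))
            s = ranks[:n1].sum()
            mu = n1 * (n1 + n2 + 1) / 2
            sd = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)
            z = (s - mu) / sd
            pvals.append(2 * sps.norm.sf(abs(z)))
            lfcs.append(np.log2((expr[inside, gi].mean() + 1e-9)
                                / (expr[~inside, gi].mean() + 1e-9)))
        pvals = np.array(pvals)
        # Benjamini-Hochberg by direct enumeration
        order = np.argsort(pvals)
        m = len(pvals)
        adj = np.empty(m)
        running = 1.0
        for rank_pos in range(m - 1, -1, -1):
            gi = order[rank_pos]
            running = min(running, pvals[gi] * m / (rank_pos + 1))
            adj[gi] = running
        expected = {f"g{gi}" for gi in range(m)
                    if lfcs[gi] >= 0.25 and adj[gi] <= 0.05}
        got = set(table[table.cluster == c].gene)
        assert got == expected
    # and the planted markers are exactly the cluster-1 calls
    assert set(table[table.cluster == 1].gene) == set(markers)


def test_small_cluster_excluded_with_warning(caplog):
    rng = np.random.default_rng(1)
    X = rng.lognormal(size=(10, 5))
    labels = np.array([1] * 8 + [2] * 2)
    with caplog.at_level("WARNING"):
        table = call_svgs(make_dataset(X), labels)
    assert 2 not in set(table.cluster)
    assert "excluded" in caplog.text


# ---------------------------------------------------------------------------
# gene encoder
# ---------------------------------------------------------------------------

def _toy_gene_graph(rng, n_genes=6, n_spots=8, n_states=2):
    X = rng.lognormal(size=(n_spots, n_genes))
    ds = make_dataset(X)
    table = pd.DataFrame(
        [(f"g{j}", 1 + j % n_states, 1.0, 0.01) for j in range(n_genes)],
        columns=["gene", "cluster", "lfc", "p_adj"])
    latent = rng.normal(size=(n_spots, 4))
    return ds, build_gene_hetero_graph(ds, latent, table, m=3)


def test_singleton_views_have_unit_attention():
    rng = np.random.default_rng(0)
    ds, g2 = _toy_gene_graph(rng)
    g2.expressed_by_mask[:] = False
    g2.expressed_by_mask[:, 0] = True
    enc = GeneEncoder(g2, b=5, rng=rng)
    _, tables = gene_forward(g2, enc)
    np.testing.assert_allclose(tables["alpha_spot"][:, 0], 1.0, atol=1e-12)
    np.testing.assert_allclose(tables["alpha_state"].sum(axis=1), 1.0,
                               atol=1e-9)


def test_view_weight_endpoint_selects_state_view():
    rng = np.random.default_rng(1)
    _, g2 = _toy_gene_graph(rng)
    enc = GeneEncoder(g2, b=5, rng=rng)
    enc.beta_override = np.array([0.0, 1.0])
    G, _ = gene_forward(g2, enc)
    # genes assigned to the same single state share their embedding row
    states = np.argmax(g2.state_mask, axis=1)
    for s in np.unique(states):
        rows = G[states == s]
        np.testing.assert_allclose(rows - rows[0], 0.0, atol=1e-12)


def test_gene_forward_matches_scalar_oracle():
    rng = np.random.default_rng(6)
    _, g2 = _toy_gene_graph(rng)
    enc = GeneEncoder(g2, b=4, rng=rng)
    G, tables = gene_forward(g2, enc)

    def relu(x):
        return np.maximum(x, 0)

    def lrelu(x):
        return np.where(x > 0, x, 0.2 * x)

    def softmax(v):
        e = np.exp(v - v.max())
        return e / e.sum()

    d_gene = [relu(enc.W_spot.data @ e + enc.b_spot.data)
              for e in g2.gene_encodings]
    d_spot = [relu(enc.W_gene.data @ e + enc.b_gene.data)
              for e in g2.spot_encodings]
    d_state = [relu(enc.W_region.data @ e + enc.b_region.data)
               for e in g2.state_encodings]
    b = enc.d
    view_spot, view_state = [], []
    for gi in range(len(g2.candidate_genes)):
        nbrs = np.where(g2.expressed_by_mask[gi])[0]
        logits = np.array([lrelu(enc.a_gene.data
                                 @ np.concatenate([d_gene[gi], d_spot[j]]))
                           for j in nbrs])
        al = softmax(logits)
        view_spot.append(relu(sum(a * d_spot[j] for a, j in zip(al, nbrs))))
        snbrs = np.where(g2.state_mask[gi])[0]
        logits = np.array([lrelu(enc.a_region.data
                                 @ np.concatenate([d_gene[gi], d_state[s]]))
                           for s in snbrs])
        al = softmax(logits)
        view_state.append(relu(sum(a * d_state[s] for a, s in zip(al, snbrs))))
    w = [np.mean([enc.a_view.data @ np.tanh(enc.W_view.data @ v + enc.b_view.data)
                  for v in view]) for view in (view_spot, view_state)]
    beta = softmax(np.array(w))
    expected = np.array([beta[0] * view_spot[i] + beta[1] * view_state[i]
                         for i in range(len(view_spot))])
    np.testing.assert_allclose(G, expected, atol=1e-6)


# ---------------------------------------------------------------------------
# contrastive training
# ---------------------------------------------------------------------------

def test_rho_zero_keeps_all_kb_pairs(standard_fixture, svg_table):
    ds, kb = standard_fixture["ds"], standard_fixture["kb"]
    candidates = sorted(svg_table["gene"].unique(),
                        key=lambda g: ds.gene_ids.index(g))
    mask0, kb_pairs = gene_positive_pairs(ds, kb, candidates, rho=0.0)
    assert mask0.sum() // 2 == kb_pairs
    mask5, _ = gene_positive_pairs(ds, kb, candidates, rho=0.5)
    assert mask5.sum() <= mask0.sum()


def test_all_pairs_filtered_raises_actionable_error(standard_fixture, svg_table):
    model = GeneModuleModel(standard_fixture["ds"], standard_fixture["kb"],
                            svg_table=svg_table,
                            latent_cell=standard_fixture["latent"], rho=1.0)
    with pytest.raises(ValidationError, match="lower rho"):
        model.fit(seed=0)


def test_fixed_seed_reproducible(standard_fixture, svg_table):
    kwargs = dict(svg_table=svg_table, latent_cell=standard_fixture["latent"],
                  max_epochs=15)
    a = GeneModuleModel(standard_fixture["ds"], standard_fixture["kb"],
                        **kwargs).fit(seed=4)
    b = GeneModuleModel(standard_fixture["ds"], standard_fixture["kb"],
                        **kwargs).fit(seed=4)
    np.testing.assert_array_equal(a.G, b.G)


def test_planted_pairs_closer_than_random(standard_fixture, gene_fit):
    """Embedding distances of planted-module KB pairs are significantly
    smaller than distances of random candidate pairs."""
    gt = standard_fixture["gt"]
    idx = {g: i for i, g in enumerate(gene_fit.candidate_genes)}
    pairs = [(a, b) for a, b in gt.planted_ppi + gt.planted_grn
             if a in idx and b in idx]
    d_mod = [np.linalg.norm(gene_fit.G[idx[a]] - gene_fit.G[idx[b]])
             for a, b in pairs]
    rng = np.random.default_rng(0)
    n = len(gene_fit.candidate_genes)
    d_rand = []
    while len(d_rand) < len(d_mod):
        a, b = rng.integers(n), rng.integers(n)
        if a != b:
            d_rand.append(np.linalg.norm(gene_fit.G[a] - gene_fit.G[b]))
    p = sps.ranksums(d_mod, d_rand, alternative="less").pvalue
    assert p < 0.01


# ---------------------------------------------------------------------------
# module clustering
# ---------------------------------------------------------------------------

def test_orthogonal_modules_recovered_exactly():
    rng = np.random.default_rng(0)
    G = np.zeros((40, 6))
    G[:20, :3] = 1.0 + 0.01 * rng.normal(size=(20, 3))
    G[20:, 3:] = 1.0 + 0.01 * rng.normal(size=(20, 3))
    labels = cluster_gene_modules(G, seed=0)
    truth = np.repeat([1, 2], 20)
    assert adjusted_rand_score(truth, labels) == 1.0


def test_resolution_sweep_is_monotone_in_community_count():
    rng = np.random.default_rng(1)
    G = rng.normal(size=(60, 8))
    counts = [cluster_gene_modules(G, resolution=r, seed=2).max()
              for r in (0.2, 0.5, 1.0, 2.0, 4.0)]
    assert all(b >= a for a, b in zip(counts[:-1], counts[1:]))


def test_planted_module_purity(standard_fixture, gene_fit):
    gt = standard_fixture["gt"]
    labels = gene_fit.cluster(seed=1)
    idx = {g: i for i, g in enumerate(gene_fit.candidate_genes)}
    for members in gt.modules.values():
        hit = [labels[idx[g]] for g in members if g in idx]
        _, counts = np.unique(hit, return_counts=True)
        assert counts.max() / len(hit) >= 0.8


def test_degenerate_embeddings_rejected():
    with pytest.raises(ValidationError, match="zero variance"):
        cluster_gene_modules(np.ones((30, 4)))
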