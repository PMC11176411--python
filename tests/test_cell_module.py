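"""Cell-module encoders and contrastive objective vs independent oracles."""

import numpy as np
import pytest

from conftest import make_dataset
from sthet._autodiff import Parameter, Tensor
from sthet.cell import (CellModuleModel, ContrastiveConfig,
                        HierarchicalEncoder, PositiveNegativeSets,
                        SemanticEncoder, contrastive_loss,
                        hierarchical_forward, info_nce_per_anchor,
                        sample_positives_negatives, semantic_forward)
from sthet.graphs import (CellHeteroGraph, SemanticGraphSet,
                          build_semantic_graphs)
from sthet.simulate import SimConfig, simulate_dataset
import sthet as st


def relu(x):
    return np.maximum(x, 0.0)


def lrelu(x, s=0.2):
    return np.where(x > 0, x, s * x)


def softmax(v):
    e = np.exp(v - np.max(v))
    return e / e.sum()


def random_cell_graph(rng, n=4, h=3, K=2, latent=5, min_deg=1):
    express = rng.random((n, h)) < 0.6
    for i in range(n):
        if express[i].sum() < min_deg:
            express[i, rng.integers(h)] = True
    regions = rng.integers(1, K + 1, size=n)
    regions[:K] = np.arange(1, K + 1)       # every region present
    return CellHeteroGraph(
        express_mask=express, region_onehot=np.eye(K)[regions - 1],
        spot_encodings=rng.normal(size=(n, latent)),
        gene_encodings=np.eye(h), region_encodings=np.eye(K),
        hvgs=[f"g{j}" for j in range(h)], m=h)


def oracle_hierarchical(g1: CellHeteroGraph, enc: HierarchicalEncoder):
    """Straight-line scalar evaluation of the hierarchical equations."""
    d_spot = [relu(enc.W_spot.data @ l + enc.b_spot.data)
              for l in g1.spot_encodings]
    d_gene = [relu(enc.W_gene.data @ e + enc.b_gene.data)
              for e in g1.gene_encodings]
    d_region = [relu(enc.W_region.data @ e + enc.b_region.data)
                for e in g1.region_encodings]
    n = len(d_spot)
    d = enc.d
    view1, view2 = [], []
    for i in range(n):
        nbrs = np.where(g1.express_mask[i])[0]
        logits = np.array([
            lrelu(enc.a_gene.data @ np.concatenate([d_spot[i], d_gene[j]]))
            for j in nbrs])
        alpha = softmax(logits)
        view2.append(relu(sum(a * d_gene[j] for a, j in zip(alpha, nbrs))))
        r = int(np.argmax(g1.region_onehot[i]))
        view1.append(relu(d_region[r]))      # singleton attention = 1
    w = np.zeros(2)
    for m, view in enumerate((view1, view2)):
        w[m] = np.mean([enc.a_view.data
                        @ np.tanh(enc.W_view.data @ v + enc.b_view.data)
                        for v in view])
    beta = softmax(w)
    R1 = np.array([beta[0] * view1[i] + beta[1] * view2[i] for i in range(n)])
    return R1, beta


def oracle_semantic(adjacencies, h0, enc: SemanticEncoder):
    """Scalar evaluation of the stacked GAT layers and fusion attention."""
    P = []
    for g, adj in enumerate(adjacencies):
        h = np.asarray(h0, dtype=float)
        for layer in enc.layers[g]:
            n = adj.shape[0]
            out = np.zeros((n, layer.out_dim))
            for q in range(layer.heads):
                W, a = layer.W[q].data, layer.a[q].data
                Wh = np.array([W @ h[i] for i in range(n)])
                for i in range(n):
                    nbrs = np.where(adj[i])[0]
                    logits = np.array([
                        lrelu(a @ np.concatenate([Wh[i], Wh[j]])) for j in nbrs])
                    alpha = softmax(logits)
                    out[i] += sum(al * Wh[j] for al, j in zip(alpha, nbrs))
            out /= layer.heads
            if layer.activation == "elu":
                out = np.where(out > 0, out, np.exp(np.minimum(out, 0)) - 1)
            h = out
        P.append(h)
    n = P[0].shape[0]
    R2 = np.zeros_like(P[0])
    gammas = np.zeros((n, len(P)))
    for i in range(n):
        pc = np.concatenate([p[i] for p in P])
        gam = softmax(np.array([enc.fusion.data[m] @ pc for m in range(len(P))]))
        gammas[i] = gam
        R2[i] = sum(g * p[i] for g, p in zip(gam, P))
    return R2, gammas


# ---------------------------------------------------------------------------
# hierarchical encoder
# ---------------------------------------------------------------------------

def test_singleton_gene_attention_is_one():
    rng = np.random.default_rng(0)
    g1 = random_cell_graph(rng, n=3, h=4)
    g1.express_mask[:] = False
    g1.express_mask[:, 2] = True                 # one linked gene each
    enc = HierarchicalEncoder(5, 4, 2, d=6, rng=rng)
    _, alpha, _ = hierarchical_forward(g1, enc)
    np.testing.assert_allclose(alpha[:, 2], 1.0, atol=1e-12)


def test_beta_endpoint_selects_region_view():
    rng = np.random.default_rng(1)
    g1 = random_cell_graph(rng, n=5, h=3)
    enc = HierarchicalEncoder(5, 3, 2, d=4, rng=rng)
    enc.beta_override = np.array([1.0, 0.0])
    R1, _, _ = hierarchical_forward(g1, enc)
    # region view only: spots in the same region share the embedding
    regions = np.argmax(g1.region_onehot, axis=1)
    for r in np.unique(regions):
        rows = R1[regions == r]
        np.testing.assert_allclose(rows - rows[0], 0.0, atol=1e-12)


def test_hierarchical_forward_matches_scalar_oracle():
    rng = np.random.default_rng(11)
    g1 = random_cell_graph(rng, n=4, h=3, K=2)
    enc = HierarchicalEncoder(5, 3, 2, d=4, rng=rng)
    R1, _, beta = hierarchical_forward(g1, enc)
    R1_o, beta_o = oracle_hierarchical(g1, enc)
    np.testing.assert_allclose(R1, R1_o, atol=1e-6)
    np.testing.assert_allclose(beta, beta_o, atol=1e-6)


# ---------------------------------------------------------------------------
# semantic encoder
# ---------------------------------------------------------------------------

def _ring_adj(n, k=2):
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for step in range(1, k // 2 + 1):
            adj[i, (i + step) % n] = True
            adj[i, (i - step) % n] = True
    return adj


def test_identical_graphs_and_shared_parameters_give_uniform_gamma():
    rng = np.random.default_rng(2)
    n = 8
    adj = _ring_adj(n)
    enc = SemanticEncoder(in_dim=5, n_graphs=3, d=4, n_layers=1, heads=2,
                          rng=rng)
    for g in (1, 2):       # share parameters across graphs
        for lq, l0 in zip(enc.layers[g], enc.layers[0]):
            for q in range(l0.heads):
                lq.W[q].data = l0.W[q].data.copy()
                lq.a[q].data = l0.a[q].data.copy()
    enc.fusion.data[:] = enc.fusion.data[0]
    h0 = rng.normal(size=(n, 5))
    graphs = SemanticGraphSet(adjacencies={"slg": adj, "hsg": adj.copy(),
                                           "tsg": adj.copy()}, k=2)
    R2, gamma, P = semantic_forward(graphs, h0, enc)
    np.testing.assert_allclose(P[0], P[1], atol=1e-12)
    np.testing.assert_allclose(P[0], P[2], atol=1e-12)
    np.testing.assert_allclose(gamma, 1 / 3, atol=1e-9)


def test_single_head_identity_layer_averages_neighbors():
    """On a 3-node path with identity weights, zero attention vector and a
    linear activation, each node's output is the mean of its neighbors."""
    enc = SemanticEncoder(in_dim=2, n_graphs=1, d=2, n_layers=1, heads=1,
                          activation="linear", rng=np.random.default_rng(0))
    enc.layers[0][0].W[0].data = np.eye(2)
    enc.layers[0][0].a[0].data = np.zeros(4)
    adj = np.zeros((3, 3), dtype=bool)
    adj[0, 1] = adj[1, 0] = adj[1, 2] = adj[2, 1] = True
    h0 = np.array([[1.0, 0], [3, 2], [5, -4]])
    R2, tables = enc.forward([adj], h0)
    P = tables["P"][0]
    np.testing.assert_allclose(P[0], h0[1], atol=1e-12)
    np.testing.assert_allclose(P[1], (h0[0] + h0[2]) / 2, atol=1e-12)
    np.testing.assert_allclose(P[2], h0[1], atol=1e-12)


def test_semantic_forward_matches_scalar_oracle():
    rng = np.random.default_rng(21)
    n = 7
    adjs = [_ring_adj(n), _ring_adj(n, 4)[:, ::-1][:, np.argsort(np.arange(n))]]
    adjs[1] = _ring_adj(n, 4)
    enc = SemanticEncoder(in_dim=3, n_graphs=2, d=4, n_layers=2, heads=2,
                          rng=rng)
    h0 = rng.normal(size=(n, 3))
    R2, tables = enc.forward(adjs, h0)
    R2_o, gamma_o = oracle_semantic(adjs, h0, enc)
    np.testing.assert_allclose(R2.data, R2_o, atol=1e-6)
    np.testing.assert_allclose(tables["gamma"], gamma_o, atol=1e-6)


def test_spot_permutation_equivariance():
    rng = np.random.default_rng(5)
    n = 9
    g1 = random_cell_graph(rng, n=n, h=4, K=2)
    adj = _ring_adj(n, 2)
    henc = HierarchicalEncoder(5, 4, 2, d=4, rng=np.random.default_rng(8))
    senc = SemanticEncoder(in_dim=5, n_graphs=1, d=4, rng=np.random.default_rng(9))
    R1, _, _ = hierarchical_forward(g1, henc)
    R2, _ = senc.forward([adj], g1.spot_encodings)

    perm = rng.permutation(n)
    g1p = CellHeteroGraph(express_mask=g1.express_mask[perm],
                          region_onehot=g1.region_onehot[perm],
                          spot_encodings=g1.spot_encodings[perm],
                          gene_encodings=g1.gene_encodings,
                          region_encodings=g1.region_encodings,
                          hvgs=g1.hvgs, m=g1.m)
    R1p, _, _ = hierarchical_forward(g1p, henc)
    R2p, _ = senc.forward([adj[np.ix_(perm, perm)]], g1.spot_encodings[perm])
    np.testing.assert_allclose(R1p, R1[perm], atol=1e-6)
    np.testing.assert_allclose(R2p.data, R2.data[perm], atol=1e-6)


# ---------------------------------------------------------------------------
# contrastive objective
# ---------------------------------------------------------------------------

def _random_sets(rng, n, n_pos):
    pos = np.zeros((n, n), dtype=bool)
    for i in range(n):
        choices = rng.choice([j for j in range(n) if j != i], size=n_pos,
                             replace=False)
        pos[i, choices] = True
    neg = ~pos
    np.fill_diagonal(neg, False)
    return PositiveNegativeSets(pos_mask=pos, neg_mask=neg,
                                anchor_mask=np.ones(n, dtype=bool))


def test_constant_similarity_closed_form():
    n = 8
    sets = _random_sets(np.random.default_rng(0), n, n_pos=2)
    sim = Tensor(np.full((n, n), 0.37))
    L = info_nce_per_anchor(sim, sets).data.ravel()
    expected = -np.log(2 / (n - 1))
    np.testing.assert_allclose(L, expected, atol=1e-12)


def test_lambda_endpoints_reduce_to_single_terms():
    rng = np.random.default_rng(3)
    n = 7
    R1, R2 = rng.normal(size=(n, 4)), rng.normal(size=(n, 4))
    sets = _random_sets(rng, n, 2)
    for lam in (0.0, 1.0):
        Lt, LH, LS = contrastive_loss(R1, R2, sets,
                                      ContrastiveConfig(lam=lam, tau=0.5))
        expected = LH.data if lam == 1.0 else LS.data
        np.testing.assert_allclose(Lt.data, expected, atol=1e-12)


def test_contrastive_loss_matches_scalar_oracle():
    rng = np.random.default_rng(3)
    n, d, tau = 7, 4, 0.5
    R1, R2 = rng.normal(size=(n, d)), rng.normal(size=(n, d))
    sets = _random_sets(rng, n, n_pos=2)
    _, LH, LS = contrastive_loss(R1, R2, sets, ContrastiveConfig(tau=tau))

    def cos(a, b):
        return a @ b / (np.linalg.norm(a) * np.linalg.norm(b))

    def loop(anchor, cand):
        vals = []
        for i in range(n):
            num = sum(np.exp(cos(anchor[i], cand[j]) / tau)
                      for j in np.where(sets.pos_mask[i])[0])
            den = sum(np.exp(cos(anchor[i], cand[k]) / tau)
                      for k in np.where(sets.pos_mask[i] | sets.neg_mask[i])[0])
            vals.append(-np.log(num / den))
        return np.mean(vals)

    np.testing.assert_allclose(float(LH.data), loop(R2, R1), atol=1e-6)
    np.testing.assert_allclose(float(LS.data), loop(R1, R2), atol=1e-6)


def test_lambda_one_gradients_equal_pure_hierarchical_loss():
    rng = np.random.default_rng(9)
    n = 6
    R1 = Parameter(rng.normal(size=(n, 3)))
    R2 = Parameter(rng.normal(size=(n, 3)))
    sets = _random_sets(rng, n, 2)
    Lt, _, _ = contrastive_loss(R1, R2, sets, ContrastiveConfig(lam=1.0))
    Lt.backward()
    g1_total, g2_total = R1.grad.copy(), R2.grad.copy()
    R1.grad = R2.grad = None
    _, LH, _ = contrastive_loss(R1, R2, sets, ContrastiveConfig(lam=1.0))
    LH.backward()
    np.testing.assert_allclose(g1_total, R1.grad, atol=1e-12)
    np.testing.assert_allclose(g2_total, R2.grad, atol=1e-12)


def test_invalid_temperature_and_lambda_rejected():
    from sthet.datasets import ValidationError
    with pytest.raises(ValidationError, match="tau"):
        ContrastiveConfig(tau=0.0)
    with pytest.raises(ValidationError, match="lambda"):
        ContrastiveConfig(lam=1.5)


# ---------------------------------------------------------------------------
# positive / negative sampling
# ---------------------------------------------------------------------------

def test_uniform_region_positives_equal_slg_rows():
    rng = np.random.default_rng(0)
    ds = make_dataset(np.ones((12, 3)), coords=rng.normal(size=(12, 2)),
                      regions=np.ones(12, dtype=int))
    graphs = build_semantic_graphs(ds, rng.normal(size=(12, 4)), k=3)
    sets = sample_positives_negatives(ds, graphs)
    np.testing.assert_array_equal(sets.pos_mask, graphs.adjacencies["slg"])


def test_checkerboard_regions_use_fallback_positives():
    n = 10
    coords = np.column_stack([np.arange(n), np.zeros(n)])
    regions = np.tile([1, 2], n // 2)
    ds = make_dataset(np.ones((n, 3)), coords=coords, regions=regions)
    graphs = build_semantic_graphs(ds, np.random.default_rng(0).normal(size=(n, 4)),
                                   k=1)   # only the adjacent spot -> other region
    sets = sample_positives_negatives(ds, graphs)
    assert np.all(sets.pos_mask.sum(axis=1) == 1)
    rows, cols = np.where(sets.pos_mask)
    assert np.all(regions[rows] == regions[cols])
    assert not np.any(sets.pos_mask & graphs.adjacencies["slg"])


def test_singleton_region_spot_excluded_with_warning(caplog):
    n = 8
    regions = np.ones(n, dtype=int)
    regions[-1] = 2
    ds = make_dataset(np.ones((n, 3)),
                      coords=np.column_stack([np.arange(n), np.zeros(n)]),
                      regions=regions)
    graphs = build_semantic_graphs(ds, np.random.default_rng(0).normal(size=(n, 4)),
                                   k=2)
    with caplog.at_level("WARNING"):
        sets = sample_positives_negatives(ds, graphs)
    assert not sets.anchor_mask[-1]
    assert "alone in its region" in caplog.text


def test_block_interior_positives_are_full_slg_rows(standard_fixture,
                                                    standard_graphs):
    ds = standard_fixture["ds"]
    gt = standard_fixture["gt"]
    graphs = standard_graphs["semantic"]
    sets = sample_positives_negatives(ds, graphs)
    slg = graphs.adjacencies["slg"]
    same = gt.domains[:, None] == gt.domains[None, :]
    interior = np.array([np.all(same[i, slg[i]]) for i in range(ds.n_spots)])
    assert interior.sum() > 100
    np.testing.assert_array_equal(sets.pos_mask[interior], slg[interior])


# ---------------------------------------------------------------------------
# training contract
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def tiny_trained():
    ds, _, gt = simulate_dataset(SimConfig(
        grid_shape=(8, 6), n_genes=40, genes_per_program=6,
        n_planted_lrps=0, n_decoy_lrps=0, seed=2))
    ds, _ = st.normalize_and_select_hvgs(ds, n_hvg=40)
    rng = np.random.default_rng(0)
    latent = rng.normal(size=(ds.n_spots, 8))
    g1 = st.build_cell_hetero_graph(ds, latent, m=10)
    graphs = st.build_semantic_graphs(ds, latent, k=4)
    model = CellModuleModel(ds, g1, graphs, d=8, max_epochs=80)
    return model, model.fit(seed=3)


def test_early_stop_satisfies_patience_rule(tiny_trained):
    model, res = tiny_trained
    curve = np.asarray(res.loss_curve)
    assert np.all(np.isfinite(curve))
    if res.n_epochs < model.max_epochs:
        best = np.inf
        bad = 0
        stop_at = None
        for e, v in enumerate(curve):
            if v < best - model.min_delta:
                best, bad = v, 0
            else:
                bad += 1
            if bad >= model.patience:
                stop_at = e
                break
        assert stop_at == res.n_epochs - 1


def test_same_seed_reproduces_identical_embeddings(tiny_trained):
    model, res = tiny_trained
    res2 = model.fit(seed=3)
    np.testing.assert_array_equal(res.R, res2.R)
    assert res.loss_curve == res2.loss_curve


def test_training_pulls_positive_pairs_together(tiny_trained):
    model, res = tiny_trained
    sets = sample_positives_negatives(model.ds, model.graphs)
    r1 = res.R1 / np.linalg.norm(res.R1, axis=1, keepdims=True)
    r2 = res.R2 / np.linalg.norm(res.R2, axis=1, keepdims=True)
    sim = r2 @ r1.T
    rng = np.random.default_rng(0)
    pos_vals = sim[sets.pos_mask]
    neg_idx = np.where(sets.neg_mask)
    pick = rng.choice(len(neg_idx[0]), size=len(pos_vals), replace=False)
    neg_vals = sim[neg_idx[0][pick], neg_idx[1][pick]]
    assert pos_vals.mean() > neg_vals.mean()


def test_domain_recovery_on_standard_fixture(standard_fixture, cell_fit,
                                             cell_labels):
    from sklearn.metrics import adjusted_rand_score
    ari = adjusted_rand_score(standard_fixture["gt"].domains, cell_labels)
    assert ari >= 0.8
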