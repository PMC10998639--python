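"""VGAE building blocks: losses vs naive oracles, decoder, gradient check."""

import numpy as np
import pytest
import scipy.sparse as sp

from graphanno.graphs import AnchorSet, CellGraph, build_hybrid_graph
from graphanno.io import FeatureMatrix
from graphanno.model import (
    ModelConfig,
    alignment_loss,
    classification_loss,
    decode,
    encode,
    kl_loss,
    normalize_adjacency,
    peak_importance,
    predict_labels,
    reconstruction_loss,
    reparameterize,
    total_loss,
    train,
)

# ---------------------------------------------------------------------------
# naive oracle implementations (element-by-element, loop-based)


def naive_kl(mu_h, sig_h, mu_a, sig_a, mode):
    total = 0.0
    for mu, sig in ((mu_h, sig_h), (mu_a, sig_a)):
        acc = 0.0
        for i in range(mu.shape[0]):
            for d in range(mu.shape[1]):
                acc += -0.5 * (1 + 2 * np.log(sig[i, d]) - mu[i, d] ** 2 - sig[i, d] ** 2)
        total += acc / mu.shape[0] if mode == "mean" else acc
    return total


def naive_alignment(Z_h, Z_a, rows_h, rows_a, norm):
    vals = []
    for h, a in zip(rows_h, rows_a):
        diff = Z_h[h] - Z_a[a]
        vals.append(np.sqrt((diff**2).sum()) if norm == "l2" else np.abs(diff).sum())
    return float(np.mean(vals))


def naive_bce(G, G_hat, mode):
    N = G.shape[0]
    eps = 1e-7
    E = G.sum()
    pw = (N * N - E) / E if mode == "weighted" else 1.0
    acc = 0.0
    for i in range(N):
        for j in range(N):
            p = min(max(G_hat[i, j], eps), 1 - eps)
            acc += -(pw * G[i, j] * np.log(p) + (1 - G[i, j]) * np.log(1 - p))
    if mode == "weighted":
        return N * N / (2 * (N * N - E)) * acc / (N * N)
    return acc / N


def naive_class(Z_hat, Y, rows):
    acc = 0.0
    for c, row in enumerate(rows):
        for f in range(Y.shape[1]):
            acc += -Y[c, f] * np.log(max(Z_hat[row, f], 1e-7))
    return acc / len(rows)


def random_instance(rng, n=10, k=3):
    mu_h = rng.standard_normal((n, k))
    sig_h = np.exp(rng.standard_normal((n, k)) * 0.3)
    mu_a = rng.standard_normal((n - 2, k))
    sig_a = np.exp(rng.standard_normal((n - 2, k)) * 0.3)
    return mu_h, sig_h, mu_a, sig_a


class TestLossOracles:
    @pytest.mark.parametrize("mode", ["mean", "sum"])
    def test_kl_matches_naive(self, rng, mode):
        for _ in range(10):
            mu_h, sig_h, mu_a, sig_a = random_instance(rng)
            got = kl_loss(mu_h, sig_h, mu_a, sig_a, mode)
            assert got == pytest.approx(naive_kl(mu_h, sig_h, mu_a, sig_a, mode), abs=1e-6)

    def test_kl_zero_at_standard_normal(self):
        z = np.zeros((4, 3))
        assert kl_loss(z, np.ones_like(z), z, np.ones_like(z)) == 0.0

    def test_kl_single_element_closed_form(self):
        # KL(N(1,1) || N(0,1)) = 0.5 per element, one element per branch
        mu = np.array([[1.0]])
        sig = np.ones((1, 1))
        assert kl_loss(mu, sig, mu, sig, "sum") == pytest.approx(1.0)

    def test_kl_nonnegative(self, rng):
        for _ in range(20):
            mu_h, sig_h, mu_a, sig_a = random_instance(rng, n=5, k=2)
            assert kl_loss(mu_h, sig_h, mu_a, sig_a) >= 0

    def test_kl_rejects_nonpositive_sigma(self):
        z = np.zeros((2, 2))
        with pytest.raises(ValueError):
            kl_loss(z, np.zeros((2, 2)), z, np.ones((2, 2)))

    @pytest.mark.parametrize("norm", ["l2", "l1"])
    def test_alignment_matches_naive(self, rng, norm):
        for _ in range(10):
            Z_h = rng.standard_normal((10, 4))
            Z_a = rng.standard_normal((8, 4))
            rows_h = rng.choice(10, size=5, replace=False)
            rows_a = rng.choice(8, size=5, replace=False)
            got = alignment_loss(Z_h, Z_a, rows_h, rows_a, norm)
            assert got == pytest.approx(naive_alignment(Z_h, Z_a, rows_h, rows_a, norm), abs=1e-9)

    def test_alignment_345_triangle(self):
        Z_h = np.array([[3.0, 4.0]])
        Z_a = np.array([[0.0, 0.0]])
        assert alignment_loss(Z_h, Z_a, [0], [0]) == pytest.approx(5.0)

    def test_alignment_ignores_non_anchor_rows(self, rng):
        Z_h = rng.standard_normal((6, 3))
        Z_a = rng.standard_normal((6, 3))
        base = alignment_loss(Z_h, Z_a, [1], [2])
        Z_h2 = Z_h.copy()
        Z_h2[0] += 100
        assert alignment_loss(Z_h2, Z_a, [1], [2]) == base

    def test_alignment_requires_anchors(self):
        with pytest.raises(ValueError):
            alignment_loss(np.zeros((2, 2)), np.zeros((2, 2)), [], [])

    @pytest.mark.parametrize("mode", ["weighted", "unweighted"])
    def test_reconstruction_matches_naive(self, rng, mode):
        for _ in range(10):
            N = 10
            G = (rng.random((N, N)) < 0.3).astype(float)
            G = np.triu(G, 1)
            G = G + G.T
            if G.sum() == 0:
                G[0, 1] = G[1, 0] = 1.0
            G_hat = rng.uniform(0.01, 0.99, (N, N))
            got = reconstruction_loss(G, G_hat, mode)
            assert got == pytest.approx(naive_bce(G, G_hat, mode), rel=1e-6)

    def test_reconstruction_2x2_closed_form(self):
        G = np.zeros((2, 2))
        G_hat = np.full((2, 2), 0.5)
        assert reconstruction_loss(G, G_hat, "unweighted") == pytest.approx(2 * np.log(2))

    def test_reconstruction_monotone_toward_target(self, rng):
        G = np.array([[0.0, 1.0], [1.0, 0.0]])
        close = np.array([[0.1, 0.9], [0.9, 0.1]])
        closer = np.array([[0.05, 0.95], [0.95, 0.05]])
        assert reconstruction_loss(G, closer, "unweighted") < reconstruction_loss(
            G, close, "unweighted")

    def test_classification_matches_naive(self, rng):
        for _ in range(10):
            n1, k, N = 6, 3, 10
            Z = rng.standard_normal((N, k))
            Z_hat = np.exp(Z) / np.exp(Z).sum(axis=1, keepdims=True)
            Y = np.eye(k)[rng.integers(0, k, n1)]
            rows = np.arange(n1)
            got = classification_loss(Z_hat, Y, rows)
            assert got == pytest.approx(naive_class(Z_hat, Y, rows), abs=1e-9)

    def test_classification_uniform_indicator_log_k(self):
        k, n1 = 4, 7
        Z_hat = np.full((n1 + 3, k), 1 / k)
        Y = np.eye(k)[np.zeros(n1, dtype=int)]
        assert classification_loss(Z_hat, Y, np.arange(n1)) == pytest.approx(np.log(4))

    def test_classification_ignores_target_columns(self, rng):
        k, n1 = 3, 5
        Z_hat = np.full((8, k), 1 / k)
        Y = np.eye(k)[rng.integers(0, k, n1)]
        base = classification_loss(Z_hat, Y, np.arange(n1))
        Z2 = Z_hat.copy()
        Z2[n1:] = [0.98, 0.01, 0.01]
        assert classification_loss(Z2, Y, np.arange(n1)) == base

    def test_total_loss_arithmetic_and_ablation(self):
        assert total_loss(1, 2, 3, 4, lam=1.0) == 10
        assert total_loss(1, 2, 3, 4, lam=0.0) == 7


class TestDecode:
    def test_zero_latent_gives_half_everywhere(self):
        np.testing.assert_allclose(decode(np.zeros((5, 3))), 0.5)

    def test_orthogonal_unit_rows_closed_form(self):
        Z = np.eye(2)
        G_hat = decode(Z)
        sig1 = 1 / (1 + np.exp(-1))
        np.testing.assert_allclose(np.diag(G_hat), sig1)
        assert G_hat[0, 1] == pytest.approx(0.5)

    def test_symmetry_for_random_latents(self, rng):
        for _ in range(100):
            Z = rng.standard_normal((6, 3)) * rng.uniform(0.1, 3)
            G_hat = decode(Z)
            np.testing.assert_allclose(G_hat, G_hat.T, atol=1e-12)
            assert np.all((G_hat >= 0) & (G_hat <= 1))  # saturates at float precision


class TestNormalizeAdjacency:
    def test_empty_graph_gives_identity(self):
        A = sp.csr_matrix((3, 3))
        np.testing.assert_allclose(normalize_adjacency(A).toarray(), np.eye(3))

    def test_single_edge_closed_form(self):
        A = sp.csr_matrix(np.array([[0, 1], [1, 0]]))
        np.testing.assert_allclose(normalize_adjacency(A).toarray(), 0.5 * np.ones((2, 2)))

    def test_symmetric_output(self, rng):
        A = (rng.random((6, 6)) < 0.4).astype(int)
        A = np.triu(A, 1)
        A = sp.csr_matrix(A + A.T)
        out = normalize_adjacency(A).toarray()
        np.testing.assert_allclose(out, out.T)


class TestEncodeReparameterize:
    def test_zero_input_zero_output(self, rng):
        A = normalize_adjacency(sp.csr_matrix((4, 4)))
        X = np.zeros((4, 3))
        w = {"W1": rng.standard_normal((3, 5)),
             "Wmu": rng.standard_normal((5, 2)),
             "Wls": rng.standard_normal((5, 2))}
        mu, ls, _ = encode(A, X, w)
        np.testing.assert_array_equal(mu, 0)
        np.testing.assert_array_equal(ls, 0)

    def test_scalar_closed_form(self):
        A = sp.eye(1).tocsr()
        X = np.array([[2.0]])
        w = {"W1": np.array([[3.0]]), "Wmu": np.array([[0.5]]), "Wls": np.array([[-1.0]])}
        mu, ls, _ = encode(A, X, w)
        assert mu[0, 0] == pytest.approx(max(2 * 3, 0) * 0.5)
        assert ls[0, 0] == pytest.approx(max(2 * 3, 0) * -1.0)

    def test_permutation_equivariance(self, rng):
        n, f = 6, 4
        A = (rng.random((n, n)) < 0.5).astype(float)
        A = np.triu(A, 1)
        A = sp.csr_matrix(A + A.T)
        X = rng.standard_normal((n, f))
        w = {"W1": rng.standard_normal((f, 5)),
             "Wmu": rng.standard_normal((5, 2)),
             "Wls": rng.standard_normal((5, 2))}
        perm = rng.permutation(n)
        P = np.eye(n)[perm]
        A_hat = normalize_adjacency(A)
        mu, _, _ = encode(A_hat, X, w)
        A_perm = sp.csr_matrix(P @ A.toarray() @ P.T)
        mu_p, _, _ = encode(normalize_adjacency(A_perm), X[perm], w)
        np.testing.assert_allclose(mu_p, mu[perm], atol=1e-10)

    def test_reparameterize_deterministic_and_limits(self, rng):
        mu = rng.standard_normal((3, 2))
        ls = rng.standard_normal((3, 2))
        noise = np.random.default_rng(7).standard_normal((3, 2))
        noise2 = np.random.default_rng(7).standard_normal((3, 2))
        np.testing.assert_array_equal(
            reparameterize(mu, ls, noise), reparameterize(mu, ls, noise2))
        # sigma -> 0 limit returns mu; zero mu/ls returns the raw draw
        np.testing.assert_allclose(
            reparameterize(mu, np.full_like(ls, -745.0), noise), mu)
        np.testing.assert_array_equal(
            reparameterize(np.zeros_like(mu), np.zeros_like(ls), noise), noise)


class TestPredictLabels:
    def test_threshold_rule_and_ties(self):
        Z_hat = np.array([
            [0.7, 0.2, 0.1],
            [0.4, 0.35, 0.25],
            [1 / 3, 1 / 3, 1 / 3],
        ])
        labels, prob, meets = predict_labels(Z_hat)
        np.testing.assert_array_equal(labels, [0, 0, 0])
        np.testing.assert_array_equal(meets, [True, False, False])
        assert prob[0] == pytest.approx(0.7)


# ---------------------------------------------------------------------------
# gradient check and training behaviour


def _toy_training_setup(rng, n1=4, n2=3, k=2, f_h=3, f_a=4, d=4):
    """6-node merged toy: n1 RNA + 1 anchor hybrid, n2 ATAC cells."""
    A = (rng.random((n1, n1)) < 0.6).astype(int)
    A = np.triu(A, 1)
    G_rna = CellGraph(sp.csr_matrix(A + A.T), [f"r{i}" for i in range(n1)], ["rna"] * n1)
    Aa = (rng.random((n2, n2)) < 0.6).astype(int)
    Aa = np.triu(Aa, 1)
    G_atac = CellGraph(sp.csr_matrix(Aa + Aa.T), [f"a{i}" for i in range(n2)], ["atac"] * n2)
    anchors = AnchorSet([(0, 0), (1, 2)], [1.0, 1.0])
    Xr = FeatureMatrix(rng.standard_normal((n1, f_h)), [f"r{i}" for i in range(n1)],
                       [f"g{j}" for j in range(f_h)], "rna")
    Xg = FeatureMatrix(rng.standard_normal((n2, f_h)), [f"a{i}" for i in range(n2)],
                       [f"g{j}" for j in range(f_h)], "gene_activity")
    hybrid = build_hybrid_graph(G_rna, anchors, Xr, Xg)
    from graphanno.graphs import build_merged_graph

    merged = build_merged_graph(hybrid, G_atac)
    X_atac = FeatureMatrix(np.abs(rng.standard_normal((n2, f_a))),
                           [f"a{i}" for i in range(n2)],
                           [f"p{j}" for j in range(f_a)], "atac")
    Y = np.eye(k)[rng.integers(0, k, n1)]
    return hybrid, G_atac, X_atac, merged, Y


def _loss_at(weights_flat, shapes, hybrid, G_atac, X_atac, merged, Y, config, noise):
    """Recompute the full training loss for given flattened weights."""
    from graphanno.model import (
        _softmax_rows, alignment_loss, classification_loss, kl_loss,
        normalize_adjacency, reconstruction_loss, total_loss, decode,
    )

    w = {}
    off = 0
    for key, shape in shapes:
        size = int(np.prod(shape))
        w[key] = weights_flat[off:off + size].reshape(shape)
        off += size
    w_h = {k.split("/", 1)[1]: v for k, v in w.items() if k.startswith("h/")}
    w_a = {k.split("/", 1)[1]: v for k, v in w.items() if k.startswith("a/")}
    A_h = normalize_adjacency(hybrid.graph)
    A_a = normalize_adjacency(G_atac)
    n1 = hybrid.n_rna
    mu_h, ls_h, _ = encode(A_h, hybrid.features, w_h)
    mu_a, ls_a, _ = encode(A_a, np.asarray(X_atac.values, float), w_a)
    Z_h = reparameterize(mu_h, ls_h, noise[0])
    Z_a = reparameterize(mu_a, ls_a, noise[1])
    Z_m = np.vstack([Z_h[:n1], Z_a])
    L_kl = kl_loss(mu_h, np.exp(ls_h), mu_a, np.exp(ls_a), config.kl_mode)
    G_hat = decode(Z_m)
    L_rec = reconstruction_loss(merged.adjacency.toarray(), G_hat, config.bce_mode)
    anchors_a = np.asarray(hybrid.anchor_atac_indices)
    anchors_h = n1 + np.arange(len(anchors_a))
    L_ali = alignment_loss(Z_h, Z_a, anchors_h, anchors_a, config.align_norm)
    Q = _softmax_rows(Z_m)
    L_cls = classification_loss(Q, Y, np.arange(n1))
    return total_loss(L_kl, L_rec, L_ali, L_cls, config.lam)


def test_finite_difference_gradient_check(rng):
    """Analytic gradients of the total loss agree with central differences."""
    from graphanno.model import (
        _branch_backward, _init_weights, _softmax_rows, decode,
        normalize_adjacency,
    )

    hybrid, G_atac, X_atac, merged, Y = _toy_training_setup(rng, k=2, d=4)
    config = ModelConfig(hidden_dim=4, epochs=1, seed=0)
    n1 = hybrid.n_rna
    k = 2
    w_rng = np.random.default_rng(3)
    w_h = _init_weights(w_rng, hybrid.features.shape[1], 4, k, False)
    w_a = _init_weights(w_rng, X_atac.n_features, 4, k, False)
    noise = (np.random.default_rng(5).standard_normal((hybrid.graph.n_nodes, k)),
             np.random.default_rng(6).standard_normal((G_atac.n_nodes, k)))

    # ---- analytic gradients (mirrors one training step without Adam)
    A_h = normalize_adjacency(hybrid.graph)
    A_a = normalize_adjacency(G_atac)
    X_a = np.asarray(X_atac.values, float)
    mu_h, ls_h, cache_h = encode(A_h, hybrid.features, w_h)
    mu_a, ls_a, cache_a = encode(A_a, X_a, w_a)
    cache_h["A_hat"], cache_a["A_hat"] = A_h, A_a
    sig_h, sig_a = np.exp(ls_h), np.exp(ls_a)
    Z_h = reparameterize(mu_h, ls_h, noise[0])
    Z_a = reparameterize(mu_a, ls_a, noise[1])
    Z_m = np.vstack([Z_h[:n1], Z_a])
    N = Z_m.shape[0]
    G = merged.adjacency.toarray().astype(float)
    E = G.sum()
    p = decode(Z_m)
    pw = (N * N - E) / E
    norm = N * N / (2 * (N * N - E))
    dS = norm / (N * N) * (p * (1 - G + pw * G) - pw * G)
    dS[(p <= 1e-7) | (p >= 1 - 1e-7)] = 0.0  # clipped regions are flat
    dZ_m = (dS + dS.T) @ Z_m
    Q = _softmax_rows(Z_m)
    dZ_m[:n1] += (Q[:n1] - Y) / n1
    dZ_h = np.zeros_like(Z_h)
    dZ_a = np.zeros_like(Z_a)
    dZ_h[:n1] = dZ_m[:n1]
    dZ_a += dZ_m[n1:]
    anchors_a = np.asarray(hybrid.anchor_atac_indices)
    anchors_h = n1 + np.arange(len(anchors_a))
    diff = Z_h[anchors_h] - Z_a[anchors_a]
    norms = np.maximum(np.linalg.norm(diff, axis=1, keepdims=True), 1e-12)
    dd = diff / norms / len(anchors_a)
    dZ_h[anchors_h] += dd
    np.add.at(dZ_a, anchors_a, -dd)
    dmu_h = dZ_h + mu_h / mu_h.size
    dls_h = dZ_h * noise[0] * sig_h + (sig_h**2 - 1) / mu_h.size
    dmu_a = dZ_a + mu_a / mu_a.size
    dls_a = dZ_a * noise[1] * sig_a + (sig_a**2 - 1) / mu_a.size
    g_h = _branch_backward(dmu_h, dls_h, cache_h, w_h, False)
    g_a = _branch_backward(dmu_a, dls_a, cache_a, w_a, False)

    shapes = [(f"h/{key}", v.shape) for key, v in w_h.items()] + \
             [(f"a/{key}", v.shape) for key, v in w_a.items()]
    flat = np.concatenate([w_h[key].ravel() for key in ("W1", "Wmu", "Wls")] +
                          [w_a[key].ravel() for key in ("W1", "Wmu", "Wls")])
    analytic = np.concatenate([g_h[key].ravel() for key in ("W1", "Wmu", "Wls")] +
                              [g_a[key].ravel() for key in ("W1", "Wmu", "Wls")])

    h = 1e-6
    idx = np.random.default_rng(11).choice(flat.size, size=60, replace=False)
    numeric = np.zeros_like(idx, dtype=float)
    for ii, i in enumerate(idx):
        up = flat.copy()
        up[i] += h
        down = flat.copy()
        down[i] -= h
        numeric[ii] = (
            _loss_at(up, shapes, hybrid, G_atac, X_atac, merged, Y, config, noise)
            - _loss_at(down, shapes, hybrid, G_atac, X_atac, merged, Y, config, noise)
        ) / (2 * h)
    denom = np.maximum(np.abs(numeric), np.abs(analytic[idx]))
    denom[denom < 1e-8] = 1.0
    rel = np.abs(numeric - analytic[idx]) / denom
    assert rel.max() < 1e-4


class TestTraining:
    def test_seed_reproducibility_bitwise(self, rng):
        hybrid, G_atac, X_atac, merged, Y = _toy_training_setup(rng)
        config = ModelConfig(hidden_dim=8, epochs=10, seed=123, lr=1e-2)
        r1 = train(hybrid, G_atac, X_atac, merged, Y, config)
        r2 = train(hybrid, G_atac, X_atac, merged, Y, config)
        assert (r1.trace["loss"] == r2.trace["loss"]).all()
        np.testing.assert_array_equal(r1.latent.Z_m, r2.latent.Z_m)

    def test_no_reconstruction_ablation_logs_zero(self, rng):
        hybrid, G_atac, X_atac, merged, Y = _toy_training_setup(rng)
        config = ModelConfig(hidden_dim=8, epochs=5, seed=1, no_reconstruction=True)
        r = train(hybrid, G_atac, X_atac, merged, Y, config)
        assert (r.trace["recon"] == 0).all()

    def test_no_alignment_ablation_removes_term_from_loss(self, rng):
        hybrid, G_atac, X_atac, merged, Y = _toy_training_setup(rng)
        config = ModelConfig(hidden_dim=8, epochs=3, seed=1, no_alignment=True)
        r = train(hybrid, G_atac, X_atac, merged, Y, config)
        row = r.trace.iloc[0]
        assert row["loss"] == pytest.approx(row["kl"] + row["recon"] + row["class"])

    def test_single_layer_trains_and_exposes_peak_importance(self, rng):
        hybrid, G_atac, X_atac, merged, Y = _toy_training_setup(rng)
        config = ModelConfig(hidden_dim=8, epochs=5, seed=1, single_layer=True)
        r = train(hybrid, G_atac, X_atac, merged, Y, config)
        imp = peak_importance(r.model)
        assert imp.shape == (X_atac.n_features, Y.shape[1])
        assert np.all(imp >= 0)

    def test_peak_importance_requires_single_layer(self, rng):
        hybrid, G_atac, X_atac, merged, Y = _toy_training_setup(rng)
        config = ModelConfig(hidden_dim=8, epochs=2, seed=1)
        r = train(hybrid, G_atac, X_atac, merged, Y, config)
        with pytest.raises(ValueError, match="single-layer"):
            peak_importance(r.model)

    def test_softmax_columns_normalized(self, rng):
        hybrid, G_atac, X_atac, merged, Y = _toy_training_setup(rng)
        r = train(hybrid, G_atac, X_atac, merged, Y, ModelConfig(hidden_dim=8, epochs=5, seed=2))
        np.testing.assert_allclose(r.latent.Z_hat.sum(axis=1), 1.0, atol=1e-6)
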