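"""Sphere graph construction, graph convolution, pooling, and network heads."""

import numpy as np
import pytest
import scipy.sparse as sp

from pocketsphere.graph import SphereGraph, build_graph, build_graph_hierarchy
from pocketsphere.healpix import healpix_sampling
from pocketsphere.nn import (Adam, GraphConv, NetworkConfig, SphereCNN,
                             contrastive_loss, cross_entropy, load_weights,
                             pool, save_weights, softmax)


@pytest.fixture(scope="module")
def graph2(grid2):
    return build_graph(grid2, k=8)


class TestBuildGraph:
    def test_adjacency_structure(self, graph2):
        W = graph2.adjacency.toarray()
        np.testing.assert_allclose(W, W.T)
        np.testing.assert_allclose(np.diag(W), 0.0)
        assert (W >= 0).all()
        # union symmetrization: every row keeps at least k/2 neighbors
        assert (W > 0).sum(axis=1).min() >= 4

    def test_laplacian_psd_with_zero_row_sums(self, graph2):
        L = graph2.laplacian.toarray()
        assert np.abs(L.sum(axis=1)).max() < 1e-9
        eig = np.linalg.eigvalsh(L)
        assert eig[0] > -1e-9
        # constant vector is the null eigenvector
        np.testing.assert_allclose(L @ np.ones(len(L)), 0.0, atol=1e-9)

    def test_psd_at_nside4(self):
        g = build_graph(healpix_sampling(4), k=20)
        eig = np.linalg.eigvalsh(g.laplacian.toarray())
        assert eig[0] > -1e-9
        assert abs(eig[0]) < 1e-9  # smallest eigenvalue is 0

    def test_equal_distances_equal_weights(self, graph2):
        """Gaussian kernel is isotropic: equidistant neighbor pairs of one
        pixel carry equal weights."""
        W = graph2.adjacency.toarray()
        v = healpix_sampling(2).unit_vectors
        d = np.linalg.norm(v[0] - v, axis=1)
        nz = np.flatnonzero(W[0])
        for i in nz:
            for j in nz:
                if abs(d[i] - d[j]) < 1e-12:
                    assert abs(W[0, i] - W[0, j]) < 1e-12

    def test_matches_dense_knn_oracle(self, grid2):
        """Brute-force all-pairs kNN oracle (tie-aware: the symmetric grid has
        exactly tied neighbor distances): every strictly-inside-k pair must be
        an edge, every edge must be within the k-th-neighbor distance of one
        endpoint, and every edge weight equals the Gaussian kernel."""
        k = 8
        g = build_graph(grid2, k=k)
        W = g.adjacency.toarray()
        v = grid2.unit_vectors
        D = np.linalg.norm(v[:, None] - v[None], axis=2)
        np.fill_diagonal(D, np.inf)
        dk = np.sort(D, axis=1)[:, k - 1]  # k-th neighbor distance per pixel
        t = g.kernel_width
        n = len(v)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                if D[i, j] < min(dk[i], dk[j]) - 1e-12:
                    assert W[i, j] > 0
                if W[i, j] > 0:
                    assert D[i, j] <= max(dk[i], dk[j]) + 1e-12
                    np.testing.assert_allclose(
                        W[i, j], np.exp(-D[i, j] ** 2 / (4 * t)), atol=1e-12)

    def test_k_too_large_rejected(self, grid2):
        with pytest.raises(ValueError):
            build_graph(grid2, k=48)

    def test_hierarchy_schedule(self):
        graphs = build_graph_hierarchy(16, 4, k=20)
        assert [g.n_side for g in graphs] == [16, 8, 4, 2]
        assert all(g.adjacency.shape[0] == 12 * g.n_side**2 for g in graphs)


class TestGraphConv:
    def test_identity_filter(self, graph2):
        rng = np.random.default_rng(0)
        gc = GraphConv(graph2, 3, 3, K=3, rng=rng)
        coeffs = np.zeros((4, 3, 3))
        coeffs[0] = np.eye(3)
        gc.coeffs = coeffs
        x = rng.normal(size=(2, graph2.n_pix, 3))
        np.testing.assert_allclose(gc.forward(x), x, atol=1e-12)

    def test_two_vertex_hand_expansion(self):
        """L = [[w,-w],[-w,w]]; x=(1,0), a=(0,1,0,0) gives y = (w, -w)."""
        w = 0.7
        W = sp.csr_matrix(np.array([[0, w], [w, 0]]))
        L = sp.diags([w, w]) - W
        g = SphereGraph(n_side=1, adjacency=W, laplacian=L.tocsr(),
                        kernel_width=1.0)
        gc = GraphConv(g, 1, 1, K=3, rng=np.random.default_rng(0))
        coeffs = np.zeros((4, 1, 1))
        coeffs[1, 0, 0] = 1.0
        gc.coeffs = coeffs
        y = gc.forward(np.array([[[1.0], [0.0]]]))
        np.testing.assert_allclose(y[0, :, 0], [w, -w], atol=1e-12)

    def test_matches_dense_power_oracle(self, graph2):
        """Recursive sparse application equals explicit dense L^k powers."""
        rng = np.random.default_rng(1)
        gc = GraphConv(graph2, 4, 6, K=3, rng=rng)
        x = rng.normal(size=(3, graph2.n_pix, 4))
        y = gc.forward(x)
        L = graph2.laplacian.toarray()
        a = gc.coeffs
        y_oracle = np.zeros((3, graph2.n_pix, 6))
        Lk = np.eye(graph2.n_pix)
        for k in range(4):
            y_oracle += np.einsum("pq,bqi,io->bpo", Lk, x, a[k])
            Lk = Lk @ L
        np.testing.assert_allclose(y, y_oracle, atol=1e-10)

    def test_linearity(self, graph2):
        rng = np.random.default_rng(2)
        gc = GraphConv(graph2, 2, 3, K=3, rng=rng)
        x1 = rng.normal(size=(1, graph2.n_pix, 2))
        x2 = rng.normal(size=(1, graph2.n_pix, 2))
        lhs = gc.forward(2.5 * x1 - 1.3 * x2)
        rhs = 2.5 * gc.forward(x1) - 1.3 * gc.forward(x2)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_gradients_match_finite_differences(self, graph2):
        rng = np.random.default_rng(3)
        gc = GraphConv(graph2, 2, 2, K=2, rng=rng)
        x = rng.normal(size=(2, graph2.n_pix, 2))
        y = gc.forward(x, train=True)
        gy = rng.normal(size=y.shape)
        gc.grad_a[...] = 0.0
        gx = gc.backward(gy)
        eps = 1e-6
        for _ in range(5):
            k, i, o = (rng.integers(0, s) for s in gc.a.shape)
            old = gc.a[k, i, o]
            gc.a[k, i, o] = old + eps
            lp = (gc.forward(x) * gy).sum()
            gc.a[k, i, o] = old - eps
            lm = (gc.forward(x) * gy).sum()
            gc.a[k, i, o] = old
            np.testing.assert_allclose(gc.grad_a[k, i, o], (lp - lm) / (2 * eps),
                                       rtol=1e-5, atol=1e-7)
        b, p, c = 1, int(rng.integers(0, graph2.n_pix)), 1
        old = x[b, p, c]
        xp = x.copy(); xp[b, p, c] = old + eps
        xm = x.copy(); xm[b, p, c] = old - eps
        fd = ((gc.forward(xp) * gy).sum() - (gc.forward(xm) * gy).sum()) / (2 * eps)
        np.testing.assert_allclose(gx[b, p, c], fd, rtol=1e-5, atol=1e-7)


class TestPooling:
    def test_constant_signal_preserved(self):
        x = np.full((2, 48, 3), 2.7)
        np.testing.assert_allclose(pool(x), np.full((2, 12, 3), 2.7))

    def test_max_of_children(self):
        x = np.zeros((1, 4, 1))
        x[0, :, 0] = [1, 2, 3, 4]
        assert pool(x)[0, 0, 0] == 4.0

    def test_permutation_invariance_within_blocks(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(2, 16, 3))
        base = pool(x)
        for _ in range(10):
            xp = x.reshape(2, 4, 4, 3)[:, :, rng.permutation(4), :].reshape(2, 16, 3)
            np.testing.assert_allclose(pool(xp), base)

    def test_average_mode(self):
        x = np.arange(8, dtype=float).reshape(1, 8, 1)
        np.testing.assert_allclose(pool(x, mode="average")[0, :, 0], [1.5, 5.5])

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="nested"):
            pool(np.zeros((1, 48, 2)), ordering="ring")
        with pytest.raises(ValueError, match="divisible"):
            pool(np.zeros((1, 13, 2)))


@pytest.fixture(scope="module")
def tiny_model():
    """2-block classifier at n_side=4 (fast enough for repeated forwards)."""
    cfg = NetworkConfig(n_side=4, in_channels=9, channels=(8, 16),
                        head="classifier", n_classes=3)
    return SphereCNN(cfg, seed=0)


class TestForward:
    def test_classifier_probabilities_sum_to_one(self, tiny_model):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(4, 9, 192))
        p = tiny_model.forward(x)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert (p >= 0).all()

    def test_embedder_dimension(self):
        cfg = NetworkConfig(n_side=4, channels=(8, 16), head="embedder",
                            embed_dim=256)
        model = SphereCNN(cfg, seed=1)
        d = model.embed(np.random.default_rng(0).normal(size=(2, 9, 192)))
        assert d.shape == (2, 256)

    def test_full_architecture_shapes(self):
        """n_side 16 trunk pools 3072 -> 12 pixels before global pooling."""
        model = SphereCNN(NetworkConfig(head="embedder"), seed=0)
        assert [g.n_side for g in model.graphs] == [16, 8, 4, 2]
        d = model.embed(np.zeros((1, 9, 3072)))
        assert d.shape == (1, 256)

    def test_nan_input_names_layer(self, tiny_model):
        x = np.full((1, 9, 192), np.nan)
        with pytest.raises(FloatingPointError, match="GraphConv"):
            tiny_model.forward(x)

    def test_permutation_within_bottom_blocks_invariant(self, tiny_model):
        """Max pooling makes the output exactly invariant to permutations
        inside each 4-child block of the finest level."""
        rng = np.random.default_rng(6)
        x = rng.normal(size=(1, 192, 9))
        # degenerate conv: keep only k=0 term so features are pointwise
        for layer in tiny_model.layers:
            if isinstance(layer, GraphConv):
                c = layer.coeffs
                c[1:] = 0.0
                layer.coeffs = c
        perm = np.concatenate([4 * b + rng.permutation(4) for b in range(48)])
        p0 = tiny_model.forward(x.transpose(0, 2, 1))
        p1 = tiny_model.forward(x[:, perm].transpose(0, 2, 1))
        np.testing.assert_allclose(p0, p1, atol=1e-10)


class TestLossesAndHeads:
    def test_softmax_uniform_and_closed_form(self):
        np.testing.assert_allclose(softmax(np.zeros(3)), np.ones(3) / 3)
        np.testing.assert_allclose(softmax(np.array([np.log(2), 0, 0])),
                                   [0.5, 0.25, 0.25])

    def test_softmax_shift_invariance(self):
        z = np.array([1.0, -2.0, 0.5])
        np.testing.assert_allclose(softmax(z), softmax(z + 100.0), atol=1e-12)

    def test_cross_entropy_cases(self):
        y = np.array([[1.0, 0, 0]])
        assert cross_entropy(y, y) == pytest.approx(0.0, abs=1e-9)
        uniform = np.full((1, 3), 1 / 3)
        assert cross_entropy(uniform, y) == pytest.approx(np.log(3), abs=1e-9)
        with pytest.warns(UserWarning, match="clamp"):
            val = cross_entropy(np.array([[0.0, 1.0, 0.0]]), y)
        assert val > 0

    def test_contrastive_loss_cases(self):
        f = np.array([[1.0, 2.0, 3.0]])
        assert contrastive_loss(f, f, [1])[0] == pytest.approx(0.0)
        far = f + [[2.0, 0, 0]]
        assert contrastive_loss(f, far, [0], m=1.0)[0] == pytest.approx(0.0)
        near = f + [[0.5, 0, 0]]
        assert contrastive_loss(f, near, [0], m=1.0)[0] == pytest.approx(0.25)
        assert contrastive_loss(f, near, [1], m=1.0)[0] == pytest.approx(0.25)

    def test_contrastive_gradient_finite_difference(self):
        rng = np.random.default_rng(8)
        f1 = rng.normal(size=(3, 5))
        f2 = rng.normal(size=(3, 5))
        y = np.array([1, 0, 0])
        _, g1, _ = contrastive_loss(f1, f2, y)
        eps = 1e-6
        for i, j in [(0, 1), (1, 3), (2, 0)]:
            fp = f1.copy(); fp[i, j] += eps
            fm = f1.copy(); fm[i, j] -= eps
            fd = (contrastive_loss(fp, f2, y)[0]
                  - contrastive_loss(fm, f2, y)[0]) / (2 * eps)
            np.testing.assert_allclose(g1[i, j], fd, rtol=1e-5, atol=1e-8)


class TestTrainingMachinery:
    def test_adam_reduces_loss_on_tiny_problem(self, grid2):
        cfg = NetworkConfig(n_side=2, channels=(6,), head="classifier",
                            n_classes=2)
        model = SphereCNN(cfg, seed=3)
        opt = Adam(model, lr=0.01)
        rng = np.random.default_rng(9)
        x = rng.normal(size=(8, 48, 9))
        x[:4, :, 0] += 2.0
        y = np.eye(2)[[0] * 4 + [1] * 4]
        losses = []
        for _ in range(40):
            p = model.forward(x.transpose(0, 2, 1), train=True)
            losses.append(cross_entropy(p, y))
            model.zero_grad()
            model.backward((p - y) / len(y))
            opt.step()
        assert losses[-1] < 0.3 * losses[0]

    def test_weights_roundtrip(self, tmp_path):
        cfg = NetworkConfig(n_side=4, channels=(8, 16), head="embedder")
        model = SphereCNN(cfg, seed=4)
        x = np.random.default_rng(1).normal(size=(2, 9, 192))
        d0 = model.embed(x)
        save_weights(model, tmp_path / "w.zip")
        back = load_weights(tmp_path / "w.zip")
        np.testing.assert_allclose(back.embed(x), d0, atol=1e-12)


def test_descriptor_rotation_invariance_smoke(grid16):
    """Median relative descriptor change under input rotations stays small on
    a smooth synthetic pocket (full statistics live in the acceptance run)."""
    from pocketsphere.maps import random_rotation
    from pocketsphere.synth import make_smooth_pocket

    model = SphereCNN(NetworkConfig(head="embedder"), seed=0)
    pocket = make_smooth_pocket(seed=3)
    rng = np.random.default_rng(0)
    stack = [pocket.render().channels] + [
        pocket.render(random_rotation(rng)).channels for _ in range(8)]
    d = model.embed(np.stack(stack))
    rel = np.linalg.norm(d[1:] - d[0], axis=1) / np.linalg.norm(d[0])
    # loose smoke bound at 8 rotations; the 20x100 statistic is the real check
    assert np.median(rel) <= 0.10
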