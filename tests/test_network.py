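import numpy as np
import pytest
import scipy.sparse as sp

from stdual import network as net
from stdual.autodiff import Tensor


def _params(d_in, d_hid, d_out, seed=0):
    return net.ModelParams.init(d_in, d_hid, d_out, seed=seed)


def _identity_params(d):
    p = _params(d, d, d)
    p.W1.data = np.eye(d)
    p.W2.data = np.eye(d)
    p.b2.data = np.zeros((1, d))
    return p


class TestEncoder:
    def test_identity_configuration_passthrough(self, rng):
        X = rng.uniform(0.1, 2.0, (5, 3))
        p = _identity_params(3)
        I = np.eye(5)  # already-normalized adjacency (unit diagonal)
        E1, E2 = net.encode_views(X, I, I, p)
        np.testing.assert_allclose(E1, X)
        np.testing.assert_allclose(E2, X)

    def test_identical_views_identical_embeddings(self, rng):
        X = rng.uniform(size=(6, 4))
        A = sp.csr_matrix(np.triu(rng.integers(0, 2, (6, 6)), 1))
        A = A.maximum(A.T)
        p = _params(4, 8, 3)
        E1, E2 = net.encode_views(X, A, A, p)
        np.testing.assert_array_equal(E1, E2)

    def test_three_node_path_hand_computed(self):
        A = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], float)
        X = np.eye(3)  # one-hot features
        p = _params(3, 2, 2, seed=1)
        At = net.normalize_adjacency(A)
        H1 = np.maximum(At @ X @ p.W1.data, 0)
        expect = H1 @ p.W2.data + p.b2.data
        E1, _ = net.encode_views(X, A, A, p)
        np.testing.assert_allclose(E1, expect, atol=1e-12)

    def test_dimension_mismatch(self, rng):
        p = _params(4, 8, 3)
        with pytest.raises(ValueError, match="dimension-error"):
            net.encode_views(rng.uniform(size=(5, 7)), np.eye(5), np.eye(5), p)


class TestAttention:
    def test_equal_views_give_half_half(self, rng):
        E = rng.normal(size=(7, 4))
        p = _params(4, 8, 4)
        E_att, alpha = net.fuse_attention(E, E, p)
        np.testing.assert_allclose(alpha, 0.5)
        np.testing.assert_allclose(E_att, E)

    def test_alpha_simplex(self, rng):
        p = _params(4, 8, 4)
        _, alpha = net.fuse_attention(
            rng.normal(size=(10, 4)), rng.normal(size=(10, 4)), p
        )
        np.testing.assert_allclose(alpha.sum(axis=1), 1.0)
        assert np.all(alpha > 0) and np.all(alpha < 1)

    def test_single_spot_closed_form(self):
        d = 2
        p = _params(d, 2, d)
        p.W_omega.data = np.array([[1.0, 0.0], [0.0, 1.0]])
        p.u_omega.data = np.array([[1.0], [-1.0]])
        e1 = np.array([[0.5, 0.1]])
        e2 = np.array([[0.2, 0.8]])
        s1 = (np.tanh(e1) @ p.u_omega.data).item()
        s2 = (np.tanh(e2) @ p.u_omega.data).item()
        a1 = np.exp(s1) / (np.exp(s1) + np.exp(s2))
        E_att, alpha = net.fuse_attention(e1, e2, p)
        assert alpha[0, 0] == pytest.approx(a1, abs=1e-12)
        np.testing.assert_allclose(
            E_att, a1 * e1 + (1 - a1) * e2, atol=1e-12
        )

    def test_fused_row_on_segment_between_views(self, rng):
        E1 = rng.normal(size=(8, 3))
        E2 = rng.normal(size=(8, 3))
        p = _params(3, 4, 3, seed=2)
        E_att, alpha = net.fuse_attention(E1, E2, p)
        np.testing.assert_allclose(
            E_att, alpha[:, :1] * E1 + alpha[:, 1:] * E2, atol=1e-12
        )


class TestDecoder:
    def test_matrix_arithmetic_oracle(self, rng):
        # orthonormal weights, non-negative latent: ReLU is inactive
        from scipy.linalg import qr

        W1, _ = qr(rng.normal(size=(6, 6)))
        W2, _ = qr(rng.normal(size=(6, 6)))
        p = _params(6, 6, 6)
        p.W1.data, p.W2.data = W1, W2
        E = np.abs(rng.normal(size=(4, 6)))
        # make E @ W2.T non-negative by construction
        E = np.maximum(E @ W2, 0) @ np.linalg.inv(W2)
        X1, _, _ = net.decode_views(E, E, E, p)
        np.testing.assert_allclose(
            X1, np.maximum(E @ W2.T, 0) @ W1.T, atol=1e-10
        )

    def test_zero_embedding_zero_reconstruction(self):
        p = _params(4, 3, 2)
        X1, X2, X3 = net.decode_views(
            np.zeros((5, 2)), np.zeros((5, 2)), np.zeros((5, 2)), p
        )
        np.testing.assert_array_equal(X1, 0)

    def test_identical_inputs_identical_outputs(self, rng):
        p = _params(4, 3, 2)
        E = rng.normal(size=(5, 2))
        X1, X2, X3 = net.decode_views(E, E, E, p)
        np.testing.assert_array_equal(X1, X2)
        np.testing.assert_array_equal(X2, X3)


class TestSinkhorn:
    def test_marginal_errors_below_1e6_after_50_iters(self, rng):
        scores = rng.normal(size=(10, 3))
        Q = net.sinkhorn_normalize(scores, n_iters=50, epsilon=1.0)
        np.testing.assert_allclose(Q.sum(axis=1), 1 / 10, atol=1e-6)
        np.testing.assert_allclose(Q.sum(axis=0), 1 / 3, atol=1e-6)

    def test_uniform_scores_fixed_point(self):
        Q = net.sinkhorn_normalize(np.zeros((6, 3)), n_iters=5, epsilon=0.1)
        np.testing.assert_allclose(Q, 1 / 18, atol=1e-12)

    def test_large_epsilon_limit_uniform(self, rng):
        scores = rng.normal(size=(5, 4))
        Q = net.sinkhorn_normalize(scores, n_iters=50, epsilon=1e6)
        np.testing.assert_allclose(Q, 1 / 20, atol=1e-6)

    def test_nonfinite_scores_rejected(self):
        with pytest.raises(ValueError):
            net.sinkhorn_normalize(np.array([[np.inf, 0.0]]), 3, 0.05)


class TestSwav:
    def test_equal_views_equal_assignments(self, rng):
        E = rng.normal(size=(20, 5))
        Q1, Q2 = net.swav_assignments(E, E, E, n_prototypes=3, seed=0)
        np.testing.assert_array_equal(Q1, Q2)

    def test_two_blobs_recovered(self, rng):
        E = np.vstack(
            [rng.normal(size=(15, 4)) + 8, rng.normal(size=(15, 4)) - 8]
        )
        truth = np.repeat([0, 1], 15)
        Q1, _ = net.swav_assignments(E, E, E, n_prototypes=2, seed=0)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth, Q1.argmax(axis=1)) == 1.0

    def test_marginals_uniform(self, rng):
        E1, E2 = rng.normal(size=(12, 4)), rng.normal(size=(12, 4))
        Q1, Q2 = net.swav_assignments(
            E1, E2, (E1 + E2) / 2, n_prototypes=3, seed=0, sinkhorn_iters=60
        )
        np.testing.assert_allclose(Q1.sum(axis=1), 1 / 12, atol=1e-6)


class TestLosses:
    def test_perfect_reconstruction_zero(self, rng):
        X = rng.uniform(size=(6, 4))
        lb = net.compute_losses(
            X, [X, X, X], np.eye(6), np.eye(6),
            rng.normal(size=(6, 2)), np.full((6, 2), 0.5),
        )
        assert lb.recon == 0.0

    def test_balanced_attention_zero_penalty(self, rng):
        X = rng.uniform(size=(5, 3))
        lb = net.compute_losses(
            X, [X], np.eye(5), np.eye(5),
            rng.normal(size=(5, 2)), np.full((5, 2), 0.5),
        )
        assert lb.att == 0.0

    def test_identical_assignments_zero_swav(self, rng):
        X = rng.uniform(size=(5, 3))
        Q = np.abs(rng.normal(size=(5, 3)))
        Q /= Q.sum()
        lb = net.compute_losses(
            X, [X], np.eye(5), np.eye(5),
            rng.normal(size=(5, 2)), np.full((5, 2), 0.5), Q, Q,
        )
        assert lb.swav == pytest.approx(0.0, abs=1e-12)

    def test_total_linear_in_lambdas(self, rng):
        X = rng.uniform(size=(5, 3))
        Xr = rng.uniform(size=(5, 3))
        E = rng.normal(size=(5, 2))
        alpha = rng.uniform(0.2, 0.8, (5, 2))
        Q1 = np.abs(rng.normal(size=(5, 2)))
        Q1 /= Q1.sum()
        Q2 = np.abs(rng.normal(size=(5, 2)))
        Q2 /= Q2.sum()
        A = np.eye(5)
        lb1 = net.compute_losses(X, [Xr], A, A, E, alpha, Q1, Q2, (1, 0, 0, 0))
        lb2 = net.compute_losses(X, [Xr], A, A, E, alpha, Q1, Q2, (0, 1, 0, 0))
        lb3 = net.compute_losses(X, [Xr], A, A, E, alpha, Q1, Q2, (0, 0, 1, 0))
        lb4 = net.compute_losses(X, [Xr], A, A, E, alpha, Q1, Q2, (0, 0, 0, 1))
        mixed = net.compute_losses(X, [Xr], A, A, E, alpha, Q1, Q2, (2, 3, 4, 5))
        assert mixed.total == pytest.approx(
            2 * lb1.total + 3 * lb2.total + 4 * lb3.total + 5 * lb4.total
        )

    def test_components_nonnegative(self, rng):
        X = rng.uniform(size=(6, 3))
        lb = net.compute_losses(
            X, [rng.uniform(size=(6, 3))], np.eye(6), np.eye(6),
            rng.normal(size=(6, 2)), rng.uniform(0.1, 0.9, (6, 2)),
        )
        assert lb.recon >= 0 and lb.graph >= 0 and lb.att >= 0


class TestGraphTerm:
    def test_bce_decreases_when_connected_pairs_more_similar(self):
        """On a 4-node toy, raising the embedding similarity of connected
        pairs (holding everything else fixed) lowers the graph loss."""
        A = np.array(
            [[0, 1, 0, 0], [1, 0, 0, 0], [0, 0, 0, 1], [0, 0, 1, 0]], float
        )
        E_far = np.array([[1.0, 0], [-1.0, 0], [0, 1.0], [0, -1.0]])
        E_near = np.array([[1.0, 0], [1.0, 0], [0, 1.0], [0, 1.0]])
        X = np.zeros((4, 2))
        lb_far = net.compute_losses(X, [X], A, A, E_far, np.full((4, 2), 0.5))
        lb_near = net.compute_losses(X, [X], A, A, E_near, np.full((4, 2), 0.5))
        assert lb_near.graph < lb_far.graph


class TestTraining:
    def _tiny(self, rng, n=40, g=12):
        X = rng.uniform(0, 2, (n, g))
        coords = rng.uniform(0, 10, (n, 2))
        from stdual.graphs import build_spatial_graph

        A1 = build_spatial_graph(coords, k=3)
        A2 = build_spatial_graph(coords[::-1], k=3)
        return X, A1, A2

    def test_loss_decreases(self, rng):
        X, A1, A2 = self._tiny(rng)
        cfg = net.TrainConfig(d_hid=16, d_out=8, epochs=80, seed=0)
        _, _, hist = net.train_model(X, A1, A2, cfg, n_clusters=3)
        assert hist[-1].total < hist[0].total

    def test_identical_graphs_keep_views_identical(self, rng):
        X, A1, _ = self._tiny(rng)
        cfg = net.TrainConfig(
            d_hid=16, d_out=8, epochs=30, seed=0, lambdas=(10, 10, 0, 1)
        )
        _, emb, _ = net.train_model(X, A1, A1, cfg, n_clusters=2)
        np.testing.assert_allclose(emb.E_v1, emb.E_v2, atol=1e-12)

    def test_bitwise_deterministic_history(self, rng):
        X, A1, A2 = self._tiny(rng, n=30)
        cfg = net.TrainConfig(d_hid=8, d_out=4, epochs=40, seed=3)
        _, _, h1 = net.train_model(X, A1, A2, cfg, n_clusters=2)
        _, _, h2 = net.train_model(X, A1, A2, cfg, n_clusters=2)
        assert [l.total for l in h1] == [l.total for l in h2]

    def test_single_view_alpha_pinned(self, rng):
        X, A1, _ = self._tiny(rng, n=25)
        cfg = net.TrainConfig(d_hid=8, d_out=4, epochs=20, seed=0, dual_view=False)
        _, emb, _ = net.train_model(X, A1, None, cfg)
        np.testing.assert_array_equal(emb.alpha[:, 0], 1.0)
        np.testing.assert_array_equal(emb.E_att, emb.E_v1)
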