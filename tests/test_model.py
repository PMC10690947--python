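"""Forward pass, exact gradients, and training dynamics of the classifier."""

import numpy as np
import pytest

from gfacnn.graph import GraphSample, NormalizedAdjacency
from gfacnn.model import (
    ArchConfig, ClassScores, ModelParams, forward, forward_batch, gcn_layer,
    gradients, init_params, load_params, logistic, mse_loss, one_hot,
    save_params, sgd_step,
)
from gfacnn.spectral import AttentionVector


def sym(rng, n):
    A = rng.normal(size=(n, n))
    return (A + A.T) / 2


def make_graph_sample(X, A, label=None):
    n = A.shape[0]
    return GraphSample(
        X=X,
        adjacency=NormalizedAdjacency(A_tilde=A, D_tilde=np.ones(n), A_hat=A),
        attention=AttentionVector(np.ones(n), tuple(str(i) for i in range(n))),
        label=label,
    )


def forward_reference(X, A, params):
    """Straight-line single-sample reimplementation: explicit loops, no
    reuse of the library's batched path."""
    act = {"relu": lambda z: max(z, 0.0),
           "tanh": np.tanh,
           "identity": lambda z: z}[params.arch.activation]
    H = X
    for W in params.gcn_weights:
        agg = np.zeros((A.shape[0], H.shape[1]))
        for i in range(A.shape[0]):
            for j in range(A.shape[1]):
                agg[i] += A[i, j] * H[j]
        Z = np.zeros((agg.shape[0], W.shape[1]))
        for i in range(agg.shape[0]):
            for k in range(W.shape[1]):
                Z[i, k] = sum(agg[i, t] * W[t, k] for t in range(W.shape[0]))
        H = np.vectorize(act)(Z)
    if params.arch.readout == "flatten":
        a = H.reshape(-1)
    else:
        a = H.mean(axis=0)
    for l, (W, b) in enumerate(zip(params.dense_W, params.dense_b)):
        z = np.array([sum(a[t] * W[t, k] for t in range(W.shape[0])) + b[k]
                      for k in range(W.shape[1])])
        if l < len(params.dense_W) - 1:
            a = np.vectorize(act)(z)
        else:
            a = 1.0 / (1.0 + np.exp(-z))
    return a


class TestInit:
    def test_same_seed_bitwise_identical(self, tiny_arch):
        p1 = init_params(tiny_arch, 3)
        p2 = init_params(tiny_arch, 3)
        np.testing.assert_array_equal(p1.to_vector(), p2.to_vector())

    def test_different_seed_differs(self, tiny_arch):
        assert not np.array_equal(init_params(tiny_arch, 3).to_vector(),
                                  init_params(tiny_arch, 4).to_vector())

    def test_default_architecture_shapes(self):
        """Raw 1024-sample features over 19 nodes: GCN 1024->64->32, dense
        hourglass (19*32)->128->32->128->2."""
        arch = ArchConfig()
        p = init_params(arch, 0)
        assert [w.shape for w in p.gcn_weights] == [(1024, 64), (64, 32)]
        assert [w.shape for w in p.dense_W] == [
            (19 * 32, 128), (128, 32), (32, 128), (128, 2)]
        assert all((b == 0).all() for b in p.dense_b)

    def test_vector_round_trip(self, tiny_params):
        vec = tiny_params.to_vector()
        back = tiny_params.from_vector(vec)
        np.testing.assert_array_equal(back.to_vector(), vec)


class TestGcnLayer:
    def test_identity_propagation(self, rng):
        H = rng.normal(size=(4, 3))
        out = gcn_layer(H, np.eye(4), np.eye(3), sigma="identity")
        np.testing.assert_allclose(out, H, atol=1e-14)

    def test_matches_triple_loop_oracle(self, rng):
        for _ in range(50):
            A = sym(rng, 5)
            H = rng.normal(size=(5, 3))
            W = rng.normal(size=(3, 4))
            out = gcn_layer(H, A, W, sigma="relu")
            # explicit aggregate -> weight -> activate loops
            expected = np.zeros((5, 4))
            for i in range(5):
                for k in range(4):
                    acc = 0.0
                    for j in range(5):
                        for t in range(3):
                            acc += A[i, j] * H[j, t] * W[t, k]
                    expected[i, k] = max(acc, 0.0)
            np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_permutation_equivariance(self, rng):
        for _ in range(20):
            A = sym(rng, 5)
            H = rng.normal(size=(5, 3))
            W = rng.normal(size=(3, 4))
            perm = rng.permutation(5)
            P = np.eye(5)[perm]
            lhs = gcn_layer(P @ H, P @ A @ P.T, W)
            rhs = P @ gcn_layer(H, A, W)
            np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            gcn_layer(rng.normal(size=(4, 3)), np.eye(4),
                      rng.normal(size=(5, 2)))


class TestForward:
    def test_zero_weights_give_half_scores(self, tiny_params, rng):
        p = tiny_params.from_vector(np.zeros(tiny_params.to_vector().size))
        sample = make_graph_sample(rng.normal(size=(3, 4)), sym(rng, 3))
        scores, _ = forward(sample, p)
        np.testing.assert_array_equal(scores.values, 0.5)

    def test_matches_straight_line_reference(self, tiny_params, rng):
        X = rng.normal(size=(3, 4))
        A = sym(rng, 3)
        scores, _ = forward(make_graph_sample(X, A), tiny_params)
        np.testing.assert_allclose(scores.values,
                                   forward_reference(X, A, tiny_params),
                                   atol=1e-10)

    def test_deterministic(self, tiny_params, rng):
        sample = make_graph_sample(rng.normal(size=(3, 4)), sym(rng, 3))
        s1, _ = forward(sample, tiny_params)
        s2, _ = forward(sample, tiny_params)
        np.testing.assert_array_equal(s1.values, s2.values)

    def test_tie_breaks_toward_responsive(self):
        assert ClassScores(np.array([0.5, 0.5])).predicted_label == "responsive"
        assert ClassScores(np.array([0.2, 0.7])).predicted_label == "resistant"

    def test_batch_agrees_with_single(self, tiny_params, rng):
        X = rng.normal(size=(4, 3, 4))
        A = np.stack([sym(rng, 3) for _ in range(4)])
        batch = forward_batch(X, A, tiny_params).scores
        for b in range(4):
            single, _ = forward(make_graph_sample(X[b], A[b]), tiny_params)
            np.testing.assert_allclose(single.values, batch[b], atol=1e-12)


class TestGradients:
    def test_zero_at_mse_minimum(self, tiny_params, rng):
        """When targets equal the model's own scores the MSE is at its
        minimum and every gradient vanishes."""
        X = rng.normal(size=(2, 3, 4))
        A = np.stack([sym(rng, 3) for _ in range(2)])
        scores = forward_batch(X, A, tiny_params).scores
        grads, loss = gradients((X, A), scores, tiny_params)
        assert loss == 0.0
        np.testing.assert_array_equal(grads.to_vector(), 0.0)

    def test_central_difference_check(self, tiny_params):
        # generic-position input: central differences are only valid away
        # from ReLU kinks, so guard that no pre-activation sits at zero
        r = np.random.default_rng(2)
        X = r.normal(size=(2, 3, 4))
        A = np.stack([sym(r, 3) for _ in range(2)])
        cache = forward_batch(X, A, tiny_params)
        assert min(np.abs(z).min()
                   for z in cache.Z_gcn + cache.dense_Z[:-1]) > 1e-4
        targets = one_hot(["responsive", "resistant"])
        grads, _ = gradients((X, A), targets, tiny_params)
        gvec = grads.to_vector()
        vec = tiny_params.to_vector()
        h = 1e-5
        num = np.empty_like(vec)
        for i in range(vec.size):
            e = np.zeros_like(vec)
            e[i] = h
            lp = mse_loss(forward_batch(
                X, A, tiny_params.from_vector(vec + e)).scores, targets)
            lm = mse_loss(forward_batch(
                X, A, tiny_params.from_vector(vec - e)).scores, targets)
            num[i] = (lp - lm) / (2 * h)
        mask = np.abs(num) > 1e-10
        rel = np.abs(gvec[mask] - num[mask]) / np.abs(num[mask])
        assert rel.max() <= 1e-4

    def test_duplicated_sample_matches_single(self, tiny_params, rng):
        X1 = rng.normal(size=(1, 3, 4))
        A1 = sym(rng, 3)[None]
        t1 = one_hot(["responsive"])
        g1, _ = gradients((X1, A1), t1, tiny_params)
        k = 5
        gk, _ = gradients((np.repeat(X1, k, 0), np.repeat(A1, k, 0)),
                          np.repeat(t1, k, 0), tiny_params)
        np.testing.assert_allclose(gk.to_vector(), g1.to_vector(), atol=1e-12)

    def test_bad_target_shape_rejected(self, tiny_params, rng):
        with pytest.raises(ValueError, match="targets"):
            gradients((rng.normal(size=(1, 3, 4)), sym(rng, 3)[None]),
                      np.zeros((1, 3)), tiny_params)

    def test_loss_decreases_over_first_sgd_steps(self, tiny_params, rng):
        """Five SGD steps at lr 0.01 on a fixed separable toy batch must
        monotonically reduce the training loss."""
        X = np.concatenate([rng.normal(0, 0.5, (5, 3, 4)),
                            rng.normal(0, 2.5, (5, 3, 4))])
        A = np.stack([sym(rng, 3) for _ in range(10)])
        targets = one_hot(["responsive"] * 5 + ["resistant"] * 5)
        p = tiny_params.copy()
        losses = []
        for _ in range(6):
            grads, loss = gradients((X, A), targets, p)
            losses.append(loss)
            sgd_step(p, grads, lr=0.01)
        assert all(l2 < l1 for l1, l2 in zip(losses, losses[1:]))


class TestNodePermutation:
    def test_scores_invariant_under_matched_permutation(self, tiny_params, rng):
        """Permuting nodes together with the matching block permutation of
        the first dense layer's rows leaves the scores unchanged."""
        X = rng.normal(size=(3, 4))
        A = sym(rng, 3)
        perm = np.array([2, 0, 1])
        P = np.eye(3)[perm]
        p2 = tiny_params.copy()
        k = tiny_params.arch.gcn_dims[-1]
        rows = np.concatenate([np.arange(i * k, (i + 1) * k) for i in perm])
        p2.dense_W[0] = tiny_params.dense_W[0][rows]
        s1, _ = forward(make_graph_sample(X, A), tiny_params)
        s2, _ = forward(make_graph_sample(P @ X, P @ A @ P.T), p2)
        np.testing.assert_allclose(s1.values, s2.values, atol=1e-10)


class TestPersistence:
    def test_save_load_round_trip(self, tiny_params, tmp_path):
        path = tmp_path / "model.npz"
        save_params(tiny_params, path)
        back = load_params(path)
        np.testing.assert_array_equal(back.to_vector(),
                                      tiny_params.to_vector())
        assert back.arch.gcn_dims == tiny_params.arch.gcn_dims
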