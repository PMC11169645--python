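"""Adaptive graph learning: adjacency, regularizer, GCN, connectivity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from astnet.adaptive_graph import (
    AglParameters,
    GcnStack,
    adaptive_adjacency,
    adjacency_tensor,
    connectivity_matrix,
    gcn_forward,
    graph_learning_loss,
    graph_loss_tensor,
    vectorize_upper,
)
from astnet.autodiff import Tensor

from _oracles import (
    adjacency_oracle,
    connectivity_oracle,
    gcn_layer_oracle,
    graph_loss_oracle,
)

THREE_NODE_SEGMENT = np.array([[1.0, 0.0], [0.0, 0.0], [2.0, 2.0]])
THREE_NODE_OMEGA = np.array([1.0, 1.0])


class TestAdaptiveAdjacency:
    def test_zero_omega_gives_exact_uniform(self, rng):
        seg = rng.normal(size=(4, 7))
        adj = adaptive_adjacency(seg, AglParameters(omega=np.zeros(7)))
        np.testing.assert_array_equal(adj.values, np.full((4, 4), 0.25))

    def test_identical_rows_give_uniform(self, rng):
        row = rng.normal(size=9)
        seg = np.tile(row, (5, 1))
        adj = adaptive_adjacency(seg, AglParameters(omega=rng.normal(size=9)))
        np.testing.assert_allclose(adj.values, np.full((5, 5), 0.2), atol=1e-12)

    def test_three_node_instance_matches_scalar_oracle(self):
        adj = adaptive_adjacency(
            THREE_NODE_SEGMENT, AglParameters(omega=THREE_NODE_OMEGA)
        )
        expected = adjacency_oracle(THREE_NODE_SEGMENT, THREE_NODE_OMEGA)
        np.testing.assert_allclose(adj.values, expected, atol=1e-8)

    def test_dimension_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="omega length"):
            adaptive_adjacency(rng.normal(size=(3, 5)),
                               AglParameters(omega=np.ones(4)))

    def test_random_instances_match_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 6))
            length = int(rng.integers(1, 6))
            seg = rng.normal(size=(n, length))
            omega = rng.normal(size=length)
            got = adaptive_adjacency(seg, AglParameters(omega=omega)).values
            np.testing.assert_allclose(
                got, adjacency_oracle(seg, omega), atol=1e-8
            )

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_rows_always_stochastic_and_positive(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(2, 12))
        length = int(r.integers(1, 30))
        seg = r.normal(scale=float(r.uniform(0.1, 5.0)), size=(n, length))
        adj = adaptive_adjacency(seg, AglParameters(omega=r.normal(size=length)))
        assert np.all(adj.values > 0)
        np.testing.assert_allclose(adj.values.sum(axis=1), 1.0, atol=1e-6)


class TestGraphLearningLoss:
    def test_identical_features_zero_lambda(self):
        seg = np.ones((4, 3))
        adj = adaptive_adjacency(seg, AglParameters(omega=np.zeros(3)))
        assert graph_learning_loss(seg, adj, 0.0) == 0.0

    def test_identical_features_uniform_adjacency_unit_lambda(self):
        # ||A||_F^2 of the uniform 4x4 matrix is 16 * (1/16) = 1
        seg = np.ones((4, 3))
        adj = adaptive_adjacency(seg, AglParameters(omega=np.zeros(3)))
        assert graph_learning_loss(seg, adj, 1.0) == pytest.approx(1.0, abs=1e-12)

    def test_three_node_instance_matches_oracle(self):
        adj = adaptive_adjacency(
            THREE_NODE_SEGMENT, AglParameters(omega=THREE_NODE_OMEGA)
        )
        got = graph_learning_loss(THREE_NODE_SEGMENT, adj, 0.5)
        expected = graph_loss_oracle(THREE_NODE_SEGMENT, adj.values, 0.5)
        assert got == pytest.approx(expected, abs=1e-8)

    def test_negative_lambda_raises(self):
        with pytest.raises(ValueError):
            graph_learning_loss(np.ones((3, 2)), np.full((3, 3), 1 / 3), -0.1)

    def test_random_instances_match_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 6))
            seg = rng.normal(size=(n, int(rng.integers(1, 5))))
            a = rng.uniform(size=(n, n))
            lam = float(rng.uniform(0, 2))
            assert graph_learning_loss(seg, a, lam) == pytest.approx(
                graph_loss_oracle(seg, a, lam), abs=1e-8
            )

    def test_scaling_distances_up_increases_smoothness_term(self, rng):
        seg = rng.normal(size=(5, 4))
        a = np.full((5, 5), 0.2)
        base = graph_learning_loss(seg, a, 0.0)
        scaled = graph_learning_loss(2.0 * seg, a, 0.0)
        assert scaled > base

    def test_omega_gradient_matches_finite_differences(self, rng):
        seg = rng.normal(size=(4, 3))
        omega0 = rng.normal(size=3)

        def loss_of(omega_arr):
            a = adjacency_tensor(Tensor(seg), Tensor(omega_arr))
            return float(graph_loss_tensor(seg, a, 0.01).data)

        omega = Tensor(omega0, requires_grad=True)
        graph_loss_tensor(seg, adjacency_tensor(Tensor(seg), omega), 0.01).backward()
        eps = 1e-6
        for i in range(3):
            up, dn = omega0.copy(), omega0.copy()
            up[i] += eps
            dn[i] -= eps
            num = (loss_of(up) - loss_of(dn)) / (2 * eps)
            assert omega.grad[i] == pytest.approx(num, rel=1e-4, abs=1e-8)


class TestGcnForward:
    def test_identity_fixed_point(self):
        stack = GcnStack(in_dim=3, hidden_dims=[3], dropout_rate=0.0,
                         use_batch_norm=False, activation="identity")
        stack.layer_weights[0].data = np.eye(3)
        x = np.arange(12, dtype=float).reshape(4, 3)
        out = gcn_forward(x, np.eye(4), stack)
        np.testing.assert_allclose(out, x)

    def test_uniform_adjacency_averages_rows(self, rng):
        stack = GcnStack(in_dim=3, hidden_dims=[3], dropout_rate=0.0,
                         use_batch_norm=False, activation="identity")
        stack.layer_weights[0].data = np.eye(3)
        x = rng.normal(size=(5, 3))
        out = gcn_forward(x, np.full((5, 5), 0.2), stack)
        np.testing.assert_allclose(out, np.tile(x.mean(axis=0), (5, 1)))

    def test_matches_loop_oracle_random_instances(self, rng):
        for _ in range(100):
            n, fin, fout = (int(rng.integers(2, 5)) for _ in range(3))
            stack = GcnStack(in_dim=fin, hidden_dims=[fout], dropout_rate=0.0,
                             use_batch_norm=False, activation="relu")
            w = rng.normal(size=(fin, fout))
            stack.layer_weights[0].data = w
            x = rng.normal(size=(n, fin))
            a = rng.uniform(size=(n, n))
            np.testing.assert_allclose(
                gcn_forward(x, a, stack), gcn_layer_oracle(a, x, w), atol=1e-6
            )

    def test_dimension_mismatch_raises(self, rng):
        stack = GcnStack(in_dim=4, hidden_dims=[2], use_batch_norm=False)
        with pytest.raises(ValueError, match="feature dim"):
            gcn_forward(rng.normal(size=(3, 5)), np.eye(3), stack)

    def test_eval_mode_deterministic_train_mode_stochastic(self, rng):
        stack = GcnStack(in_dim=4, hidden_dims=[8, 4], dropout_rate=0.5,
                         use_batch_norm=True)
        x = rng.normal(size=(5, 4))
        a = np.full((5, 5), 0.2)
        out1 = gcn_forward(x, a, stack)
        out2 = gcn_forward(x, a, stack)
        np.testing.assert_array_equal(out1, out2)
        t1 = gcn_forward(x, a, stack, training_mode=True,
                         rng=np.random.default_rng(0))
        t2 = gcn_forward(x, a, stack, training_mode=True,
                         rng=np.random.default_rng(1))
        assert not np.array_equal(t1, t2)


class TestConnectivity:
    def test_orthonormal_rows_give_identity(self):
        h = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        np.testing.assert_allclose(connectivity_matrix(h).values, np.eye(2))

    def test_zeros_give_zero_matrix(self):
        np.testing.assert_array_equal(
            connectivity_matrix(np.zeros((3, 4))).values, np.zeros((3, 3))
        )

    def test_random_matches_oracle_and_is_psd(self, rng):
        for _ in range(100):
            h = rng.normal(size=(5, 3))
            s = connectivity_matrix(h).values
            np.testing.assert_allclose(s, connectivity_oracle(h), atol=1e-8)
            np.testing.assert_allclose(s, s.T, atol=1e-12)
            assert np.linalg.eigvalsh(s).min() >= -1e-10


class TestVectorizeUpper:
    def test_stated_three_node_order(self):
        s = np.array([[1, 2, 3], [2, 4, 5], [3, 5, 6]], dtype=float)
        np.testing.assert_array_equal(vectorize_upper(s), [2, 3, 5])

    def test_lengths(self):
        assert vectorize_upper(np.zeros((116, 116))).shape == (6670,)
        assert vectorize_upper(np.zeros((2, 2))).shape == (1,)

    def test_reconstruction_roundtrip(self, rng):
        n = 7
        h = rng.normal(size=(n, 3))
        s = h @ h.T
        v = vectorize_upper(s)
        rebuilt = np.zeros((n, n))
        rebuilt[np.triu_indices(n, 1)] = v
        rebuilt = rebuilt + rebuilt.T
        np.testing.assert_allclose(rebuilt, s - np.diag(np.diag(s)), atol=1e-12)

    def test_non_square_raises(self):
        with pytest.raises(ValueError, match="square"):
            vectorize_upper(np.zeros((3, 4)))
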