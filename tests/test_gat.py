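"""Graph-attention encoder: attention normalization, loop-based reference,
equivariance, and determinism."""

import numpy as np
import pytest

from modilm._autodiff import constant
from modilm import gat
from modilm.graph import SimilarityGraph


def reference_gat_layer(H, support, params, att_slope=0.2, act_slope=0.01):
    """Loop-based reference: per-head attention softmax over neighbors,
    aggregation, head concatenation, LeakyReLU."""

    def leaky(x, s):
        return np.where(x > 0, x, s * x)

    n = H.shape[0]
    heads = []
    for m in range(params.n_heads):
        W = params.W.data[m]
        a = np.concatenate([params.a_src.data[m][:, 0], params.a_dst.data[m][:, 0]])
        HW = H @ W
        out = np.zeros((n, W.shape[1]))
        for i in range(n):
            nbrs = [j for j in range(n) if support[i, j]]
            logits = np.array([
                leaky(a @ np.concatenate([HW[i], HW[j]]), att_slope) for j in nbrs
            ])
            e = np.exp(logits - logits.max())
            alpha = e / e.sum()
            out[i] = sum(al * HW[j] for al, j in zip(alpha, nbrs))
        heads.append(out)
    return leaky(np.concatenate(heads, axis=1), act_slope)


def random_support(rng, n, p_edge=0.4):
    A = rng.random((n, n)) < p_edge
    A = np.triu(A, 1)
    support = A | A.T | np.eye(n, dtype=bool)
    return support


class TestAttentionWeights:
    def test_rows_sum_to_one_over_support_all_layers_and_heads(self, rng):
        for _ in range(5):
            n = int(rng.integers(5, 20))
            support = random_support(rng, n)
            H = constant(rng.standard_normal((n, 6)))
            params = gat.GATLayerParams.init(rng, 6, 4, n_heads=3)
            alpha, _ = gat.attention_weights(H, params, support)
            sums = alpha.data.sum(axis=-1)
            assert np.allclose(sums, 1.0, atol=1e-6)
            assert (alpha.data[:, ~support] == 0).all()

    def test_isolated_node_attends_only_to_itself(self, rng):
        support = np.eye(4, dtype=bool)
        H = constant(rng.standard_normal((4, 3)))
        params = gat.GATLayerParams.init(rng, 3, 2, n_heads=2)
        alpha, _ = gat.attention_weights(H, params, support)
        np.testing.assert_allclose(alpha.data.diagonal(axis1=1, axis2=2), 1.0)

    def test_identical_logits_share_attention_equally(self):
        # node 0 linked to two neighbors with identical features
        support = np.eye(3, dtype=bool)
        support[0, :] = True
        support[:, 0] = True
        H = constant(np.ones((3, 2)))
        rng = np.random.default_rng(0)
        params = gat.GATLayerParams.init(rng, 2, 2, n_heads=1)
        alpha, _ = gat.attention_weights(H, params, support)
        np.testing.assert_allclose(alpha.data[0, 0], [1 / 3, 1 / 3, 1 / 3], atol=1e-12)

    def test_missing_self_loop_is_an_error(self, rng):
        support = np.zeros((3, 3), dtype=bool)
        H = constant(rng.standard_normal((3, 2)))
        params = gat.GATLayerParams.init(rng, 2, 2, n_heads=1)
        with pytest.raises(ValueError, match="self-loop"):
            gat.attention_weights(H, params, support)


class TestGATLayer:
    @pytest.mark.parametrize("trial", range(3))
    def test_matches_loop_reference_on_small_graphs(self, rng, trial):
        n = 5
        support = random_support(rng, n)
        H = rng.standard_normal((n, 4))
        params = gat.GATLayerParams.init(rng, 4, 3, n_heads=2)
        out = gat.gat_layer(constant(H), support, params)
        ref = reference_gat_layer(H, support, params)
        np.testing.assert_allclose(out.data, ref, atol=1e-6)

    def test_identity_support_is_a_per_node_transform(self, rng):
        support = np.eye(6, dtype=bool)
        H = rng.standard_normal((6, 4))
        params = gat.GATLayerParams.init(rng, 4, 3, n_heads=2)
        out = gat.gat_layer(constant(H), support, params).data
        # alpha_ii = 1: h'_i = LeakyReLU(concat_m(W_m^T h_i))
        expected = np.concatenate([H @ params.W.data[m] for m in range(2)], axis=1)
        expected = np.where(expected > 0, expected, 0.01 * expected)
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_identical_connected_nodes_get_identical_outputs(self, rng):
        support = np.ones((2, 2), dtype=bool)
        H = np.tile(rng.standard_normal(3), (2, 1))
        params = gat.GATLayerParams.init(rng, 3, 2, n_heads=2)
        out = gat.gat_layer(constant(H), support, params).data
        np.testing.assert_allclose(out[0], out[1], atol=1e-12)


class TestEncoder:
    def _toy_graph(self, rng, n=12, d=6, k=3):
        X = rng.standard_normal((n, d))
        return X, SimilarityGraph.from_matrix(X, k=k)

    def test_permutation_equivariance(self, rng):
        X, graph = self._toy_graph(rng)
        stack = gat.init_stack(rng, X.shape[1], (4, 3), n_heads=2)
        out = gat.encode(X, graph, stack).data
        perm = rng.permutation(X.shape[0])
        graph_p = SimilarityGraph.from_matrix(X[perm], k=3)
        out_p = gat.encode(X[perm], graph_p, stack).data
        np.testing.assert_allclose(out_p, out[perm], atol=1e-8)

    def test_zero_graph_means_no_cross_sample_mixing(self, rng):
        X, graph = self._toy_graph(rng)
        empty = SimilarityGraph(S=graph.S, theta=2.0, k=1,
                                A=np.zeros_like(graph.A),
                                A_norm=np.eye(graph.n_nodes))
        stack = gat.init_stack(rng, X.shape[1], (4, 3), n_heads=2)
        base = gat.encode(X, empty, stack).data
        X2 = X.copy()
        X2[0] += 10.0  # perturb one sample
        out2 = gat.encode(X2, empty, stack).data
        np.testing.assert_allclose(out2[1:], base[1:], atol=1e-10)

    def test_pure_gat_flag_changes_only_the_smoothing(self, rng):
        X, graph = self._toy_graph(rng)
        stack = gat.init_stack(rng, X.shape[1], (4, 3), n_heads=2)
        smoothed = gat.encode(X, graph, stack, pure_gat=False).data
        pure = gat.encode(X, graph, stack, pure_gat=True).data
        assert smoothed.shape == pure.shape
        assert not np.allclose(smoothed, pure)

    def test_deterministic_given_seed(self):
        rng1 = np.random.default_rng(42)
        rng2 = np.random.default_rng(42)
        X = np.random.default_rng(0).standard_normal((10, 5))
        graph = SimilarityGraph.from_matrix(X, k=3)
        out1 = gat.encode(X, graph, gat.init_stack(rng1, 5, (4, 2), 2)).data
        out2 = gat.encode(X, graph, gat.init_stack(rng2, 5, (4, 2), 2)).data
        np.testing.assert_array_equal(out1, out2)

    def test_empty_stack_is_an_error(self, rng):
        X, graph = self._toy_graph(rng)
        with pytest.raises(ValueError, match="at least one"):
            gat.encode(X, graph, [])
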