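"""k-NN spot graph construction and graph-attention refinement."""

import numpy as np
import pytest

from histoexpr.autograd import Tensor
from histoexpr.spatial_gat import (GATParams, GATStage, aggregate,
                                   build_knn_graph, edge_scores,
                                   normalize_attention, update_embedding)


class TestKNNGraph:
    def test_3_4_5_triangle_distance(self):
        g = build_knn_graph(np.array([[0.0, 0.0], [3.0, 4.0]]), k=4)
        assert g.distances[0, 0] == pytest.approx(5.0)
        assert g.neighbors[0, 0] == 1 and g.neighbors[1, 0] == 0

    def test_collinear_spots_complete_graph(self):
        pts = np.array([[x, 0.0] for x in range(5)])
        g = build_knn_graph(pts, k=4)
        for i in range(5):
            assert set(g.neighbors[i]) == set(range(5)) - {i}
            assert g.distances[i].min() > 0

    def test_out_degree_min_k_nminus1(self):
        pts = np.array([[0.0, 0], [1, 0], [0, 1]])
        g = build_knn_graph(pts, k=4)
        assert g.neighbors.shape == (3, 2)     # N-1 = 2 < k

    def test_matches_brute_force_oracle_random_layouts(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 50))
            pts = rng.uniform(0, 100, size=(n, 2))
            g = build_knn_graph(pts, k=4)
            for i in range(n):
                d = np.sqrt(((pts - pts[i]) ** 2).sum(axis=1))
                order = sorted((dd, j) for j, dd in enumerate(d) if j != i)
                expected = [j for _, j in order[:4]]
                assert list(g.neighbors[i]) == expected

    def test_tie_break_by_spot_index(self):
        # three spots equidistant from spot 0
        pts = np.array([[0.0, 0], [1, 0], [-1, 0], [0, 1], [0, -1]])
        g = build_knn_graph(pts, k=2)
        assert list(g.neighbors[0]) == [1, 2]

    def test_single_spot_errors(self):
        with pytest.raises(ValueError, match="at least 2"):
            build_knn_graph(np.array([[0.0, 0.0]]), k=4)

    def test_edge_list_export(self, tmp_path):
        import pandas as pd
        g = build_knn_graph(np.array([[0.0, 0], [1, 0], [2, 0]]), k=2)
        path = tmp_path / "edges.tsv"
        g.to_edge_list(path)
        df = pd.read_csv(path, sep="\t")
        assert len(df) == 3 * 2 and set(df.columns) == {
            "source", "target", "distance"}


def _toy_graph_and_params(rng, n=5, m_in=3, m_hidden=4, m_out=3):
    pts = rng.uniform(0, 10, size=(n, 2))
    graph = build_knn_graph(pts, k=3)
    params = GATParams(m_in, m_hidden, m_out, rng=np.random.default_rng(9))
    h = rng.normal(size=(n, m_in))
    return h, graph, params


class TestEdgeScores:
    def test_zero_weights_zero_scores(self, rng):
        h, graph, params = _toy_graph_and_params(rng)
        params.W_h.data[...] = 0
        assert np.allclose(edge_scores(Tensor(h), graph, params).data, 0)

    def test_identical_nodes_identical_scores(self, rng):
        _, graph, params = _toy_graph_and_params(rng)
        h = np.tile(rng.normal(size=3), (5, 1))
        e = edge_scores(Tensor(h), graph, params).data
        assert np.allclose(e, e.flat[0])

    def test_hand_arithmetic_oracle(self, rng):
        h, graph, params = _toy_graph_and_params(rng, n=3)
        e = edge_scores(Tensor(h), graph, params).data
        z = h @ params.W_h.data
        for i in range(3):
            for jj, j in enumerate(graph.neighbors[i]):
                expected = np.concatenate([z[i], z[j]]) @ params.a.data
                assert e[i, jj] == pytest.approx(expected, abs=1e-12)

    def test_feature_length_mismatch_errors(self, rng):
        _, graph, params = _toy_graph_and_params(rng)
        with pytest.raises(ValueError, match="length"):
            edge_scores(Tensor(np.zeros((5, 7))), graph, params)


class TestNormalizeAttention:
    def test_equal_scores_uniform_quarter(self, rng):
        pts = rng.uniform(0, 10, size=(6, 2))
        graph = build_knn_graph(pts, k=4)
        alpha = normalize_attention(Tensor(np.ones((6, 4))), graph).data
        assert np.allclose(alpha, 0.25)

    def test_dominant_score_saturates(self):
        graph = build_knn_graph(np.array([[0.0, 0], [1, 0], [2, 0]]), k=2)
        e = np.array([[10.0, -10.0]] * 3)
        alpha = normalize_attention(Tensor(e), graph).data
        assert np.all(alpha[:, 0] > 0.999)

    def test_hand_softmax_arithmetic(self):
        graph = build_knn_graph(np.array([[0.0, 0], [1, 0], [2, 0]]), k=2)
        e = np.array([[0.0, np.log(2.0)]] * 3)
        alpha = normalize_attention(Tensor(e), graph).data
        assert np.allclose(alpha, [1 / 3, 2 / 3], atol=1e-12)

    def test_leaky_relu_applied_before_softmax(self):
        graph = build_knn_graph(np.array([[0.0, 0], [1, 0], [2, 0]]), k=2)
        e = np.array([[-1.0, 1.0]] * 3)
        alpha = normalize_attention(Tensor(e), graph, leaky_slope=0.2).data
        expected = np.exp([-0.2, 1.0])
        expected /= expected.sum()
        assert np.allclose(alpha[0], expected, atol=1e-12)

    def test_rows_sum_to_one_random(self, rng):
        pts = rng.uniform(0, 10, size=(8, 2))
        graph = build_knn_graph(pts, k=4)
        for _ in range(100):
            e = rng.normal(size=(8, 4)) * 5
            alpha = normalize_attention(Tensor(e), graph).data
            assert np.allclose(alpha.sum(axis=1), 1.0, atol=1e-6)


class TestAggregate:
    def test_identical_neighbours_convexity(self, rng):
        pts = rng.uniform(0, 10, size=(5, 2))
        graph = build_knn_graph(pts, k=3)
        v = rng.normal(size=4)
        h = np.tile(v, (5, 1))
        alpha = np.full((5, 3), 1 / 3)
        assert np.allclose(aggregate(Tensor(h), Tensor(alpha), graph).data, v)

    def test_one_hot_copies_neighbour(self, rng):
        pts = rng.uniform(0, 10, size=(4, 2))
        graph = build_knn_graph(pts, k=3)
        h = rng.normal(size=(4, 2))
        alpha = np.zeros((4, 3))
        alpha[:, 1] = 1.0
        out = aggregate(Tensor(h), Tensor(alpha), graph).data
        for i in range(4):
            assert np.allclose(out[i], h[graph.neighbors[i, 1]])

    def test_weighted_loop_oracle(self, rng):
        pts = rng.uniform(0, 10, size=(3, 2))
        graph = build_knn_graph(pts, k=2)
        h = rng.normal(size=(3, 3))
        alpha = rng.dirichlet(np.ones(2), size=3)
        out = aggregate(Tensor(h), Tensor(alpha), graph).data
        for i in range(3):
            expected = sum(alpha[i, t] * h[graph.neighbors[i, t]]
                           for t in range(2))
            assert np.allclose(out[i], expected, atol=1e-12)

    def test_output_in_convex_hull_of_neighbours(self, rng):
        pts = rng.uniform(0, 10, size=(10, 2))
        graph = build_knn_graph(pts, k=4)
        h = rng.normal(size=(10, 5))
        e = rng.normal(size=(10, 4))
        alpha = normalize_attention(Tensor(e), graph).data
        out = aggregate(Tensor(h), Tensor(alpha), graph).data
        for i in range(10):
            nb = h[graph.neighbors[i]]
            assert (out[i] >= nb.min(axis=0) - 1e-9).all()
            assert (out[i] <= nb.max(axis=0) + 1e-9).all()


class TestUpdateAndHead:
    def test_zero_combine_gives_zero(self, rng):
        h, graph, params = _toy_graph_and_params(rng)
        params.omega.data[...] = 0
        params.beta.data[...] = 0
        out = update_embedding(Tensor(h), Tensor(h), params).data
        assert np.allclose(out, 0.0)     # ELU(0) = 0

    def test_positive_preactivation_linear(self, rng):
        h, graph, params = _toy_graph_and_params(rng)
        pre = np.concatenate([h, h], axis=1) @ params.omega.data + params.beta.data
        out = update_embedding(Tensor(h), Tensor(h), params).data
        pos = pre > 0
        assert np.allclose(out[pos], pre[pos], atol=1e-12)

    def test_hand_arithmetic_oracle(self, rng):
        h, graph, params = _toy_graph_and_params(rng, n=3)
        h_om = rng.normal(size=h.shape)
        out = update_embedding(Tensor(h), Tensor(h_om), params).data
        pre = np.concatenate([h, h_om], axis=1) @ params.omega.data + params.beta.data
        expected = np.where(pre > 0, pre, np.exp(pre) - 1)
        assert np.allclose(out, expected, atol=1e-10)

    def test_stage_output_shape_and_zero_head(self, rng):
        stage = GATStage(m_in=6, n_genes=7, rng=np.random.default_rng(3))
        pts = rng.uniform(0, 10, size=(9, 2))
        graph = build_knn_graph(pts, k=4)
        out = stage(Tensor(rng.normal(size=(9, 6))), graph)
        assert out.shape == (9, 7)
        stage.W_out.data[...] = 0
        stage.b_out.data[...] = 0
        out2 = stage(Tensor(rng.normal(size=(9, 6))), graph)
        assert np.allclose(out2.data, 0.0)
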