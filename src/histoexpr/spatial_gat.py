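"""4-nearest-neighbour spot graph and graph-attention refinement.

Each spot is connected to its ``k`` nearest neighbours by Euclidean
distance on pixel coordinates (directed: Ω(v_i) is the set of the k
selected neighbours of i, self excluded; ties break by (distance, spot
index)).  One attention head scores each edge with a single-layer
feed-forward network on the transformed pair,

    e_ij = aᵀ [W_h h_i ‖ W_h h_j],
    α_ij = softmax over j ∈ Ω(v_i) of LeakyReLU(e_ij)   (slope 0.2),

aggregates neighbour features h_Ω(v_i) = Σ_t α_it h_t, and updates the
node embedding as ELU(concat(h_i, h_Ω(v_i)) ω + β).  A final linear head
projects the refined embedding to the gene panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, concat
from .io import SpotTable

__all__ = ["SpotGraph", "build_knn_graph", "GATParams", "edge_scores",
           "normalize_attention", "aggregate", "update_embedding",
           "expression_head", "GATStage"]


@dataclass
class SpotGraph:
    """Directed k-NN graph: edge (i → j) means j is a neighbour of i."""

    n_nodes: int
    neighbors: np.ndarray      # (N, k) neighbour indices, sorted by distance
    distances: np.ndarray      # (N, k) Euclidean edge lengths

    @property
    def edges(self) -> list:
        return [(i, int(j)) for i in range(self.n_nodes)
                for j in self.neighbors[i]]

    def to_edge_list(self, path) -> None:
        """Write the graph as a TSV edge list (source, target, distance)."""
        import pandas as pd
        rows = [(i, int(j), float(d)) for i in range(self.n_nodes)
                for j, d in zip(self.neighbors[i], self.distances[i])]
        pd.DataFrame(rows, columns=["source", "target", "distance"]).to_csv(
            path, sep="\t", index=False)


def build_knn_graph(spots: SpotTable | np.ndarray, k: int = 4,
                    coords: str = "pixel") -> SpotGraph:
    """k nearest neighbours per spot by Euclidean distance.

    ``coords`` selects pixel (default) or array coordinates when a
    SpotTable is given; a plain (N, 2) array is used as-is.  Duplicate
    coordinates (zero distance to another spot) are allowed.
    """
    if isinstance(spots, SpotTable):
        if coords == "pixel":
            pts = np.column_stack([spots.pixel_x, spots.pixel_y])
        elif coords == "array":
            pts = np.column_stack([spots.array_x, spots.array_y]).astype(float)
        else:
            raise ValueError("coords must be 'pixel' or 'array'")
    else:
        pts = np.asarray(spots, dtype=float)
    n = len(pts)
    if n < 2:
        raise ValueError("need at least 2 spots to build a graph")
    if not np.isfinite(pts).all():
        raise ValueError("spot coordinates must be finite")
    k_eff = min(k, n - 1)
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=-1))
    np.fill_diagonal(dist, np.inf)           # exclude self
    # ties break by (distance, spot index): argsort is stable on the
    # secondary key when we sort a structured ordering
    order = np.lexsort((np.broadcast_to(np.arange(n), (n, n)), dist), axis=-1)
    nbr = order[:, :k_eff]
    d = np.take_along_axis(dist, nbr, axis=1)
    return SpotGraph(n_nodes=n, neighbors=nbr, distances=d)


class GATParams:
    """Shared transform W_h, edge scorer a, and the combine weights ω, β."""

    def __init__(self, m_in: int, m_hidden: int, m_out: int,
                 rng: np.random.Generator | None = None,
                 leaky_slope: float = 0.2):
        rng = rng or np.random.default_rng(0)
        self.leaky_slope = leaky_slope
        self.W_h = Tensor(rng.normal(0, np.sqrt(1.0 / m_in),
                                     size=(m_in, m_hidden)),
                          requires_grad=True)
        self.a = Tensor(rng.normal(0, np.sqrt(1.0 / m_hidden),
                                   size=(2 * m_hidden,)),
                        requires_grad=True)
        self.omega = Tensor(rng.normal(0, np.sqrt(1.0 / (m_in + m_in)),
                                       size=(2 * m_in, m_out)),
                            requires_grad=True)
        self.beta = Tensor(np.zeros(m_out), requires_grad=True)

    def parameters(self) -> list:
        return [self.W_h, self.a, self.omega, self.beta]


def edge_scores(h: Tensor, graph: SpotGraph, params: GATParams) -> Tensor:
    """Raw scores e_ij = aᵀ[W_h h_i ‖ W_h h_j] per (node, neighbour), (N, k)."""
    h = h if isinstance(h, Tensor) else Tensor(h)
    if h.shape[1] != params.W_h.shape[0]:
        raise ValueError(
            f"feature length {h.shape[1]} != scorer input {params.W_h.shape[0]}")
    z = h @ params.W_h                                     # (N, m_hidden)
    m = z.shape[1]
    src = z[params_idx_src(graph)]                         # (N*k, m)
    dst = z[graph.neighbors.reshape(-1)]                   # (N*k, m)
    e = concat([src, dst], axis=1) @ params.a.reshape(2 * m, 1)
    return e.reshape(graph.n_nodes, graph.neighbors.shape[1])


def params_idx_src(graph: SpotGraph) -> np.ndarray:
    k = graph.neighbors.shape[1]
    return np.repeat(np.arange(graph.n_nodes), k)


def normalize_attention(e: Tensor, graph: SpotGraph,
                        leaky_slope: float = 0.2) -> Tensor:
    """α_ij: softmax of LeakyReLU(e_ij) over each node's neighbour set."""
    e = e if isinstance(e, Tensor) else Tensor(e)
    return e.leaky_relu(leaky_slope).softmax(axis=-1)


def aggregate(h: Tensor, alpha: Tensor, graph: SpotGraph) -> Tensor:
    """Neighbourhood features h_Ω(v_i) = Σ_{t∈Ω(v_i)} α_it h_t, (N, M)."""
    h = h if isinstance(h, Tensor) else Tensor(h)
    alpha = alpha if isinstance(alpha, Tensor) else Tensor(alpha)
    N, k = graph.neighbors.shape
    nbr_feats = h[graph.neighbors.reshape(-1)].reshape(N, k, h.shape[1])
    return (nbr_feats * alpha.reshape(N, k, 1)).sum(axis=1)


def update_embedding(h: Tensor, h_omega: Tensor, params: GATParams) -> Tensor:
    """ELU(concat(h_i, h_Ω(v_i)) ω + β)."""
    h = h if isinstance(h, Tensor) else Tensor(h)
    h_omega = h_omega if isinstance(h_omega, Tensor) else Tensor(h_omega)
    return (concat([h, h_omega], axis=1) @ params.omega + params.beta).elu()


def expression_head(h: Tensor, W_out: Tensor, b_out: Tensor) -> Tensor:
    """Linear projection of refined spot embeddings to the gene panel."""
    h = h if isinstance(h, Tensor) else Tensor(h)
    return h @ W_out + b_out


class GATStage:
    """One graph-attention layer plus the expression head."""

    def __init__(self, m_in: int, n_genes: int, m_hidden: int | None = None,
                 m_out: int | None = None, leaky_slope: float = 0.2,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        m_hidden = m_hidden or m_in
        m_out = m_out or m_in
        self.params = GATParams(m_in, m_hidden, m_out, rng=rng,
                                leaky_slope=leaky_slope)
        self.W_out = Tensor(rng.normal(0, np.sqrt(1.0 / m_out),
                                       size=(m_out, n_genes)),
                            requires_grad=True)
        self.b_out = Tensor(np.zeros(n_genes), requires_grad=True)

    def parameters(self) -> list:
        return self.params.parameters() + [self.W_out, self.b_out]

    def __call__(self, h: Tensor, graph: SpotGraph) -> Tensor:
        e = edge_scores(h, graph, self.params)
        alpha = normalize_attention(e, graph, self.params.leaky_slope)
        h_omega = aggregate(h, alpha, graph)
        refined = update_embedding(h, h_omega, self.params)
        return expression_head(refined, self.W_out, self.b_out)
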