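"""Topological similarity weights and their modularity-style correction.

The raw weight of a node pair combines its direct connection with the
number of common neighbours, via two ratios built from the degrees:

* partition ratio     ``P_ij  = 1/k_i + 1/k_j``
* neighbourhood ratio ``CN_ij = (|common neighbours| + 1) * P_ij``

and the piecewise rule (``W_ij >= 0`` always):

* non-adjacent, both degrees >= 1:     ``(CN_ij - P_ij) / 4``
* adjacent, some endpoint of degree 1: ``P_ij``
* adjacent, both degrees > 1:          ``2 CN_ij + P_ij``
* any pair touching an isolated node:  ``0``

Because these weights are non-negative, the induced coalition game is
convex and rewards the grand coalition; the approximate correction
``W'_ij = W_ij - W_i W_j / (2 Wbar)`` subtracts a modularity-style null
term so signed weights (and non-convex games) emerge. The exact null
correction lives in :mod:`coalnet.null_model`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .graph import UndirectedGraph

__all__ = [
    "PairWeightTable",
    "partition_ratio",
    "neighbourhood_ratio",
    "raw_weights",
    "approx_corrected_weights",
    "weighted_modularity",
]


@dataclass
class PairWeightTable:
    """Dense symmetric table of per-pair values with zero diagonal.

    ``kind`` is one of ``raw_W``, ``approx_Wprime``, ``exact_Wstar``,
    ``expected_We``.
    """

    values: np.ndarray
    kind: str
    labels: tuple = ()

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("pair table must be square")
        if not np.allclose(v, v.T):
            raise ValueError("pair table must be symmetric")
        np.fill_diagonal(v, 0.0)
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def value(self, i: int, j: int) -> float:
        if i == j:
            raise ValueError("pair value undefined for i == j")
        return float(self.values[i, j])

    def row_sums(self) -> np.ndarray:
        """Per-node totals ``W_i = sum_{j != i} W_ij`` (all-pairs)."""
        return self.values.sum(axis=1)

    def pair_total(self) -> float:
        """``sum_{i<j} W_ij`` over all unordered pairs."""
        return float(self.values.sum() / 2.0)

    def write_text(self, target) -> None:
        """Export as three-column text: ``label_i label_j value``."""
        labs = self.labels or tuple(range(self.n))
        lines = [
            f"{labs[i]} {labs[j]} {float(self.values[i, j])!r}"
            for i in range(self.n)
            for j in range(i + 1, self.n)
        ]
        text = "\n".join(lines) + "\n"
        if hasattr(target, "write"):
            target.write(text)
        else:
            Path(target).write_text(text)


def partition_ratio(k_i: int, k_j: int) -> float:
    """``P_ij = 1/k_i + 1/k_j``; undefined for isolated endpoints."""
    if k_i < 1 or k_j < 1:
        raise ValueError("partition ratio undefined for degree-0 nodes")
    return 1.0 / k_i + 1.0 / k_j


def neighbourhood_ratio(graph: UndirectedGraph, i: int, j: int) -> float:
    """``CN_ij = (common neighbour count + 1) * P_ij``."""
    p = partition_ratio(graph.degree(i), graph.degree(j))
    return (graph.common_neighbour_count(i, j) + 1) * p


def raw_weights(graph: UndirectedGraph) -> PairWeightTable:
    """Raw similarity weights for every unordered pair (kind ``raw_W``)."""
    n = graph.n
    deg = graph.degrees()
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            k_i, k_j = deg[i], deg[j]
            if k_i < 1 or k_j < 1:
                continue  # isolated endpoint: weight 0
            p = 1.0 / k_i + 1.0 / k_j
            cn = (graph.common_neighbour_count(i, j) + 1) * p
            if not graph.has_edge(i, j):
                w_ij = (cn - p) / 4.0
            elif k_i == 1 or k_j == 1:
                w_ij = p
            else:
                w_ij = 2.0 * cn + p
            w[i, j] = w[j, i] = w_ij
    return PairWeightTable(values=w, kind="raw_W", labels=graph.labels)


def _weight_norm(table: PairWeightTable, graph: UndirectedGraph | None, convention: str) -> float:
    if convention == "edges_only":
        if graph is None:
            raise ValueError("edges_only convention requires the graph")
        return float(sum(table.values[i, j] for i, j in graph.edges))
    if convention == "all_pairs":
        return table.pair_total()
    raise ValueError(f"unknown convention {convention!r}")


def approx_corrected_weights(
    table: PairWeightTable,
    graph: UndirectedGraph | None = None,
    convention: str = "edges_only",
) -> PairWeightTable:
    """Approximate null-corrected weights ``W'_ij = W_ij - W_i W_j / (2 Wbar)``.

    ``W_i`` sums over all pairs (raw weights live on non-edges too); the
    normaliser ``Wbar`` sums over edges only under the default convention,
    or over all unordered pairs under ``convention="all_pairs"``. The two
    disagree on generic graphs; both are exposed because the choice is a
    modelling convention, not a theorem.
    """
    if table.kind != "raw_W":
        raise ValueError("approximate correction applies to raw weight tables")
    wbar = _weight_norm(table, graph, convention)
    if wbar <= 0:
        raise ValueError("degenerate graph: total weight is zero")
    w_i = table.row_sums()
    corrected = table.values - np.outer(w_i, w_i) / (2.0 * wbar)
    np.fill_diagonal(corrected, 0.0)
    return PairWeightTable(values=corrected, kind="approx_Wprime", labels=table.labels)


def weighted_modularity(table: PairWeightTable, partition, graph: UndirectedGraph | None = None,
                        convention: str = "edges_only") -> float:
    """Modularity of a strict partition under a pair-weight table.

    ``(1 / 2Wbar) * sum_{i,j} (W_ij - W_i W_j / 2Wbar) delta(i, j)`` with the
    sum over ordered pairs including ``i = j`` (the diagonal contributes the
    ``-W_i^2 / 2Wbar`` null term, exactly as in the unweighted special case
    where the table is the adjacency matrix and the value is the standard
    Newman–Girvan modularity).

    ``partition`` is an iterable of disjoint node-index sets covering all
    nodes (a cover with one membership per node).
    """
    n = table.n
    comm = np.full(n, -1, dtype=int)
    for k, members in enumerate(partition):
        for i in members:
            if comm[i] != -1:
                raise ValueError("modularity requires a strict partition (overlap found)")
            comm[i] = k
    if (comm == -1).any():
        raise ValueError("partition does not cover all nodes")
    wbar = _weight_norm(table, graph, convention)
    if wbar <= 0:
        raise ValueError("degenerate graph: total weight is zero")
    w_i = table.row_sums()
    same = comm[:, None] == comm[None, :]
    null = np.outer(w_i, w_i) / (2.0 * wbar)
    return float(((table.values - null) * same).sum() / (2.0 * wbar))
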