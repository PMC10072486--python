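"""Exact configuration-model null: probabilities and expected pair weights.

The null hypothesis destroys community structure while preserving degrees:
every edge of the empirical graph is cut into two stubs and all ``2m``
stubs are re-paired uniformly at random (a uniform perfect matching of the
stubs, self-pairings included). Under this model the probability that two
given stubs are matched is ``1/(2m-1)``, and the adjacency, common
neighbour, and triangle events have closed-form probabilities given by
alternating inclusion-exclusion series over partial stub matchings.

Those alternating series cancel catastrophically in floating point for
moderate degrees, so everything here is computed with ``fractions.Fraction``
and converted to floats only when a table is assembled. A brute-force
matching enumerator (`MatchingOracle`) provides an independent check for
tiny stub systems.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from itertools import combinations
from math import comb, factorial

import numpy as np

from .graph import UndirectedGraph
from .weights import PairWeightTable, raw_weights

__all__ = [
    "count_matchings",
    "stub_pair_probability",
    "p_adjacency",
    "p_common_neighbour",
    "p_triangle",
    "expected_weight",
    "expected_weight_table",
    "exact_corrected_weights",
    "ExactBudgetError",
    "MatchingOracle",
]

#: Default budget on edges for exact-null tables. The rational series stay
#: exact at any size, but the per-pair triple sums make dense tables
#: impractical on large graphs; beyond this the caller should fall back to
#: the approximate correction.
DEFAULT_M_MAX = 1500


class ExactBudgetError(RuntimeError):
    """Exact-null computation refused; use the approximate correction."""


def count_matchings(m: int) -> int:
    """Number of perfect matchings of ``2m`` stubs: ``(2m)! / (2^m m!)``."""
    if m < 0:
        raise ValueError("m must be non-negative")
    return factorial(2 * m) // (2**m * factorial(m))


def stub_pair_probability(m: int) -> Fraction:
    """Probability that two given stubs are matched: ``1/(2m-1)``."""
    if m < 1:
        raise ValueError("need at least one edge")
    return Fraction(1, 2 * m - 1)


def _partial_matching_prob(t: int, m: int) -> Fraction:
    """Probability that ``t`` specified disjoint stub pairs are all matched:
    ``1 / prod_{p=1..t} (2m+1-2p)``."""
    denom = 1
    for p in range(1, t + 1):
        denom *= 2 * m + 1 - 2 * p
    return Fraction(1, denom)


@lru_cache(maxsize=None)
def p_adjacency(k_i: int, k_j: int, m: int) -> Fraction:
    """Probability that nodes with degrees ``k_i``, ``k_j`` are adjacent
    (joined by at least one edge) in the null model with ``m`` edges.

    Inclusion-exclusion over sets of ``t`` disjoint cross pairs of stubs:
    ``sum_t (-1)^(t+1) C(k_i,t) C(k_j,t) t! / prod_{p<=t}(2m+1-2p)``.
    """
    if k_i < 0 or k_j < 0:
        raise ValueError("degrees must be non-negative")
    if min(k_i, k_j) <= 0 or m < 1:
        return Fraction(0)
    if k_i + k_j > 2 * m:
        raise ValueError("degree sum exceeds available stubs")
    total = Fraction(0)
    for t in range(1, min(k_i, k_j) + 1):
        term = comb(k_i, t) * comb(k_j, t) * factorial(t) * _partial_matching_prob(t, m)
        total += term if t % 2 == 1 else -term
    return total


@lru_cache(maxsize=None)
def p_common_neighbour(k_i: int, k_j: int, k_r: int, m: int) -> Fraction:
    """Probability that ``r`` is adjacent to both ``i`` and ``j``.

    Recursion through `p_adjacency` with ``t`` stubs of ``r`` committed to
    ``j``; the range ``t <= min(k_j, k_r - 1)`` keeps at least one stub of
    ``r`` free for the i-r connection.
    """
    if min(k_i, k_j, k_r) < 0:
        raise ValueError("degrees must be non-negative")
    if min(k_i, k_j) <= 0 or k_r <= 1 or m < 1:
        return Fraction(0)
    total = Fraction(0)
    for t in range(1, min(k_j, k_r - 1) + 1):
        if m - t < 1:
            continue
        inner = p_adjacency(k_i, k_r - t, m - t)
        term = inner * comb(k_r, t) * comb(k_j, t) * factorial(t) * _partial_matching_prob(t, m)
        total += term if t % 2 == 1 else -term
    return total


@lru_cache(maxsize=None)
def p_triangle(k_i: int, k_j: int, k_r: int, m: int) -> Fraction:
    """Probability that ``i``, ``j``, ``r`` are pairwise adjacent.

    Recursion through `p_common_neighbour` with ``t`` direct i-j pairs
    committed; ``t <= min(k_i - 1, k_j - 1)`` keeps a stub of each free for
    the connections through ``r``.
    """
    if min(k_i, k_j, k_r) < 0:
        raise ValueError("degrees must be non-negative")
    if min(k_i, k_j) <= 1 or k_r <= 1 or m < 1:
        return Fraction(0)
    total = Fraction(0)
    for t in range(1, min(k_i - 1, k_j - 1) + 1):
        if m - t < 1:
            continue
        inner = p_common_neighbour(k_i - t, k_j - t, k_r, m - t)
        term = inner * comb(k_i, t) * comb(k_j, t) * factorial(t) * _partial_matching_prob(t, m)
        total += term if t % 2 == 1 else -term
    return total


def expected_weight(graph: UndirectedGraph, i: int, j: int) -> Fraction:
    """Exact expected raw weight ``E[W_ij]`` under the degree-preserving null.

    The case split mirrors the piecewise weight definition; degrees and the
    partition ratio are invariants of the null model, only the adjacency
    and common-neighbour indicators are random.
    """
    deg = graph.degrees()
    k_i, k_j, m = deg[i], deg[j], graph.m
    if k_i < 1 or k_j < 1:
        return Fraction(0)
    p_ij = Fraction(1, k_i) + Fraction(1, k_j)
    others = [r for r in range(graph.n) if r != i and r != j]
    p_adj = p_adjacency(k_i, k_j, m)
    if k_i == 1 or k_j == 1:
        cn_sum = sum((p_common_neighbour(k_i, k_j, deg[r], m) for r in others), Fraction(0))
        return p_ij * cn_sum / 4 + p_ij * p_adj
    cn_sum = Fraction(0)
    tri_sum = Fraction(0)
    for r in others:
        cn_sum += p_common_neighbour(k_i, k_j, deg[r], m)
        tri_sum += p_triangle(k_i, k_j, deg[r], m)
    return p_ij * (cn_sum - tri_sum) / 4 + 2 * p_ij * tri_sum + 3 * p_ij * p_adj


def _expected_pairs(graph: UndirectedGraph, m_max: int):
    if graph.m > m_max:
        raise ExactBudgetError(
            f"graph has {graph.m} edges > budget {m_max}; "
            "use approx_corrected_weights instead"
        )
    n = graph.n
    exp = np.zeros((n, n))
    # probabilities are memoised on degree tuples, so the cost is driven by
    # distinct degrees, not by n
    for i in range(n):
        for j in range(i + 1, n):
            exp[i, j] = exp[j, i] = float(expected_weight(graph, i, j))
    return exp


def expected_weight_table(graph: UndirectedGraph, m_max: int = DEFAULT_M_MAX) -> PairWeightTable:
    """Dense table of ``E[W_ij]`` (kind ``expected_We``)."""
    exp = _expected_pairs(graph, m_max)
    return PairWeightTable(values=exp, kind="expected_We", labels=graph.labels)


def exact_corrected_weights(graph: UndirectedGraph, m_max: int = DEFAULT_M_MAX) -> PairWeightTable:
    """Exactly corrected weights ``W*_ij = W_ij - E[W_ij]`` (kind ``exact_Wstar``).

    Signed values; the induced coalition game is non-convex, which is what
    lets small stable communities beat the grand coalition.
    """
    raw = raw_weights(graph)
    exp = _expected_pairs(graph, m_max)
    return PairWeightTable(values=raw.values - exp, kind="exact_Wstar", labels=graph.labels)


@dataclass
class MatchingOracle:
    """Exhaustive stub-matching enumerator for tiny degree sequences.

    Enumerates all ``(2m)!/(2^m m!)`` perfect matchings of the stub system
    (self-pairings of a node's own stubs included, mirroring the counting in
    the closed forms) and measures exact event frequencies. Intended as an
    independent test oracle; refuses ``m > 6``.
    """

    degrees: tuple

    def __post_init__(self):
        self.degrees = tuple(self.degrees)
        total = sum(self.degrees)
        if total % 2 != 0:
            raise ValueError("degree sum must be even")
        self.m = total // 2
        if self.m > 6:
            raise ValueError("oracle limited to m <= 6")
        owner = []
        for node, k in enumerate(self.degrees):
            owner.extend([node] * k)
        self._owner = owner

    def _matchings(self):
        stubs = list(range(2 * self.m))

        def rec(remaining, acc):
            if not remaining:
                yield acc
                return
            first = remaining[0]
            for idx in range(1, len(remaining)):
                pair = (first, remaining[idx])
                rest = remaining[1:idx] + remaining[idx + 1:]
                yield from rec(rest, acc + [pair])

        yield from rec(stubs, [])

    def _adjacency_counts(self, matching):
        """Multigraph edge-count matrix of one matching (self-loops on diag)."""
        n = len(self.degrees)
        counts = np.zeros((n, n), dtype=int)
        for a, b in matching:
            u, v = self._owner[a], self._owner[b]
            counts[u, v] += 1
            if u != v:
                counts[v, u] += 1
        return counts

    def event_probabilities(self, i: int, j: int, r: int | None = None):
        """Exact frequencies of adjacency(i,j), and when ``r`` is given also
        common-neighbour(i,j;r) and triangle(i,j,r)."""
        total = 0
        adj = 0
        cn = 0
        tri = 0
        for matching in self._matchings():
            total += 1
            c = self._adjacency_counts(matching)
            a_ij = c[i, j] > 0
            adj += a_ij
            if r is not None:
                both = c[i, r] > 0 and c[j, r] > 0
                cn += both
                tri += both and a_ij
        out = {"adjacency": Fraction(adj, total)}
        if r is not None:
            out["common_neighbour"] = Fraction(cn, total)
            out["triangle"] = Fraction(tri, total)
        return out

    def all_statistics(self):
        """One enumeration pass: exact adjacency/common-neighbour/triangle
        frequencies for every pair and ordered-(i,j,r) triple, plus exact
        expected raw weights for every pair.

        Returns a dict with keys ``adjacency[(i,j)]``, ``cn[(i,j,r)]``,
        ``triangle[(i,j,r)]``, ``expected_w[(i,j)]`` (Fractions).
        """
        n = len(self.degrees)
        total = 0
        adj = {}
        cn = {}
        tri = {}
        ew = {}
        p_ij = {}
        for i in range(n):
            for j in range(i + 1, n):
                adj[(i, j)] = 0
                ew[(i, j)] = Fraction(0)
                if self.degrees[i] >= 1 and self.degrees[j] >= 1:
                    p_ij[(i, j)] = Fraction(1, self.degrees[i]) + Fraction(1, self.degrees[j])
                for r in range(n):
                    if r != i and r != j:
                        cn[(i, j, r)] = 0
                        tri[(i, j, r)] = 0
        for matching in self._matchings():
            total += 1
            c = self._adjacency_counts(matching)
            a = c > 0
            for i in range(n):
                for j in range(i + 1, n):
                    if a[i, j]:
                        adj[(i, j)] += 1
                    cn_count = 0
                    for r in range(n):
                        if r == i or r == j:
                            continue
                        if a[i, r] and a[j, r]:
                            cn[(i, j, r)] += 1
                            cn_count += 1
                            if a[i, j]:
                                tri[(i, j, r)] += 1
                    if (i, j) in p_ij:
                        k_i, k_j = self.degrees[i], self.degrees[j]
                        pij = p_ij[(i, j)]
                        if not a[i, j]:
                            ew[(i, j)] += cn_count * pij / 4
                        elif k_i == 1 or k_j == 1:
                            ew[(i, j)] += pij
                        else:
                            ew[(i, j)] += 2 * (cn_count + 1) * pij + pij
        return {
            "adjacency": {k: Fraction(v, total) for k, v in adj.items()},
            "cn": {k: Fraction(v, total) for k, v in cn.items()},
            "triangle": {k: Fraction(v, total) for k, v in tri.items()},
            "expected_w": {k: v / total for k, v in ew.items()},
        }

    def expected_weight(self, i: int, j: int) -> Fraction:
        """Exact mean of the realized raw weight of the pair over matchings.

        The realized weight uses the empirical degrees (preserved by the
        null) for the ratios and the matching's adjacency indicators for
        the direct-edge and common-neighbour terms.
        """
        k_i, k_j = self.degrees[i], self.degrees[j]
        if k_i < 1 or k_j < 1:
            return Fraction(0)
        p_ij = Fraction(1, k_i) + Fraction(1, k_j)
        n = len(self.degrees)
        total = 0
        acc = Fraction(0)
        for matching in self._matchings():
            total += 1
            c = self._adjacency_counts(matching)
            y_ij = 1 if c[i, j] > 0 else 0
            cn_count = sum(
                1 for r in range(n) if r != i and r != j and c[i, r] > 0 and c[j, r] > 0
            )
            cn_ij = (cn_count + 1) * p_ij
            if y_ij == 0:
                acc += (cn_ij - p_ij) / 4
            elif k_i == 1 or k_j == 1:
                acc += p_ij
            else:
                acc += 2 * cn_ij + p_ij
        return acc / total
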