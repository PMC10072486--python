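"""The weighted graph community game: values, Shapley shares, stability.

Nodes are players; a coalition's worth is the sum of the pair weights it
encloses. Restricted to a coalition ``S``, player ``i``'s Shapley value is
half its total weight to the other members. A coalition is *stable* when no
member would gain by defecting to the complement-plus-itself; with
non-negative weights every game of this family is convex and the grand
coalition dominates, which is exactly why the signed, null-corrected
weights matter.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .weights import PairWeightTable

__all__ = [
    "Cover",
    "coalition_value",
    "shapley_value",
    "is_stable",
    "is_stable_strong",
    "total_shapley",
    "cover_objective",
    "read_cover",
    "write_cover",
]

STABILITY_TOL = 1e-9


@dataclass
class Cover:
    """An overlapping community structure: a list of node-index sets.

    Communities may share nodes; ``membership(i)`` returns the set of
    community indices containing ``i``.
    """

    communities: list
    n: int

    def __post_init__(self):
        self.communities = [frozenset(c) for c in self.communities]
        for c in self.communities:
            for i in c:
                if not (0 <= i < self.n):
                    raise ValueError(f"node index {i} out of range 0..{self.n - 1}")

    def membership(self, i: int) -> frozenset:
        return frozenset(k for k, c in enumerate(self.communities) if i in c)

    def memberships(self) -> list[set]:
        out = [set() for _ in range(self.n)]
        for k, c in enumerate(self.communities):
            for i in c:
                out[i].add(k)
        return out

    @property
    def num_communities(self) -> int:
        return len(self.communities)

    def bridge_nodes(self) -> set:
        """Nodes belonging to more than one community."""
        return {i for i, ms in enumerate(self.memberships()) if len(ms) >= 2}

    def is_complete(self) -> bool:
        covered = set().union(*self.communities) if self.communities else set()
        return covered == set(range(self.n))

    def is_p_bounded(self, p: int) -> bool:
        return all(len(ms) <= p for ms in self.memberships())

    def is_inclusion_free(self) -> bool:
        cs = self.communities
        for a in range(len(cs)):
            for b in range(len(cs)):
                if a != b and cs[a] <= cs[b]:
                    return False
        return True

    def canonical(self) -> tuple:
        """Order-free representation for equality checks."""
        return tuple(sorted(tuple(sorted(c)) for c in self.communities))


def coalition_value(table: PairWeightTable, coalition: Iterable[int]) -> float:
    """``phi(S) = sum_{i<j in S} W_ij``."""
    members = sorted(set(coalition))
    total = 0.0
    for a in range(len(members)):
        for b in range(a + 1, len(members)):
            total += table.values[members[a], members[b]]
    return total


def shapley_value(table: PairWeightTable, i: int, coalition: Iterable[int]) -> float:
    """``phi_i(S) = 1/2 sum_{j in S, j != i} W_ij``; requires ``i in S``."""
    members = set(coalition)
    if i not in members:
        raise ValueError("node must belong to the coalition")
    return 0.5 * sum(table.values[i, j] for j in members if j != i)


def is_stable(table: PairWeightTable, coalition: Iterable[int], tol: float = STABILITY_TOL):
    """Check defection-stability of a coalition; ties count as stable.

    Returns ``(stable, margins)`` where ``margins[i]`` is the Shapley-value
    margin ``phi_i(S) - phi_i((V \\ S) + i)``; stability requires every
    margin ``>= -tol``.
    """
    members = sorted(set(coalition))
    if not members:
        raise ValueError("coalition must be non-empty")
    member_set = set(members)
    margins = {}
    for i in members:
        inside = sum(table.values[i, j] for j in member_set if j != i)
        outside = sum(
            table.values[i, j] for j in range(table.n) if j != i and j not in member_set
        )
        margins[i] = 0.5 * (inside - outside)
    return all(v >= -tol for v in margins.values()), margins


def is_stable_strong(table: PairWeightTable, coalition: Iterable[int], tol: float = STABILITY_TOL) -> bool:
    """Stability against defection to *every* subset of the complement.

    Exponential-time check for analysis only (n <= 20); detectors use the
    complement-defection notion implemented in `is_stable`.
    """
    members = sorted(set(coalition))
    outside = [j for j in range(table.n) if j not in set(members)]
    if len(outside) > 20:
        raise ValueError("strong stability check limited to small complements")
    for i in members:
        phi_in = shapley_value(table, i, members)
        # best defection payoff: pick the positive-weight outsiders
        best = 0.5 * sum(max(table.values[i, j], 0.0) for j in outside)
        if best > phi_in + tol:
            return False
    return True


def total_shapley(table: PairWeightTable, cover: Cover) -> float:
    """Sum of all nodes' Shapley values over all communities.

    Each co-membered pair counts once per shared community, so duplicated
    communities double the score — the pathology the once-per-pair
    objective removes.
    """
    return sum(coalition_value(table, c) for c in cover.communities)


def cover_objective(table: PairWeightTable, cover: Cover) -> float:
    """Once-per-pair objective: ``sum_{i<j : memberships intersect} W_ij``."""
    ms = cover.memberships()
    total = 0.0
    for i in range(cover.n):
        for j in range(i + 1, cover.n):
            if ms[i] & ms[j]:
                total += table.values[i, j]
    return total


def read_cover(source, labels: Sequence) -> Cover:
    """Read a cover file: one community per line, space-separated labels."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()
    index = {str(lab): i for i, lab in enumerate(labels)}
    communities = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        communities.append({index[tok] for tok in line.split()})
    return Cover(communities=communities, n=len(labels))


def write_cover(cover: Cover, labels: Sequence, target) -> None:
    lines = [
        " ".join(str(labels[i]) for i in sorted(c)) for c in cover.communities
    ]
    text = "\n".join(lines) + "\n"
    if hasattr(target, "write"):
        target.write(text)
    else:
        Path(target).write_text(text)
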