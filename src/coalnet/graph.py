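"""Simple undirected graphs with label-preserving 0-based internal indexing.

All downstream weight computations work on internal indices ``0..n-1``;
original external labels (strings or integers, 1-based in most published
social-network datasets) are kept in a bijective label map so that covers
and weight tables can be written back in the input's vocabulary.

Input graphs are treated as unweighted simple graphs: edge weights found in
a file are ignored (with a warning), duplicate and reversed edge lines are
collapsed, self-loops are rejected.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "UndirectedGraph",
    "GraphFormatError",
    "read_graph",
    "write_edgelist",
    "load_fixture",
    "FIXTURE_NAMES",
]


class GraphFormatError(ValueError):
    """Raised when a graph source cannot be parsed or violates simplicity."""


@dataclass(frozen=True)
class UndirectedGraph:
    """An unweighted simple undirected graph.

    Attributes
    ----------
    labels:
        External label of each internal node index; ``labels[i]`` is the
        original name of node ``i``.
    edges:
        Frozen set of unordered pairs ``(i, j)`` with ``i < j`` over internal
        indices.
    """

    labels: tuple
    edges: frozenset
    _adj: tuple = field(repr=False, compare=False, default=())

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def m(self) -> int:
        return len(self.edges)

    @property
    def adjacency(self) -> tuple:
        """Tuple of frozensets: neighbours of every node."""
        return self._adj

    def degree(self, i: int) -> int:
        return len(self._adj[i])

    def degrees(self) -> list[int]:
        """Degree sequence ``k_i`` on internal indices; sums to ``2m``."""
        return [len(a) for a in self._adj]

    def has_edge(self, i: int, j: int) -> bool:
        return (min(i, j), max(i, j)) in self.edges

    def common_neighbour_count(self, i: int, j: int) -> int:
        """Number of nodes adjacent to both ``i`` and ``j`` (``i != j``)."""
        if i == j:
            raise ValueError("common neighbours undefined for i == j")
        return len(self._adj[i] & self._adj[j])

    def index_of(self, label) -> int:
        return self._label_index[label]

    @property
    def _label_index(self) -> dict:
        # built lazily; cached on the instance despite frozen dataclass
        cache = object.__getattribute__(self, "__dict__").get("_label_cache")
        if cache is None:
            cache = {lab: i for i, lab in enumerate(self.labels)}
            object.__getattribute__(self, "__dict__")["_label_cache"] = cache
        return cache

    @classmethod
    def from_edge_pairs(cls, pairs: Iterable[tuple], nodes: Sequence = ()) -> "UndirectedGraph":
        """Build from an iterable of label pairs.

        ``nodes`` may list extra isolated nodes. Labels are indexed in first
        appearance order. Self-loops raise; duplicates are collapsed.
        """
        labels: list = []
        index: dict = {}

        def idx(lab):
            if lab not in index:
                index[lab] = len(labels)
                labels.append(lab)
            return index[lab]

        for lab in nodes:
            idx(lab)
        edges = set()
        for a, b in pairs:
            if a == b:
                raise GraphFormatError(f"self-loop on node {a!r}")
            i, j = idx(a), idx(b)
            edges.add((min(i, j), max(i, j)))
        adj = [set() for _ in labels]
        for i, j in edges:
            adj[i].add(j)
            adj[j].add(i)
        return cls(
            labels=tuple(labels),
            edges=frozenset(edges),
            _adj=tuple(frozenset(a) for a in adj),
        )

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.labels)
        g.add_edges_from((self.labels[i], self.labels[j]) for i, j in self.edges)
        return g


def _parse_edgelist(lines: Iterable[str]) -> UndirectedGraph:
    pairs = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace(",", " ").split()
        if len(parts) < 2:
            raise GraphFormatError(f"line {lineno}: expected two labels, got {line!r}")
        if len(parts) > 2:
            logger.warning("line %d: ignoring extra fields (edge weights are not used)", lineno)
        a, b = parts[0], parts[1]
        if a == b:
            raise GraphFormatError(f"line {lineno}: self-loop on node {a!r}")
        pairs.append((a, b))
    return UndirectedGraph.from_edge_pairs(pairs)


def read_graph(source, format: str = "edgelist") -> UndirectedGraph:
    """Read a simple undirected graph from a path, stream, or string content.

    Parameters
    ----------
    source:
        Path to a file, or an open text stream.
    format:
        ``"edgelist"`` (whitespace/comma separated labels, ``#`` comments) or
        ``"gml"``.
    """
    if format == "edgelist":
        if hasattr(source, "read"):
            return _parse_edgelist(source.read().splitlines())
        return _parse_edgelist(Path(source).read_text().splitlines())
    if format == "gml":
        if hasattr(source, "read"):
            data = source.read()
            g = nx.parse_gml(data, label="label")
        else:
            g = nx.read_gml(Path(source), label="label")
        if g.is_directed():
            g = g.to_undirected()
        if any(u == v for u, v in g.edges()):
            raise GraphFormatError("GML graph contains a self-loop")
        if any("weight" in d for _, _, d in g.edges(data=True)):
            logger.warning("ignoring GML edge weights (graphs are treated as unweighted)")
        return UndirectedGraph.from_edge_pairs(g.edges(), nodes=list(g.nodes()))
    raise ValueError(f"unknown graph format {format!r}")


def write_edgelist(graph: UndirectedGraph, target) -> None:
    """Write one ``label_i label_j`` line per edge (sorted internal order)."""
    text = "\n".join(
        f"{graph.labels[i]} {graph.labels[j]}" for i, j in sorted(graph.edges)
    )
    if hasattr(target, "write"):
        target.write(text + "\n")
    else:
        Path(target).write_text(text + "\n")


# Canonical 34-node / 78-edge karate-club social network, 1-based labels as
# in the original sociological study.
_ZACHARY_EDGES = """
1 2  1 3  1 4  1 5  1 6  1 7  1 8  1 9  1 11  1 12  1 13  1 14  1 18  1 20
1 22  1 32  2 3  2 4  2 8  2 14  2 18  2 20  2 22  2 31  3 4  3 8  3 9
3 10  3 14  3 28  3 29  3 33  4 8  4 13  4 14  5 7  5 11  6 7  6 11  6 17
7 17  9 31  9 33  9 34  10 34  14 34  15 33  15 34  16 33  16 34  19 33
19 34  20 34  21 33  21 34  23 33  23 34  24 26  24 28  24 30  24 33  24 34
25 26  25 28  25 32  26 32  27 30  27 34  28 34  29 32  29 34  30 33  30 34
31 33  31 34  32 33  32 34  33 34
"""

FIXTURE_NAMES = ("zachary", "triangle", "path3", "two_triangles")


def load_fixture(name: str) -> UndirectedGraph:
    """Return a bundled canonical graph.

    ``zachary``: the 34-node/78-edge karate-club network.
    ``triangle``: K3 on labels a, b, c.
    ``path3``: the path a-b-c.
    ``two_triangles``: two triangles joined by a single bridge edge (6 nodes,
    7 edges).
    """
    if name == "zachary":
        toks = _ZACHARY_EDGES.split()
        pairs = [(int(toks[t]), int(toks[t + 1])) for t in range(0, len(toks), 2)]
        return UndirectedGraph.from_edge_pairs(pairs)
    if name == "triangle":
        return UndirectedGraph.from_edge_pairs([("a", "b"), ("b", "c"), ("a", "c")])
    if name == "path3":
        return UndirectedGraph.from_edge_pairs([("a", "b"), ("b", "c")])
    if name == "two_triangles":
        return UndirectedGraph.from_edge_pairs(
            [("a", "b"), ("b", "c"), ("a", "c"),
             ("d", "e"), ("e", "f"), ("d", "f"),
             ("c", "d")]
        )
    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
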