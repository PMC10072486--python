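"""Random networks with planted overlapping communities and bridge nodes.

A variant of the Lancichinetti–Fortunato–Radicchi benchmark family: degrees
follow a truncated power law, community sizes a flatter truncated power
law, and each node splits its links between its own community (fraction
``1 - mu`` for ordinary nodes) and the rest of the graph. ``N_o`` *bridge*
nodes belong to several communities and give each of them a fraction
``1 - mu_o`` of their links, so a bridge in ``q`` communities keeps
``q * (1 - mu_o)`` of its links internal — which is why ``mu_o >= 1 - 1/p``
is required (0.5 is the smallest value at ``p = 2``, about 0.7 at
``p = 3``).

Edges are realised by degree-respecting stub matching with rejection of
self-loops and multi-edges; stubs that cannot be placed without violating
simplicity are dropped, so realised degrees can fall slightly short of
their targets. Instances carry their exact parameters and seed and are
fully replayable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .game import Cover, write_cover
from .graph import UndirectedGraph, write_edgelist

__all__ = ["BenchmarkParams", "BenchmarkInstance", "generate", "realized_mixing"]


@dataclass(frozen=True)
class BenchmarkParams:
    """Generator controls; defaults are the desk-scale study conditions."""

    N: int = 40
    n_c: int = 4
    p: int = 2
    N_o: int | None = None        # default: ceil(0.1 N)
    mu: float = 0.0               # external-link fraction, ordinary nodes
    mu_o: float = 0.5             # per-community external complement, bridges
    mean_degree: float = 8.0
    max_degree: int | None = None  # default: min(2.5 * mean, N/2)
    degree_exponent: float = 2.0
    size_exponent: float = 1.0
    seed: int = 0

    def resolved_n_o(self) -> int:
        return int(np.ceil(0.1 * self.N)) if self.N_o is None else self.N_o

    def validate(self) -> None:
        n_o = self.resolved_n_o()
        if not (0 <= n_o <= self.N):
            raise ValueError("N_o must lie in [0, N]")
        if n_o > 0 and self.p < 2:
            raise ValueError("bridge nodes require p >= 2")
        if not (0.0 <= self.mu < 1.0):
            raise ValueError("mu must lie in [0, 1)")
        if n_o > 0 and self.mu_o < 1.0 - 1.0 / self.p - 1e-9:
            raise ValueError(
                f"mu_o = {self.mu_o} infeasible for p = {self.p}: a node in p "
                f"communities cannot give each more than 1/p of its links"
            )
        if self.n_c < 2 and n_o > 0:
            raise ValueError("bridges need at least two communities")
        if self.n_c > self.N:
            raise ValueError("more communities than nodes")


@dataclass
class BenchmarkInstance:
    graph: UndirectedGraph
    truth: Cover
    bridges: set
    params: BenchmarkParams
    target_degrees: list = field(default_factory=list)

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        write_edgelist(self.graph, d / "graph.edgelist")
        write_cover(self.truth, self.graph.labels, d / "truth.cover")
        (d / "bridges.txt").write_text(
            " ".join(str(self.graph.labels[i]) for i in sorted(self.bridges)) + "\n"
        )
        (d / "meta.json").write_text(json.dumps(asdict(self.params), indent=2) + "\n")


def _truncated_power_law(rng, exponent, lo, hi, size):
    """Integer samples from p(x) ~ x^-exponent on [lo, hi]."""
    xs = np.arange(lo, hi + 1, dtype=float)
    probs = xs ** (-float(exponent))
    probs /= probs.sum()
    return rng.choice(np.arange(lo, hi + 1), size=size, p=probs)


def _stochastic_round(rng, x: float) -> int:
    base = int(np.floor(x))
    return base + (1 if rng.random() < x - base else 0)


def generate(params: BenchmarkParams) -> BenchmarkInstance:
    """Draw one benchmark instance; deterministic given ``params.seed``."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    N, n_c, p = params.N, params.n_c, params.p
    n_o = params.resolved_n_o()
    max_deg = params.max_degree or int(min(2.5 * params.mean_degree, N / 2))
    max_deg = max(max_deg, 3)

    # --- community sizes: flat-ish power law scaled to N memberships of
    # ordinary nodes (bridge memberships come on top)
    raw_sizes = _truncated_power_law(
        rng, params.size_exponent, max(3, N // (2 * n_c)), max(4, N // 2), n_c
    ).astype(float)
    share = raw_sizes / raw_sizes.sum()

    # --- membership assignment
    bridges = set(rng.choice(N, size=n_o, replace=False).tolist())
    memberships: list[set] = [set() for _ in range(N)]
    slots = [share[k] * N for k in range(n_c)]  # soft capacity targets
    counts = np.zeros(n_c)
    for i in rng.permutation(N):
        if i in bridges:
            q = 2 if p == 2 else int(rng.integers(2, p + 1))
        else:
            q = 1
        # draw communities with probability proportional to remaining soft
        # capacity, so realised sizes track the sampled size distribution
        room = np.maximum(np.asarray(slots) - counts, 0.05)
        chosen = rng.choice(n_c, size=q, replace=False, p=room / room.sum())
        memberships[int(i)] = {int(k) for k in chosen}
        for k in chosen:
            counts[int(k)] += 1
    # guarantee every community has at least 3 members
    comm_members = [set() for _ in range(n_c)]
    for i, ms in enumerate(memberships):
        for k in ms:
            comm_members[k].add(i)
    for k in range(n_c):
        while len(comm_members[k]) < 3:
            donors = [i for i in range(N)
                      if i not in comm_members[k] and i not in bridges
                      and len(comm_members[next(iter(memberships[i]))]) > 3]
            if not donors:
                raise ValueError(
                    f"infeasible parameters: cannot give community {k} three "
                    f"members with N={N}, n_c={n_c}"
                )
            i = int(rng.choice(donors))
            old = next(iter(memberships[i]))
            comm_members[old].discard(i)
            memberships[i] = {k}
            comm_members[k].add(i)

    # --- degrees
    degrees = _truncated_power_law(rng, params.degree_exponent, 2, max_deg, N)
    # rescale toward the requested mean
    scale = params.mean_degree / degrees.mean()
    degrees = np.clip(np.round(degrees * scale), 2, max_deg).astype(int)
    # internal degree cannot exceed community size - 1
    for i in range(N):
        cap = max(len(comm_members[k]) - 1 for k in memberships[i])
        if i in bridges:
            cap = sum(len(comm_members[k]) - 1 for k in memberships[i])
        degrees[i] = min(degrees[i], max(2, cap))

    # --- split degrees into per-community internal targets + external
    internal: list[dict] = [dict() for _ in range(N)]
    external = np.zeros(N, dtype=int)
    for i in range(N):
        d = int(degrees[i])
        if i in bridges:
            per = (1.0 - params.mu_o) * d
            tot_int = 0
            for k in memberships[i]:
                t = min(_stochastic_round(rng, per), len(comm_members[k]) - 1)
                internal[i][k] = t
                tot_int += t
            external[i] = max(d - tot_int, 0)
        else:
            k = next(iter(memberships[i]))
            t = min(_stochastic_round(rng, (1.0 - params.mu) * d),
                    len(comm_members[k]) - 1)
            internal[i][k] = t
            external[i] = d - t

    # --- realise internal edges per community by stub matching
    edges: set[tuple] = set()

    def try_match(stubs: list[int], forbid_same_comm: bool) -> list[int]:
        """Greedy randomized matching of stubs (node ids), avoiding self-loops,
        multi-edges and (optionally) same-community pairs. Commits the best of
        several shuffles to ``edges``; returns the unplaceable leftover stubs.
        """
        best_edges: list[tuple] = []
        best_left = list(stubs)
        for _ in range(30):
            pool = list(stubs)
            rng.shuffle(pool)
            new_edges: list[tuple] = []
            left: list[int] = []
            used = set(edges)
            while pool:
                a = pool.pop()
                placed = False
                for idx in range(len(pool) - 1, -1, -1):
                    b = pool[idx]
                    if a == b:
                        continue
                    e = (min(a, b), max(a, b))
                    if e in used:
                        continue
                    if forbid_same_comm and (memberships[a] & memberships[b]):
                        continue
                    pool.pop(idx)
                    new_edges.append(e)
                    used.add(e)
                    placed = True
                    break
                if not placed:
                    left.append(a)
            if len(left) < len(best_left):
                best_left, best_edges = left, new_edges
            if not best_left:
                break
        edges.update(best_edges)
        return best_left

    # internal edges: leftovers are dropped (not externalised) so that the
    # mu = 0 guarantee — no cross-community link at an ordinary node — is exact
    for k in range(n_c):
        stubs = []
        for i in comm_members[k]:
            stubs.extend([i] * internal[i].get(k, 0))
        if len(stubs) % 2 == 1:
            stubs.pop(int(rng.integers(0, len(stubs))))
        try_match(stubs, forbid_same_comm=False)

    ext_stubs = []
    for i in range(N):
        ext_stubs.extend([i] * int(external[i]))
    if len(ext_stubs) % 2 == 1:
        ext_stubs.pop(int(rng.integers(0, len(ext_stubs))))
    try_match(ext_stubs, forbid_same_comm=True)

    graph = UndirectedGraph.from_edge_pairs(list(edges), nodes=list(range(N)))
    truth = Cover([frozenset(c) for c in comm_members], N)
    return BenchmarkInstance(
        graph=graph, truth=truth, bridges=bridges, params=params,
        target_degrees=[int(d) for d in degrees],
    )


def realized_mixing(instance: BenchmarkInstance):
    """Empirical mixing fractions ``(mu_hat, mu_o_hat)``.

    ``mu_hat``: mean over ordinary (non-bridge) nodes of the fraction of
    their links leaving their community. ``mu_o_hat``: mean over bridge
    nodes of ``1 - (average per-community internal fraction)``, matching
    the per-community interpretation of ``mu_o``. Either is ``None`` when
    its node class is empty or has only degree-0 members.
    """
    g = instance.graph
    ms = instance.truth.memberships()
    comm = [set(c) for c in instance.truth.communities]
    mu_vals = []
    muo_vals = []
    for i in range(g.n):
        neigh = g.adjacency[i]
        if not neigh:
            continue
        if i in instance.bridges:
            fracs = [
                len(neigh & (comm[k] - {i})) / len(neigh) for k in ms[i]
            ]
            muo_vals.append(1.0 - float(np.mean(fracs)))
        else:
            inside = {j for k in ms[i] for j in comm[k]} - {i}
            mu_vals.append(1.0 - len(neigh & inside) / len(neigh))
    mu_hat = float(np.mean(mu_vals)) if mu_vals else None
    muo_hat = float(np.mean(muo_vals)) if muo_vals else None
    return mu_hat, muo_hat
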