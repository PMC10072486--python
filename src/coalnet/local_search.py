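"""Local Stability Exploration: feasibility-preserving steepest-ascent search.

Explores covers by three move kinds — Add a node to a community, Remove a
node from a community, Swap two nodes between two communities — always
keeping the cover complete (no orphaned node), within the membership cap
``p``, inclusion-free, and (in the feasible phase) with every modified
community defection-stable. Objective deltas are computed incrementally
from the membership structure, never by re-summing the whole objective.

Infeasible starts (random covers with unstable communities) are handled in
two phases: phase 1 applies improving moves while ignoring stability, and
the search switches permanently to the stability-enforcing phase 2 as soon
as every community is stable. A phase-1 iteration cap prevents
non-termination on hopeless starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .game import Cover, cover_objective, is_stable
from .milp import build_fsh_mod, solve
from .weights import PairWeightTable

__all__ = [
    "Move",
    "LSEState",
    "feasible_moves",
    "delta_add",
    "delta_remove",
    "delta_swap",
    "lse_run",
    "initial_solution",
    "multi_start_lse",
    "LSEFailure",
]

ADD, REMOVE, SWAP = 1, 2, 3
_TOL = 1e-9


class LSEFailure(RuntimeError):
    """No feasible (stable) cover was reached from any start."""


@dataclass(frozen=True)
class Move:
    kind: int                 # ADD, REMOVE or SWAP
    i: int
    k: int
    i2: int | None = None     # swap partner
    k2: int | None = None
    delta: float = 0.0


@dataclass
class LSEState:
    """Mutable search state: communities, memberships, objective."""

    table: PairWeightTable
    communities: list            # list[set[int]]
    p: int
    enforce_stability: bool = True

    def __post_init__(self):
        self.n = self.table.n
        self.w = self.table.values
        self.row_tot = self.w.sum(axis=1)
        self.communities = [set(c) for c in self.communities]
        self.memberships = [set() for _ in range(self.n)]
        for k, c in enumerate(self.communities):
            for i in c:
                self.memberships[i].add(k)
        if any(not ms for ms in self.memberships):
            raise ValueError("start cover must cover every node")
        if any(len(ms) > self.p for ms in self.memberships):
            raise ValueError("start cover exceeds the membership cap")
        if any(not c for c in self.communities):
            raise ValueError("start cover has an empty community")
        # in_sum[i, k] = sum of W_ij over j in S_k, j != i
        self.in_sum = np.zeros((self.n, len(self.communities)))
        for k, c in enumerate(self.communities):
            for i in range(self.n):
                self.in_sum[i, k] = sum(self.w[i, j] for j in c if j != i)
        self.objective = cover_objective(self.table, self.cover())

    def cover(self) -> Cover:
        return Cover([frozenset(c) for c in self.communities], self.n)

    # -- feasibility predicates ------------------------------------------

    def community_deficit(self, k: int, add: int | None = None, remove: int | None = None) -> float:
        """Total stability deficit of ``S_k`` after a hypothetical change.

        Sum over members of ``max(0, phi_i(outside) - phi_i(S_k))``; zero iff
        the community is defection-stable."""
        members = self.communities[k]
        check = set(members)
        if remove is not None:
            check.discard(remove)
        if add is not None:
            check.add(add)
        deficit = 0.0
        for i in check:
            if add is not None and i == add:
                s = self.in_sum[add, k]
            else:
                s = self.in_sum[i, k]
                if add is not None:
                    s += self.w[i, add]
            if remove is not None and i != remove:
                s -= self.w[i, remove]
            # Shapley margin: inside - outside = (2 s - row_tot) / 2
            gap = (self.row_tot[i] - 2.0 * s) / 2.0
            if gap > _TOL:
                deficit += gap
        return deficit

    def community_stable(self, k: int, add: int | None = None, remove: int | None = None) -> bool:
        return self.community_deficit(k, add=add, remove=remove) <= _TOL

    def total_deficit(self) -> float:
        return sum(self.community_deficit(k) for k in range(len(self.communities)))

    def _hypothetical(self, k: int, add=None, remove=None) -> set:
        c = set(self.communities[k])
        if add is not None:
            c.add(add)
        if remove is not None:
            c.discard(remove)
        return c

    def inclusion_free_after(self, changed: dict) -> bool:
        """``changed`` maps community index -> its new member set."""
        comms = [changed.get(k, c) for k, c in enumerate(self.communities)]
        for a in range(len(comms)):
            for b in range(len(comms)):
                if a != b and comms[a] <= comms[b]:
                    return False
        return True

    def all_stable(self) -> bool:
        return self.total_deficit() <= _TOL

    # -- applying moves ---------------------------------------------------

    def _join(self, i: int, k: int) -> None:
        self.communities[k].add(i)
        self.memberships[i].add(k)
        for j in range(self.n):
            if j != i:
                self.in_sum[j, k] += self.w[j, i]

    def _leave(self, i: int, k: int) -> None:
        self.communities[k].discard(i)
        self.memberships[i].discard(k)
        for j in range(self.n):
            if j != i:
                self.in_sum[j, k] -= self.w[j, i]

    def apply(self, move: Move) -> None:
        if move.kind == ADD:
            self._join(move.i, move.k)
        elif move.kind == REMOVE:
            self._leave(move.i, move.k)
        else:
            self._leave(move.i, move.k)
            self._leave(move.i2, move.k2)
            self._join(move.i, move.k2)
            self._join(move.i2, move.k)
        self.objective += move.delta


def delta_add(state: LSEState, i: int, k: int) -> float:
    """Objective gain of adding ``i`` to ``S_k``: newly co-membered pairs only."""
    if i in state.communities[k]:
        raise ValueError("node already in community")
    ms_i = state.memberships[i]
    return float(sum(
        state.w[i, j] for j in state.communities[k] if not (ms_i & state.memberships[j])
    ))


def delta_remove(state: LSEState, i: int, k: int) -> float:
    """Objective change of removing ``i`` from ``S_k``: pairs co-membered only
    through ``S_k`` stop counting."""
    if i not in state.communities[k]:
        raise ValueError("node not in community")
    ms_i = state.memberships[i]
    return float(-sum(
        state.w[i, j]
        for j in state.communities[k]
        if j != i and len(ms_i & state.memberships[j]) == 1
    ))


def delta_swap(state: LSEState, i: int, k: int, i2: int, k2: int) -> float:
    """Objective change of swapping ``i`` (from ``S_k``) with ``i2`` (from
    ``S_k2``); all membership-overlap conditions on the pre-move state.

    Per swapped node: gains over the destination's members it shared no
    community with, losses over source members co-membered only through the
    source and not themselves in the destination.
    """
    comm, ms, w = state.communities, state.memberships, state.w
    if i not in comm[k] or i2 not in comm[k2] or i in comm[k2] or i2 in comm[k] or k == k2:
        raise ValueError("invalid swap preconditions")

    def one_side(a, src, dst, other):
        ms_a = ms[a]
        gain = sum(
            w[a, j] for j in comm[dst]
            if j != other and not (ms_a & ms[j])
        )
        loss = sum(
            w[a, j] for j in comm[src]
            if j != a and j not in comm[dst] and len(ms_a & ms[j]) == 1
        )
        return gain - loss

    return float(one_side(i, k, k2, i2) + one_side(i2, k2, k, i))


def feasible_moves(state: LSEState) -> list[Move]:
    """All admissible moves with their deltas, in the fixed scan order
    (ascending i, then k, then swap partner)."""
    moves: list[Move] = []
    comm = state.communities
    n_c = len(comm)
    for i in range(state.n):
        for k in range(n_c):
            if i not in comm[k]:
                # Add
                if len(state.memberships[i]) < state.p:
                    if not state.enforce_stability or state.community_stable(k, add=i):
                        newc = state._hypothetical(k, add=i)
                        if state.inclusion_free_after({k: newc}):
                            moves.append(Move(ADD, i, k, delta=delta_add(state, i, k)))
            else:
                # Remove
                if len(state.memberships[i]) >= 2 and len(comm[k]) >= 2:
                    if not state.enforce_stability or state.community_stable(k, remove=i):
                        newc = state._hypothetical(k, remove=i)
                        if state.inclusion_free_after({k: newc}):
                            moves.append(Move(REMOVE, i, k, delta=delta_remove(state, i, k)))
    for i in range(state.n):
        for k in sorted(state.memberships[i]):
            for i2 in range(state.n):
                if i2 == i or k in state.memberships[i2]:
                    continue
                for k2 in sorted(state.memberships[i2]):
                    if k2 == k or k2 in state.memberships[i]:
                        continue
                    ok = True
                    if state.enforce_stability:
                        ok = (state.community_stable(k, add=i2, remove=i)
                              and state.community_stable(k2, add=i, remove=i2))
                    if ok:
                        ck = state._hypothetical(k, add=i2, remove=i)
                        ck2 = state._hypothetical(k2, add=i, remove=i2)
                        if state.inclusion_free_after({k: ck, k2: ck2}):
                            moves.append(Move(SWAP, i, k, i2, k2,
                                              delta=delta_swap(state, i, k, i2, k2)))
    return moves


def _move_deficit_change(state: LSEState, mv: Move) -> float:
    if mv.kind == ADD:
        return state.community_deficit(mv.k, add=mv.i) - state.community_deficit(mv.k)
    if mv.kind == REMOVE:
        return state.community_deficit(mv.k, remove=mv.i) - state.community_deficit(mv.k)
    return (
        state.community_deficit(mv.k, add=mv.i2, remove=mv.i)
        - state.community_deficit(mv.k)
        + state.community_deficit(mv.k2, add=mv.i, remove=mv.i2)
        - state.community_deficit(mv.k2)
    )


def lse_run(
    table: PairWeightTable,
    start: Cover,
    p: int,
    max_iters: int = 10_000,
    phase1_cap_factor: int = 50,
):
    """Steepest-ascent run from one start; returns ``(cover, trace)``.

    ``trace`` is the list of objective values after each accepted move.
    An unstable start first goes through a repair phase: steepest descent
    on the total stability deficit (ties broken by the objective delta),
    which strictly decreases a bounded quantity and therefore terminates;
    it ends at zero deficit (success) or at a deficit local minimum
    (`LSEFailure`). The stability-enforcing ascent then applies the single
    best strictly-improving move per iteration, preferring a swap whenever
    its delta beats both zero and the best add/remove delta, and stops at a
    local optimum.
    """
    state = LSEState(table, list(start.communities), p, enforce_stability=True)

    # phase 1: repair an unstable start by steepest deficit descent
    if not state.all_stable():
        state.enforce_stability = False
        for _ in range(phase1_cap_factor * state.n):
            if state.all_stable():
                break
            moves = feasible_moves(state)
            chosen, best_key = None, (-_TOL, -np.inf)
            for mv in moves:
                dv = _move_deficit_change(state, mv)
                key = (-dv, mv.delta)
                if dv < -_TOL and key > best_key:
                    chosen, best_key = mv, key
            if chosen is None:
                break
            state.apply(chosen)
        if not state.all_stable():
            raise LSEFailure("start never reached a stable cover")
        state.enforce_stability = True

    trace = [state.objective]
    for _ in range(max_iters):
        moves = feasible_moves(state)
        best_ar = None
        best_swap = None
        for mv in moves:
            if mv.kind == SWAP:
                if best_swap is None or mv.delta > best_swap.delta + _TOL:
                    best_swap = mv
            else:
                if best_ar is None or mv.delta > best_ar.delta + _TOL:
                    best_ar = mv
        ar_delta = best_ar.delta if best_ar is not None else -np.inf
        if best_swap is not None and best_swap.delta > max(0.0, ar_delta) + _TOL:
            chosen = best_swap
        elif best_ar is not None and ar_delta > _TOL:
            chosen = best_ar
        else:
            break  # local optimum
        state.apply(chosen)
        trace.append(state.objective)
    return state.cover(), trace


def _seeded_affinity_cover(
    table: PairWeightTable, n_c: int, rng: np.random.Generator
) -> Cover:
    """Partition grown from random seeds: each node joins the community to
    which its total weight is largest (random insertion order). Disjoint
    non-empty blocks, hence inclusion-free; stability is left to repair."""
    n = table.n
    w = table.values
    seeds = rng.choice(n, size=n_c, replace=False)
    comms = [{int(s)} for s in seeds]
    for i in rng.permutation(n):
        if i in seeds:
            continue
        aff = [sum(w[i, j] for j in c) for c in comms]
        comms[int(np.argmax(aff))].add(int(i))
    return Cover([frozenset(c) for c in comms], n)


def _random_cover(n: int, n_c: int, p: int, rng: np.random.Generator) -> Cover:
    for _ in range(200):
        comms = [set() for _ in range(n_c)]
        for i in range(n):
            q = int(rng.integers(1, p + 1))
            for k in rng.choice(n_c, size=min(q, n_c), replace=False):
                comms[int(k)].add(i)
        # patch empty communities with a random multi-covered or random node
        for k, c in enumerate(comms):
            if not c:
                c.add(int(rng.integers(0, n)))
        cover = Cover([frozenset(c) for c in comms], n)
        if cover.is_inclusion_free() and cover.is_p_bounded(p):
            return cover
    raise LSEFailure("could not draw a valid random start")


def initial_solution(
    table: PairWeightTable,
    n_c: int,
    p: int,
    strategy: str = "seeded_affinity",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    ilp_time_limit_s: float = 300.0,
    ilp_node_limit: int = 100,
) -> Cover:
    """Produce a start cover.

    ``seeded_affinity`` (default): affinity partition around random seeds —
    cheap and structurally informed, usually unstable (repaired by the
    search). ``random_cover``: each node in 1..p random communities.
    ``disjoint_ilp``: the optimal non-overlapping partition (cap ``p = 1``).
    ``first_feasible_ilp``: an incumbent from branch-and-bound truncated
    after a bounded number of nodes — the strongest (and costliest) start,
    intended for instances whose stability landscape defeats the cheap
    starts."""
    if rng is None:
        rng = np.random.default_rng(seed)
    if strategy == "seeded_affinity":
        return _seeded_affinity_cover(table, n_c, rng)
    if strategy == "random_cover":
        return _random_cover(table.n, n_c, p, rng)
    if strategy == "disjoint_ilp":
        res = solve(build_fsh_mod(table, n_c, 1), time_limit_s=ilp_time_limit_s)
        if res.cover is None:
            raise LSEFailure("disjoint ILP found no cover")
        return res.cover
    if strategy == "first_feasible_ilp":
        res = solve(build_fsh_mod(table, n_c, p), time_limit_s=ilp_time_limit_s,
                    node_limit=ilp_node_limit)
        if res.cover is None:
            raise LSEFailure("truncated ILP found no cover")
        return res.cover
    raise ValueError(f"unknown start strategy {strategy!r}")


def multi_start_lse(
    table: PairWeightTable,
    n_c: int,
    p: int,
    t_max: int = 10,
    seed: int = 0,
    strategy: str = "seeded_affinity",
    max_iters: int = 10_000,
):
    """Best-of-``t_max`` independent runs; deterministic given ``seed``.

    ``strategy`` names a single start family, or ``"mixed"``: the first
    start is a truncated branch-and-bound incumbent and the remaining
    ``t_max - 1`` are seeded-affinity partitions — the combination used for
    the hardest small instances.

    Returns ``(best_cover, best_objective, report)`` where the report lists
    per-start objectives (``None`` for failed starts)."""
    if t_max < 1:
        raise ValueError("t_max must be >= 1")
    rng = np.random.default_rng(seed)
    best_cover, best_obj = None, -np.inf
    per_start = []
    for t in range(t_max):
        if strategy == "mixed":
            start_strategy = "first_feasible_ilp" if t == 0 else "seeded_affinity"
        else:
            start_strategy = strategy
        result = None
        # a start whose repair phase dead-ends is redrawn a few times; the
        # redraws consume the same seed stream, so results stay reproducible
        for _attempt in range(5):
            try:
                start = initial_solution(table, n_c, p, strategy=start_strategy, rng=rng)
                result = lse_run(table, start, p, max_iters=max_iters)
                break
            except LSEFailure:
                if start_strategy in ("disjoint_ilp", "first_feasible_ilp"):
                    break  # deterministic start: retrying cannot help
        if result is None:
            per_start.append(None)
            continue
        cover, trace = result
        obj = trace[-1]
        per_start.append(obj)
        if obj > best_obj:
            best_cover, best_obj = cover, obj
    if best_cover is None:
        raise LSEFailure("no start reached a feasible cover")
    return best_cover, best_obj, {"per_start": per_start, "t_max": t_max, "seed": seed}
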