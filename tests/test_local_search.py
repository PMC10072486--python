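import numpy as np
import pytest

from coalnet.game import Cover, cover_objective, is_stable
from coalnet.local_search import (
    ADD,
    REMOVE,
    SWAP,
    LSEFailure,
    LSEState,
    Move,
    delta_add,
    delta_remove,
    delta_swap,
    feasible_moves,
    initial_solution,
    lse_run,
    multi_start_lse,
)
from coalnet.milp import brute_force_optimal_cover
from coalnet.null_model import exact_corrected_weights
from tests.conftest import random_graph


def _random_state(table, rng, n_c=3, p=2):
    """A random complete, p-bounded, inclusion-free, non-empty-communities
    state (stability not required: enforce_stability left off)."""
    n = table.n
    for _ in range(100):
        comms = [set() for _ in range(n_c)]
        for i in range(n):
            q = int(rng.integers(1, p + 1))
            for k in rng.choice(n_c, size=q, replace=False):
                comms[int(k)].add(i)
        for c in comms:
            if not c:
                c.add(int(rng.integers(0, n)))
        cover = Cover(comms, n)
        if cover.is_inclusion_free():
            state = LSEState(table, comms, p, enforce_stability=False)
            return state
    raise RuntimeError("no valid random state")


def _apply_and_recompute(state, move):
    """Oracle: objective after the move minus before, by full recomputation."""
    before = cover_objective(state.table, state.cover())
    state.apply(move)
    after = cover_objective(state.table, state.cover())
    return after - before


class TestDeltas:
    def test_add_example_path3(self, path3_wstar):
        state = LSEState(path3_wstar, [{0, 1}, {1, 2}], 2, enforce_stability=False)
        # adding c to {a, b}: pairs (c,a) and (c,b)... but (c,b) already share S_2
        assert delta_add(state, 2, 0) == pytest.approx(-0.5)

    def test_deltas_match_recompute_oracle(self, small_weighted_suite):
        rng = np.random.default_rng(0)
        checked = {ADD: 0, REMOVE: 0, SWAP: 0}
        while min(checked.values()) < 1000:
            _, _, ws = small_weighted_suite[int(rng.integers(len(small_weighted_suite)))]
            state = _random_state(ws, rng)
            moves = feasible_moves(state)
            if not moves:
                continue
            mv = moves[int(rng.integers(len(moves)))]
            measured = _apply_and_recompute(state, mv)
            assert mv.delta == pytest.approx(measured, abs=1e-9)
            checked[mv.kind] += 1

    def test_remove_is_inverse_of_add(self, small_weighted_suite):
        rng = np.random.default_rng(1)
        for _ in range(60):
            _, _, ws = small_weighted_suite[int(rng.integers(len(small_weighted_suite)))]
            state = _random_state(ws, rng)
            adds = [m for m in feasible_moves(state) if m.kind == ADD]
            if not adds:
                continue
            mv = adds[int(rng.integers(len(adds)))]
            state.apply(mv)
            back = delta_remove(state, mv.i, mv.k)
            assert back == pytest.approx(-mv.delta, abs=1e-9)

    def test_swap_antisymmetry(self, small_weighted_suite):
        rng = np.random.default_rng(2)
        seen = 0
        for _ in range(300):
            _, _, ws = small_weighted_suite[int(rng.integers(len(small_weighted_suite)))]
            state = _random_state(ws, rng)
            swaps = [m for m in feasible_moves(state) if m.kind == SWAP]
            if not swaps:
                continue
            mv = swaps[int(rng.integers(len(swaps)))]
            state.apply(mv)
            reverse = delta_swap(state, mv.i2, mv.k, mv.i, mv.k2)
            assert reverse == pytest.approx(-mv.delta, abs=1e-9)
            seen += 1
            if seen >= 50:
                break
        assert seen >= 20


class TestFeasibleMoves:
    def test_never_empties_or_orphans(self, small_weighted_suite):
        rng = np.random.default_rng(3)
        for _ in range(30):
            _, _, ws = small_weighted_suite[int(rng.integers(len(small_weighted_suite)))]
            state = _random_state(ws, rng)
            for mv in feasible_moves(state):
                if mv.kind == REMOVE:
                    assert len(state.communities[mv.k]) >= 2
                    assert len(state.memberships[mv.i]) >= 2

    def test_inclusion_blocked(self, path3_wstar):
        state = LSEState(path3_wstar, [{0, 1}, {1, 2}], 2, enforce_stability=False)
        adds = [(m.i, m.k) for m in feasible_moves(state) if m.kind == ADD]
        # adding c to {a,b} would create {a,b,c} containing {b,c}: forbidden
        assert (2, 0) not in adds
        assert (0, 1) not in adds

    def test_applied_moves_keep_state_consistent(self, small_weighted_suite):
        rng = np.random.default_rng(4)
        _, _, ws = small_weighted_suite[0]
        state = _random_state(ws, rng)
        for _ in range(15):
            moves = feasible_moves(state)
            if not moves:
                break
            state.apply(moves[int(rng.integers(len(moves)))])
            cover = state.cover()
            assert cover.is_complete()
            assert cover.is_p_bounded(state.p)
            assert cover.is_inclusion_free()
            assert state.objective == pytest.approx(
                cover_objective(state.table, cover), abs=1e-8
            )


class TestLseRun:
    def test_local_optimum_is_fixed_point(self, path3_wstar):
        bf = brute_force_optimal_cover(path3_wstar, 2, 2)
        cover, trace = lse_run(path3_wstar, bf.cover, 2)
        assert len(trace) == 1
        assert cover.canonical() == bf.cover.canonical()

    def test_trace_strictly_increasing_in_stable_phase(self, small_weighted_suite):
        rng = np.random.default_rng(5)
        for _, _, ws in small_weighted_suite[:4]:
            try:
                start = initial_solution(ws, 2, 2, rng=rng)
                cover, trace = lse_run(ws, start, 2)
            except LSEFailure:
                continue
            assert all(b > a for a, b in zip(trace, trace[1:]))
            for c in cover.communities:
                assert is_stable(ws, c)[0]

    def test_reaches_overlapping_optimum_on_path3(self, path3_wstar):
        start = Cover([{0, 1, 2}, {0, 1}], 3)
        cover, trace = lse_run(path3_wstar, start, 2)
        assert trace[-1] == pytest.approx(1.0)


class TestStarts:
    def test_random_cover_reproducible(self, path3_wstar):
        a = initial_solution(path3_wstar, 2, 2, strategy="random_cover", seed=9)
        b = initial_solution(path3_wstar, 2, 2, strategy="random_cover", seed=9)
        assert a.canonical() == b.canonical()

    def test_seeded_affinity_is_partition(self, small_weighted_suite):
        _, _, ws = small_weighted_suite[0]
        cover = initial_solution(ws, 2, 2, strategy="seeded_affinity", seed=0)
        assert cover.is_complete() and cover.is_p_bounded(1)

    def test_disjoint_ilp_is_partition(self, path3_wstar):
        cover = initial_solution(path3_wstar, 2, 2, strategy="disjoint_ilp")
        assert cover.is_p_bounded(1) and cover.is_complete()


class TestMultiStart:
    def test_tmax1_equals_single_run(self, small_weighted_suite):
        _, _, ws = small_weighted_suite[1]
        rng = np.random.default_rng(11)
        start = initial_solution(ws, 2, 2, rng=np.random.default_rng(11))
        _, trace = lse_run(ws, start, 2)
        _, obj, _ = multi_start_lse(ws, 2, 2, t_max=1, seed=11)
        assert obj == pytest.approx(trace[-1])

    def test_best_objective_monotone_in_tmax(self, small_weighted_suite):
        _, _, ws = small_weighted_suite[2]
        objs = [multi_start_lse(ws, 2, 2, t_max=t, seed=5)[1] for t in (1, 3, 6)]
        assert objs[0] <= objs[1] + 1e-9 <= objs[2] + 2e-9

    def test_deterministic_given_seed(self, small_weighted_suite):
        _, _, ws = small_weighted_suite[3]
        a = multi_start_lse(ws, 2, 2, t_max=4, seed=7)
        b = multi_start_lse(ws, 2, 2, t_max=4, seed=7)
        assert a[1] == b[1]
        assert a[0].canonical() == b[0].canonical()
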