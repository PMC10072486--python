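from fractions import Fraction

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from coalnet.game import coalition_value
from coalnet.graph import UndirectedGraph, load_fixture
from coalnet.null_model import (
    ExactBudgetError,
    MatchingOracle,
    count_matchings,
    exact_corrected_weights,
    expected_weight,
    expected_weight_table,
    p_adjacency,
    p_common_neighbour,
    p_triangle,
    stub_pair_probability,
)
from coalnet.weights import raw_weights
from tests.conftest import random_graph


@pytest.mark.parametrize("m, expected", [(0, 1), (1, 1), (2, 3), (3, 15), (5, 945)])
def test_count_matchings(m, expected):
    assert count_matchings(m) == expected


@pytest.mark.parametrize("m, expected", [(1, 1), (2, Fraction(1, 3)), (10, Fraction(1, 19))])
def test_stub_pair_probability(m, expected):
    assert stub_pair_probability(m) == expected


class TestClosedForms:
    def test_pinned_values(self):
        assert p_adjacency(1, 1, 1) == 1
        assert p_adjacency(2, 2, 2) == Fraction(2, 3)
        assert p_adjacency(0, 3, 5) == 0
        assert p_common_neighbour(1, 1, 2, 2) == Fraction(2, 3)
        assert p_common_neighbour(1, 2, 1, 2) == 0   # r has one stub only
        assert p_common_neighbour(0, 2, 2, 3) == 0
        assert p_triangle(2, 2, 2, 3) == Fraction(8, 15)
        assert p_triangle(1, 4, 3, 4) == 0           # k_i = 1 cannot close a triangle
        assert p_triangle(2, 2, 1, 3) == 0

    @given(m=st.integers(min_value=1, max_value=50))
    @settings(deadline=None, derandomize=True)
    def test_adjacency_of_two_leaves_is_stub_pair_probability(self, m):
        assert p_adjacency(1, 1, m) == stub_pair_probability(m)

    @given(
        m=st.integers(min_value=2, max_value=40),
        k_i=st.integers(min_value=1, max_value=8),
        k_j=st.integers(min_value=1, max_value=8),
        k_r=st.integers(min_value=1, max_value=8),
    )
    @settings(deadline=None, derandomize=True, max_examples=150)
    def test_probability_bounds_and_dominance(self, m, k_i, k_j, k_r):
        assume(k_i + k_j + k_r <= 2 * m)  # realisable on an m-edge graph
        a = p_adjacency(k_i, k_j, m)
        c = p_common_neighbour(k_i, k_j, k_r, m)
        t = p_triangle(k_i, k_j, k_r, m)
        assert 0 <= a <= 1 and 0 <= c <= 1 and 0 <= t <= 1
        assert t <= c
        assert t <= a


def _degree_sequences(max_m=5):
    """All sorted degree sequences (3-5 nodes, degrees >= 1) with m <= max_m."""
    out = []
    for n in (3, 4, 5):
        def rec(prefix, remaining):
            if len(prefix) == n:
                if sum(prefix) % 2 == 0 and 1 <= sum(prefix) // 2 <= max_m:
                    out.append(tuple(prefix))
                return
            lo = prefix[-1] if prefix else 1
            for k in range(lo, 2 * max_m):
                if sum(prefix) + k + (n - len(prefix) - 1) > 2 * max_m:
                    break
                rec(prefix + [k], remaining)
        rec([], None)
    return out


@pytest.mark.parametrize("degrees", _degree_sequences(4))
def test_closed_forms_equal_enumeration(degrees):
    """Exact rational equality between the inclusion-exclusion series and
    brute-force matching enumeration, for every pair and triple role."""
    oracle = MatchingOracle(degrees)
    stats = oracle.all_statistics()
    m = oracle.m
    n = len(degrees)
    for (i, j), prob in stats["adjacency"].items():
        assert p_adjacency(degrees[i], degrees[j], m) == prob
    for (i, j, r), prob in stats["cn"].items():
        assert p_common_neighbour(degrees[i], degrees[j], degrees[r], m) == prob
    for (i, j, r), prob in stats["triangle"].items():
        assert p_triangle(degrees[i], degrees[j], degrees[r], m) == prob


def test_symmetry_of_common_neighbour_in_ij():
    rng = np.random.default_rng(1)
    for _ in range(50):
        m = int(rng.integers(2, 25))
        k_i, k_j, k_r = (int(rng.integers(1, 7)) for _ in range(3))
        if k_i + k_j + k_r > 2 * m:
            continue
        assert p_common_neighbour(k_i, k_j, k_r, m) == p_common_neighbour(k_j, k_i, k_r, m)


class TestExpectedWeight:
    def test_path3_hand_values(self, path3):
        assert expected_weight(path3, 0, 1) == 1     # 1.5 * 2/3
        assert expected_weight(path3, 0, 2) == 1     # 2*(2/3)/4 + 2*(1/3)

    def test_against_matching_oracle_on_connected_graphs(self):
        for seed in range(6):
            g = random_graph(4, 0.6, seed=seed)
            if g.m > 5:
                continue
            oracle = MatchingOracle(tuple(g.degrees()))
            stats = oracle.all_statistics()
            for (i, j), ew in stats["expected_w"].items():
                assert expected_weight(g, i, j) == ew

    def test_isolated_endpoint_gives_zero(self):
        g = UndirectedGraph.from_edge_pairs([("a", "b")], nodes=["a", "b", "z"])
        assert expected_weight(g, 0, 2) == 0


class TestCorrectedWeights:
    def test_path3_wstar(self, path3_wstar):
        w = path3_wstar
        assert w.value(0, 1) == pytest.approx(0.5)
        assert w.value(1, 2) == pytest.approx(0.5)
        assert w.value(0, 2) == pytest.approx(-0.5)

    def test_sign_change_exists(self, small_weighted_suite):
        for _, _, ws in small_weighted_suite:
            assert (ws.values > 1e-12).any() and (ws.values < -1e-12).any()

    def test_deterministic_on_zachary(self, zachary, zachary_wstar):
        again = exact_corrected_weights(zachary)
        assert (again.values == zachary_wstar.values).all()

    def test_budget_error(self, zachary):
        with pytest.raises(ExactBudgetError, match="approx_corrected_weights"):
            exact_corrected_weights(zachary, m_max=10)

    def test_expected_table_nonnegative(self, path3):
        t = expected_weight_table(path3)
        assert (t.values >= 0).all()


def _convexity_violated(table, rng, trials=300):
    """Search a counterexample to phi(T+i)-phi(T) >= phi(S+i)-phi(S), S in T."""
    n = table.n
    for _ in range(trials):
        nodes = list(range(n))
        rng.shuffle(nodes)
        i = nodes[0]
        t_size = int(rng.integers(2, n - 1))
        T = set(nodes[1 : 1 + t_size])
        s_size = int(rng.integers(1, t_size))
        S = set(list(T)[:s_size])
        lhs = coalition_value(table, T | {i}) - coalition_value(table, T)
        rhs = coalition_value(table, S | {i}) - coalition_value(table, S)
        if lhs < rhs - 1e-9:
            return True
    return False


def test_corrected_game_nonconvex_raw_game_convex(small_weighted_suite):
    rng = np.random.default_rng(7)
    nonconvex_found = 0
    for _, raw, ws in small_weighted_suite:
        assert not _convexity_violated(raw, rng)
        if _convexity_violated(ws, rng):
            nonconvex_found += 1
    assert nonconvex_found >= len(small_weighted_suite) // 2
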