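import numpy as np
import pytest

from coalnet.game import Cover
from coalnet.metrics import (
    ConfusionCounts,
    bridge_confusion,
    bridge_metrics,
    compare_covers,
    omega_index,
    overlapping_nmi,
)


def _random_cover(n, n_c, rng, p=2):
    comms = [set() for _ in range(n_c)]
    for i in range(n):
        for k in rng.choice(n_c, size=int(rng.integers(1, p + 1)), replace=False):
            comms[int(k)].add(i)
    for c in comms:
        if not c:
            c.add(int(rng.integers(0, n)))
    return Cover(comms, n)


class TestOverlappingNmi:
    def test_identical_covers_give_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            c = _random_cover(30, 4, rng)
            assert overlapping_nmi(c, c) == pytest.approx(1.0)

    def test_pinned_partition_vs_whole(self):
        """Two blocks vs the single whole-set community: each block variable
        needs a full bit given Y, while Y itself is deterministic, so the
        index is exactly one half."""
        a = Cover([{0, 1}, {2, 3}], 4)
        b = Cover([{0, 1, 2, 3}], 4)
        assert overlapping_nmi(a, b) == pytest.approx(0.5)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            a = _random_cover(25, 3, rng)
            b = _random_cover(25, 4, rng)
            assert overlapping_nmi(a, b) == pytest.approx(overlapping_nmi(b, a))

    def test_mismatched_nodes_rejected(self):
        with pytest.raises(ValueError):
            overlapping_nmi(Cover([{0}], 1), Cover([{0, 1}], 2))

    def test_in_unit_interval(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = _random_cover(20, 3, rng)
            b = _random_cover(20, 5, rng)
            assert 0.0 <= overlapping_nmi(a, b) <= 1.0


class TestOmegaIndex:
    def test_identical_covers_give_one(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            c = _random_cover(25, 4, rng)
            assert omega_index(c, c) == pytest.approx(1.0)

    def test_pinned_zero_example(self):
        a = Cover([{0, 1}, {2, 3}], 4)
        b = Cover([{0, 1, 2}, {3}], 4)
        # obs = 3/6 pairs agree, exp = 1/2 -> omega = 0
        assert omega_index(a, b) == pytest.approx(0.0)

    def test_relabel_invariance(self):
        rng = np.random.default_rng(4)
        a = _random_cover(20, 3, rng)
        b = _random_cover(20, 3, rng)
        perm = rng.permutation(20)
        a2 = Cover([{int(perm[i]) for i in c} for c in a.communities], 20)
        b2 = Cover([{int(perm[i]) for i in c} for c in b.communities], 20)
        assert omega_index(a, b) == pytest.approx(omega_index(a2, b2))
        assert overlapping_nmi(a, b) == pytest.approx(overlapping_nmi(a2, b2))

    def test_independent_random_covers_near_zero(self):
        rng = np.random.default_rng(5)
        vals = []
        for _ in range(10):
            a = _random_cover(200, 5, rng)
            b = _random_cover(200, 5, rng)
            vals.append(omega_index(a, b))
        assert abs(np.mean(vals)) <= 0.1


class TestBridgeDetection:
    def test_exact_recovery(self):
        truth = Cover([{0, 1, 2}, {2, 3, 4}], 5)
        c = bridge_confusion({2}, truth)
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 0, 0, 4)
        m = bridge_metrics(c)
        assert m["accuracy"] == m["tpr"] == m["auc"] == m["precision"] == m["f1"] == 1.0
        assert m["fpr"] == 0.0

    def test_strict_partition_predicts_no_bridges(self):
        est = Cover([{0, 1}, {2, 3, 4}], 5)
        c = bridge_confusion({1, 2}, est)
        assert c.tp == 0 and c.fp == 0 and c.fn == 2

    def test_worked_counts_and_metrics(self):
        c = ConfusionCounts(tp=3, fp=1, fn=1, tn=15)
        m = bridge_metrics(c)
        assert m["accuracy"] == pytest.approx(0.9)
        assert m["tpr"] == pytest.approx(0.75)
        assert m["fpr"] == pytest.approx(0.0625)
        assert m["auc"] == pytest.approx(0.84375)
        assert m["precision"] == pytest.approx(0.75)
        assert m["f1"] == pytest.approx(0.75)

    def test_f1_is_harmonic_mean(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            tp, fp, fn, tn = (int(x) for x in rng.integers(0, 20, size=4))
            if tp + fp == 0 or tp + fn == 0 or tp == 0:
                continue
            m = bridge_metrics(ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn))
            harmonic = 2 * m["precision"] * m["tpr"] / (m["precision"] + m["tpr"])
            assert m["f1"] == pytest.approx(harmonic)

    def test_auc_one_iff_perfect(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            tp, fp, fn, tn = (int(x) for x in rng.integers(0, 10, size=4))
            if tp + fn == 0 or tn + fp == 0:
                continue
            m = bridge_metrics(ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn))
            assert (m["auc"] == 1.0) == (m["tpr"] == 1.0 and m["fpr"] == 0.0)

    def test_undefined_metrics_are_none(self):
        m = bridge_metrics(ConfusionCounts(tp=0, fp=0, fn=0, tn=10))
        assert m["tpr"] is None and m["precision"] is None and m["auc"] is None
        assert m["accuracy"] == 1.0


def test_compare_covers_bundle():
    truth = Cover([{0, 1, 2}, {2, 3, 4}], 5)
    row = compare_covers(truth, truth, truth_bridges={2})
    assert row["nmi"] == pytest.approx(1.0)
    assert row["omega"] == pytest.approx(1.0)
    assert row["fp"] == row["fn"] == 0
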