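"""Cover-comparison metrics: overlapping NMI, Omega index, bridge confusion.

The NMI variant is the Lancichinetti–Fortunato–Kertész (LFK) definition for
covers: each community is a binary membership variable, conditional
entropies are minimised over the other cover's communities subject to the
LFK admissibility condition, and the index is
``1 - (H(X|Y)_norm + H(Y|X)_norm) / 2``.

The Omega index is the chance-corrected fraction of node pairs on whose
*number* of shared communities the two covers agree — the overlapping
generalisation of the adjusted Rand index.

Bridge detection (a bridge is a node in at least two communities) is scored
by the usual confusion-matrix bundle, with ``AUC = (1 - FPR + TPR) / 2``.
Metrics with zero denominators are reported as ``None``, never as 0.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .game import Cover

__all__ = [
    "overlapping_nmi",
    "omega_index",
    "ConfusionCounts",
    "bridge_confusion",
    "bridge_metrics",
    "compare_covers",
]


def _h(p: float) -> float:
    """Entropy contribution ``-p log2 p`` (0 at p = 0)."""
    return 0.0 if p <= 0.0 else -p * np.log2(p)


def _conditional_entropy_term(a: np.ndarray, b: np.ndarray, n: int) -> float | None:
    """``H(X_a | X_b) = H(X_a, X_b) - H(X_b)`` if LFK-admissible, else None.

    ``a`` and ``b`` are boolean membership vectors. Admissibility requires
    ``h(11) + h(00) >= h(01) + h(10)``: community ``b`` must explain ``a``
    better than ``a``'s complement would.
    """
    p11 = np.count_nonzero(a & b) / n
    p10 = np.count_nonzero(a & ~b) / n
    p01 = np.count_nonzero(~a & b) / n
    p00 = np.count_nonzero(~a & ~b) / n
    if _h(p11) + _h(p00) < _h(p01) + _h(p10):
        return None
    joint = _h(p11) + _h(p10) + _h(p01) + _h(p00)
    hb = _h(p11 + p01) + _h(p10 + p00)
    return joint - hb


def _half_nmi(cover_x: Cover, cover_y: Cover) -> float:
    """Normalised ``H(X|Y)``: mean over X's communities of H(X_k|Y)/H(X_k)."""
    n = cover_x.n
    xs = [np.zeros(n, dtype=bool) for _ in cover_x.communities]
    for k, c in enumerate(cover_x.communities):
        xs[k][list(c)] = True
    ys = [np.zeros(n, dtype=bool) for _ in cover_y.communities]
    for k, c in enumerate(cover_y.communities):
        ys[k][list(c)] = True
    terms = []
    for a in xs:
        px = np.count_nonzero(a) / n
        hx = _h(px) + _h(1 - px)
        if hx == 0.0:
            terms.append(0.0)  # deterministic variable: perfectly explained
            continue
        cands = [t for b in ys if (t := _conditional_entropy_term(a, b, n)) is not None]
        hxy = min(cands) if cands else hx
        terms.append(hxy / hx)
    return float(np.mean(terms)) if terms else 0.0


def overlapping_nmi(cover_a: Cover, cover_b: Cover) -> float:
    """LFK normalised mutual information between two covers, in [0, 1]."""
    if cover_a.n != cover_b.n:
        raise ValueError("covers must be over the same node set")
    return 1.0 - 0.5 * (_half_nmi(cover_a, cover_b) + _half_nmi(cover_b, cover_a))


def omega_index(cover_a: Cover, cover_b: Cover) -> float:
    """Chance-corrected agreement on shared-community counts of node pairs."""
    n = cover_a.n
    if cover_b.n != n:
        raise ValueError("covers must be over the same node set")
    if n < 2:
        raise ValueError("need at least two nodes")
    ms_a = cover_a.memberships()
    ms_b = cover_b.memberships()
    total = n * (n - 1) // 2
    obs = 0
    dist_a: Counter = Counter()
    dist_b: Counter = Counter()
    for i in range(n):
        for j in range(i + 1, n):
            t_a = len(ms_a[i] & ms_a[j])
            t_b = len(ms_b[i] & ms_b[j])
            obs += t_a == t_b
            dist_a[t_a] += 1
            dist_b[t_b] += 1
    obs_frac = obs / total
    exp = sum(dist_a[t] * dist_b.get(t, 0) for t in dist_a) / total**2
    if exp >= 1.0 - 1e-15:
        if obs_frac >= 1.0 - 1e-15:
            return 1.0
        raise ValueError("omega undefined: expected agreement is 1 but observed < 1")
    return (obs_frac - exp) / (1.0 - exp)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def bridge_confusion(truth_bridges: set, estimated: Cover) -> ConfusionCounts:
    """Confusion counts for bridge detection (predicted = >= 2 memberships)."""
    predicted = estimated.bridge_nodes()
    truth = set(truth_bridges)
    universe = set(range(estimated.n))
    tp = len(predicted & truth)
    fp = len(predicted - truth)
    fn = len(truth - predicted)
    tn = len(universe - predicted - truth)
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def bridge_metrics(c: ConfusionCounts) -> dict:
    """Accuracy, TPR, FPR, AUC, precision, F1; undefined entries are None."""
    if c.total == 0:
        raise ValueError("empty confusion matrix")
    tpr = _ratio(c.tp, c.tp + c.fn)
    fpr = _ratio(c.fp, c.tn + c.fp)
    auc = None if tpr is None or fpr is None else (1.0 - fpr + tpr) / 2.0
    return {
        "accuracy": (c.tp + c.tn) / c.total,
        "tpr": tpr,
        "fpr": fpr,
        "auc": auc,
        "precision": _ratio(c.tp, c.tp + c.fp),
        "f1": _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
    }


def compare_covers(truth: Cover, estimated: Cover, truth_bridges: set | None = None) -> dict:
    """One metrics row: NMI, Omega, and (optionally) bridge confusion scores."""
    row: dict = {
        "nmi": overlapping_nmi(truth, estimated),
        "omega": omega_index(truth, estimated),
    }
    if truth_bridges is not None:
        c = bridge_confusion(truth_bridges, estimated)
        row.update(tp=c.tp, tn=c.tn, fp=c.fp, fn=c.fn)
        row.update(bridge_metrics(c))
    return row
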