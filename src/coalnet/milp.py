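"""Mixed-integer linear programs for stable-coalition community detection.

Two formulations are built as explicit sparse MILPs and solved with HiGHS
(through :func:`scipy.optimize.milp`):

* ``fsh_jk`` — maximise the total Shapley value over all communities
  (pairs count once per shared community) subject to coverage, stability,
  non-inclusion and symmetry-breaking constraints. With non-negative raw
  weights its optima are near-grand coalitions: the formulation exists to
  demonstrate that pathology exactly.
* ``fsh_mod`` — maximise the once-per-pair sum of *signed* null-corrected
  weights (``W*`` exact or ``W'`` approximate) subject to coverage, a
  membership cap ``p``, and a stability constraint valid for signed
  weights. This is the working detector.

Variables other than the memberships ``x_ik`` are declared continuous in
``[0, 1]``; the constraints force them to binary values at any integral
``x``. A brute-force cover enumerator provides the independent optimum on
tiny instances.
"""

from __future__ import annotations

import itertools
import time
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .game import Cover, cover_objective, is_stable, total_shapley
from .weights import PairWeightTable

__all__ = [
    "MILPInstance",
    "SolveResult",
    "build_fsh_jk",
    "build_fsh_mod",
    "solve",
    "brute_force_optimal_cover",
]


@dataclass
class MILPInstance:
    """An assembled MILP in ``max c'v`` form with two-sided row bounds."""

    name: str
    n: int
    n_c: int
    p: int | None
    objective: np.ndarray           # maximisation coefficients
    rows: sparse.csr_matrix
    row_lb: np.ndarray
    row_ub: np.ndarray
    var_lb: np.ndarray
    var_ub: np.ndarray
    integrality: np.ndarray
    weight_kind: str
    table: PairWeightTable = field(repr=False)

    def x_index(self, i: int, k: int) -> int:
        return i * self.n_c + k

    @property
    def num_vars(self) -> int:
        return self.objective.shape[0]

    def write_lp(self, target) -> None:
        """Export in CPLEX LP format (debugging aid)."""
        lines = ["Maximize", " obj: " + _lp_expr(
            {j: c for j, c in enumerate(self.objective) if c != 0.0}
        ), "Subject To"]
        coo = self.rows.tocoo()
        by_row: dict[int, dict[int, float]] = {}
        for r, c, v in zip(coo.row, coo.col, coo.data):
            by_row.setdefault(int(r), {})[int(c)] = float(v)
        for r in range(self.rows.shape[0]):
            expr = _lp_expr(by_row.get(r, {}))
            lb, ub = self.row_lb[r], self.row_ub[r]
            if np.isfinite(lb):
                lines.append(f" r{r}lo: {expr} >= {lb}")
            if np.isfinite(ub):
                lines.append(f" r{r}up: {expr} <= {ub}")
        lines.append("Bounds")
        for j in range(self.num_vars):
            lines.append(f" {self.var_lb[j]} <= v{j} <= {self.var_ub[j]}")
        lines.append("Binaries")
        lines.append(" " + " ".join(f"v{j}" for j in range(self.num_vars)
                                    if self.integrality[j]))
        lines.append("End")
        text = "\n".join(lines) + "\n"
        if hasattr(target, "write"):
            target.write(text)
        else:
            from pathlib import Path

            Path(target).write_text(text)


@dataclass
class SolveResult:
    cover: Cover | None
    objective: float | None
    status: str                     # optimal | time_limit_feasible | infeasible | no_solution
    bound: float | None
    wall_time_s: float
    formulation: str = ""
    weight_kind: str = ""


def _lp_expr(coeffs: dict[int, float]) -> str:
    parts = []
    for j, c in sorted(coeffs.items()):
        sign = "+" if c >= 0 else "-"
        parts.append(f"{sign} {abs(c)} v{j}")
    return " ".join(parts) if parts else "0 v0"


class _Builder:
    def __init__(self, num_vars: int):
        self.num_vars = num_vars
        self.data: list[float] = []
        self.ri: list[int] = []
        self.ci: list[int] = []
        self.lb: list[float] = []
        self.ub: list[float] = []
        self.nrows = 0

    def add_row(self, cols, vals, lb=-np.inf, ub=np.inf):
        r = self.nrows
        self.ri.extend([r] * len(cols))
        self.ci.extend(cols)
        self.data.extend(vals)
        self.lb.append(lb)
        self.ub.append(ub)
        self.nrows += 1

    def matrix(self) -> sparse.csr_matrix:
        return sparse.coo_matrix(
            (self.data, (self.ri, self.ci)), shape=(self.nrows, self.num_vars)
        ).tocsr()


def _pair_index(n: int):
    idx = {}
    for c, (i, j) in enumerate(itertools.combinations(range(n), 2)):
        idx[(i, j)] = c
    return idx


def build_fsh_jk(table: PairWeightTable, n_c: int) -> MILPInstance:
    """Total-Shapley maximisation over raw (non-negative) weights.

    Decision variables: binary memberships ``x_ik``; co-membership products
    ``z_ijk`` linearised by the three standard McCormick rows; indicator
    ``h_ikr`` (``i`` in community ``r`` but not ``k``) linearised likewise
    and used to forbid community ``r`` being contained in community ``k``;
    plus per-node coverage and size-ordering symmetry-breaking rows.
    """
    if n_c < 1:
        raise ValueError("n_c must be >= 1")
    n = table.n
    w = table.values
    pairs = _pair_index(n)
    kr_pairs = list(itertools.combinations(range(n_c), 2))
    num_x = n * n_c
    num_z = len(pairs) * n_c
    num_h = n * len(kr_pairs)
    num_vars = num_x + num_z + num_h

    def xi(i, k):
        return i * n_c + k

    def zi(i, j, k):
        return num_x + pairs[(min(i, j), max(i, j))] * n_c + k

    def hi(i, kr):
        return num_x + num_z + i * len(kr_pairs) + kr

    obj = np.zeros(num_vars)
    for (i, j), c in pairs.items():
        for k in range(n_c):
            obj[num_x + c * n_c + k] = w[i, j]

    b = _Builder(num_vars)
    # z linearisation: z <= x_ik, z <= x_jk, x_ik + x_jk - z <= 1
    for (i, j) in pairs:
        for k in range(n_c):
            z = zi(i, j, k)
            b.add_row([z, xi(i, k)], [1.0, -1.0], ub=0.0)
            b.add_row([z, xi(j, k)], [1.0, -1.0], ub=0.0)
            b.add_row([xi(i, k), xi(j, k), z], [1.0, 1.0, -1.0], ub=1.0)
    # stability: sum_j W_ij x_jk >= (x_ik / 2) sum_j W_ij
    row_tot = w.sum(axis=1)
    for i in range(n):
        for k in range(n_c):
            cols = [xi(j, k) for j in range(n) if j != i] + [xi(i, k)]
            vals = [w[i, j] for j in range(n) if j != i] + [-row_tot[i] / 2.0]
            b.add_row(cols, vals, lb=0.0)
    # h linearisation and non-inclusion
    for idx_kr, (k, r) in enumerate(kr_pairs):
        for i in range(n):
            h = hi(i, idx_kr)
            b.add_row([h, xi(i, k)], [1.0, 1.0], ub=1.0)          # h <= 1 - x_ik
            b.add_row([h, xi(i, r)], [1.0, -1.0], ub=0.0)         # h <= x_ir
            b.add_row([xi(i, r), xi(i, k), h], [1.0, -1.0, -1.0], ub=0.0)
        for i in range(n):
            # sum_j h_jkr >= x_ir  (some member of S_r lies outside S_k)
            cols = [hi(j, idx_kr) for j in range(n)] + [xi(i, r)]
            vals = [1.0] * n + [-1.0]
            b.add_row(cols, vals, lb=0.0)
    # symmetry breaking: community sizes non-increasing in the label
    for k in range(n_c - 1):
        cols = [xi(i, k) for i in range(n)] + [xi(i, k + 1) for i in range(n)]
        vals = [1.0] * n + [-1.0] * n
        b.add_row(cols, vals, lb=0.0)
    # coverage
    for i in range(n):
        b.add_row([xi(i, k) for k in range(n_c)], [1.0] * n_c, lb=1.0)

    integrality = np.zeros(num_vars)
    integrality[:num_x] = 1
    return MILPInstance(
        name="fsh_jk", n=n, n_c=n_c, p=None,
        objective=obj, rows=b.matrix(),
        row_lb=np.array(b.lb), row_ub=np.array(b.ub),
        var_lb=np.zeros(num_vars), var_ub=np.ones(num_vars),
        integrality=integrality, weight_kind=table.kind, table=table,
    )


def build_fsh_mod(
    table: PairWeightTable,
    n_c: int,
    p: int,
    include_z_lower: bool = True,
    symmetry_cut: bool = False,
) -> MILPInstance:
    """Once-per-pair objective over signed corrected weights.

    ``y_ij`` is 1 iff the pair shares at least one community: forced up by
    ``y >= x_ik + x_jk - 1`` and capped by ``y <= sum_k z_ijk``. Stability
    is written so that it binds only when ``x_ik = 1``, with the sum of the
    node's negative weights as the always-valid relaxation constant.
    ``include_z_lower`` keeps the ``z >= x + x - 1`` rows (harmless; a flag
    allows measuring the LP relaxation without them). ``symmetry_cut``
    optionally orders community sizes.
    """
    if n_c < 1 or p < 1:
        raise ValueError("n_c and p must be >= 1")
    n = table.n
    w = table.values
    pairs = _pair_index(n)
    num_x = n * n_c
    num_z = len(pairs) * n_c
    num_y = len(pairs)
    num_vars = num_x + num_z + num_y

    def xi(i, k):
        return i * n_c + k

    def zi(i, j, k):
        return num_x + pairs[(min(i, j), max(i, j))] * n_c + k

    def yi(i, j):
        return num_x + num_z + pairs[(min(i, j), max(i, j))]

    obj = np.zeros(num_vars)
    for (i, j), c in pairs.items():
        obj[num_x + num_z + c] = w[i, j]

    b = _Builder(num_vars)
    for (i, j) in pairs:
        for k in range(n_c):
            z = zi(i, j, k)
            b.add_row([z, xi(i, k)], [1.0, -1.0], ub=0.0)
            b.add_row([z, xi(j, k)], [1.0, -1.0], ub=0.0)
            if include_z_lower:
                b.add_row([xi(i, k), xi(j, k), z], [1.0, 1.0, -1.0], ub=1.0)
        # y_ij >= x_ik + x_jk - 1 for every k;  y_ij <= sum_k z_ijk
        for k in range(n_c):
            b.add_row([xi(i, k), xi(j, k), yi(i, j)], [1.0, 1.0, -1.0], ub=1.0)
        b.add_row(
            [yi(i, j)] + [zi(i, j, k) for k in range(n_c)],
            [1.0] + [-1.0] * n_c, ub=0.0,
        )
    # signed-weight stability:
    # sum_j W_ij x_jk - (S_i/2 - N_i) x_ik >= N_i,  N_i = sum of negative W_ij
    row_tot = w.sum(axis=1)
    neg_tot = np.where(w < 0, w, 0.0).sum(axis=1)
    for i in range(n):
        for k in range(n_c):
            cols = [xi(j, k) for j in range(n) if j != i] + [xi(i, k)]
            vals = [w[i, j] for j in range(n) if j != i] + [
                -(row_tot[i] / 2.0 - neg_tot[i])
            ]
            b.add_row(cols, vals, lb=neg_tot[i])
    # coverage and membership cap
    for i in range(n):
        b.add_row([xi(i, k) for k in range(n_c)], [1.0] * n_c, lb=1.0)
        b.add_row([xi(i, k) for k in range(n_c)], [1.0] * n_c, ub=float(p))
    if symmetry_cut:
        for k in range(n_c - 1):
            cols = [xi(i, k) for i in range(n)] + [xi(i, k + 1) for i in range(n)]
            vals = [1.0] * n + [-1.0] * n
            b.add_row(cols, vals, lb=0.0)

    integrality = np.zeros(num_vars)
    integrality[:num_x] = 1
    return MILPInstance(
        name="fsh_mod", n=n, n_c=n_c, p=p,
        objective=obj, rows=b.matrix(),
        row_lb=np.array(b.lb), row_ub=np.array(b.ub),
        var_lb=np.zeros(num_vars), var_ub=np.ones(num_vars),
        integrality=integrality, weight_kind=table.kind, table=table,
    )


def _decode_cover(model: MILPInstance, x: np.ndarray) -> Cover:
    n, n_c = model.n, model.n_c
    comms = []
    for k in range(n_c):
        members = frozenset(i for i in range(n) if x[model.x_index(i, k)] >= 0.5)
        if members:
            comms.append(members)
    # drop duplicated / included communities: for the once-per-pair objective
    # they contribute nothing, and the total-Shapley formulation forbids them
    # by constraint so this is a no-op there at optimality
    keep = []
    for c in sorted(comms, key=len, reverse=True):
        if not any(c <= other for other in keep):
            keep.append(c)
    return Cover(communities=keep, n=n)


def solve(
    model: MILPInstance,
    time_limit_s: float | None = None,
    mip_gap: float = 1e-6,
    node_limit: int | None = None,
    validate: bool = True,
) -> SolveResult:
    """Solve a built instance with HiGHS and decode/validate the cover.

    The returned objective is recomputed from the decoded cover (once per
    pair for ``fsh_mod``, once per shared community for ``fsh_jk``), so it
    is exactly consistent with the rest of the package rather than subject
    to solver tolerances.
    """
    options = {"mip_rel_gap": mip_gap, "disp": False}
    if time_limit_s is not None:
        options["time_limit"] = float(time_limit_s)
    if node_limit is not None:
        options["node_limit"] = int(node_limit)
    t0 = time.perf_counter()
    res = milp(
        c=-model.objective,
        constraints=LinearConstraint(model.rows, model.row_lb, model.row_ub),
        bounds=Bounds(model.var_lb, model.var_ub),
        integrality=model.integrality,
        options=options,
    )
    wall = time.perf_counter() - t0
    bound = -res.mip_dual_bound if getattr(res, "mip_dual_bound", None) is not None else None
    if res.x is None:
        status = "infeasible" if res.status == 2 else "no_solution"
        return SolveResult(None, None, status, bound, wall, model.name, model.weight_kind)
    cover = _decode_cover(model, res.x)
    if model.name == "fsh_mod":
        objective = cover_objective(model.table, cover)
    else:
        objective = total_shapley(model.table, cover)
    status = "optimal" if res.status == 0 else "time_limit_feasible"
    if validate:
        _validate_cover(model, cover)
    return SolveResult(cover, objective, status, bound, wall, model.name, model.weight_kind)


def _validate_cover(model: MILPInstance, cover: Cover) -> None:
    if not cover.is_complete():
        raise AssertionError("decoded cover does not cover every node")
    if model.p is not None and not cover.is_p_bounded(model.p):
        raise AssertionError("decoded cover violates the membership cap")
    if not cover.is_inclusion_free():
        raise AssertionError("decoded cover has nested communities")
    for c in cover.communities:
        stable, _ = is_stable(model.table, c, tol=1e-6)
        if not stable:
            raise AssertionError("decoded community is not stable")


def brute_force_optimal_cover(
    table: PairWeightTable,
    n_c: int,
    p: int,
    stability: bool = True,
    objective: str = "once_per_pair",
) -> SolveResult:
    """Exhaustive search over covers — the independent oracle (n <= 8, n_c <= 2).

    Enumerates every complete, inclusion-free, p-bounded cover with at most
    ``n_c`` communities, optionally filtered by per-community stability, and
    maximises either the once-per-pair sum (``fsh_mod``'s objective) or the
    per-shared-community sum (``fsh_jk``'s, pass ``objective="total_shapley"``).
    Subsets are bitmasks; intra-subset weight sums come from a subset DP so
    each candidate cover costs O(1).
    """
    n = table.n
    if n > 8 or n_c > 2:
        raise ValueError("brute force limited to n <= 8, n_c <= 2")
    if objective not in ("once_per_pair", "total_shapley"):
        raise ValueError("unknown objective")
    t0 = time.perf_counter()
    w = table.values
    full = (1 << n) - 1
    # val[mask] = sum of W over unordered pairs inside mask
    val = np.zeros(1 << n)
    for mask in range(1, 1 << n):
        low = (mask & -mask).bit_length() - 1
        rest = mask & (mask - 1)
        val[mask] = val[rest] + sum(w[low, j] for j in range(n) if rest >> j & 1)
    row_tot = w.sum(axis=1)
    stable_mask = np.ones(1 << n, dtype=bool)
    if stability:
        for mask in range(1, 1 << n):
            for i in range(n):
                if not mask >> i & 1:
                    continue
                inside = sum(w[i, j] for j in range(n) if j != i and mask >> j & 1)
                if inside < (row_tot[i] - inside) - 1e-9:
                    stable_mask[mask] = False
                    break

    best_masks = None
    best_val = -np.inf

    def consider(masks, value):
        nonlocal best_masks, best_val
        if value > best_val + 1e-12:
            best_masks, best_val = masks, value

    if stable_mask[full]:
        consider((full,), val[full])
    if n_c >= 2:
        for s1 in range(1, full + 1):
            if not stable_mask[s1]:
                continue
            for s2 in range(s1 + 1, full + 1):
                if s1 | s2 != full or s1 & s2 == s1 or s1 & s2 == s2:
                    continue  # incomplete or nested
                if p < 2 and s1 & s2:
                    continue
                if not stable_mask[s2]:
                    continue
                if objective == "once_per_pair":
                    value = val[s1] + val[s2] - val[s1 & s2]
                else:
                    value = val[s1] + val[s2]
                consider((s1, s2), value)
    wall = time.perf_counter() - t0
    if best_masks is None:
        return SolveResult(None, None, "infeasible", None, wall, "brute_force", table.kind)
    cover = Cover(
        [frozenset(i for i in range(n) if mask >> i & 1) for mask in best_masks], n
    )
    return SolveResult(cover, float(best_val), "optimal", float(best_val), wall,
                       "brute_force", table.kind)
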