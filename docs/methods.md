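# Methods

## The model

`coalnet` treats community detection as a cooperative-game problem. The
nodes of an unweighted simple graph `G = (V, E)` are players; every
unordered pair `(i, j)` carries a similarity weight, and the worth of a
coalition `S ⊆ V` is the sum of the weights of the pairs it encloses:

    φ(S) = Σ_{i<j ∈ S} W_ij .

In this family of games each player's Shapley value restricted to `S` is
half its total weight to the other members, `φ_i(S) = ½ Σ_{j∈S} W_ij`. A
coalition is **stable** when no member would earn more by defecting to the
complement-plus-itself:

    φ_i(S) ≥ φ_i((V \ S) ∪ {i})   for all i ∈ S,

with ties counting as stable. Communities are stable coalitions, and
because a node may sit in several stable coalitions, community structures
are *covers* (overlapping assignments), not partitions.

### Similarity weights

The raw weight combines the direct link and the common neighbourhood of a
pair through the partition ratio `P_ij = 1/k_i + 1/k_j` and the
neighbourhood ratio `CN_ij = (c_ij + 1) P_ij`, where `k` are degrees and
`c_ij` the common-neighbour count:

* `(CN_ij − P_ij)/4`  if `i, j` non-adjacent (both degrees ≥ 1);
* `P_ij`              if adjacent and one endpoint has degree 1;
* `2·CN_ij + P_ij`    if adjacent with both degrees > 1;
* `0`                 for any pair touching an isolated node.

Raw weights are non-negative, which makes the game **convex**: marginal
gains grow with coalition size, every Shapley value is maximised by huge
coalitions, and the optimal "communities" degenerate into copies of the
grand coalition missing one node. The `fsh_jk` formulation reproduces this
pathology on purpose; it is the motivation for the correction, not a
usable detector.

### The configuration-model correction

The cure is to measure each pair's weight against its expectation in a
null graph with the same degrees but no communities — the configuration
model, in which every edge is cut into two stubs and all `2m` stubs are
re-matched uniformly (self-pairings included in the matching count). The
corrected weight is

    W*_ij = W_ij − E[W_ij],

signed, hence a **non-convex** game in which small stable coalitions can
beat large ones. `E[W_ij]` needs three null probabilities — that two nodes
are adjacent, that a third node is a common neighbour, and that a triangle
closes — which have exact closed forms as alternating inclusion–exclusion
series over partial stub matchings (the probability that `t` disjoint stub
pairs all match is `1/Π_{p≤t}(2m+1−2p)`; a pair of given stubs matches
with probability `1/(2m−1)`).

**Numerics.** The alternating series cancel catastrophically in floating
point (terms grow combinatorially while the sum stays in `[0, 1]`), so all
probabilities are computed in exact rational arithmetic
(`fractions.Fraction`), memoised on `(k_i, k_j, k_r, m)`, and converted to
floats only when the dense pair table is assembled. Empty summation ranges
and recursive calls with fewer than one remaining edge contribute zero.
Exact tables are refused above a configurable budget (default `m_max =
1500` edges) — not for accuracy reasons but because the per-pair sum over
all third nodes makes dense tables slow on large graphs; beyond the budget
the approximate correction applies.

The cheaper approximation replaces `E[W_ij]` by the weighted-modularity
null term `W_i W_j / (2 W̄)` with `W_i = Σ_j W_ij`. Two conventions exist
for `W̄`: the sum of weights over *edges* or over *all pairs*. They differ
on generic graphs because raw weights live on non-edges too. The all-pairs
convention is the default: it is the one that reproduces the published
karate-club objective (122.578) — with the edges-only normaliser the
optimum provably cannot reach that value (the sum of all positive
corrected weights is already smaller). The edges-only variant remains
available behind the `convention` switch.

## Detection

### Exact: mixed-integer programming

Both formulations use binary memberships `x_ik` (node `i` in community
`k ≤ n_c`) with co-membership products linearised by McCormick rows, and a
per-node coverage row `Σ_k x_ik ≥ 1`. Stability is linear in `x` for fixed
`i, k`; for signed weights the constraint is deactivated at `x_ik = 0` by
the node's total negative weight (no big-M constant). The working
formulation (`fsh_mod`) maximises `Σ_{i<j} W*_ij y_ij` where `y_ij = 1`
iff the pair shares at least one community — counting each pair once makes
duplicated or nested communities worthless, so no explicit non-inclusion
constraints are needed — subject to the membership cap `Σ_k x_ik ≤ p`. The
demonstration formulation (`fsh_jk`) maximises the total Shapley value
(pairs count once per shared community) and needs explicit non-inclusion
(`h` variables) and size-ordering symmetry-breaking rows.

Models are solved with HiGHS through `scipy.optimize.milp`,
single-threaded and deterministic. Decoded covers (threshold `x ≥ 0.5`,
empty and dominated communities dropped) are re-validated — complete,
p-bounded, inclusion-free, every community stable — and the reported
objective is recomputed from the decoded cover rather than read from the
solver. Optimal objective values are solver-independent; solution *paths*
are not, and where the optimum is degenerate a different optimal cover of
equal objective may be returned.

A brute-force enumerator of all complete, inclusion-free, p-bounded covers
(bitmask subset DP, `n ≤ 8`, at most two communities) provides the
independent optimum that both formulations are tested against.

### Heuristic: local stability exploration

A steepest-ascent search over covers with three move kinds — Add a node to
a community, Remove one, or Swap two nodes between two communities — where
every applied move must keep the cover complete, within the membership
cap, inclusion-free, with non-empty and (in the stable phase) stable
modified communities. Move values are exact incremental deltas of the
once-per-pair objective: an Add counts only newly co-membered pairs, a
Remove only pairs co-membered solely through the abandoned community, a
Swap the corresponding four terms evaluated on the pre-move state; all
delta formulas are tested against full objective recomputation. A swap is
preferred whenever its delta beats both zero and the best add/remove
delta; ties break by the fixed scan order (ascending node, then
community), so runs are deterministic given the seed. Strict improvement
is required; the search stops at the first local optimum.

**Unstable starts.** Most cheap starting covers contain unstable
communities. A literal two-phase scheme that ignores stability while
ascending the objective and waits for a stable cover to appear never finds
one in practice (objective ascent exerts no pressure toward stability), so
the search instead opens with a *repair phase*: steepest descent on the
total stability deficit `Σ_k Σ_{i∈S_k} max(0, φ_i(outside) − φ_i(S_k))`,
ties broken by objective delta. The deficit strictly decreases, so repair
terminates; it either reaches zero deficit and hands over to the
stability-enforcing ascent, or dead-ends and the start is reported failed
(multi-start redraws it a few times).

**Starts and multi-start.** Four start families: `seeded_affinity`
(default — a partition grown around random seed nodes by total-weight
affinity; cheap and structurally informed), `random_cover`,
`disjoint_ilp` (the optimal non-overlapping partition), and
`first_feasible_ilp` (an incumbent from branch-and-bound truncated after a
bounded number of nodes, default 100 — enough for the solver's primal
heuristics to act beyond the root relaxation). The `mixed` strategy uses
one truncated-branch-and-bound start plus seeded-affinity starts; it is
the intended configuration for small instances whose stability landscape
defeats cheap starts. The karate-club optimum is such a case: its
overlapping community is stable only as a whole (every single-node
addition is blocked by the joining node's own defection margin), so no
monotone move path assembles it from a clean partition, and start quality
decides whether the heuristic attains the exact optimum. Multi-start keeps
the best of `t_max` independent runs and is deterministic given the seed.

## Benchmark generator

Synthetic instances emulate networks with planted overlapping communities:
degrees from a truncated power law (exponent 2, configurable mean, default
8, and cap), community sizes from a flatter truncated power law (exponent
1), `N_o` bridge nodes (default ⌈0.1·N⌉) in two to `p` communities and all
other nodes in exactly one. An ordinary node aims fraction `1 − μ` of its
links inside its community; a bridge node aims fraction `1 − μ_o` inside
*each* of its `q` communities, which forces `μ_o ≥ 1 − 1/p` (0.5 at
`p = 2`, ≈ 0.7 at `p = 3`). Edges are realised by per-community stub
matching, then a cross-community pass for external stubs, rejecting
self-loops, multi-edges and (for external stubs) same-community pairs.
Internal stubs that cannot be placed are dropped rather than externalised,
so at `μ = 0` the guarantee that ordinary nodes have no cross-community
links is exact; realised degrees may therefore fall slightly short of
their targets, and the empirical mixing `μ̂` (reported per instance)
tracks the requested `μ` to within sampling error.

What the generator does *not* emulate: degree–membership correlations,
hierarchical or nested communities, weighted or directed interactions.
Recovery scores on these benchmarks therefore speak to the detector's
ability to undo stub-matching-style mixing, not to any particular
empirical network.

## Evaluation metrics

Covers are compared with the Lancichinetti–Fortunato–Kertész overlapping
NMI (per-community binary membership variables; conditional entropies
minimised over the other cover subject to the admissibility condition
`h(1,1) + h(0,0) ≥ h(0,1) + h(1,0)`, falling back to the marginal entropy;
communities with zero marginal entropy contribute zero) and the Omega
index (chance-corrected agreement on the *number* of communities each
unordered node pair shares). Bridge detection — a predicted bridge is any
node with at least two memberships — is scored by the confusion-matrix
bundle with `AUC = (1 − FPR + TPR)/2`. Metrics with zero denominators are
reported as `None`, never as zero, so averages over replicates are not
silently biased. Sweeps average metrics per instance, then across
replicates.

## Default problem sizes

The test suite and the reproduction script run the exact MILPs on the
34-node karate club, solver-vs-enumeration identities on random graphs
with up to 8 nodes, and benchmark sweeps at 40 nodes, 4 communities,
3 bridges, 10 replicates per mixing value with 5 local-search starts —
desk-scale defaults chosen so a full reproduction completes on one CPU in
well under an hour; all sizes are parameters and can be raised.

## Known limitations

* The exact MILPs are practical only for tens of nodes; `n_c = 4` on the
  karate club already takes an open solver far longer than `n_c = 3`.
* The local search cannot create or destroy communities, so the start must
  supply the right number of non-empty communities; covers whose optima
  need fewer communities than `n_c` are reached only by leaving a
  community's worth of structure in another basin.
* Stability is the defection-to-complement notion only; the stronger
  any-subset notion is exposed as an exponential-time checker
  (`is_stable_strong`) but unused by the detectors.
* Generator constants (degree/size exponents, mean degree) are this
  package's conventions; recovery *trends* across mixing values are
  meaningful, exact table values are generator-specific.
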