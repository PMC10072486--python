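# coalnet

Overlapping community detection for undirected networks, built on a
cooperative-game view of communities: nodes are players, every node pair
carries a topological similarity weight, a coalition is worth the sum of
the weights it encloses, and a **community is a stable coalition** — one
that no member would leave for the rest of the graph, judged by Shapley
values (`φ_i(S) = ½ Σ_{j∈S} W_ij`). Because a node can sit in several
stable coalitions, the output is a *cover* (overlapping communities), and
the nodes in more than one community are the network's *bridges*. The
intended users are network scientists — in systems biology, sociology, or
anywhere interaction graphs arise — who want overlapping communities with
an explicit stability guarantee and, on small networks, a certificate of
optimality.

The raw similarity weights (built from degrees `k_i` and common-neighbour
counts via `P_ij = 1/k_i + 1/k_j` and `CN_ij = (c_ij + 1) P_ij`) are
non-negative, which makes the game convex and drags every detector toward
the grand coalition. The package's core is the cure: pair weights are
re-centred by their **exact expectation under the configuration model**
(degree-preserving random stub matching),

    W*_ij = W_ij − E[W_ij],

where `E[W_ij]` is assembled from closed-form adjacency, common-neighbour
and triangle probabilities — alternating inclusion–exclusion series over
stub matchings, evaluated in exact rational arithmetic. The signed `W*`
game is non-convex and its stable coalitions are real communities.
Detection is either exact (two mixed-integer linear programs solved with
HiGHS: the corrected model `fsh_mod`, and the uncorrected total-Shapley
model `fsh_jk` kept as a demonstration of the grand-coalition pathology)
or heuristic (multi-start local search with Add/Remove/Swap moves and a
stability-repair phase). A benchmark generator with planted overlapping
communities and bridge nodes, plus overlapping-NMI / Omega / bridge
confusion metrics, closes the validation loop.

## Worked example

The 3-node path `a–b–c` is the smallest instance where the correction
matters. Raw weights are `W_ab = W_bc = 1.5`, `W_ac = 0.5`; under the
2-edge configuration model every pair has expected weight exactly 1, so
`W*_ab = W*_bc = 0.5` and `W*_ac = −0.5`. With at most two communities and
two memberships per node, the optimal stable cover overlaps on the hub:

```python
>>> import coalnet as cn
>>> g = cn.load_fixture("path3")
>>> ws = cn.exact_corrected_weights(g)
>>> [round(ws.value(0, 1), 3), round(ws.value(1, 2), 3), round(ws.value(0, 2), 3)]
[0.5, 0.5, -0.5]
>>> res = cn.solve(cn.build_fsh_mod(ws, n_c=2, p=2))
>>> res.objective, [sorted(c) for c in res.cover.communities]
(1.0, [[0, 1], [1, 2]])
```

The objective 1.0 counts each co-membered pair once (`0.5 + 0.5`; the
negative pair `a,c` never shares a community), and node `b` — the only
node in both communities — is the bridge. The same optimum comes out of
exhaustive cover enumeration and of the local-search heuristic.

From the shell, the same pipeline on the bundled 34-node karate-club
network:

```bash
coalnet detect zachary --weights exact --nc 3 --p 2 --method ilp --out run/
# objective 157.652 status optimal -> run/communities.cover
```

The cover file lists one community per line in the input's node labels;
`report.json` records the objective, solver status, and the full
configuration. `coalnet generate` writes a benchmark instance (edge list,
ground-truth cover, bridge list, metadata), and `coalnet evaluate` scores
an estimated cover against the truth (NMI, Omega, bridge confusion
metrics) as a CSV row.

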