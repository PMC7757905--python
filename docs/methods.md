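# Methods

This note records the model implemented by `hgcrd`, the parameter
conventions, the numerical and tie-breaking choices, what the synthetic
generators do and do not emulate, and known limitations.

## Quantities

For a hypergraph `H = (V, E)` whose hyperedges are motif instances:

* `eta(v)` — number of hyperedges containing `v`;
* motif degree `d_M(v) = Σ_{e ∋ v} (|e| − 1)`, which reduces to
  `(k − 1) eta(v)` on a k-uniform hypergraph. The per-edge-additive form is
  the unique extension to variable hyperedge sizes consistent with the
  eligibility threshold `|e| − 1` (each incident hyperedge asks for one flow
  unit per co-member);
* `vol_M(S) = Σ_{v ∈ S} eta(v)` — hyperedge endpoints in `S`. Conductance
  ratios are identical under the `(k − 1)`-scaled volume for uniform
  hypergraphs, so the endpoint count is used throughout;
* `cut_M(S)` — hyperedges with at least one endpoint on each side;
* `phi_M(S) = cut_M(S) / min(vol_M(S), vol_M(V∖S))`, undefined when the
  smaller side has no endpoints. Undefined values raise rather than return a
  sentinel, because a silent sentinel corrupts the sweep's argmin.

For 3-node motifs, conductance on the weighted motif adjacency matrix
`W_M(i,j)` (co-occurrence counts) equals `phi_M` exactly: a cut triangle
contributes 2 to the weighted cut and weighted degrees double the endpoint
count, so the factors cancel. The test suite verifies this equivalence
exhaustively on small random graphs.

## The diffusion

State per node: flow `m_M(v)`, level `l(v) ∈ [0, h]`, excess
`ex(v) = max(m_M(v) − d_M(v), 0)`; per hyperedge: flow `m_M(e) ∈ [0, C]`.
All flows are integers at all times.

Inner routine: the lowest-level active node (FIFO among equal levels) picks
the first eligible hyperedge in its incidence list and pushes

```
Psi = min( floor(ex(v) / (|e|−1)),  min(l(v), C)·w_e − m_M(e),
           min_{u ∈ e∖v} (2 d_M(u) − m_M(u)) )
```

units to every co-member (the sender is debited `(|e|−1)·Psi`). With no
eligible hyperedge, or `Psi = 0` (receivers saturated at `2 d_M`), the node
relabels one level; at `l = h` it leaves the process. A node is active while
its excess covers its cheapest incident hyperedge,
`ex(v) ≥ min_{e ∋ v}(|e|−1)`. The edge weight `w_e` is 1 for hypergraph
diffusion; the motif-matrix variant sets it to `W_M(u, v)`, which is the
multigraph reading of motif-weighted edges (`W` parallel unit edges, each
with the level-coupled capacity `min(l(v), C)`), and uses weighted degrees
for `d`.

Outer loop, for `j = 0..t`: double flows, run the inner routine, sweep,
truncate `m_M ← min(m_M, d_M)`, and stop when the retained total drops to
`(2 d_M(s) 2^j)/tau` or less. The published pseudocode prints the stopping
inequality with `tau` multiplying the right-hand side, which can never fail
for `tau ≥ 1` since total flow never exceeds `2 d_M(s) 2^j`; the
implementation follows the accompanying prose — stop when retained flow is
*significantly less* than the no-bottleneck total, i.e. more than a
`1 − 1/tau` fraction was removed as excess.

Numerical/tie-break conventions (the process is exactly deterministic):

* levels start at 0 (a fresh seed must relabel once before its first push);
* hyperedge flows reset to 0 at every inner call — each doubling round is a
  fresh flow problem; carrying saturated hyperedges across rounds would
  permanently block the very bottleneck the doubling is meant to probe;
* active-queue ties: FIFO among equal levels; hyperedge choice: first
  eligible index in the node's incidence list (file/enumeration order);
* sweep order: level descending, then node flow descending, then node id;
  only nodes the diffusion touched (positive flow or level, plus the seed)
  are swept — ordering all of `V` would break locality and flood the order
  with level-0 ties. Undefined prefixes are skipped; the first minimizer
  wins. If an isolated component absorbs all volume, the full prefix is
  undefined and the best *defined* prefix (possibly a singleton at
  `phi = 1`) is returned;
* the returned cluster is the best sweep prefix over all iterations
  (initialised at `phi = +inf`, so a defined sweep always beats no answer);
  the excess set `{v : m_M(v) ≥ d_M(v)}` at the final inner run — the
  cluster characterisation used in the theory — is reported separately as
  `excess_cluster`;
* parameter derivations when only `phi` is given: `C = ceil(1/phi)` and
  `h = ceil(3 ln(F)/phi)` with `F` the total flow at that inner run's start
  (natural log; ceilings preserve the bound direction). Explicit `C`/`h`
  always win, and all worked examples set them explicitly.

Defaults `tau = 2`, `iterations = 20`, `alpha = 1` follow the settings used
for the reference experiments; `C = h = 3` is the conventional choice for
the benchmark runs in the CLI `protocol` command.

## Motif enumeration

Built-ins are the 3-node patterns: undirected triangle, and on directed
hosts M1 (each pair joined by ≥ 1 arc in either direction), M2 (directed
3-cycle) and M3 (feed-forward loop). Each unordered triple satisfying a
pattern is emitted once, in lexicographic order, regardless of how many
orientations realize it — cut counts are defined at the instance (triple)
level, and set-level emission keeps them well defined when pairs are
bidirected. Arbitrary-size motifs are out of scope; any hypergraph can be
supplied directly instead.

## Synthetic generators

All generators are pure functions of their parameters and seed.

* `metabolic_fixture` — the fixed 9-hyperedge metabolic motif hypergraph
  used as the worked example.
* `triangle_path_family(p, l)` — p chains of l edge-sharing triangles attached to a
  hub by one triangle each, plus exactly one "bridge" triangle
  `{hub, v, w}` to an external node fronting a dense clique of size 2l. The
  outside attachment is deliberately minimal: the localization argument
  needs only a sparse bridge and a non-trivial outside. Target cluster
  B = hub + path nodes contains `p(l+1)` triangles.
* `planted_hypergraph` — every within-block node triple (more generally,
  `edge_size`-subset) appears with probability `p_in`, every cross-block
  candidate with `p_out`. Candidate spaces beyond 200,000 subsets are
  uniformly subsampled first (documented cap; desk-scale bound). The default
  test conditions — two blocks of 30, `p_in = 0.02`, `p_out = 0.0005` —
  give expected within-block degrees around 8 with a handful of cross
  hyperedges, a strongly separated regime.
* `lfr_sweep` — LFR benchmark graphs via networkx's generator with the
  conventional parameterisation (degree exponent 2, average degree 10,
  maximum 50, community sizes 20–100). The community-size exponent is set
  to 1.1 because the generator requires an exponent strictly above 1.
  Default evaluations use n = 300 rather than n = 1000: the sweep backs a
  qualitative monotone-trend property (recovery degrades as the mixing
  parameter mu grows), for which the reduced size is sufficient.

What passing tests on these generators show — and what they do not: the
planted and LFR instances have sharp, homogeneous community structure;
recovery there demonstrates the mechanics (localization, bottleneck
detection, sweep optimality) but does not certify performance on real
interaction networks, whose motif degree distributions are heavier-tailed
and whose communities overlap.

## Evaluation protocols

`best_seed_f1` runs the algorithm from every community node and reports the
best F1 with its seed (ties to the smallest id); seeds where the algorithm
fails — e.g. no motif instance at the seed — are skipped, and only
all-seeds-failing is an error. `seed_distribution` reports the per-seed
(F1, phi_M) table with medians; medians take the lower middle element for
even counts, keeping summaries deterministic.

## Limitations

* Only 3-node built-in motifs are enumerated; larger patterns must be
  supplied as hypergraphs.
* `crd_m` materialises the full motif adjacency matrix; on hypergraphs with
  very large hyperedges its clique expansion is quadratic per hyperedge and
  the direct hypergraph diffusion should be preferred.
* The planted generator's subsampling cap makes very large candidate spaces
  approximate rather than exhaustive.
* No attempt is made to certify the theoretical `O(k·phi)` conductance
  guarantee or running-time bounds; tests check runtime invariants (flow
  conservation, caps, monotone levels, sweep optimality) instead.
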