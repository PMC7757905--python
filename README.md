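# hgcrd — local hypergraph clustering by capacity-releasing diffusion

`hgcrd` finds a well-connected cluster *near a seed node* in an interaction
network whose higher-order structure is encoded as a hypergraph: each
hyperedge is one instance of a motif — a triangle in a social graph, a
directed feed-forward loop, or the participants of one metabolic reaction
(M1 + M2 → M3). It is aimed at systems-biology and network-science users who
want motif-aware local community detection without touching the rest of a
large graph.

## The method

Cluster quality is *motif conductance*

```
phi_M(S) = cut_M(S) / min(vol_M(S), vol_M(V \ S))
```

where `cut_M(S)` counts hyperedges with endpoints on both sides and
`vol_M(S)` counts hyperedge endpoints in `S`. The core algorithm, HG-CRD
(hypergraph capacity-releasing diffusion), is an integer push-relabel flow
process over hyperedges. The seed `s` starts with flow `2 d_M(s)`, where
`d_M(v) = Σ_{e ∋ v} (|e| − 1)` is the motif degree. Each outer iteration

1. doubles every node's flow (the "capacity release"),
2. lets nodes with excess flow (`m_M(v) > d_M(v)`) push integer flow through
   *eligible* hyperedges — at least `alpha` co-members strictly below the
   sender's level, residual capacity `min(l(v), C) − m_M(e) > 0`, and excess
   of at least `|e| − 1` — relabelling a node one level up (to at most `h`)
   when it cannot push,
3. sweeps the nodes by level (descending) and keeps the prefix with the
   lowest motif conductance seen so far,
4. truncates flow back to `m_M(v) ≤ d_M(v)` and stops when less than `1/tau`
   of the no-bottleneck total `2 d_M(s) 2^j` survives — the signature of a
   cluster boundary.

Because flow moves only through motif instances, the diffusion stays far
more localized than spectral/random-walk alternatives. Two reference
variants are included: `crd` (classical edge diffusion, the `k = 2` case)
and `crd_m` (edge diffusion on the motif adjacency matrix `W_M`, whose entry
`(i, j)` counts motif instances containing both nodes), plus the
`top_neighbors` / `best_neighbors` baselines, planted-partition and LFR
benchmark generators, and a best-seed / median-seed evaluation harness.

## Worked example

The package ships a small metabolic motif hypergraph over metabolites 1..10
with nine reaction hyperedges. Clustering metabolite 7:

```python
from hgcrd import DiffusionParams, hgcrd, metabolic_fixture, motif_cut

H = metabolic_fixture()
params = DiffusionParams(capacity=2, max_level=2, tau=2.0, iterations=5, alpha=1)
res = hgcrd(H, seed=7, params=params)
print(sorted(res.cluster), round(res.phi_star, 2), motif_cut(H, res.cluster))
```

prints

```
[1, 6, 7, 8] 0.27 3
```

i.e. metabolites {1, 6, 7, 8} form the local cluster: only 3 of the 9
reaction motifs straddle its boundary, and its motif conductance is
3/11 ≈ 0.27 (3 cut hyperedges over the cluster side's 11 hyperedge
endpoints). The same run from the shell:

```sh
hgcrd generate --kind metabolic --out fixture
hgcrd cluster --hypergraph fixture.hyp --seed 7 \
      --capacity 2 --max-level 2 --tau 2 --iters 5 --alpha 1
```

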