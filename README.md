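# bionetkit

Topological analysis of biological networks: build and annotate molecular
interaction graphs, quantify vertex importance, test for scale-free structure,
detect and evaluate community structure, and measure how annotation sets
(diseases, functions, pathways) are placed on the network.

Proteomic experiments yield parts lists; the biology lives in how the parts
connect. Given an undirected protein–protein interaction (PPI) network — or
any other molecular network supplied as an edge list, GML or GraphML —
`bionetkit` supports the full analysis cycle a systems biologist runs on such
data: which vertices are hubs or brokers, whether the degree distribution is
heavy-tailed, which sub-complexes (communities) exist and how much to trust
them, and whether two sets of annotated genes occupy the same network
neighbourhood.

## What it computes

**Vertex topology.** A seven-measure centrality panel per vertex: degree
(DEG), betweenness (BET), local clustering coefficient (CC), semi-local
centrality (SL, a two-hop neighbourhood aggregation normalized to [0, 1]),
mean and standard deviation of shortest-path length (mnSP, sdSP), and
PageRank (PR). Null models (Erdős–Rényi G(n, p), Barabási–Albert, and edge
perturbation of the observed graph) support observed-vs-random comparisons.

**Scale-free structure.** Discrete power-law fits P(k) ∝ k^(−α) by
Hurwitz-zeta maximum likelihood with the lower bound x_min selected by
Kolmogorov–Smirnov distance, plus an optional semi-parametric bootstrap.
Independently, an entropy-rate perturbation analysis: for the vertex-weighted
random walk with transition p_ij = x_j / Σ_{k∈Γ(i)} x_k and stationary
distribution π_i ∝ x_i Σ_{k∈Γ(i)} x_k, the entropy rate SR = Σ_i π_i S_i is
recomputed after perturbing each vertex's weight in turn (2→14 models
over-expression, 16→14 under-expression). On scale-free graphs the SR response
is bi-phasic in degree, with the two directions opposing.

**Communities.** Fast-greedy (fc), walktrap (wt), spin-glass (sg),
leading-eigenvector (lec), Louvain and Infomap via igraph, plus a native
spectral algorithm: recursive bisection by the leading eigenvector of the
modularity matrix B_ij = A_ij − k_i k_j / 2m, with Kernighan–Lin fine-tuning
after each split and a final partition-level refinement. Modularity
Q = (1/2m) Σ_ij B_ij δ(c_i, c_j) is recomputed from every membership; a
normalized modularity divides Q by its mean over degree-preserving rewired
copies. Oversized communities can be re-clustered hierarchically, summarized
in a per-algorithm table (community counts, singletons, μ = between-community
edge fraction, size quartiles), and drawn with a cluster-driven layout.

**Consensus and bridgeness.** Re-clustering random 80 % vertex subsamples
(500× by default) yields a consensus matrix M of co-clustering frequencies.
Cluster robustness is the mean of M within a cluster. Bridgeness converts each
vertex's consensus row into an affiliation distribution p_i over the K
communities and scores B_i = 1 − √(K/(K−1)) · ‖p_i − 1/K‖₂ ∈ [0, 1]: 0 for a
vertex firmly in one community, 1 for a global bridge. Plotting B against a
normalized centrality (e.g. SL) separates local hubs from global bridges.

**Annotation statistics.** For annotation sets A, B the separation statistic
s_AB = d_AB − (d_AA + d_BB)/2 uses mean nearest-member shortest-path
distances (shared members count 0); s_AB < 0 means topological overlap.
Significance comes from permuting term placements (each term keeps its size),
with Bonferroni- and BH-adjusted q-values. Hypergeometric over-representation
(ORA) tests term enrichment in any vertex grouping, and an intra-class edge
count with a label-permutation null tests whether same-class vertices
preferentially interact. Bipartite networks (e.g. disease–gene) come with
one-mode projection and degree-preserving rewiring.

## Worked example

Simulate a planted-partition network with annotation terms placed pairwise in
the same blocks, then cluster it and test annotation overlap:

```bash
$ bionetkit simulate -o toy --blocks 3 --block-size 12 --p-in 0.55 \
    --p-out 0.03 --terms 4 --term-size 8 --mode same_block --seed 42
planted graph: 36 vertices, 118 edges

$ bionetkit cluster toy_edges.tsv -o membership.tsv --alg spectral --seed 42
3 communities, Q=0.5642 -> membership.tsv

$ bionetkit separation toy_edges.tsv toy_annotations.tsv -o sep.tsv \
    --n-perm 500 --seed 42
6 annotation pairs -> sep.tsv
```

The spectral algorithm recovers the three planted blocks (Q = 0.5642). In
`sep.tsv`, the two term pairs planted in a shared block overlap (s_AB = −0.75,
permutation p = 0.052 and 0.028), while all cross-block pairs separate
(s_AB > 0.5, p ≈ 1) — the permutation null correctly singles out the planted
structure:

```
term_a   term_b     s_AB          p
T000     T001      -0.75      0.052
T000     T002      0.5625     1.000
T002     T003      -0.75      0.028
```

The same steps are available as library calls (`bk.planted_partition`,
`bk.spectral_cluster`, `bk.run_permutation_test`, …) and as a declarative
pipeline (`bionetkit run config.yaml`).

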