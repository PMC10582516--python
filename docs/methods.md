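# Methods

This note documents the models and procedures implemented in `bionetkit`,
the defaults and numerical choices behind them, what the synthetic generators
do and do not emulate, and the design decisions taken where the literature
leaves room.

## Graphs and annotations

Networks are simple undirected `igraph.Graph` objects with string vertex IDs
(`name`). All I/O coerces IDs to stripped strings: gene identifiers such as
Entrez IDs are numeric-looking and silently re-typing them is a classic source
of join bugs. Simplification (removing self-loops and duplicate edges) is on
by default because molecular interaction networks are simple graphs. The
largest-connected-component extractor breaks size ties deterministically in
favour of the component containing the lexicographically smallest vertex ID.

Annotations arrive as three-column tables (term_id, term_name, vertex_id) and
are attached as a semicolon-joined vertex attribute. The join is de-duplicated
and sorted before joining so attribute strings are canonical and diffable.
Rows referencing vertices absent from the network are skipped with a logged
count rather than raised: annotation files routinely cover a superset of any
one network.

Edge-list dialect: the first two whitespace- or comma-separated columns are
endpoints; `#` lines are comments. A first row is treated as a header only
when both its tokens are non-numeric **and** neither token recurs anywhere as
an endpoint — so headers are stripped without ever eating a real edge. Writers
emit vertices and edges in sorted order, making outputs byte-reproducible.

## Centrality panel

Seven measures per vertex. Betweenness is reported as raw shortest-path pair
counts (unnormalized), the common default in graph libraries. The clustering
coefficient of degree-<2 vertices is defined as 0, not NaN, so the matrix is
total. PageRank uses damping 0.85. Shortest-path statistics (mnSP, sdSP) are
computed over reachable vertices only; unreachable pairs are dropped and
counted in a log message — imputing a pseudo-diameter would distort the scale
on fragmented networks. sdSP is the population standard deviation (a vertex
with one reachable partner gets 0).

Semi-local centrality follows the two-hop aggregation: N(w) is the number of
distinct vertices within distance ≤ 2 of w (excluding w), Q(u) = Σ_{w∈Γ(u)}
N(w), CL(v) = Σ_{u∈Γ(v)} Q(u). The normalized variant divides by the maximum
observed CL, so values lie in [0, 1] with at least one 1. Normalizing by an
observed maximum (rather than a theoretical bound, for which no closed form
exists at arbitrary topology) makes values comparable within a network but
not across networks; this is an approximation and is flagged as such.

Null models for observed-vs-random comparison are matched on vertex and edge
counts: G(n, p) with p = 2m/(n(n−1)), Barabási–Albert with m ≈ |E|/|V|, or
edge perturbation of the observed graph. Random graphs share no vertex
identity with the observed one, so comparisons are made rank-by-rank on the
sorted centrality vectors.

## Discrete power-law fit

For each candidate lower bound x_min (restricted to candidates leaving at
least 10 tail points, to avoid vacuous fits on a handful of hubs), the
exponent is estimated by maximizing the discrete log-likelihood under
p(k) = k^(−α) / ζ(α, x_min), with the Hurwitz zeta from scipy and a bounded
scalar search on α ∈ (1, 25]. The selected x_min minimizes the KS distance
between the empirical tail CDF and the fitted CDF. The optional plausibility
p-value uses the standard semi-parametric bootstrap — resample the body
empirically and the tail from the fitted model, refit, and count KS distances
at least as large as observed — and is off by default because it multiplies
the cost by the replicate count while the exponent itself is usually the
quantity of interest.

The inverse-CDF sampler for the same family (used as the recovery oracle and
by the synthetic module) extends a cumulative table of the zeta-normalized pmf
until it covers the largest uniform draw, then looks draws up by binary
search. Recovery of α = 2.5 at n = 10⁴ is within ±0.1 on every tested seed.

## Entropy rate and perturbation

The network is treated as a vertex-weighted random walk: from i the walker
moves to neighbour j with probability x_j / Σ_{k∈Γ(i)} x_k. This chain is
reversible with stationary distribution π_i ∝ x_i Σ_{k∈Γ(i)} x_k, which is
used in closed form (validated in tests against the leading left eigenvector
of the transition matrix). The entropy rate SR = Σ_i π_i S_i, with S_i the
entropy of row i, uses natural logarithms throughout, so SR ∈ [0, ln k_max],
with equality at uniform weights on regular graphs (SR = ln k). SR is
invariant under uniform weight rescaling; the computation requires a
connected graph and strictly positive weights, and refuses anything else with
an instruction to extract the LCC.

The perturbation protocol is expression-free: every vertex carries a uniform
baseline weight, one vertex at a time is set to the perturbed weight, and the
global SR is recorded. Defaults are baseline 2 → perturbed 14 (modelling
over-expression/activity) and 16 → 14 (under-expression/inactivity). On
scale-free graphs the SR-vs-log-degree response is bi-phasic: under
over-expression the low-degree bulk depresses SR while the top hubs raise it,
and under-expression mirrors this, so the two directions produce opposing
rankings. The tests assert exactly this qualitative signature (hub decile vs
bottom half, and negative rank correlation between directions) rather than
absolute SR values, which depend on the weight pair chosen.

## Community detection

Standard algorithms (fast-greedy, walktrap, spin-glass, leading-eigenvector,
Louvain, Infomap) are delegated to igraph; stochastic ones are seeded through
the stdlib `random` generator that python-igraph draws from. Memberships are
canonicalized — 1-based consecutive indices ordered by each community's
smallest vertex ID — so results are stable under vertex relabeling and
diffable across runs. A graph with no edges clusters to singletons with
Q = 0. Spin-glass state counts are exposed as a `spins` parameter; running it
at different spin counts bounds the community count from above.

Modularity is computed natively from the membership (per-community edge and
degree sums; equal to the double-sum definition) and cross-checked in tests
against both the literal formula and igraph. Every `Clustering` stores a Q
that is recomputed from its membership, never trusted from the backend.

The native spectral algorithm performs recursive bisection: on vertex group
g it builds the generalized modularity matrix B(g)_ij = B_ij − δ_ij Σ_{k∈g}
B_ik, takes the leading eigenvector (dense symmetric eigendecomposition —
exact and robust at the network sizes this package targets), splits by sign,
and stops when the leading eigenvalue or the split's ΔQ is ≤ 1e−9.
Fine-tuning is Kernighan–Lin style: within a sweep every vertex is flipped at
most once, always the best flip next (even if locally negative), and the best
visited state is kept; sweeps repeat while they improve ΔQ. Because divisive
bisection is greedy, a locally better split can occasionally lead to a worse
final partition; the fine-tuned variant therefore adds a partition-level
refinement (single-vertex moves between communities while ΔQ > 0) and keeps
the refined plain-bisection partition as a fallback candidate, so fine-tuning
never returns lower Q than plain leading-eigenvector bisection — a guarantee
by construction, verified on hundreds of random graphs.

Normalized modularity divides observed Q by the mean Q that the same
algorithm achieves on degree-preserving rewired copies (igraph double-edge
swaps, 10×|E| swaps per copy, ≥ 10 replicates). Values near 1 indicate no
more structure than the degree sequence implies; planted structure gives
Q_norm > 1.

Re-clustering replaces each community larger than a size threshold with the
communities found on its induced subgraph, renumbering consecutively; with
`recurse` it repeats until nothing exceeds the threshold or a pass changes
nothing.

The cluster-driven layout places each community's Fruchterman–Reingold layout
(scaled to radius √size) on a grid with pitch 2.2 × the largest radius,
largest community first, guaranteeing disjoint bounding boxes; it is
deterministic given the seed.

## Consensus, robustness, bridgeness

The consensus matrix resamples a fraction (default 0.8) of vertices uniformly
(default 500 reps), clusters each induced subgraph, and records for every
pair the fraction of co-sampled reps that placed them together. The
denominator is the co-sampled count, not the total rep count, so subsampling
does not bias entries downward; pairs never co-sampled get 0 with a logged
count. Per-rep seeds derive from the master seed through a spawned seed
sequence with the rep index as counter.

Cluster robustness is the mean consensus over pairs within a cluster
(singletons are 1 by convention — there is no pair to disagree). Bridgeness
builds each vertex's affiliation vector by summing its consensus row over
every community's members (self excluded) and renormalizing; all-zero rows
get the uniform affiliation. Then B_i = 1 − √(K/(K−1)) · ‖p_i − 1/K‖₂, which
is exactly 0 for a one-hot affiliation and exactly 1 for a uniform one. The
influence table pairs B with any [0, 1]-normalized centrality and labels the
(0.5, 0.5) quadrants: global bridge, local hub, bridging hub, peripheral.

## Annotation placement statistics

Mean set distances follow the disease-module localization convention: d_AA is
the mean over members of the distance to the nearest *other* member; d_AB
averages, over all members of both sets, the distance to the nearest member
of the opposite set, and members shared by A and B contribute 0. This makes
s_AB = d_AB − (d_AA + d_BB)/2 strictly negative for heavily co-annotated
pairs — deliberately: co-annotation *is* overlap in this framework.
Unreachable members are dropped from means with a reported count; a pair with
no finite cross-distance raises rather than imputing.

The permutation null re-places each term independently as a uniform random
vertex set of the same size. An alternative null that applies one shared
relabeling to all terms (preserving co-occurrence and randomizing only
placement) is available via `null_model="global"`; it answers a different
question — whether the *joint* placement is special given the co-annotation
structure — and cannot flag pairs whose overlap consists of shared members.
Empirical p-values carry the +1 correction, p = (1 + #extreme)/(n_perm + 1),
so they are strictly positive and super-uniform under the null (verified by a
one-sided KS test over 400 null pairs). Bonferroni is over tested pairs;
q-values use the Benjamini–Hochberg estimator — with the tens of pairs
typical here, π₀-smoothing estimators are unstable and BH is the conservative
choice. Because the graph never changes, the full distance matrix is computed
once and every permutation reduces to array indexing; memory is O(n²), which
is the intended operating range (networks of up to a few thousand vertices).

ORA uses the one-sided hypergeometric upper tail P(X ≥ k) for each
(group, term) pair with k ≥ 1 (k = 0 rows are omitted unless requested, in
which case p = 1), BH adjustment across all reported rows, and lists the
contributing vertices sorted. Vertices outside the declared universe are
dropped with a log message. The tail probability is verified against exact
binomial-coefficient sums for every configuration with N ≤ 30.

The intra-class edge statistic counts edges whose endpoints share a class
label and compares against permuting labels over vertices (class sizes
preserved), upper-tail p with the +1 correction. Its null mean matches the
closed form |E| · Σ_c n_c(n_c−1)/(n(n−1)).

Bipartite handling: projections connect two same-part vertices iff they share
an opposite-part neighbour (unweighted, simple); rewiring performs attempted
double-edge swaps that reject collisions, preserving both parts' degree
sequences exactly, with 10×|E| attempts by default.

## Synthetic generators

The generators provide construction-time ground truth, not realism:

- `planted_partition` — independent Bernoulli edges, p_in within blocks,
  p_out between. The recovery conditions used in the tests (4 blocks × 16
  vertices, p_in = 0.5, p_out = 0.02) put the planted structure well above
  the detectability threshold.
- `power_law_degree_sample` — exact i.i.d. draws from the zeta-normalized
  discrete power law; the oracle for exponent recovery.
- `annotated_planted_graph` — term sets placed per mode (`same_block` pairs
  terms within one block, `cross_block` alternates blocks, `random` is the
  calibrated null), with exact term sizes.
- `toy_diseasome` — each disease linked to a fixed number of distinct random
  genes; exercises projection and rewiring mechanics.

None of these reproduce properties of real PPI data — heavy-tailed *and*
assortative degree structure, annotation terms correlated with degree,
incomplete and biased interaction sampling. Passing tests demonstrate
correctness of the statistics under their stated models, not performance on
real proteomes. The published reference checks (MASC complex, 2007 diseasome,
presynaptic compartment) cover real data and require the user-deposited files
described in `data/README.md`.

## Problem sizes and determinism

Test and acceptance-script workloads are sized for interactive runs: planted
graphs of 36–2000 vertices, consensus at 200 reps on ~13 vertices,
permutation calibration at 400 pairs × 120 permutations, exponent recovery at
n = 10⁴ × 20 seeds. All stochastic operations take explicit seeds; per-rep
seeds derive from the master seed via spawned seed sequences, and every CLI
output records its version, seed, and parameters in `#` header lines.

## Known limitations

- Dense matrices in the spectral algorithm and distance-matrix reuse in the
  permutation test bound practical network size to a few thousand vertices;
  the delegated igraph algorithms scale much further.
- SL normalization by the observed maximum prevents cross-network comparison
  of SL values.
- The consensus-based bridgeness depends on the subsample fraction and rep
  count; absolute B values are comparable only at fixed settings (defaults
  0.8 / 500).
- Degree-preserving nulls for annotation placement (picking random sets
  matched on degree, as some localization studies do) are not implemented;
  the permutation null matches set sizes only.
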