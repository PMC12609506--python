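# Methods

This note documents the models, the numerical choices and the deliberate
design decisions behind `tepcontrol`, in the order the pipeline runs.

## Network reconstruction

The signaling network is built from a curated interaction table in four
steps, each logged with its edge count:

1. **Curation filter.** Keep interactions that are directed, signed
   (stimulation xor inhibition) and supported by `min_curation ≥ 3` curation
   events (inclusive, "at least 3"). Rows flagged as both stimulation and
   inhibition are ambiguous curation and get sign 0; parallel records for one
   directed pair collapse to a single edge, and conflicting curated signs
   (+1 vs −1) also collapse to 0 with a warning — downstream contradiction
   filtering needs one sign per edge.
2. **Expression filter.** Keep nodes with average expression ≥
   `expr_threshold` (default 1.0, the first quartile of the source
   expression distribution; inclusive) or present in any supplied proteomics
   list.
3. **Sign-contradiction removal.** Each edge's *predicted* sign is
   sign(log2FC_i · log2FC_j), defined only when both endpoints are
   differentially expressed (|log2FC| > 0.58 and adjusted p < 0.05, both
   strict); otherwise the prediction is unknown and can never contradict.
   An edge is dropped exactly when curated and predicted signs are both
   known and differ.
4. **Largest component.** "Connected" is read as *weak* connectivity —
   signaling networks contain pure-source receptors that strong connectivity
   would discard. Ties between equal-sized components break toward the one
   containing the lexicographically smallest label.

The DEG subnetwork keeps edges with **at least one** differentially expressed
endpoint (requiring both would leave almost nothing in a sparse network). The
expanded interactome applies only the node-expression filter: all
interactions count, direction and sign ignored, unordered duplicates merged.

## Structural controllability

The bipartite representation splits each node into an out-copy and in-copy;
a directed edge u→v (self-loops included — a self-looped node may match
itself) becomes the link out(u)–in(v). Maximum matchings are computed with an
iterative Kuhn augmenting-path search; the *canonical* matching processes
nodes and adjacency lexicographically and is fully deterministic, while
seeded runs shuffle the processing order. Warm-started re-matching after
deleting single node copies makes the per-node classifications O(E) each.

- **Driver count.** N_D = max(N − |M*|, 1); drivers are nodes with unmatched
  in-copies. Under a perfect matching every singleton is a valid driver set;
  by convention the lexicographically smallest node is reported, all nodes
  are classed intermittent, and each has control capacity 1/N (the
  alternative reading "always matched ⇒ redundant" would contradict MDS
  membership).
- **critical / intermittent / redundant.** A node is redundant iff removing
  its in-copy shrinks the maximum matching; critical iff no in-neighbor can
  be forced to match it without shrinking the matching (in-degree-0 nodes
  are trivially critical); intermittent otherwise.
- **indispensable / neutral / dispensable.** Recompute N_D with the node and
  its edges deleted and compare.
- **Control capacity** is the fraction of *distinct* minimum driver sets
  containing the node. For N ≤ 12 (`exact_below`) all MDSs are enumerated by
  checking every candidate node subset of size N_D for a matching covering
  its complement. Above that, note that the matchable in-copy sets form a
  transversal matroid whose bases are exactly the MDS complements; a
  Metropolis basis-exchange walk (swap one driver for one non-driver, accept
  when still matchable) is therefore uniform over MDSs in its stationary
  law. Defaults: burn-in 10·N steps, thinning 4 steps per recorded sample.
  Naively sampling randomized maximum matchings instead is *not* unbiased —
  MDSs reachable by many matchings are oversampled (we measured errors up to
  0.44 on 12-node graphs, versus ≤ 0.05 for the basis-exchange sampler at
  2000 samples).
- **Control centrality** is the generic dimension of the subspace
  controllable from one input at the node: the largest number of vertices
  covered by a single input-rooted simple path plus vertex-disjoint cycles
  inside the node's reachable set. A plain maximum matching on the reachable
  subgraph would overcount — it can open a second path at a dilation the
  input cannot feed independently — so the cover is computed exactly as a
  minimum-cost circulation (edges cost −1, unit vertex bottlenecks, one
  return arc for the single path) with `networkx.network_simplex`. The
  implementation is validated against the numeric Kalman rank
  rank[B, AB, …, A^{N−1}B] with random edge weights (5 draws, maximum taken)
  on toys and 100 seeded digraphs.
- **Minimum steering set.** The driver set of the canonical matching: size
  N_D and a superset of the critical nodes by construction. The intermittent
  members of an MSS are tie-break-dependent; only those two defining
  properties are contractual.
- **Class comparisons** use the two-sided Mann–Whitney U test: exact null
  when both groups have ≤ 10 members and no ties, otherwise the
  tie-corrected normal approximation without continuity correction (so
  identical groups give p = 1 exactly). Two-sided was chosen because no
  direction is privileged a priori.

## Subnetworks and gene scores

Edge weights are W_ij = 1/|log2FC_i · log2FC_j|. The absolute value is a
deliberate deviation from the naive product: discordant fold changes would
give negative weights, which shortest-path algorithms cannot accept, and the
intent — stronger regulation ⇒ cheaper edge — is preserved. Edges with a
non-significant endpoint get 10× the largest finite weight in the network:
traversable through hub shortcuts, but discouraged. If no edge joins two
significant genes, all edges get unit weight with a warning.

Significance for *weighting* (edge and node weights both) means adjusted
p < 0.05 with **no** fold-change cutoff — the reference weight table contains
genes with |log2FC| well below the 0.58 DEG cutoff but nonzero weight, so
the DEG flag cannot be the gate. Genes with a missing fold change (or
adjusted p ≥ 0.05) get the substitute fold change 10⁻⁶, making hub weights
vanish at 2-decimal reporting precision without dividing by zero.

Shortest paths use Dijkstra with a lexicographic tie-break on the node
sequence (implemented by carrying the path in the heap key, which is exact
for positive weights). One path is retained per ordered (critical,
indispensable) pair — mirroring single-path routing — and the subnetwork is
the union of retained paths; unreachable pairs are logged, not errors.

The Knode score K_i = (2/p) Σ_{j≠i, d(i,j)≤s} (p_j − p̄) reads the "2p"
prefix as 2/p with p the total node weight, excludes the self term, and uses
unweighted geodesic distance. The neighborhood radius s defaults to 2
(direct plus second neighbors) and is configurable; the score's ranking is
invariant to rescaling all weights. Top-fraction selection takes
⌈fraction·N⌉ nodes and includes all nodes tied at the cut value. The score
subnetwork unites one *unweighted* shortest path per unordered
(top-score, top-weight) pair — node classification already encodes the
regulation, so edge weights are deliberately not reused there.

## Drug ranking

Coverage of a combination is the union (never the sum) of member coverages.
The published criteria name the ranking ingredients without formulas, so two
concretizations are documented as this package's own: inhibition strength is
Σ 1/log10(Ki[nM]) over covered targets with known Ki (monotone decreasing in
Ki; sub-nanomolar binders are capped at 10 to avoid the log singularity),
and the control score is the rank-sum of covered targets' control centrality
and betweenness. Ordering is lexicographic — coverage, then strength, then
control, then alphabetical — keeping the criteria separable. Drug–drug
interaction pairs are symmetric and checked pairwise only; interaction
filtering applies at the combination stage, not to single-agent ranking.

## Synthetic data

The generators are pure functions of (config, seed) and emulate the
statistical shape of the real inputs at desk scale (defaults: 300 genes,
1500 interactions): preferential-attachment edge growth for heavy-tailed
degrees; ~55% of records signed+directed; geometric curation counts with
P(≥ 3) = 25%; a 15% DEG minority with |log2FC| ~ N(1.2, 0.4) and tiny raw
p-values against a N(0, 0.25) null with uniform p; Benjamini–Hochberg
adjustment applied *inside* the simulator so consumers never re-adjust;
log-normal average expression with first quartile ≈ 1; drug targeting biased
toward hubs (switchable off) with log-uniform Ki in [1, 10⁴] nM. Planting
helpers attach a zero-in-degree receptor (guaranteed critical) and a private
host→x→bridge→y chain (guaranteed indispensable: deleting the bridge removes
exactly two matched links while shrinking the network by one node).

What the simulations do *not* emulate: real interactome motif structure
(feedback loop density, bow-tie layering), correlated expression between
interacting genes, gene-symbol aliasing, and batch structure in the DE
statistics. Passing tests therefore demonstrate algorithmic correctness and
pipeline robustness, not biological recovery on real data.

## Problem sizes and determinism

Test and example networks run at 40–300 nodes, chosen so the full suite and
the acceptance script finish in minutes on one CPU while still exercising
heavy-tailed topologies; all stochastic steps take explicit seeds and every
pipeline run is byte-reproducible given (inputs, config, seed).

## Known limitations

- Exact MDS enumeration is combinatorial (C(N, N_D) matching checks) and is
  gated at N ≤ 12; the basis-exchange sampler above that has Monte Carlo
  error of order 1/√samples.
- Node-removal classification recomputes a matching per node (O(N·E)); fine
  to a few thousand nodes, not for huge interactomes.
- No control-energy / Gramian analysis, no edge controllability, no temporal
  networks, no identifier mapping, and no live database clients — inputs are
  symbol-keyed exports by design.
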