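# tepcontrol

Controllability-based therapeutic target prioritization for signed signaling
networks, built around the tumor-educated platelet (TEP) setting: platelets
whose transcriptome has been reprogrammed by tumor-derived signals. The
package is aimed at systems biologists who have a curated interaction table
(an OmniPath-style export) and a differential-expression gene table (limma-style
`topTable` output) and want to know *which proteins to hit, and with which
approved drugs*, to steer the network away from its tumor-educated state.

## What it computes

**Network reconstruction.** Interactions are kept if signed, directed and
supported by ≥ 3 curation events; nodes if platelet-expressed (average
expression ≥ 1, or proteomic detection). Each edge's sign is compared with the
sign predicted from its endpoints' fold changes — sign(log2FC_i · log2FC_j)
when both are significant — and contradictory edges are removed; the largest
weakly connected component is the signaling network. An *expanded interactome*
variant keeps all interactions, undirected.

**Structural controllability.** Viewing the network as a structured linear
system ẋ = Ax + Bu, the minimum number of driver nodes is
N_D = max(N − |M*|, 1), where M* is a maximum matching of the bipartite
representation (node split into out-/in-copies, edge u→v becomes link
out(u)–in(v)). Per node the package computes:

- **critical / intermittent / redundant** — the node sits in every / some / no
  minimum driver set (MDS);
- **indispensable / neutral / dispensable** — deleting the node raises /
  keeps / lowers N_D;
- **control capacity** — the fraction of MDSs containing the node (exact by
  enumeration on small networks, otherwise an unbiased matroid
  basis-exchange sampler);
- **control centrality** — the generic dimension of the subspace controllable
  from a single input at the node, computed exactly as a minimum-cost
  circulation (one input-rooted path plus vertex-disjoint cycles);
- the minimum steering set (one concrete MDS), topology metrics, and
  Mann–Whitney comparisons between node classes.

**Subnetwork extraction and gene scores.** Edges are weighted
W_ij = 1/|log2FC_i · log2FC_j| (non-significant endpoints get a penalty
weight), and the union of minimum-weight paths from critical to indispensable
nodes is the controllable subnetwork. On the expanded interactome, nodes get
weight p_i = degree_i · |log2FC_i| and a proximity score
K_i = (2/p) Σ_{j≠i, d(i,j)≤s} (p_j − p̄); shortest paths between the top-decile
scored and top-decile weighted nodes form the score subnetwork.

**Drug ranking.** Prioritized nodes are mapped to a drug–target table; drugs
are filtered for approval + known pharmacological action, ranked by coverage,
and assembled into pairwise non-interacting combinations around an anchor
drug, ordered by (coverage, inhibition strength from Ki values, control-metric
rank of covered targets).

A seeded synthetic-data module generates all inputs (curated interactome,
gene table with a planted DEG minority and BH-adjusted p-values, drug tables),
so the whole pipeline is testable offline.

## Worked example

```python
from tepcontrol import maximum_matching, driver_count_and_set, node_control_profiles
from tepcontrol.synthetic import load_reference_fixtures

star = load_reference_fixtures()["toy_graphs"]["star4"]   # h -> a, b, c
n_d, drivers = driver_count_and_set(star, maximum_matching(star))
print(n_d, sorted(drivers))
profiles = node_control_profiles(star, seed=1, n_samples=200)
print(profiles[["mds_class", "removal_class", "control_capacity"]])
```

prints

```
3 ['b', 'c', 'h']
         mds_class removal_class  control_capacity
node
a     intermittent   dispensable          0.666667
b     intermittent   dispensable          0.666667
c     intermittent   dispensable          0.666667
h         critical       neutral          1.000000
```

The hub can feed only one leaf per input signal, so three drivers are needed;
the hub itself is critical (nothing feeds it, so it is in every MDS, capacity
1), while each leaf appears in two of the three MDSs (capacity 2/3).

The `examples/` directory holds one short script per capability
(reconstruction, classification, subnetwork extraction, gene scoring, drug
ranking, full pipeline), each printing what the numbers mean. A thin CLI
mirrors the orchestration level: `tepcontrol simulate`, `tepcontrol run-all`,
`tepcontrol classify`.

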