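"""Structural controllability of signed directed networks.

A directed network, viewed as a structured linear system x' = Ax + Bu, can be
steered between arbitrary states by injecting inputs at a minimum set of
*driver nodes*.  The minimum number of drivers N_D follows from a maximum
matching of the bipartite representation (each node split into an out-copy and
an in-copy; every directed edge u->v becomes a bipartite link out(u)-in(v)):
nodes whose in-copy is unmatched must be driven, and N_D = max(N - |M*|, 1).

On top of the matching this module computes two node classifications:

* critical / intermittent / redundant — the node appears in every / some / no
  minimum driver set (MDS);
* indispensable / neutral / dispensable — removing the node increases /
  preserves / decreases N_D;

plus per-node *control capacity* (fraction of MDSs containing the node),
*control centrality* (generic dimension of the subspace controllable from a
single input at the node), the minimum steering set (one concrete MDS), a
table of standard topology metrics, and Mann-Whitney comparisons between node
classes.
"""

from __future__ import annotations

import itertools
import logging
import random
from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from tepcontrol.errors import EmptyInputError, UsageError

logger = logging.getLogger(__name__)

Node = Hashable


# ---------------------------------------------------------------------------
# bipartite representation and matching machinery
# ---------------------------------------------------------------------------


class BipartiteRep:
    """Bipartite representation of a digraph for matching-based controllability.

    Out-copies index the left side, in-copies the right side; a directed edge
    u->v (self-loops included) contributes the link out(u)-in(v).
    """

    def __init__(self, net: nx.DiGraph, rng: random.Random | None = None):
        self.nodes: list[Node] = sorted(net.nodes())
        self.adj: dict[Node, list[Node]] = {
            u: sorted(net.successors(u)) for u in self.nodes
        }
        self.order: list[Node] = list(self.nodes)
        if rng is not None:
            rng.shuffle(self.order)
            for u in self.adj:
                rng.shuffle(self.adj[u])

    # -- Kuhn augmenting-path maximum matching (iterative DFS) --------------

    def _try_augment(
        self,
        root: Node,
        match_in: dict[Node, Node],
        match_out: dict[Node, Node],
        excluded_in: frozenset,
    ) -> bool:
        visited: set[Node] = set()
        stack = [(root, iter(self.adj[root]))]
        trail: list[tuple[Node, Node]] = []
        while stack:
            u, it = stack[-1]
            advanced = False
            for v in it:
                if v in excluded_in or v in visited:
                    continue
                visited.add(v)
                w = match_in.get(v)
                trail.append((u, v))
                if w is None:
                    for uu, vv in trail:
                        match_in[vv] = uu
                        match_out[uu] = vv
                    return True
                stack.append((w, iter(self.adj[w])))
                advanced = True
                break
            if not advanced:
                stack.pop()
                if trail:
                    trail.pop()
        return False

    def max_matching(
        self,
        excluded_out: Iterable[Node] = (),
        excluded_in: Iterable[Node] = (),
        warm_start: Mapping[Node, Node] | None = None,
    ) -> dict[Node, Node]:
        """Maximum matching as a map in-copy -> out-copy.

        ``excluded_out`` / ``excluded_in`` delete node copies from the
        bipartite graph; ``warm_start`` (an in->out map) seeds the search with
        a previous matching, from which excluded pairs are dropped.
        """
        ex_out = frozenset(excluded_out)
        ex_in = frozenset(excluded_in)
        match_in: dict[Node, Node] = {}
        if warm_start:
            match_in = {
                v: u
                for v, u in warm_start.items()
                if v not in ex_in and u not in ex_out
            }
        match_out = {u: v for v, u in match_in.items()}
        for u in self.order:
            if u in ex_out or u in match_out:
                continue
            self._try_augment(u, match_in, match_out, ex_in)
        return match_in


@dataclass(frozen=True)
class Matching:
    """A maximum matching: pairs (u, v) encode links out(u)-in(v)."""

    pairs: frozenset
    size: int

    @property
    def matched_in(self) -> frozenset:
        return frozenset(v for _, v in self.pairs)


def maximum_matching(net: nx.DiGraph, seed: int | None = None) -> Matching:
    """Maximum matching of the bipartite representation.

    With ``seed=None`` the matching is the deterministic canonical one (nodes
    and adjacency processed in lexicographic order); a seed randomizes the
    processing order, which samples alternative maximum matchings.
    """
    if net.number_of_nodes() == 0:
        raise EmptyInputError("cannot match an empty network")
    rng = random.Random(seed) if seed is not None else None
    bip = BipartiteRep(net, rng)
    match_in = bip.max_matching()
    pairs = frozenset((u, v) for v, u in match_in.items())
    return Matching(pairs=pairs, size=len(pairs))


def driver_count_and_set(
    net: nx.DiGraph, matching: Matching
) -> tuple[int, frozenset]:
    """Driver count N_D = max(N - |M*|, 1) and the matching's driver set.

    Drivers are the nodes whose in-copy is unmatched.  Under a perfect
    matching every singleton is a valid driver set; by convention the
    lexicographically smallest node is reported.
    """
    nodes = sorted(net.nodes())
    unmatched = [v for v in nodes if v not in matching.matched_in]
    if not unmatched:  # perfect matching
        return 1, frozenset({nodes[0]})
    return max(len(unmatched), 1), frozenset(unmatched)


def _driver_count(net: nx.DiGraph) -> int:
    if net.number_of_nodes() == 0:
        return 0
    bip = BipartiteRep(net)
    return max(net.number_of_nodes() - len(bip.max_matching()), 1)


def classify_mds_membership(net: nx.DiGraph) -> dict[Node, str]:
    """Jia-style classes: node in every / some / no minimum driver set.

    * critical — unmatched in every maximum matching (equivalently: no
      maximum matching covers its in-copy);
    * redundant — matched in every maximum matching (deleting its in-copy
      shrinks the maximum matching);
    * intermittent — otherwise.

    When the network has a perfect matching every singleton is an MDS, so all
    nodes are intermittent.
    """
    if net.number_of_nodes() == 0:
        return {}
    bip = BipartiteRep(net)
    base = bip.max_matching()
    m_star = len(base)
    n = net.number_of_nodes()
    if m_star == n:  # perfect matching: every singleton is an MDS
        return {v: "intermittent" for v in net.nodes()}
    classes: dict[Node, str] = {}
    for v in net.nodes():
        if len(bip.max_matching(excluded_in=[v], warm_start=base)) == m_star - 1:
            classes[v] = "redundant"
            continue
        # coverable iff forcing some edge u->v still permits a matching of
        # size m_star (i.e. m_star - 1 on the graph minus out(u), in(v))
        coverable = False
        for u in net.predecessors(v):
            size = len(
                bip.max_matching(
                    excluded_out=[u], excluded_in=[v], warm_start=base
                )
            )
            if size == m_star - 1:
                coverable = True
                break
        classes[v] = "intermittent" if coverable else "critical"
    return classes


def classify_node_removal(net: nx.DiGraph) -> dict[Node, str]:
    """Vinayagam-style classes from the effect of node deletion on N_D.

    indispensable — N_D increases; dispensable — N_D decreases;
    neutral — N_D unchanged.
    """
    if net.number_of_nodes() < 2:
        raise UsageError("node-removal classification needs at least 2 nodes")
    n_d = _driver_count(net)
    classes: dict[Node, str] = {}
    for v in net.nodes():
        reduced = net.copy()
        reduced.remove_node(v)
        n_d_prime = _driver_count(reduced)
        if n_d_prime > n_d:
            classes[v] = "indispensable"
        elif n_d_prime < n_d:
            classes[v] = "dispensable"
        else:
            classes[v] = "neutral"
    return classes


def _enumerate_mds(net: nx.DiGraph) -> list[frozenset]:
    """All distinct minimum driver sets, by checking every candidate node
    subset of size N_D for a matching that covers its complement's in-copies.

    Exponential in N; callers gate on small networks.
    """
    nodes = sorted(net.nodes())
    n = len(nodes)
    bip = BipartiteRep(net)
    base = bip.max_matching()
    m_star = len(base)
    if m_star == n:  # perfect matching: every singleton
        return [frozenset({v}) for v in nodes]
    n_d = n - m_star
    out: list[frozenset] = []
    for combo in itertools.combinations(nodes, n_d):
        d = frozenset(combo)
        if len(bip.max_matching(excluded_in=d, warm_start=base)) == m_star:
            out.append(d)
    return out


def control_capacity(
    net: nx.DiGraph,
    n_samples: int = 1000,
    seed: int | None = None,
    exact_below: int = 12,
) -> dict[Node, float]:
    """Per-node fraction of minimum driver sets containing the node.

    Exact (enumeration of all MDSs) when N <= ``exact_below``.  Larger
    networks are sampled: the matchable in-copy sets form a transversal
    matroid whose bases are exactly the complements of the minimum driver
    sets, so a basis-exchange random walk (swap one driver for one
    non-driver, accept when the complement stays matchable) has the uniform
    distribution over MDSs as its stationary law and gives an asymptotically
    unbiased estimate.  Critical nodes get 1 and redundant nodes 0 by
    construction in either mode.
    """
    if n_samples < 1:
        raise UsageError("n_samples must be >= 1")
    nodes = sorted(net.nodes())
    n = len(nodes)
    if n <= exact_below:
        mds_list = _enumerate_mds(net)
        total = len(mds_list)
        return {
            v: sum(1 for d in mds_list if v in d) / total for v in nodes
        }
    bip = BipartiteRep(net)
    base = bip.max_matching()
    m_star = len(base)
    if m_star == n:  # perfect matching: every singleton is an MDS
        return {v: 1.0 / n for v in nodes}
    rng = random.Random(seed)
    drivers = sorted(v for v in nodes if v not in base)
    counts = {v: 0 for v in nodes}
    current = set(drivers)
    burn_in = 10 * n
    thin = 4  # decorrelate successive basis-exchange states
    for step in range(burn_in + thin * n_samples):
        out_node = rng.choice(sorted(current))
        in_node = rng.choice([v for v in nodes if v not in current])
        proposal = (current - {out_node}) | {in_node}
        if len(bip.max_matching(excluded_in=proposal, warm_start=base)) == m_star:
            current = proposal
        if step >= burn_in and (step - burn_in) % thin == 0:
            for v in current:
                counts[v] += 1
    capacity = {v: counts[v] / n_samples for v in nodes}
    # pin the exact endpoints for nodes whose class forces them
    for v, cls in classify_mds_membership(net).items():
        if cls == "critical":
            capacity[v] = 1.0
        elif cls == "redundant":
            capacity[v] = 0.0
    return capacity


def control_centrality(net: nx.DiGraph, node: Node) -> int:
    """Generic dimension of the subspace controllable from one input at ``node``.

    Structurally, that dimension is the largest number of nodes covered by one
    simple path starting at ``node`` together with vertex-disjoint cycles, all
    inside the set reachable from ``node`` (a stem-and-buds cover).  A plain
    maximum matching on the reachable subgraph would overcount: it can open a
    second path at a node the input cannot feed independently (a dilation).
    The cover is found exactly as a minimum-cost circulation: every network
    edge has cost -1 and unit capacity, each vertex passes at most one unit
    (so paths and cycles stay disjoint), only ``node`` may emit without
    receiving, and a unit return arc closes the single path.  Equals the
    generic rank of the Kalman controllability matrix.
    """
    if node not in net:
        raise UsageError(f"unknown node {node!r}")
    reachable = {node} | nx.descendants(net, node)
    sub = net.subgraph(reachable)
    if sub.number_of_edges() == 0:
        return 1
    flow = nx.DiGraph()
    for v in sub.nodes():
        if v != node:  # the root only emits; a cycle through it would double-count
            # unit bottleneck r->m enforces in-degree <= 1 whether the unit
            # continues (m->e) or ends the path (m->T)
            flow.add_edge(("r", v), ("m", v), capacity=1, weight=0)
            flow.add_edge(("m", v), ("e", v), capacity=1, weight=0)
            flow.add_edge(("m", v), "T", capacity=1, weight=0)
    for u, v in sub.edges():
        flow.add_edge(("e", u), ("r", v), capacity=1, weight=-1)
    flow.add_edge("S", ("e", node), capacity=1, weight=0)
    flow.add_edge("T", "S", capacity=1, weight=0)
    cost, _ = nx.network_simplex(flow)
    return 1 - cost


def minimum_steering_set(net: nx.DiGraph) -> frozenset:
    """One concrete MDS: the driver set of the canonical maximum matching.

    Always contains every critical node and has size N_D.
    """
    matching = maximum_matching(net)
    _, drivers = driver_count_and_set(net, matching)
    return drivers


# ---------------------------------------------------------------------------
# topology metrics and class comparison
# ---------------------------------------------------------------------------


def _geodesic_counts(und: nx.Graph, nodes: list[Node]) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs unweighted distances and geodesic counts (BFS per source)."""
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    dist = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    for s in nodes:
        si = index[s]
        dist[si, si] = 0
        sigma[si, si] = 1
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                ui = index[u]
                for w in und.neighbors(u):
                    wi = index[w]
                    if np.isinf(dist[si, wi]):
                        dist[si, wi] = dist[si, ui] + 1
                        nxt.append(w)
                    if dist[si, wi] == dist[si, ui] + 1:
                        sigma[si, wi] += sigma[si, ui]
            frontier = nxt
    return dist, sigma


def topology_metrics(net: nx.DiGraph | nx.Graph) -> pd.DataFrame:
    """Standard per-node topology metrics on the underlying graph.

    Betweenness, closeness, clustering, eccentricity, stress and average
    shortest path length are computed on the undirected view; in/out degree on
    the directed network (equal to degree/2-splits for undirected input);
    ``multi_edge_partner_count`` counts reciprocal-edge partners.
    """
    nodes = sorted(net.nodes())
    und = nx.Graph(net.to_undirected() if net.is_directed() else net)
    und.remove_edges_from(nx.selfloop_edges(und))
    dist, sigma = _geodesic_counts(und, nodes)
    n = len(nodes)

    betweenness = nx.betweenness_centrality(und)
    closeness = nx.closeness_centrality(und)
    clustering = nx.clustering(und)

    stress = {}
    aspl = {}
    for vi, v in enumerate(nodes):
        through = dist[:, vi][:, None] + dist[vi, :][None, :]
        on_path = np.isfinite(dist) & (through == dist)
        weight = sigma[:, vi][:, None] * sigma[vi, :][None, :]
        mask = on_path.copy()
        mask[vi, :] = False
        mask[:, vi] = False
        np.fill_diagonal(mask, False)
        stress[v] = float(np.sum(weight[mask]))
        finite = np.isfinite(dist[vi]) & (np.arange(n) != vi)
        aspl[v] = float(dist[vi, finite].mean()) if finite.any() else 0.0

    rows = []
    for v in nodes:
        if net.is_directed():
            in_deg, out_deg = net.in_degree(v), net.out_degree(v)
            partners = sum(
                1 for u in net.successors(v) if net.has_edge(u, v) and u != v
            )
        else:
            in_deg = out_deg = net.degree(v)
            partners = 0
        neighbors = list(und.neighbors(v))
        rows.append(
            {
                "node": v,
                "in_degree": in_deg,
                "out_degree": out_deg,
                "degree": und.degree(v),
                "betweenness": betweenness[v],
                "closeness": closeness[v],
                "clustering_coefficient": clustering[v],
                "eccentricity": float(
                    np.max(dist[nodes.index(v)][np.isfinite(dist[nodes.index(v)])])
                ),
                "stress": stress[v],
                "avg_shortest_path_length": aspl[v],
                "neighborhood_connectivity": (
                    float(np.mean([und.degree(u) for u in neighbors]))
                    if neighbors
                    else 0.0
                ),
                "multi_edge_partner_count": partners,
            }
        )
    return pd.DataFrame(rows).set_index("node")


def compare_classes(
    metrics: pd.DataFrame,
    labels: Mapping[Node, str],
    metric_name: str,
    class_a: str,
    class_b: str,
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test of one metric between two node classes.

    Exact null distribution when both groups have <= 10 members and no ties;
    otherwise the tie-corrected normal approximation (no continuity
    correction, so identical groups give p = 1 exactly).
    """
    a = [metrics.loc[v, metric_name] for v, c in labels.items() if c == class_a]
    b = [metrics.loc[v, metric_name] for v, c in labels.items() if c == class_b]
    if not a or not b:
        raise UsageError(f"empty class among {class_a!r}, {class_b!r}")
    has_ties = len(set(a) | set(b)) < len(a) + len(b)
    method = "exact" if (len(a) <= 10 and len(b) <= 10 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=False
    )
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# profile assembly
# ---------------------------------------------------------------------------


def node_control_profiles(
    net: nx.DiGraph,
    seed: int | None = None,
    n_samples: int = 1000,
    exact_below: int = 12,
    with_topology: bool = True,
) -> pd.DataFrame:
    """Complete per-node controllability profile table.

    Columns: driver flag under the canonical matching, both class labels,
    control capacity, control centrality, MSS membership, and (optionally)
    all topology metrics.
    """
    matching = maximum_matching(net)
    _, drivers = driver_count_and_set(net, matching)
    mds_class = classify_mds_membership(net)
    removal_class = classify_node_removal(net)
    capacity = control_capacity(net, n_samples=n_samples, seed=seed,
                                exact_below=exact_below)
    mss = minimum_steering_set(net)
    rows = []
    for v in sorted(net.nodes()):
        rows.append(
            {
                "node": v,
                "is_driver_canonical": v in drivers,
                "mds_class": mds_class[v],
                "removal_class": removal_class[v],
                "control_capacity": capacity[v],
                "control_centrality": control_centrality(net, v),
                "in_mss": v in mss,
            }
        )
    profiles = pd.DataFrame(rows).set_index("node")
    if with_topology:
        profiles = profiles.join(topology_metrics(net))
    return profiles
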