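"""Fold-change-weighted subnetwork extraction and proximity gene scoring.

Two prioritization routes are implemented:

* the *controllable subnetwork*: edges of the signaling network are weighted
  by the reciprocal of the absolute product of their endpoints' log2 fold
  changes (strongly co-regulated edges are cheap), and minimum-weight paths
  from every critical node to every indispensable node are united into one
  subnetwork;
* the *score subnetwork*: nodes of the undirected interactome get weights
  degree x |log2FC|, a proximity score (Knode) sums centred weights of all
  nodes within geodesic distance s, and unweighted shortest paths between the
  top-scoring and top-weight deciles are united.
"""

from __future__ import annotations

import heapq
import logging
import math
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping

import networkx as nx

from tepcontrol.errors import UsageError
from tepcontrol.io import GeneStatRecord

logger = logging.getLogger(__name__)

Node = Hashable


@dataclass
class WeightedSubnetwork:
    """An edge-weighted network plus the provenance of each retained path."""

    base: nx.DiGraph | nx.Graph
    edge_weights: dict[tuple[Node, Node], float] = field(default_factory=dict)
    retained_paths: list[tuple[tuple[Node, Node], tuple[Node, ...]]] = field(
        default_factory=list
    )

    def subgraph(self) -> nx.DiGraph | nx.Graph:
        """Union of all retained paths (shared edges counted once)."""
        out = nx.DiGraph() if self.base.is_directed() else nx.Graph()
        for _, path in self.retained_paths:
            out.add_nodes_from(path)
            for u, v in zip(path, path[1:]):
                out.add_edge(u, v, **self.base.edges[u, v])
        return out


def _regulated(rec: GeneStatRecord | None, p_threshold: float) -> bool:
    """Significantly regulated for weighting: a fold change with adjusted p
    below threshold (or no p-value reported at all).  Deliberately has no
    fold-change cutoff, unlike the DEG flag."""
    return (
        rec is not None
        and rec.log2fc is not None
        and (rec.adj_p is None or rec.adj_p < p_threshold)
    )


def compute_edge_weights(
    net: nx.DiGraph | nx.Graph,
    stats: Mapping[str, GeneStatRecord],
    na_penalty_factor: float = 10.0,
    p_threshold: float = 0.05,
) -> WeightedSubnetwork:
    """Weight each edge by 1 / |log2FC_i * log2FC_j|.

    Only fold changes of significantly regulated endpoints (adjusted p below
    ``p_threshold``) enter; edges with a non-significant or missing endpoint
    receive a penalty weight of ``na_penalty_factor`` times the largest
    finite weight in the network, so they remain traversable but are
    discouraged.  The absolute product is used so that discordantly regulated
    pairs still yield a positive weight.
    """
    finite: dict[tuple[Node, Node], float] = {}
    pending: list[tuple[Node, Node]] = []
    for u, v in net.edges():
        su, sv = stats.get(u), stats.get(v)
        if (
            _regulated(su, p_threshold)
            and _regulated(sv, p_threshold)
            and su.log2fc
            and sv.log2fc
        ):
            finite[(u, v)] = 1.0 / abs(su.log2fc * sv.log2fc)
        else:
            pending.append((u, v))
    if finite:
        penalty = na_penalty_factor * max(finite.values())
    else:
        penalty = 1.0
        logger.warning(
            "no edge joins two significant genes; all edges get unit penalty weight"
        )
    weights = dict(finite)
    for edge in pending:
        weights[edge] = penalty
    return WeightedSubnetwork(base=net, edge_weights=weights)


def _lex_dijkstra(
    net: nx.DiGraph | nx.Graph,
    weights: Mapping[tuple[Node, Node], float],
    source: Node,
    target: Node,
) -> tuple[Node, ...] | None:
    """Minimum-weight path with lexicographic node-sequence tie-break."""

    def w(u: Node, v: Node) -> float:
        if (u, v) in weights:
            return weights[(u, v)]
        return weights[(v, u)]  # undirected storage

    heap: list[tuple[float, tuple[Node, ...]]] = [(0.0, (source,))]
    done: set[Node] = set()
    while heap:
        dist, path = heapq.heappop(heap)
        node = path[-1]
        if node in done:
            continue
        done.add(node)
        if node == target:
            return path
        for nxt in net.neighbors(node) if not net.is_directed() else net.successors(node):
            if nxt not in done:
                heapq.heappush(heap, (dist + w(node, nxt), path + (nxt,)))
    return None


def extract_controllable_subnetwork(
    weighted: WeightedSubnetwork,
    sources: Iterable[Node],
    sinks: Iterable[Node],
) -> WeightedSubnetwork:
    """Union of one minimum-weight path per (source, sink) pair.

    Sources are typically the critical nodes and sinks the indispensable
    nodes.  Ties between equal-weight paths break toward the lexicographically
    smallest node sequence; pairs with no connecting path are logged and
    skipped.  Self-pairs contribute nothing.
    """
    sources = sorted(set(sources))
    sinks = sorted(set(sinks))
    if not sources or not sinks:
        raise UsageError("source and sink sets must be non-empty")
    net = weighted.base
    retained = []
    unreachable = 0
    for s in sources:
        for t in sinks:
            if s == t or s not in net or t not in net:
                continue
            path = _lex_dijkstra(net, weighted.edge_weights, s, t)
            if path is None:
                unreachable += 1
                continue
            retained.append(((s, t), path))
    if unreachable:
        logger.info("%d (source, sink) pairs had no connecting path", unreachable)
    return WeightedSubnetwork(
        base=net, edge_weights=dict(weighted.edge_weights), retained_paths=retained
    )


def compute_node_weights(
    net: nx.DiGraph | nx.Graph,
    stats: Mapping[str, GeneStatRecord],
    nonsig_fc: float = 1e-6,
    p_threshold: float = 0.05,
) -> dict[Node, float]:
    """Node weight = degree x |log2FC| (``nonsig_fc`` stands in for the fold
    change of non-significant or unmeasured genes).

    "Significantly regulated" here means adjusted p below ``p_threshold``
    (or a reported fold change with no p-value at all): unlike the DEG flag
    there is no fold-change cutoff, so modestly regulated hubs still carry
    weight.  Degree is the total degree (in + out on directed networks).
    Weights of non-significant genes are vanishingly small but nonzero, so
    they round to 0 at the 2-decimal reporting precision used in result
    tables.
    """
    weights: dict[Node, float] = {}
    for v in net.nodes():
        rec = stats.get(v)
        fc = abs(rec.log2fc) if _regulated(rec, p_threshold) else nonsig_fc
        weights[v] = net.degree(v) * fc
    return weights


def compute_gene_scores(
    net: nx.Graph,
    node_weights: Mapping[Node, float],
    s: int = 2,
) -> dict[Node, float]:
    """Proximity (Knode) score: K_i = (2/p) * sum_{j != i, d(i,j) <= s} (p_j - pbar).

    p_j are the node weights, p their total, pbar their mean, and d the
    unweighted geodesic distance.  A node scores high when the nodes within
    distance s carry above-average weight.
    """
    total = float(sum(node_weights[v] for v in net.nodes()))
    if total == 0:
        raise UsageError("all node weights are zero; scores are undefined")
    mean = total / net.number_of_nodes()
    scores: dict[Node, float] = {}
    for v in net.nodes():
        within = nx.single_source_shortest_path_length(net, v, cutoff=s)
        acc = sum(node_weights[j] - mean for j in within if j != v)
        scores[v] = (2.0 / total) * acc
    return scores


def select_top_fraction(
    scores: Mapping[Node, float], fraction: float = 0.10
) -> set[Node]:
    """The ceil(fraction * N) highest-scoring nodes; ties at the cut are all kept."""
    if not 0 < fraction <= 1:
        raise UsageError("fraction must be in (0, 1]")
    k = math.ceil(fraction * len(scores))
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    cut_value = ranked[k - 1][1]
    selected = {v for v, sc in ranked[:k]}
    tied = {v for v, sc in scores.items() if sc == cut_value}
    if not tied <= selected:
        logger.info("including %d extra nodes tied at the cut", len(tied - selected))
    return selected | tied


def extract_score_subnetwork(
    net: nx.Graph,
    top_scores: Iterable[Node],
    top_weights: Iterable[Node],
) -> WeightedSubnetwork:
    """Union of one unweighted shortest path per (top-score, top-weight) pair.

    Pairs are unordered; a node present in both sets contributes no self-path.
    Ties break toward the lexicographically smallest node sequence.
    """
    top_scores = sorted(set(top_scores))
    top_weights = sorted(set(top_weights))
    if not top_scores or not top_weights:
        raise UsageError("both node sets must be non-empty")
    unit = {(u, v): 1.0 for u, v in net.edges()}
    seen_pairs: set[frozenset] = set()
    retained = []
    isolated = 0
    for a in top_scores:
        for b in top_weights:
            if a == b or a not in net or b not in net:
                continue
            key = frozenset((a, b))
            if key in seen_pairs:
                continue
            seen_pairs.add(key)
            s, t = sorted((a, b))
            path = _lex_dijkstra(net, unit, s, t)
            if path is None:
                isolated += 1
                continue
            retained.append(((s, t), path))
    if isolated:
        logger.info("%d pairs were not connected", isolated)
    return WeightedSubnetwork(base=net, edge_weights=unit, retained_paths=retained)
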