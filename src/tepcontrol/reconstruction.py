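"""Reconstruction of the platelet signaling network from curated interactions.

The pipeline keeps only well-curated, signed, directed interactions; restricts
nodes to genes expressed in platelets (or detected in proteomics); predicts an
expected sign for every edge from the product of its endpoints' log2 fold
changes; drops edges whose curated and predicted signs contradict; and retains
the largest (weakly) connected component.  A companion builder produces the
expanded undirected interactome that ignores direction and sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from tepcontrol.errors import EmptyInputError
from tepcontrol.io import GeneStatRecord, InteractionRecord, records_to_digraph

logger = logging.getLogger(__name__)


@dataclass
class ReconstructionConfig:
    """Thresholds governing network reconstruction.

    min_curation
        Minimum number of curation events supporting an interaction
        (inclusive; default 3).
    expr_threshold
        Minimum average expression for a node to count as platelet-expressed
        (inclusive; default 1.0, the first quartile of the expression
        distribution in the source data).
    fc_threshold, p_threshold
        Differential-expression cutoffs (strict; |log2FC| > 0.58,
        adjusted p < 0.05).
    require_signed_directed
        When True (the signaling-network path) only directed edges with a
        known sign pass the curation filter; the expanded-interactome path
        sets this False and applies no curation cutoff.
    """

    min_curation: int = 3
    expr_threshold: float = 1.0
    fc_threshold: float = 0.58
    p_threshold: float = 0.05
    require_signed_directed: bool = True

    def __post_init__(self) -> None:
        if self.min_curation < 0:
            raise ValueError("min_curation must be >= 0")
        if self.expr_threshold <= 0 or self.fc_threshold <= 0 or self.p_threshold <= 0:
            raise ValueError("thresholds must be positive")


def filter_curated_interactions(
    records: Iterable[InteractionRecord], cfg: ReconstructionConfig
) -> list[InteractionRecord]:
    """Keep interactions meeting the curation (and optionally sign/direction) bar."""
    out = []
    for rec in records:
        if rec.curation_effort < cfg.min_curation:
            continue
        if cfg.require_signed_directed and not (rec.is_directed and rec.sign != 0):
            continue
        out.append(rec)
    return out


def select_expressed_nodes(
    stats: Mapping[str, GeneStatRecord],
    proteome_sets: Sequence[set[str]] = (),
    cfg: ReconstructionConfig | None = None,
) -> set[str]:
    """Nodes with average expression >= threshold, or detected in any proteome set."""
    cfg = cfg or ReconstructionConfig()
    detected: set[str] = set().union(*proteome_sets) if proteome_sets else set()
    expressed = {
        gene for gene, rec in stats.items() if rec.avg_expr >= cfg.expr_threshold
    }
    return expressed | detected


def predict_edge_sign(
    fc_source: float | None, fc_target: float | None, both_significant: bool
) -> int:
    """Predicted interaction sign from the product of endpoint log2 fold changes.

    Only fold changes of significant genes are trusted; when either endpoint is
    non-significant or missing the prediction is unknown (0) and can never
    contradict a curated sign.
    """
    if not both_significant or fc_source is None or fc_target is None:
        return 0
    product = fc_source * fc_target
    if product > 0:
        return 1
    if product < 0:
        return -1
    return 0


def _predicted_sign_for_edge(
    u: str, v: str, stats: Mapping[str, GeneStatRecord]
) -> int:
    su, sv = stats.get(u), stats.get(v)
    both = bool(su and sv and su.significant and sv.significant)
    return predict_edge_sign(
        su.log2fc if su else None, sv.log2fc if sv else None, both
    )


def remove_contradictions(
    net: nx.DiGraph, stats: Mapping[str, GeneStatRecord]
) -> nx.DiGraph:
    """Drop edges whose curated sign contradicts the predicted sign.

    An edge is removed iff both its curated and predicted signs are known and
    they differ.  Unknown predictions (either endpoint non-significant) never
    remove an edge.
    """
    out = net.copy()
    removed = 0
    for u, v, data in list(net.edges(data=True)):
        curated = data.get("sign", 0)
        predicted = _predicted_sign_for_edge(u, v, stats)
        if curated != 0 and predicted != 0 and curated != predicted:
            out.remove_edge(u, v)
            removed += 1
    logger.info("contradiction removal: %d edges dropped", removed)
    return out


def largest_connected_component(net: nx.DiGraph | nx.Graph) -> nx.DiGraph | nx.Graph:
    """Subgraph induced on the largest (weakly) connected component.

    Ties between equally large components are broken toward the component
    containing the lexicographically smallest node label.
    """
    if net.number_of_nodes() == 0:
        raise EmptyInputError("cannot take the largest component of an empty network")
    if net.is_directed():
        components = nx.weakly_connected_components(net)
    else:
        components = nx.connected_components(net)
    comps = list(components)
    biggest = max(len(c) for c in comps)
    best = min((c for c in comps if len(c) == biggest), key=min)
    return net.subgraph(best).copy()


def build_signaling_network(
    records: Iterable[InteractionRecord],
    stats: Mapping[str, GeneStatRecord],
    proteome_sets: Sequence[set[str]] = (),
    cfg: ReconstructionConfig | None = None,
    provenance: dict[str, int] | None = None,
) -> nx.DiGraph:
    """Full reconstruction: curation filter -> expression node filter ->
    sign-contradiction removal -> largest weakly connected component.

    ``provenance`` (if given) collects the edge count after each step; the
    sequence is monotone non-increasing.
    """
    cfg = cfg or ReconstructionConfig()
    records = list(records)
    log = provenance if provenance is not None else {}
    log["input_edges"] = len(records)

    curated = filter_curated_interactions(records, cfg)
    log["after_curation_filter"] = len(curated)

    nodes = select_expressed_nodes(stats, proteome_sets, cfg)
    expressed = [r for r in curated if r.source in nodes and r.target in nodes]
    log["after_expression_filter"] = len(expressed)
    if not expressed:
        raise EmptyInputError("no interactions among expressed nodes")

    net = records_to_digraph(expressed)
    net = remove_contradictions(net, stats)
    log["after_contradiction_removal"] = net.number_of_edges()

    net.remove_nodes_from(list(nx.isolates(net)))
    if net.number_of_nodes() == 0:
        raise EmptyInputError("contradiction removal emptied the network")
    net = largest_connected_component(net)
    log["largest_component_edges"] = net.number_of_edges()
    log["largest_component_nodes"] = net.number_of_nodes()
    logger.info("reconstruction provenance: %s", log)
    return net


def build_deg_subnetwork(
    net: nx.DiGraph, stats: Mapping[str, GeneStatRecord]
) -> nx.DiGraph:
    """Subnetwork of interactions involving differentially expressed genes.

    Keeps every edge with at least one DEG endpoint (the network passed in is
    assumed contradiction-filtered already), then prunes isolated nodes.
    """
    degs = {g for g, rec in stats.items() if rec.significant}
    out = nx.DiGraph()
    for u, v, data in net.edges(data=True):
        if u in degs or v in degs:
            out.add_edge(u, v, **data)
    return out


def build_expanded_interactome(
    records: Iterable[InteractionRecord],
    stats: Mapping[str, GeneStatRecord],
    proteome_sets: Sequence[set[str]] = (),
    cfg: ReconstructionConfig | None = None,
) -> nx.Graph:
    """Undirected interactome over expressed nodes, ignoring sign and direction.

    All interactions are eligible (no curation cutoff); reciprocal directed
    records collapse to one undirected edge; the largest component is kept.
    """
    cfg = cfg or ReconstructionConfig()
    nodes = select_expressed_nodes(stats, proteome_sets, cfg)
    net = nx.Graph()
    for rec in records:
        if rec.source in nodes and rec.target in nodes:
            net.add_edge(rec.source, rec.target)
    if net.number_of_nodes() == 0:
        raise EmptyInputError("no interactions among expressed nodes")
    return largest_connected_component(net)
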