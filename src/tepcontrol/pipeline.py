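"""End-to-end orchestration: reconstruction -> controllability -> subnetworks
-> gene scores -> drug ranking, with per-stage artifacts and a provenance log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from tepcontrol import controllability as ctl
from tepcontrol import drugs as drug_mod
from tepcontrol import reconstruction as rec
from tepcontrol import subnetworks as sub
from tepcontrol.errors import TepControlError
from tepcontrol.io import (
    GeneStatRecord,
    InteractionRecord,
    export_network,
    parse_gene_stats,
    parse_interaction_table,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and knobs for a full pipeline run."""

    interactions: str | Path = ""
    gene_stats: str | Path = ""
    drug_table: str | Path | None = None
    drug_interactions: str | Path | None = None
    proteome_lists: Sequence[str | Path] = ()
    reconstruction: rec.ReconstructionConfig = field(
        default_factory=rec.ReconstructionConfig
    )
    seed: int = 0
    capacity_samples: int = 200
    knode_distance: int = 2
    top_fraction: float = 0.10
    anchor_drug: str | None = None
    max_combination_size: int = 3
    out_dir: str | Path | None = None


@dataclass
class RunReport:
    """Everything a run computed, ready for serialization."""

    provenance: dict
    mds_class_counts: dict
    removal_class_counts: dict
    profiles: pd.DataFrame
    controllable_nodes: int
    controllable_edges: int
    score_table: pd.DataFrame
    top_score_nodes: list
    top_weight_nodes: list
    ranked_drugs: list
    combinations: list

    def summary(self) -> dict:
        return {
            "provenance": self.provenance,
            "mds_class_counts": self.mds_class_counts,
            "removal_class_counts": self.removal_class_counts,
            "controllable_subnetwork": {
                "nodes": self.controllable_nodes,
                "edges": self.controllable_edges,
            },
            "top_score_nodes": self.top_score_nodes[:10],
            "top_weight_nodes": self.top_weight_nodes[:10],
            "ranked_drugs": self.ranked_drugs[:10],
            "combinations": [
                {
                    "members": list(c.members),
                    "coverage": c.coverage,
                    "strength_score": round(c.strength_score, 4),
                    "control_score": round(c.control_score, 4),
                }
                for c in self.combinations[:5]
            ],
        }


def run_pipeline_data(
    records: Sequence[InteractionRecord],
    stats: Mapping[str, GeneStatRecord],
    drug_records: Sequence[drug_mod.DrugRecord] = (),
    drug_pairs: set[frozenset] | None = None,
    proteome_sets: Sequence[set[str]] = (),
    cfg: PipelineConfig | None = None,
) -> RunReport:
    """Run the full analysis on in-memory inputs (see :func:`run_pipeline`)."""
    cfg = cfg or PipelineConfig()
    drug_pairs = drug_pairs or set()
    provenance: dict = {"seed": cfg.seed}

    # --- stage 1: reconstruction
    recon_log: dict = {}
    net = rec.build_signaling_network(
        records, stats, proteome_sets, cfg.reconstruction, provenance=recon_log
    )
    provenance["reconstruction"] = recon_log
    deg_net = rec.build_deg_subnetwork(net, stats)
    provenance["deg_subnetwork"] = {
        "nodes": deg_net.number_of_nodes(),
        "edges": deg_net.number_of_edges(),
    }
    expanded_cfg = dataclasses.replace(
        cfg.reconstruction, require_signed_directed=False
    )
    interactome = rec.build_expanded_interactome(
        records, stats, proteome_sets, expanded_cfg
    )
    provenance["expanded_interactome"] = {
        "nodes": interactome.number_of_nodes(),
        "edges": interactome.number_of_edges(),
    }

    # --- stage 2: controllability
    profiles = ctl.node_control_profiles(
        net, seed=cfg.seed, n_samples=cfg.capacity_samples
    )
    mds_counts = profiles["mds_class"].value_counts().to_dict()
    removal_counts = profiles["removal_class"].value_counts().to_dict()

    # --- stage 3: fold-change-weighted controllable subnetwork
    weighted = sub.compute_edge_weights(net, stats)
    critical = sorted(profiles.index[profiles["mds_class"] == "critical"])
    indispensable = sorted(
        profiles.index[profiles["removal_class"] == "indispensable"]
    )
    if critical and indispensable:
        controllable = sub.extract_controllable_subnetwork(
            weighted, critical, indispensable
        )
        csub = controllable.subgraph()
    else:
        logger.warning("no critical or no indispensable nodes; empty controllable subnetwork")
        controllable = None
        csub = nx.DiGraph()
    priority_targets = sorted(set(indispensable) & set(csub.nodes()))

    # --- stage 4: node weights + proximity scores on the expanded interactome
    node_weights = sub.compute_node_weights(interactome, stats)
    gene_scores = sub.compute_gene_scores(
        interactome, node_weights, s=cfg.knode_distance
    )
    top_scores = sub.select_top_fraction(gene_scores, cfg.top_fraction)
    top_weights = sub.select_top_fraction(node_weights, cfg.top_fraction)
    score_sub = sub.extract_score_subnetwork(interactome, top_scores, top_weights)
    score_table = pd.DataFrame(
        {
            "degree": {v: interactome.degree(v) for v in interactome.nodes()},
            "log2FC": {
                v: (stats[v].log2fc if v in stats else None)
                for v in interactome.nodes()
            },
            "weight": node_weights,
            "gene_score": gene_scores,
        }
    ).sort_values("gene_score", ascending=False)

    # --- stage 5: drugs
    ranked: list = []
    combos: list = []
    if drug_records and priority_targets:
        actionable = drug_mod.filter_actionable(drug_records)
        coverage = drug_mod.map_targets(priority_targets, actionable)
        ranked = drug_mod.rank_drugs(coverage)
        if ranked:
            anchor = cfg.anchor_drug or ranked[0][0]
            combos = drug_mod.rank_combinations(
                [d for d in actionable if d.drug in coverage],
                anchor,
                drug_pairs,
                priority_targets,
                node_profiles=profiles,
                max_size=cfg.max_combination_size,
            )
    elif not drug_records:
        logger.info("drug stage: no candidates (empty drug table)")

    report = RunReport(
        provenance=provenance,
        mds_class_counts=mds_counts,
        removal_class_counts=removal_counts,
        profiles=profiles,
        controllable_nodes=csub.number_of_nodes(),
        controllable_edges=csub.number_of_edges(),
        score_table=score_table,
        top_score_nodes=sorted(top_scores),
        top_weight_nodes=sorted(top_weights),
        ranked_drugs=ranked,
        combinations=combos,
    )

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        export_network(net, out / "signaling_network.tsv", "tsv")
        export_network(net, out / "signaling_network.graphml", "graphml")
        if csub.number_of_edges():
            export_network(csub, out / "controllable_subnetwork.tsv", "tsv")
        profiles.to_csv(out / "node_profiles.tsv", sep="\t")
        score_table.to_csv(out / "gene_scores.tsv", sep="\t")
        write_report(report, out / "report.json", fmt="json")
        write_report(report, out / "report.md", fmt="markdown")
    return report


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Load the configured input tables and run the full analysis.

    Stages: reconstruction of the signed signaling network (with provenance
    counts), node controllability classification, extraction of the
    fold-change-weighted controllable subnetwork from critical to
    indispensable nodes, proximity gene scoring on the expanded undirected
    interactome, and drug/combination ranking over the prioritized targets.
    """
    try:
        records = parse_interaction_table(cfg.interactions)
        stats = parse_gene_stats(
            cfg.gene_stats,
            fc_threshold=cfg.reconstruction.fc_threshold,
            p_threshold=cfg.reconstruction.p_threshold,
        )
    except TepControlError as exc:
        raise TepControlError(f"input stage: {exc}") from exc
    proteomes = [
        {line.strip() for line in Path(p).read_text().splitlines() if line.strip()}
        for p in cfg.proteome_lists
    ]
    drug_records: list = []
    pairs: set[frozenset] = set()
    if cfg.drug_table:
        drug_records = drug_mod.parse_drug_table(cfg.drug_table)
    if cfg.drug_interactions:
        pairs = drug_mod.parse_interaction_pairs(cfg.drug_interactions)
    return run_pipeline_data(records, stats, drug_records, pairs, proteomes, cfg)


def write_report(report: RunReport, path: str | Path, fmt: str = "json") -> Path:
    """Serialize a run summary as JSON or markdown."""
    path = Path(path)
    summary = report.summary()
    if fmt == "json":
        path.write_text(json.dumps(summary, indent=2, sort_keys=True, default=str))
    elif fmt == "markdown":
        lines = ["# Pipeline run report", ""]
        lines += ["## Reconstruction", "```json",
                  json.dumps(summary["provenance"], indent=2, default=str), "```", ""]
        lines += ["## Controllability",
                  f"- MDS classes: {summary['mds_class_counts']}",
                  f"- Removal classes: {summary['removal_class_counts']}", ""]
        lines += ["## Controllable subnetwork",
                  f"- nodes: {summary['controllable_subnetwork']['nodes']}, "
                  f"edges: {summary['controllable_subnetwork']['edges']}", ""]
        lines += ["## Gene scores",
                  f"- top score nodes: {', '.join(map(str, summary['top_score_nodes']))}",
                  f"- top weight nodes: {', '.join(map(str, summary['top_weight_nodes']))}", ""]
        lines += ["## Drugs"]
        if summary["ranked_drugs"]:
            lines += [f"- {d}: {c} targets" for d, c in summary["ranked_drugs"]]
            lines += ["", "### Combinations"]
            lines += [
                f"- {' + '.join(c['members'])} (coverage {c['coverage']})"
                for c in summary["combinations"]
            ]
        else:
            lines.append("- no candidates")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise TepControlError(f"unknown report format {fmt!r}")
    return path
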