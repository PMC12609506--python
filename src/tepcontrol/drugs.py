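"""Drug and drug-combination ranking over prioritized network nodes.

Prioritized nodes (e.g. the indispensable nodes of the controllable
subnetwork) are intersected with a drug-target table; drugs are ranked by how
many prioritized nodes they cover, filtered for clinical actionability
(approval plus known pharmacological action), and assembled into
non-interacting combinations around an anchor drug.  Combinations are ordered
lexicographically by (target coverage, inhibition strength, control-metric
rank of the covered targets).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Iterable, Mapping, Sequence

import pandas as pd

from tepcontrol.errors import EmptyInputError, FormatError, UsageError

logger = logging.getLogger(__name__)

Node = Hashable


@dataclass(frozen=True)
class DrugRecord:
    """One drug with its protein targets and clinical-actionability flags.

    ``ki`` optionally maps a subset of the targets to inhibition constants in
    nM (smaller = stronger inhibition).
    """

    drug: str
    targets: frozenset
    approved: bool = True
    known_action: bool = True
    ki: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError(f"{self.drug}: target set must be non-empty")
        if not set(self.ki) <= set(self.targets):
            raise ValueError(f"{self.drug}: ki keys must be targets")


@dataclass(frozen=True)
class CombinationRanking:
    """A ranked drug combination with the targets it covers."""

    members: tuple[str, ...]
    covered_targets: frozenset
    coverage: int
    strength_score: float
    control_score: float


def parse_drug_table(path: str | Path) -> list[DrugRecord]:
    """Read a drug-target TSV (drug, target, approved, known_action, ki_nM).

    One row per (drug, target) pair; rows for one drug are merged into a
    single record (flags are AND-ed across rows).
    """
    frame = pd.read_csv(Path(path), sep="\t", dtype=str, keep_default_na=False)
    if frame.empty:
        raise EmptyInputError(f"{path}: empty drug table")
    for col in ("drug", "target"):
        if col not in frame.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    by_drug: dict[str, dict] = {}
    for _, row in frame.iterrows():
        entry = by_drug.setdefault(
            row["drug"], {"targets": set(), "approved": True, "known_action": True, "ki": {}}
        )
        entry["targets"].add(row["target"])
        if "approved" in frame.columns:
            entry["approved"] &= row["approved"].strip().lower() in {"1", "true", "yes"}
        if "known_action" in frame.columns:
            entry["known_action"] &= row["known_action"].strip().lower() in {"1", "true", "yes"}
        if "ki_nM" in frame.columns and row["ki_nM"].strip() not in {"", "NA"}:
            entry["ki"][row["target"]] = float(row["ki_nM"])
    return [
        DrugRecord(
            drug=name,
            targets=frozenset(entry["targets"]),
            approved=entry["approved"],
            known_action=entry["known_action"],
            ki=dict(entry["ki"]),
        )
        for name, entry in sorted(by_drug.items())
    ]


def parse_interaction_pairs(path: str | Path) -> set[frozenset]:
    """Read a drug-drug interaction TSV (drug_a, drug_b) as symmetric pairs."""
    frame = pd.read_csv(Path(path), sep="\t", dtype=str, keep_default_na=False)
    for col in ("drug_a", "drug_b"):
        if col not in frame.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    return {
        frozenset((a, b))
        for a, b in zip(frame["drug_a"], frame["drug_b"])
        if a != b
    }


def map_targets(
    nodes: Iterable[Node], drugs: Sequence[DrugRecord]
) -> dict[str, frozenset]:
    """Per-drug coverage of the prioritized node set; empty coverages dropped."""
    node_set = set(nodes)
    covered = {}
    for rec in drugs:
        overlap = rec.targets & node_set
        if overlap:
            covered[rec.drug] = frozenset(overlap)
    return covered


def rank_drugs(coverage: Mapping[str, frozenset]) -> list[tuple[str, int]]:
    """Drugs ordered by descending coverage count, ties alphabetical."""
    return sorted(
        ((drug, len(targets)) for drug, targets in coverage.items()),
        key=lambda item: (-item[1], item[0]),
    )


def filter_actionable(drugs: Sequence[DrugRecord]) -> list[DrugRecord]:
    """Keep only approved drugs with known pharmacological action."""
    kept = [d for d in drugs if d.approved and d.known_action]
    logger.info("actionability filter: %d of %d drugs kept", len(kept), len(drugs))
    return kept


def _strength(ki: float) -> float:
    """Monotone-decreasing inhibition-strength contribution of one ki (nM)."""
    if ki <= 1.0:
        return 10.0  # sub-nanomolar binders: capped maximal contribution
    return 1.0 / math.log10(ki)


def rank_combinations(
    drugs: Sequence[DrugRecord],
    anchor: str,
    interactions: set[frozenset],
    nodes: Iterable[Node],
    node_profiles: pd.DataFrame | None = None,
    max_size: int = 3,
) -> list[CombinationRanking]:
    """Rank anchor-based combinations of pairwise non-interacting drugs.

    Candidates are the anchor plus up to ``max_size - 1`` drugs that do not
    interact with the anchor or with each other.  Ordering is lexicographic by
    (descending union coverage of the prioritized nodes, descending strength
    score = sum of 1/log10(ki) over covered targets with known ki, descending
    control score = rank-sum of the covered targets' control centrality and
    betweenness from ``node_profiles``), then alphabetically by members.
    """
    by_name = {d.drug: d for d in drugs}
    if anchor not in by_name:
        raise UsageError(f"anchor drug {anchor!r} not in the drug table")
    node_set = set(nodes)

    ranks: dict[Node, float] = {}
    if node_profiles is not None:
        for col in ("control_centrality", "betweenness"):
            if col in node_profiles.columns:
                col_ranks = node_profiles[col].rank(method="average")
                for node, r in col_ranks.items():
                    ranks[node] = ranks.get(node, 0.0) + float(r)

    compatible = [
        name
        for name in sorted(by_name)
        if name != anchor and frozenset((name, anchor)) not in interactions
    ]

    combos: list[CombinationRanking] = []
    for extra in range(0, max_size):
        for others in itertools.combinations(compatible, extra):
            if any(
                frozenset((a, b)) in interactions
                for a, b in itertools.combinations(others, 2)
            ):
                continue
            members = tuple(sorted((anchor, *others)))
            covered = frozenset().union(
                *(by_name[m].targets & node_set for m in members)
            )
            strength = sum(
                _strength(by_name[m].ki[t])
                for m in members
                for t in by_name[m].targets & node_set
                if t in by_name[m].ki
            )
            control = sum(ranks.get(t, 0.0) for t in covered)
            combos.append(
                CombinationRanking(
                    members=members,
                    covered_targets=covered,
                    coverage=len(covered),
                    strength_score=strength,
                    control_score=control,
                )
            )
    combos.sort(
        key=lambda c: (-c.coverage, -c.strength_score, -c.control_score, c.members)
    )
    return combos
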