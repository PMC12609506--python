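"""Synthetic inputs with the statistical structure of the real pipeline inputs,
plus small reference fixtures (published result tables and toy graphs).

The generators emulate what the pipeline consumes: a sparse curated
interactome whose edges carry direction/sign flags and a long-tailed curation
count; a gene table in which a minority of genes are genuinely differentially
expressed (Benjamini-Hochberg-adjusted p-values, log-normal average
expression); and drug tables whose target choices are biased toward network
hubs.  Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Hashable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats as sps

from tepcontrol.drugs import DrugRecord
from tepcontrol.errors import UsageError
from tepcontrol.io import GeneStatRecord, InteractionRecord, make_gene_stat

Node = Hashable


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic input generators.

    The defaults emulate the scale and composition of the real study inputs
    at desk size: a few-hundred-node curated interactome in which roughly
    half the records are signed and directed, about a quarter reach a
    curation effort of 3, ~15% of genes are differentially expressed with
    |log2FC| ~ 1.2, and ~75% of genes clear the average-expression cutoff
    of 1 (its first quartile).
    """

    seed: int = 0
    n_nodes: int = 300
    n_edges: int = 1500
    frac_directed_signed: float = 0.55
    curation_shape: float = 0.5  # geometric success prob; P(effort >= 3) = (1-p)^2
    frac_significant: float = 0.15
    de_effect_mean: float = 1.2
    de_effect_sd: float = 0.4
    null_sd: float = 0.25
    fc_threshold: float = 0.58
    p_threshold: float = 0.05
    n_drugs: int = 40
    targets_per_drug: float = 3.0
    frac_approved: float = 0.75
    frac_known_action: float = 0.8
    frac_interacting_pairs: float = 0.05

    def __post_init__(self) -> None:
        for name in (
            "frac_directed_signed",
            "frac_significant",
            "frac_approved",
            "frac_known_action",
            "frac_interacting_pairs",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise UsageError(f"{name} must be in [0, 1]")
        if self.n_edges > self.n_nodes**2:
            raise UsageError("n_edges exceeds the number of possible directed pairs")


def _gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def simulate_interactome(cfg: SimulationConfig) -> list[InteractionRecord]:
    """Curated interaction records with heavy-tailed degrees.

    Edges are grown by degree-preferential attachment (new endpoints are
    drawn with probability proportional to current degree + 1), giving the
    hub-dominated topology of curated interactomes.  Each record is signed
    and directed with probability ``frac_directed_signed`` (sign +/-1
    equiprobable) and carries a geometric curation-effort count.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_names(cfg.n_nodes)
    degree = np.ones(cfg.n_nodes)
    seen: set[tuple[int, int]] = set()
    records: list[InteractionRecord] = []
    while len(records) < cfg.n_edges:
        prob = degree / degree.sum()
        u = int(rng.choice(cfg.n_nodes, p=prob))
        v = int(rng.choice(cfg.n_nodes, p=prob))
        if u == v or (u, v) in seen:
            continue
        seen.add((u, v))
        degree[u] += 1
        degree[v] += 1
        signed_directed = rng.random() < cfg.frac_directed_signed
        sign = int(rng.choice([-1, 1])) if signed_directed else 0
        records.append(
            InteractionRecord(
                source=genes[u],
                target=genes[v],
                is_directed=signed_directed,
                sign=sign,
                curation_effort=int(rng.geometric(cfg.curation_shape)),
            )
        )
    return records


def simulate_gene_stats(
    cfg: SimulationConfig, nodes: Sequence[str]
) -> dict[str, GeneStatRecord]:
    """Per-gene statistics with a planted differentially expressed minority.

    A fraction ``frac_significant`` of genes receives |log2FC| drawn from
    N(de_effect_mean, de_effect_sd) with a random sign and a tiny raw
    p-value; the rest get null fold changes N(0, null_sd) and uniform raw
    p-values.  Raw p-values are Benjamini-Hochberg adjusted here, so the
    emitted table matches real differential-expression output and must never
    be re-adjusted downstream.  Average expression is log-normal with its
    first quartile near 1.
    """
    if not nodes:
        raise UsageError("nodes must be non-empty")
    rng = np.random.default_rng(cfg.seed + 1)
    n = len(nodes)
    planted = rng.random(n) < cfg.frac_significant
    fc = np.where(
        planted,
        rng.choice([-1.0, 1.0], size=n)
        * rng.normal(cfg.de_effect_mean, cfg.de_effect_sd, size=n),
        rng.normal(0.0, cfg.null_sd, size=n),
    )
    raw_p = np.where(
        planted,
        10.0 ** rng.uniform(-10.0, -4.0, size=n),
        rng.uniform(0.0, 1.0, size=n),
    )
    adj_p = sps.false_discovery_control(raw_p, method="bh")
    avg_expr = rng.lognormal(mean=0.8, sigma=1.2, size=n)
    return {
        gene: make_gene_stat(
            gene,
            float(fc[i]),
            float(adj_p[i]),
            float(avg_expr[i]),
            cfg.fc_threshold,
            cfg.p_threshold,
        )
        for i, gene in enumerate(nodes)
    }


def simulate_drug_tables(
    cfg: SimulationConfig,
    nodes: Sequence[str] | nx.Graph | nx.DiGraph,
) -> tuple[list[DrugRecord], set[frozenset]]:
    """Drug-target records and symmetric drug-drug interaction pairs.

    When ``nodes`` is a network, target choices are biased toward hubs
    (probability proportional to degree + 1), reflecting the empirical
    druggability of highly connected proteins; a plain node sequence gives
    uniform targeting.  Inhibition constants are log-uniform in [1, 1e4] nM.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    if isinstance(nodes, (nx.Graph, nx.DiGraph)):
        names = sorted(nodes.nodes())
        weight = np.array([nodes.degree(v) + 1.0 for v in names])
    else:
        names = list(nodes)
        weight = np.ones(len(names))
    if not names:
        raise UsageError("nodes must be non-empty")
    prob = weight / weight.sum()
    drugs: list[DrugRecord] = []
    for d in range(cfg.n_drugs):
        k = min(len(names), max(1, int(rng.poisson(cfg.targets_per_drug))))
        targets = rng.choice(len(names), size=k, replace=False, p=prob)
        ki = {
            names[t]: float(10.0 ** rng.uniform(0.0, 4.0))
            for t in targets
            if rng.random() < 0.7
        }
        drugs.append(
            DrugRecord(
                drug=f"drug{d:03d}",
                targets=frozenset(names[t] for t in targets),
                approved=bool(rng.random() < cfg.frac_approved),
                known_action=bool(rng.random() < cfg.frac_known_action),
                ki=ki,
            )
        )
    all_pairs = list(itertools.combinations([d.drug for d in drugs], 2))
    n_pairs = int(round(cfg.frac_interacting_pairs * len(all_pairs)))
    chosen = rng.choice(len(all_pairs), size=n_pairs, replace=False)
    interactions = {frozenset(all_pairs[i]) for i in chosen}
    return drugs, interactions


def plant_receptor(
    records: list[InteractionRecord],
    targets: Iterable[str],
    name: str = "RCPT1",
    curation: int = 5,
) -> list[InteractionRecord]:
    """Append a zero-in-degree receptor driving ``targets``.

    A node with no incoming edges can never be matched, so it must be
    critical after reconstruction (provided it survives the node filters).
    """
    extra = [
        InteractionRecord(name, t, is_directed=True, sign=1, curation_effort=curation)
        for t in sorted(set(targets))
    ]
    return list(records) + extra


def plant_bridge(
    records: list[InteractionRecord],
    host: str,
    name: str = "BRDG1",
    curation: int = 5,
) -> tuple[list[InteractionRecord], tuple[str, str, str]]:
    """Append a private chain host -> x -> bridge -> y hanging off ``host``.

    The in-copies of x, bridge and y have no suitors outside the chain, so
    every maximum matching contains out(x)-in(bridge) and out(bridge)-in(y)
    and the out(host)-in(x) option is unaffected by the bridge.  Deleting the
    bridge therefore removes exactly two matched links while shrinking the
    network by one node, raising the driver count by exactly one: the bridge
    is guaranteed indispensable.
    """
    x, y = f"{name}_IN", f"{name}_OUT"
    extra = [
        InteractionRecord(host, x, is_directed=True, sign=1, curation_effort=curation),
        InteractionRecord(x, name, is_directed=True, sign=1, curation_effort=curation),
        InteractionRecord(name, y, is_directed=True, sign=1, curation_effort=curation),
    ]
    return list(records) + extra, (x, name, y)


# ---------------------------------------------------------------------------
# reference fixtures: published result tables and toy graphs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScoreRow:
    """One row of the published targetable high-score node table."""

    gene: str
    degree: int
    log2fc: float | None
    weight: float
    gene_score: float
    drugs: tuple[str, ...]


_TABLE3: list[tuple[str, tuple[str, ...]]] = [
    ("Fostamatinib", ("CAMK1", "JAK2", "MAPK14", "PRKCD", "PTK2")),
    ("Minocycline", ("CASP3", "MAPK1", "MAPK14", "MAPK3")),
    ("Acetylsalicylic acid", ("CASP3", "MAPK1", "MAPK3")),
    ("Arsenic trioxide", ("MAPK3", "MAPK1", "AKT1")),
    ("Copper", ("APP", "GAPDH", "HSP90AA1")),
    ("Benzoyl peroxide", ("PRKCA", "PRKCD")),
    ("Dequalinium", ("PRKCA", "PRKCD")),
    ("Ingenol mebutate", ("PRKCD", "PRKCA")),
    ("Tamoxifen", ("PRKCA", "PRKCD")),
    ("Abrocitinib", ("JAK2",)),
]

_TABLE4: list[tuple[str, int, float | None, float, float, tuple[str, ...]]] = [
    ("LYN", 48, -0.24, 11.34, 0.48,
     ("Dasatinib", "Bosutinib", "Ponatinib", "Nintedanib", "Fostamatinib")),
    ("JAK1", 21, None, 0.0, 0.47,
     ("Ruxolitinib", "Tofacitinib", "Momelotinib", "Baricitinib", "Fostamatinib",
      "Fedratinib", "Filgotinib", "Abrocitinib", "Upadacitinib", "Pralsetinib")),
    ("FCGR2A", 4, 0.68, 2.71, 0.46,
     ("Cetuximab", "Etanercept", "Human immunoglobulin G", "Abciximab",
      "Alemtuzumab", "Bevacizumab", "Catumaxomab", "Sarilumab")),
    ("TEC", 10, 0.25, 2.47, 0.46,
     ("Bosutinib", "Fostamatinib", "Ritlecitinib", "Zanubrutinib")),
    ("TUBA4A", 1, -0.13, 0.13, 0.45, ("Vincristine", "Podofilox")),
    ("PTPN6", 29, -0.09, 2.73, 0.45, ("Tiludronic acid",)),
    ("SYK", 37, -0.1, 3.84, 0.45, ("Fostamatinib",)),
    ("ITGA5", 5, None, 0.0, 0.45, ("Tauroursodeoxycholic acid",)),
    ("GRB2", 37, None, 0.0, 0.45, ("Pegademase",)),
    ("JAK3", 16, 0.45, 7.3, 0.44,
     ("Ruxolitinib", "Tofacitinib", "Momelotinib", "Baricitinib", "Fostamatinib",
      "Ritlecitinib", "Abrocitinib", "Zanubrutinib")),
    ("P2RY12", 1, -0.49, 0.49, 0.44,
     ("Ticlopidine", "Treprostinil", "Clopidogrel", "Promethazine", "Epoprostenol",
      "Prasugrel", "Cangrelor", "Ticagrelor")),
    ("BTK", 19, -0.271, 5.08, 0.44,
     ("Dasatinib", "Ibrutinib", "Acalabrutinib", "Fostamatinib", "Ritlecitinib",
      "Zanubrutinib", "Pirtobrutinib")),
    ("PPIA", 1, None, 0.0, 0.44, ("Cyclosporine", "Copper", "Artenimol")),
    ("PIK3CB", 1, 0.13, 0.13, 0.44, ("Caffeine", "Copanlisib")),
    ("CSK", 18, 0.11, 1.95, 0.44, ("Dasatinib", "Fostamatinib")),
    ("PTK2B", 37, 0.18, 6.76, 0.44, ("Leflunomide", "Fostamatinib")),
]


def _toy_graphs() -> dict[str, nx.DiGraph]:
    chain = nx.DiGraph([("a", "b"), ("b", "c")])
    star = nx.DiGraph([("h", "a"), ("h", "b"), ("h", "c")])
    cycle = nx.DiGraph([("a", "b"), ("b", "c"), ("c", "a")])
    detour = nx.DiGraph([("a", "d"), ("a", "b"), ("b", "d")])
    for g in (chain, star, cycle, detour):
        nx.set_edge_attributes(g, 1, "sign")
    return {"chain3": chain, "star4": star, "cycle3": cycle, "detour": detour}


def load_reference_fixtures() -> dict:
    """Published result tables and the toy graphs used across examples.

    Returns a dict with keys ``table3`` (drug name -> :class:`DrugRecord`
    of the published drugs-per-indispensable-node table), ``table4``
    (gene -> :class:`ScoreRow` of the published high-score node table) and
    ``toy_graphs`` (name -> small signed digraph).
    """
    table3 = {
        name: DrugRecord(drug=name, targets=frozenset(targets))
        for name, targets in _TABLE3
    }
    table4 = {
        gene: ScoreRow(gene, degree, fc, weight, score, drugs)
        for gene, degree, fc, weight, score, drugs in _TABLE4
    }
    return {"table3": table3, "table4": table4, "toy_graphs": _toy_graphs()}


def write_simulated_inputs(cfg: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write the full simulated input bundle as TSV files under ``out_dir``."""
    from tepcontrol.io import write_gene_stats, write_interactions

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = simulate_interactome(cfg)
    genes = _gene_names(cfg.n_nodes)
    stats = simulate_gene_stats(cfg, genes)
    net = nx.DiGraph((r.source, r.target) for r in records)
    drugs, pairs = simulate_drug_tables(cfg, net)
    paths = {
        "interactions": write_interactions(records, out / "interactions.tsv"),
        "gene_stats": write_gene_stats(stats, out / "gene_stats.tsv"),
    }
    drug_path = out / "drugs.tsv"
    with drug_path.open("w") as fh:
        fh.write("drug\ttarget\tapproved\tknown_action\tki_nM\n")
        for rec in drugs:
            for t in sorted(rec.targets):
                ki = f"{rec.ki[t]:.4g}" if t in rec.ki else "NA"
                fh.write(
                    f"{rec.drug}\t{t}\t{int(rec.approved)}\t{int(rec.known_action)}\t{ki}\n"
                )
    paths["drugs"] = drug_path
    pair_path = out / "drug_interactions.tsv"
    with pair_path.open("w") as fh:
        fh.write("drug_a\tdrug_b\n")
        for pair in sorted(tuple(sorted(p)) for p in pairs):
            fh.write(f"{pair[0]}\t{pair[1]}\n")
    paths["drug_interactions"] = pair_path
    return paths
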