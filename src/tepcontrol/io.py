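"""Domain records and readers/writers for the pipeline's tabular and graph formats.

The pipeline consumes two tables: a curated-interaction table (OmniPath-style
export with per-row direction, stimulation/inhibition flags and a curation
effort count) and a per-gene statistics table (limma-style ``topTable`` output
with log2 fold change, adjusted p-value and average expression).  Networks are
held as :class:`networkx.DiGraph` (signed, directed; per-edge ``sign`` in
{-1, 0, +1}) or :class:`networkx.Graph` (undirected interactome) and can be
written as tab-delimited edge lists, SIF or GraphML.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from tepcontrol.errors import EmptyInputError, FormatError, UsageError

logger = logging.getLogger(__name__)

#: tokens accepted as "missing" in numeric gene-table columns
MISSING_TOKENS = {"NA", "--", "", "NaN", "nan"}

#: default header map for OmniPath-style interaction exports
INTERACTION_DIALECT: dict[str, str] = {
    "source": "source_genesymbol",
    "target": "target_genesymbol",
    "is_directed": "is_directed",
    "is_stimulation": "is_stimulation",
    "is_inhibition": "is_inhibition",
    "curation_effort": "curation_effort",
}

#: default header map for limma-style gene statistics tables
GENE_STATS_DIALECT: dict[str, str] = {
    "gene": "gene",
    "log2fc": "logFC",
    "adj_p": "adj.P.Val",
    "avg_expr": "AveExpr",
}

SIF_RELATIONS = {1: "activates", -1: "inhibits", 0: "interacts"}
SIF_SIGNS = {v: k for k, v in SIF_RELATIONS.items()}


@dataclass(frozen=True)
class InteractionRecord:
    """One curated interaction between two gene symbols.

    ``sign`` is +1 for stimulation, -1 for inhibition and 0 for
    unknown/unsigned; ``curation_effort`` counts independent curation events
    supporting the interaction in the source database.
    """

    source: str
    target: str
    is_directed: bool
    sign: int
    curation_effort: int

    def __post_init__(self) -> None:
        if not self.source or not self.target:
            raise ValueError("source and target must be non-empty symbols")
        if self.sign not in (-1, 0, 1):
            raise ValueError(f"sign must be -1, 0 or +1, got {self.sign}")
        if self.curation_effort < 0:
            raise ValueError("curation_effort must be non-negative")


@dataclass(frozen=True)
class GeneStatRecord:
    """Per-gene differential-expression statistics.

    ``significant`` is derived at construction: both log2fc and adj_p present,
    ``|log2fc| > fc_threshold`` and ``adj_p < p_threshold`` (strict, matching
    the convention that a gene exactly at the cutoff is not differential).
    """

    gene: str
    log2fc: float | None
    adj_p: float | None
    avg_expr: float
    significant: bool = field(default=False)

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("gene symbol must be non-empty")
        if self.adj_p is not None and not (0.0 <= self.adj_p <= 1.0):
            raise ValueError(f"adjusted p-value out of [0, 1]: {self.adj_p}")


def make_gene_stat(
    gene: str,
    log2fc: float | None,
    adj_p: float | None,
    avg_expr: float,
    fc_threshold: float = 0.58,
    p_threshold: float = 0.05,
) -> GeneStatRecord:
    """Build a :class:`GeneStatRecord` with the significance flag computed."""
    significant = (
        log2fc is not None
        and adj_p is not None
        and abs(log2fc) > fc_threshold
        and adj_p < p_threshold
    )
    return GeneStatRecord(gene, log2fc, adj_p, avg_expr, significant)


def resolve_sign(is_stimulation: bool, is_inhibition: bool) -> int:
    """Map stimulation/inhibition flags to a sign.

    Rows flagged as both stimulation and inhibition are ambiguous curation and
    map to 0 (unknown), as do rows with neither flag set.
    """
    if is_stimulation and not is_inhibition:
        return 1
    if is_inhibition and not is_stimulation:
        return -1
    return 0


def _as_bool(token: str) -> bool:
    return str(token).strip().lower() in {"1", "true", "yes", "t"}


def parse_interaction_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> list[InteractionRecord]:
    """Read an OmniPath-style TSV of curated interactions.

    Parameters
    ----------
    path
        Tab-delimited file with one interaction per row.
    dialect
        Mapping from canonical field names (``source``, ``target``,
        ``is_directed``, ``is_stimulation``, ``is_inhibition``,
        ``curation_effort``) to the column headers used in the file.
        Defaults to the OmniPath export headers.

    Returns
    -------
    list of :class:`InteractionRecord`, one per parseable row.  Malformed rows
    are skipped with a logged warning naming the line number; rows flagged as
    both stimulation and inhibition get sign 0 with a warning.
    """
    cols = dict(INTERACTION_DIALECT)
    if dialect:
        cols.update(dialect)
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise EmptyInputError(f"{path}: empty interaction table")
        for key in ("source", "target", "curation_effort"):
            if cols[key] not in reader.fieldnames:
                raise FormatError(f"{path}: missing mandatory column {cols[key]!r}")
        records: list[InteractionRecord] = []
        for lineno, row in enumerate(reader, start=2):
            try:
                stim = _as_bool(row.get(cols["is_stimulation"], "0"))
                inhib = _as_bool(row.get(cols["is_inhibition"], "0"))
                if stim and inhib:
                    logger.warning(
                        "%s line %d: both stimulation and inhibition flags set; "
                        "sign recorded as unknown",
                        path,
                        lineno,
                    )
                records.append(
                    InteractionRecord(
                        source=row[cols["source"]].strip(),
                        target=row[cols["target"]].strip(),
                        is_directed=_as_bool(row.get(cols["is_directed"], "1")),
                        sign=resolve_sign(stim, inhib),
                        curation_effort=int(row[cols["curation_effort"]]),
                    )
                )
            except (ValueError, KeyError) as exc:
                logger.warning("%s line %d: malformed row skipped (%s)", path, lineno, exc)
    if not records:
        raise EmptyInputError(f"{path}: no interaction records parsed")
    return records


def _parse_optional_float(token: object) -> float | None:
    if token is None:
        return None
    text = str(token).strip()
    if text in MISSING_TOKENS:
        return None
    try:
        value = float(text)
    except ValueError as exc:
        raise FormatError(f"unrecognized numeric token {text!r}") from exc
    if math.isnan(value):
        return None
    return value


def parse_gene_stats(
    path: str | Path,
    fc_threshold: float = 0.58,
    p_threshold: float = 0.05,
    dialect: Mapping[str, str] | None = None,
) -> dict[str, GeneStatRecord]:
    """Read a limma-style gene statistics TSV keyed by gene symbol.

    ``NA``, ``--`` and empty cells are treated as missing log2FC / adjusted p.
    Duplicate symbols are collapsed to the row with the smallest adjusted p
    (rows with missing adjusted p lose ties to any row that has one).
    """
    cols = dict(GENE_STATS_DIALECT)
    if dialect:
        cols.update(dialect)
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if frame.empty:
        raise EmptyInputError(f"{path}: empty gene statistics table")
    for key in ("gene", "log2fc", "adj_p", "avg_expr"):
        if cols[key] not in frame.columns:
            raise FormatError(f"{path}: missing mandatory column {cols[key]!r}")
    table: dict[str, GeneStatRecord] = {}
    for _, row in frame.iterrows():
        gene = row[cols["gene"]].strip()
        log2fc = _parse_optional_float(row[cols["log2fc"]])
        adj_p = _parse_optional_float(row[cols["adj_p"]])
        avg = _parse_optional_float(row[cols["avg_expr"]])
        rec = make_gene_stat(gene, log2fc, adj_p, avg if avg is not None else 0.0,
                             fc_threshold, p_threshold)
        prev = table.get(gene)
        if prev is not None:
            prev_p = prev.adj_p if prev.adj_p is not None else math.inf
            new_p = adj_p if adj_p is not None else math.inf
            if new_p >= prev_p:
                continue
        table[gene] = rec
    return table


def records_to_digraph(records: Iterable[InteractionRecord]) -> nx.DiGraph:
    """Collapse interaction records into a signed digraph.

    Parallel records for one directed pair are collapsed to a single edge;
    when collapsed records disagree on sign (+1 vs -1) the edge gets sign 0
    with a warning.  ``curation_effort`` keeps the maximum across records.
    """
    net = nx.DiGraph()
    for rec in records:
        net.add_node(rec.source)
        net.add_node(rec.target)
        if net.has_edge(rec.source, rec.target):
            data = net.edges[rec.source, rec.target]
            if data["sign"] != rec.sign and 0 not in (data["sign"], rec.sign):
                logger.warning(
                    "conflicting curated signs for %s -> %s; sign set to unknown",
                    rec.source,
                    rec.target,
                )
                data["sign"] = 0
            elif data["sign"] == 0 and rec.sign != 0:
                data["sign"] = rec.sign
            data["curation_effort"] = max(data["curation_effort"], rec.curation_effort)
        else:
            net.add_edge(
                rec.source,
                rec.target,
                sign=rec.sign,
                curation_effort=rec.curation_effort,
            )
    return net


def export_network(
    net: nx.DiGraph | nx.Graph,
    path: str | Path,
    fmt: str = "tsv",
) -> Path:
    """Write a network as a tab-delimited edge list, SIF or GraphML file.

    The export round-trips: :func:`read_network` on the output reproduces the
    node and edge sets (and signs) exactly.  SIF relation tokens are
    ``activates`` / ``inhibits`` / ``interacts``.
    """
    if net.number_of_nodes() == 0:
        raise EmptyInputError("refusing to export an empty network")
    path = Path(path)
    if fmt == "tsv":
        with path.open("w") as fh:
            fh.write("source\ttarget\tsign\n")
            for u, v, data in sorted(net.edges(data=True)):
                fh.write(f"{u}\t{v}\t{data.get('sign', 0)}\n")
    elif fmt == "sif":
        with path.open("w") as fh:
            for u, v, data in sorted(net.edges(data=True)):
                fh.write(f"{u}\t{SIF_RELATIONS[data.get('sign', 0)]}\t{v}\n")
    elif fmt == "graphml":
        out = net.copy()
        for _, _, data in out.edges(data=True):
            data.setdefault("sign", 0)
        nx.write_graphml(out, path)
    else:
        raise UsageError(f"unknown export format {fmt!r}; use tsv, sif or graphml")
    return path


def read_network(
    path: str | Path,
    fmt: str = "tsv",
    directed: bool = True,
) -> nx.DiGraph | nx.Graph:
    """Read a network written by :func:`export_network`."""
    path = Path(path)
    net: nx.DiGraph | nx.Graph = nx.DiGraph() if directed else nx.Graph()
    if fmt == "tsv":
        with path.open() as fh:
            next(fh)  # header
            for line in fh:
                u, v, sign = line.rstrip("\n").split("\t")
                net.add_edge(u, v, sign=int(sign))
    elif fmt == "sif":
        with path.open() as fh:
            for line in fh:
                u, rel, v = line.rstrip("\n").split("\t")
                net.add_edge(u, v, sign=SIF_SIGNS[rel])
    elif fmt == "graphml":
        raw = nx.read_graphml(path)
        for u, v, data in raw.edges(data=True):
            net.add_edge(u, v, sign=int(data.get("sign", 0)))
        net.add_nodes_from(raw.nodes())
    else:
        raise UsageError(f"unknown format {fmt!r}")
    return net


def write_gene_stats(
    stats: Mapping[str, GeneStatRecord], path: str | Path
) -> Path:
    """Write a gene statistics table in the limma-style layout we read."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("gene\tlogFC\tadj.P.Val\tAveExpr\n")
        for gene in sorted(stats):
            rec = stats[gene]
            fc = "NA" if rec.log2fc is None else f"{rec.log2fc:.6g}"
            p = "NA" if rec.adj_p is None else f"{rec.adj_p:.6g}"
            fh.write(f"{gene}\t{fc}\t{p}\t{rec.avg_expr:.6g}\n")
    return path


def write_interactions(
    records: Sequence[InteractionRecord], path: str | Path
) -> Path:
    """Write interaction records in the OmniPath-style layout we read."""
    path = Path(path)
    cols = INTERACTION_DIALECT
    with path.open("w") as fh:
        fh.write(
            "\t".join(
                cols[k]
                for k in (
                    "source",
                    "target",
                    "is_directed",
                    "is_stimulation",
                    "is_inhibition",
                    "curation_effort",
                )
            )
            + "\n"
        )
        for rec in records:
            fh.write(
                f"{rec.source}\t{rec.target}\t{int(rec.is_directed)}\t"
                f"{int(rec.sign == 1)}\t{int(rec.sign == -1)}\t{rec.curation_effort}\n"
            )
    return path
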