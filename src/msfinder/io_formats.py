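"""Readers and writers for DGEA tables, edge lists and the MSF output files.

Input: a differential-expression result table (the raw output shape of edgeR
or DESeq2, or a generic three-column table) and a directed interaction
network as a two-column edge list (e.g. Reactome functional interactions
filtered to direct interactions).

Output: a Cytoscape-importable SIF file with the directed edges of every
reported sub-graph, a node-attribute table (log-fold changes, source/sink
flags, impact scores) and a sources/sinks report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .pcombine import clamp_pvalue, normal_score

__all__ = [
    "DgeaTable",
    "GeneStat",
    "parse_dgea",
    "parse_network",
    "write_network",
    "write_node_attributes",
    "write_sources_sinks_report",
    "write_subgraph_network",
]

logger = logging.getLogger(__name__)

# Header signatures for dialect auto-detection (matched case-insensitively).
_DIALECTS = {
    "edgeR": {"p": "pvalue", "lfc": "logfc"},
    "DESeq2": {"p": "pvalue", "lfc": "log2foldchange"},
    "generic": {"p": "p_value", "lfc": "log_fc"},
}
_GENE_COLUMNS = {"gene", "genes", "gene_id", "geneid", "id", "symbol", "row.names"}


@dataclass
class GeneStat:
    """One gene's differential-expression evidence.

    ``p_value`` is stored clamped to ``[1e-15, 1 - 1e-15]``; ``normal_score``
    (the upper-tail quantile ``Phi^{-1}(1 - p)``) is computed lazily and
    cached.  A gene whose p-value could not be parsed is flagged ``missing``
    and is invisible to the sub-graph search.
    """

    gene_id: str
    p_value: float | None
    log_fc: float | None = None
    _normal_score: float | None = field(default=None, repr=False, compare=False)

    @property
    def missing(self) -> bool:
        return self.p_value is None

    @property
    def normal_score(self) -> float:
        if self.p_value is None:
            raise ValueError(f"gene {self.gene_id!r} has no p-value")
        if self._normal_score is None:
            self._normal_score = normal_score(self.p_value)
        return self._normal_score


@dataclass
class DgeaTable:
    """A parsed DGEA result table: one :class:`GeneStat` per gene."""

    records: dict[str, GeneStat]
    source_dialect: str = "generic"

    def __contains__(self, gene_id: str) -> bool:
        rec = self.records.get(gene_id)
        return rec is not None and not rec.missing

    def __len__(self) -> int:
        return len(self.records)

    def p(self, gene_id: str) -> float:
        return self.records[gene_id].p_value

    def score(self, gene_id: str) -> float:
        return self.records[gene_id].normal_score

    def log_fc(self, gene_id: str) -> float | None:
        rec = self.records.get(gene_id)
        return None if rec is None else rec.log_fc

    def scored_genes(self) -> set[str]:
        """Genes with a usable (non-missing) p-value."""
        return {g for g, rec in self.records.items() if not rec.missing}


def _detect_dialect(columns: list[str]) -> str:
    lower = {c.lower() for c in columns}
    if {"p_value", "log_fc"} <= lower:
        return "generic"
    if "log2foldchange" in lower and "pvalue" in lower:
        return "DESeq2"
    if "logfc" in lower and "pvalue" in lower:
        return "edgeR"
    raise ValueError(
        "cannot detect DGEA dialect: no recognised p-value column among "
        f"{columns!r} (expected PValue/logFC, pvalue/log2FoldChange, "
        "or p_value/log_fc)"
    )


def _find_column(columns: list[str], wanted: str) -> str | None:
    for c in columns:
        if c.lower() == wanted:
            return c
    return None


def parse_dgea(path: str | Path, dialect: str = "auto") -> DgeaTable:
    """Read a DGEA result table (edgeR, DESeq2 or generic layout).

    The gene identifier is taken from a ``gene``-like column if present and
    otherwise from the first (index) column, matching how edgeR and DESeq2
    write gene names as row names.  Delimiter is sniffed (TSV or CSV).

    Raises
    ------
    ValueError
        If no p-value column can be identified, or a gene id occurs twice.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    columns = list(df.columns)

    if dialect == "auto":
        dialect = _detect_dialect(columns)
    elif dialect not in _DIALECTS:
        raise ValueError(f"unknown DGEA dialect {dialect!r}")
    p_col = _find_column(columns, _DIALECTS[dialect]["p"])
    lfc_col = _find_column(columns, _DIALECTS[dialect]["lfc"])
    if p_col is None:
        raise ValueError(
            f"DGEA file {path} lacks the p-value column required by the "
            f"{dialect} dialect"
        )

    gene_col = None
    for c in columns:
        if c.lower() in _GENE_COLUMNS:
            gene_col = c
            break
    if gene_col is not None:
        genes = df[gene_col].astype(str)
    else:
        # edgeR/DESeq2 style: gene names in the first, untyped column
        first = columns[0]
        if first.lower() not in {p_col.lower(), (lfc_col or "").lower()}:
            genes = df[first].astype(str)
        else:
            raise ValueError(f"DGEA file {path} has no gene-identifier column")

    records: dict[str, GeneStat] = {}
    n_missing = 0
    for gene, p_raw, lfc_raw in zip(
        genes, df[p_col], df[lfc_col] if lfc_col else [None] * len(df)
    ):
        if gene in records:
            raise ValueError(f"duplicate gene id {gene!r} in DGEA file {path}")
        p_num = pd.to_numeric(pd.Series([p_raw]), errors="coerce").iloc[0]
        if pd.isna(p_num):
            n_missing += 1
            p_val = None
        else:
            p_val = clamp_pvalue(float(p_num))
        lfc_num = pd.to_numeric(pd.Series([lfc_raw]), errors="coerce").iloc[0]
        lfc = None if pd.isna(lfc_num) else float(lfc_num)
        records[gene] = GeneStat(gene_id=gene, p_value=p_val, log_fc=lfc)
    if n_missing:
        logger.warning(
            "%d of %d genes in %s have unparseable p-values and are "
            "excluded from scoring",
            n_missing,
            len(records),
            path,
        )
    return DgeaTable(records=records, source_dialect=dialect)


def parse_network(path: str | Path) -> nx.DiGraph:
    """Read a directed interaction network from a 2+ column edge list.

    Lines are whitespace- or tab-separated ``from  to  [ignored...]``; blank
    lines and ``#`` comments are skipped.  Self-loops are dropped (counted in
    a warning) and duplicate edges collapsed.

    Raises
    ------
    ValueError
        On a data line with fewer than two fields (reported with its line
        number).
    """
    path = Path(path)
    graph = nx.DiGraph()
    n_self_loops = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected at least two fields, "
                    f"got {line!r}"
                )
            u, v = fields[0], fields[1]
            if u == v:
                n_self_loops += 1
                graph.add_node(u)
                continue
            graph.add_edge(u, v)
    if n_self_loops:
        logger.warning("dropped %d self-loop(s) from %s", n_self_loops, path)
    if graph.number_of_nodes() == 0:
        logger.warning("network file %s is empty; search will find nothing", path)
    return graph


def write_network(graph: nx.DiGraph, path: str | Path) -> None:
    """Write a directed network as a 2-column TSV edge list.

    Isolated nodes are emitted as single-field comment-free lines would be
    unparseable, so they are recorded as self-documenting ``# node`` comments
    (the parser skips them; edge structure round-trips exactly).
    """
    path = Path(path)
    with open(path, "w") as fh:
        for u, v in sorted(graph.edges()):
            fh.write(f"{u}\t{v}\n")
        for node in sorted(n for n in graph.nodes() if graph.degree(n) == 0):
            fh.write(f"# isolated node: {node}\n")


def write_subgraph_network(subgraphs: Iterable, path: str | Path) -> None:
    """Write the directed edges of all reported sub-graphs in SIF dialect.

    Each sub-graph is preceded by a comment header with its id, size and
    combined p-value; edge lines are ``from<TAB>directed<TAB>to``.
    """
    path = Path(path)
    with open(path, "w") as fh:
        for sg in subgraphs:
            fh.write(
                f"# subgraph {sg.id}\tsize={len(sg.genes)}\t"
                f"combined_p={sg.score.combined_p:.6g}\n"
            )
            for u, v in sorted(sg.induced_edges):
                fh.write(f"{u}\tdirected\t{v}\n")


def _fmt(value, spec: str = "") -> str:
    if value is None:
        return ""
    return format(value, spec) if spec else str(value)


def write_node_attributes(
    subgraphs: Iterable,
    dgea: DgeaTable,
    annotations: Iterable,
    path: str | Path,
) -> None:
    """Write the Cytoscape node-attribute table.

    One row per gene per sub-graph: gene_id, subgraph_id, log_fc, is_source,
    is_sink, impact_score, reliability_p.  Impact and reliability are empty
    for non-sources; log_fc is empty (with a warning) for genes absent from
    the DGEA table.
    """
    path = Path(path)
    by_gene: dict[tuple[str, int], object] = {}
    for ann in annotations:
        by_gene[(ann.gene_id, ann.subgraph_id)] = ann
    with open(path, "w") as fh:
        fh.write(
            "gene_id\tsubgraph_id\tlog_fc\tis_source\tis_sink\t"
            "impact_score\treliability_p\n"
        )
        for sg in subgraphs:
            for gene in sorted(sg.genes):
                lfc = dgea.log_fc(gene)
                if gene not in dgea.records:
                    logger.warning(
                        "gene %s of subgraph %d absent from DGEA table",
                        gene,
                        sg.id,
                    )
                ann = by_gene.get((gene, sg.id))
                is_source = ann is not None and ann.role == "source"
                is_sink = ann is not None and ann.role == "sink"
                impact = ann.impact_score if is_source else None
                rel_p = ann.reliability_p if is_source else None
                fh.write(
                    f"{gene}\t{sg.id}\t{_fmt(lfc, '.6g')}\t"
                    f"{str(is_source).lower()}\t{str(is_sink).lower()}\t"
                    f"{_fmt(impact, '.4f')}\t{_fmt(rel_p, '.6g')}\n"
                )


def write_sources_sinks_report(annotations: Iterable, path: str | Path) -> None:
    """Write the sources/sinks report.

    One row per source (with impact score and reliability test) and one per
    sink; within each sub-graph, sources come first, sorted by descending
    impact score.
    """
    path = Path(path)
    anns = list(annotations)
    by_sg: dict[int, list] = {}
    for ann in anns:
        by_sg.setdefault(ann.subgraph_id, []).append(ann)
    with open(path, "w") as fh:
        fh.write(
            "gene_id\tsubgraph_id\trole\timpact_score\t"
            "reliability_t\treliability_p\n"
        )
        for sg_id in sorted(by_sg):
            rows = by_sg[sg_id]
            sources = [a for a in rows if a.role == "source"]
            sinks = [a for a in rows if a.role == "sink"]
            sources.sort(key=lambda a: (-a.impact_score, a.gene_id))
            sinks.sort(key=lambda a: a.gene_id)
            for a in sources + sinks:
                fh.write(
                    f"{a.gene_id}\t{a.subgraph_id}\t{a.role}\t"
                    f"{_fmt(a.impact_score, '.4f')}\t"
                    f"{_fmt(a.reliability_t, '.6g')}\t"
                    f"{_fmt(a.reliability_p, '.6g')}\n"
                )
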