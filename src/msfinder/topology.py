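"""Sources, sinks, impact scores and source reliability of sub-graphs.

Within a reported sub-graph's directed induced edges, a *source* is a member
with no incoming edges (and at least one outgoing) — a candidate entry point
of the perturbation — and a *sink* has no outgoing edges (and at least one
incoming).  Directed cycles may leave a sub-graph without either.

Each source gets an *impact score*: the percentage of the sub-graph's other
genes reachable from it along directed induced edges — an upper bound on how
much of the sub-graph's modulation the source could have triggered.

Source *reliability* is a Welch two-sample t-test on natural-log-transformed
p-values of the genes immediately downstream of the source (inside the
sub-graph) versus those immediately upstream of it in the global network
(necessarily outside the sub-graph, since a source has no internal in-edges).
A significant difference supports the source marking a boundary between two
regulation regimes.  The t statistic is invariant to the logarithm base.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
from scipy import stats

from .io_formats import DgeaTable
from .search import ModulatedSubgraph

__all__ = [
    "SourceAnnotation",
    "annotate_subgraphs",
    "find_sources_sinks",
    "impact_score",
    "source_reliability",
]


@dataclass(frozen=True)
class SourceAnnotation:
    """A source or sink of one sub-graph.

    ``impact_score`` (percent), ``reliability_t``/``reliability_p`` and the
    group sizes ``n_down``/``n_up`` are populated for sources only;
    reliability fields stay ``None`` when either t-test group has fewer
    than two members (flagged, never raised).
    """

    gene_id: str
    subgraph_id: int
    role: str  # "source" | "sink"
    impact_score: float | None = None
    reliability_t: float | None = None
    reliability_p: float | None = None
    n_down: int = 0
    n_up: int = 0


def _induced_digraph(sg: ModulatedSubgraph) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(sg.genes)
    g.add_edges_from(sg.induced_edges)
    return g


def find_sources_sinks(sg: ModulatedSubgraph) -> list[SourceAnnotation]:
    """Sources (in-degree 0, out-degree >= 1) and sinks (out-degree 0,
    in-degree >= 1) within the sub-graph's induced edges.  Bare role
    annotations; see :func:`annotate_subgraphs` for scored ones."""
    g = _induced_digraph(sg)
    out = []
    for gene in sorted(sg.genes):
        indeg, outdeg = g.in_degree(gene), g.out_degree(gene)
        if indeg == 0 and outdeg >= 1:
            out.append(SourceAnnotation(gene, sg.id, "source"))
        elif outdeg == 0 and indeg >= 1:
            out.append(SourceAnnotation(gene, sg.id, "sink"))
    return out


def impact_score(
    source: str, sg: ModulatedSubgraph, mode: str = "reachable"
) -> float:
    """Impact of a source: percent of the sub-graph's other genes downstream.

    ``mode="reachable"`` (default) counts the full directed reachable set;
    ``mode="immediate"`` counts only direct out-neighbours.  Requires
    ``|genes| > 1``.  Downstream sets of distinct sources may overlap; no
    normalisation is applied across sources.
    """
    g = _induced_digraph(sg)
    if g.in_degree(source) != 0 or g.out_degree(source) == 0:
        raise ValueError(f"gene {source!r} is not a source of subgraph {sg.id}")
    if len(sg.genes) < 2:
        raise ValueError("impact score undefined for singleton sub-graphs")
    if mode == "reachable":
        n_down = len(nx.descendants(g, source))
    elif mode == "immediate":
        n_down = g.out_degree(source)
    else:
        raise ValueError(f"unknown impact mode {mode!r}")
    return 100.0 * n_down / (len(sg.genes) - 1)


def source_reliability(
    source: str,
    sg: ModulatedSubgraph,
    network: nx.DiGraph,
    dgea: DgeaTable,
) -> tuple[float | None, float | None, int, int]:
    """Welch t-test contrasting ln(p) downstream vs upstream of a source.

    Downstream group: immediate out-neighbours of the source within the
    sub-graph's induced edges.  Upstream group: immediate in-neighbours of
    the source in the global network that carry a DGEA p-value.  Returns
    ``(t, two_sided_p, n_down, n_up)``; ``(None, None, ...)`` when either
    group has fewer than two usable members.
    """
    g = _induced_digraph(sg)
    down_genes = [v for v in g.successors(source) if v in dgea]
    up_genes = (
        [u for u in network.predecessors(source) if u in dgea]
        if source in network
        else []
    )
    n_down, n_up = len(down_genes), len(up_genes)
    if n_down < 2 or n_up < 2:
        return None, None, n_down, n_up
    down = [math.log(dgea.p(v)) for v in down_genes]
    up = [math.log(dgea.p(u)) for u in up_genes]
    t, p = stats.ttest_ind(down, up, equal_var=False)
    return float(t), float(p), n_down, n_up


def annotate_subgraphs(
    subgraphs: list[ModulatedSubgraph],
    network: nx.DiGraph,
    dgea: DgeaTable,
    impact: str = "reachable",
) -> list[SourceAnnotation]:
    """Full annotation of all sub-graphs: roles, impacts, reliability."""
    out = []
    for sg in subgraphs:
        g = _induced_digraph(sg)
        for ann in find_sources_sinks(sg):
            if ann.role == "sink":
                out.append(ann)
                continue
            score = impact_score(ann.gene_id, sg, mode=impact)
            t, p, n_down_grp, n_up_grp = source_reliability(
                ann.gene_id, sg, network, dgea
            )
            n_down = (
                len(nx.descendants(g, ann.gene_id))
                if impact == "reachable"
                else g.out_degree(ann.gene_id)
            )
            out.append(
                SourceAnnotation(
                    gene_id=ann.gene_id,
                    subgraph_id=sg.id,
                    role="source",
                    impact_score=score,
                    reliability_t=t,
                    reliability_p=p,
                    n_down=n_down,
                    n_up=n_up_grp,
                )
            )
    return out
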