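"""Synthetic networks and DGEA tables with planted modulated sub-graphs.

The generator emulates, at desk scale, the inputs of the robustness and
cut-off-comparison experiments: a directed interaction network (Erdos-Renyi
or preferential-attachment topology), a connected *planted module* selected
by random walk, signal p-values drawn from Beta(a, 1) with ``a << 1``
(strongly right-skewed towards 0) against a Uniform(0, 1) background, and
log-fold changes Normal(+-2, 1) inside the module versus Normal(0, 1)
outside.  Measurement noise is injected in normal-score space: each gene's
score ``t = Phi^{-1}(1 - p)`` receives independent Normal(0, noise_sd) and
the p-value is re-derived — a minimal stand-in for count-level noise routed
through a DGEA, exercising the search's sensitivity to p-value changes
across the whole range.

Everything is reproducible from an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
from scipy.stats import norm

from .io_formats import DgeaTable, GeneStat, write_network
from .pcombine import clamp_pvalue
from .search import ModulatedSubgraph

__all__ = [
    "PlantedInstance",
    "generate_instance",
    "perturb_pvalues",
    "recall",
    "threshold_baseline",
    "write_instance",
]


@dataclass
class PlantedInstance:
    """A synthetic benchmark instance with known ground truth."""

    network: nx.DiGraph
    dgea: DgeaTable
    planted_genes: frozenset[str]
    params: dict


def _random_walk_module(
    graph: nx.DiGraph, module_size: int, rng: np.random.Generator
) -> frozenset[str] | None:
    """Select a connected module by undirected random walk; None if stuck."""
    und = graph.to_undirected(as_view=True)
    nodes = sorted(graph.nodes())
    start = nodes[rng.integers(len(nodes))]
    visited = {start}
    current = start
    for _ in range(50 * module_size):
        if len(visited) >= module_size:
            return frozenset(visited)
        nbrs = sorted(und.neighbors(current))
        if not nbrs:
            # restart inside the visited set to escape dead ends
            current = sorted(visited)[rng.integers(len(visited))]
            continue
        current = nbrs[rng.integers(len(nbrs))]
        visited.add(current)
    return frozenset(visited) if len(visited) >= module_size else None


def generate_instance(
    n_nodes: int = 500,
    topology: str = "erdos_renyi",
    module_size: int = 40,
    signal_beta_a: float = 0.1,
    rng_seed: int = 0,
    mean_degree: float = 3.0,
) -> PlantedInstance:
    """Generate a directed network with one planted modulated module.

    Parameters
    ----------
    n_nodes : int
        Number of genes/nodes.
    topology : str
        ``"erdos_renyi"`` (directed G(n, p) with expected out-degree
        ``mean_degree``) or ``"preferential"`` (Barabasi-Albert skeleton
        with random edge orientation).
    module_size : int
        Number of planted genes; must be smaller than ``n_nodes``.
    signal_beta_a : float
        Beta(a, 1) shape of planted p-values; ``a=1`` is the uniform null
        (no signal), smaller ``a`` means stronger signal (mean a/(a+1)).
    rng_seed : int
        Seed for full reproducibility.
    mean_degree : float
        Expected out-degree (Erdos-Renyi) or attachment count
        (preferential).
    """
    if not 0 < signal_beta_a <= 1:
        raise ValueError("signal_beta_a must lie in (0, 1]")
    if module_size >= n_nodes:
        raise ValueError("module_size must be smaller than n_nodes")
    rng = np.random.default_rng(rng_seed)
    width = len(str(n_nodes))
    names = {i: f"g{i + 1:0{width}d}" for i in range(n_nodes)}

    if topology == "erdos_renyi":
        p_edge = min(mean_degree / (n_nodes - 1), 1.0)
        skeleton = nx.fast_gnp_random_graph(
            n_nodes, p_edge, seed=int(rng.integers(2**31)), directed=True
        )
        graph = nx.relabel_nodes(nx.DiGraph(skeleton), names)
    elif topology == "preferential":
        m = max(1, round(mean_degree))
        und = nx.barabasi_albert_graph(
            n_nodes, m, seed=int(rng.integers(2**31))
        )
        graph = nx.DiGraph()
        graph.add_nodes_from(names[i] for i in range(n_nodes))
        for u, v in und.edges():
            if rng.random() < 0.5:
                u, v = v, u
            graph.add_edge(names[u], names[v])
    else:
        raise ValueError(f"unknown topology {topology!r}")
    graph.remove_edges_from(nx.selfloop_edges(graph))

    planted = None
    for _ in range(100):
        planted = _random_walk_module(graph, module_size, rng)
        if planted is not None:
            break
    if planted is None:
        raise RuntimeError(
            "could not embed a connected module; the network is too sparse"
        )

    records = {}
    for i in range(n_nodes):
        gene = names[i]
        if gene in planted:
            p = float(rng.beta(signal_beta_a, 1.0))
            lfc = float(rng.normal(2.0 * rng.choice([-1.0, 1.0]), 1.0))
        else:
            p = float(rng.uniform())
            lfc = float(rng.normal(0.0, 1.0))
        records[gene] = GeneStat(gene, clamp_pvalue(p), lfc)
    dgea = DgeaTable(records=records, source_dialect="generic")
    return PlantedInstance(
        network=graph,
        dgea=dgea,
        planted_genes=planted,
        params={
            "n_nodes": n_nodes,
            "topology": topology,
            "module_size": module_size,
            "signal_beta_a": signal_beta_a,
            "rng_seed": rng_seed,
            "mean_degree": mean_degree,
        },
    )


def perturb_pvalues(
    instance: PlantedInstance, noise_sd: float, rng_seed: int = 0
) -> PlantedInstance:
    """Add Normal(0, noise_sd) noise to every gene's normal score and
    re-derive the p-values; ``noise_sd=0`` is the identity."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(rng_seed)
    records = {}
    for gene in sorted(instance.dgea.records):
        rec = instance.dgea.records[gene]
        if rec.missing:
            records[gene] = GeneStat(gene, None, rec.log_fc)
            continue
        if noise_sd == 0:
            p = rec.p_value
        else:
            t = rec.normal_score + rng.normal(0.0, noise_sd)
            p = clamp_pvalue(float(norm.sf(t)))
        records[gene] = GeneStat(gene, p, rec.log_fc)
    return PlantedInstance(
        network=instance.network,
        dgea=DgeaTable(records=records, source_dialect="generic"),
        planted_genes=instance.planted_genes,
        params={**instance.params, "noise_sd": noise_sd, "noise_seed": rng_seed},
    )


def recall(
    detected: list[ModulatedSubgraph], planted_genes: frozenset[str]
) -> float:
    """Fraction of planted genes covered by the union of detected genes."""
    if not planted_genes:
        raise ValueError("planted gene set must be non-empty")
    covered = set()
    for sg in detected:
        covered.update(sg.genes)
    return len(covered & set(planted_genes)) / len(planted_genes)


def threshold_baseline(
    network: nx.DiGraph, dgea: DgeaTable, alpha: float
) -> list[set[str]]:
    """The cut-off comparator: keep genes with p <= alpha and return the
    connected components (singletons included) of the induced undirected
    sub-network."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    keep = {
        g
        for g in network.nodes()
        if g in dgea and dgea.p(g) <= alpha
    }
    sub = network.subgraph(keep).to_undirected()
    return [set(c) for c in nx.connected_components(sub)]


def write_instance(
    instance: PlantedInstance, dgea_path: str | Path, network_path: str | Path
) -> None:
    """Write the instance in the file formats the parsers read
    (generic DGEA TSV + 2-column edge list)."""
    dgea_path = Path(dgea_path)
    with open(dgea_path, "w") as fh:
        fh.write("gene\tp_value\tlog_fc\n")
        for gene in sorted(instance.dgea.records):
            rec = instance.dgea.records[gene]
            p = "NA" if rec.missing else f"{rec.p_value:.17g}"
            lfc = "NA" if rec.log_fc is None else f"{rec.log_fc:.17g}"
            fh.write(f"{gene}\t{p}\t{lfc}\n")
    write_network(instance.network, network_path)
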