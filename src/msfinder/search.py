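"""Seed-extend-merge search for modulated sub-graphs.

The heuristic mirrors a four-step strategy:

1. *Initialize*: seed a sub-graph at the unassigned gene with the smallest
   p-value, then greedily add immediate (undirected) neighbours while the
   combined p-value of the sub-graph strictly improves; repeat with the
   remaining genes while a seed at or below ``seed_alpha`` exists.
2. *Extend*: try to add whole simple paths of up to ``max_extension_len``
   unassigned genes anchored at member nodes — this bridges small gaps of
   genes without a clear individual signal.
3. *Merge*: join pairs of sub-graphs through connectors of up to
   ``max_connector_len`` unassigned genes when the merged sub-graph scores
   strictly better than both parents.
4. *Finalize*: filter by size and significance, renumber by ascending
   combined p-value, and compute the directed induced edge sets.

Membership decisions use undirected adjacency (statistical evidence of
co-regulation has no direction); edge directions are preserved for the
topology annotation.

Scoring.  Candidates are compared on the weighted inverse-normal statistic
of :mod:`msfinder.pcombine` evaluated at a *fixed* score correlation
``score_rho`` (default 0, the equal-weight Stouffer special case of the same
formula).  The moment estimator of rho is deliberately not re-estimated per
candidate: for heterogeneous score sets it collapses to its lower clamp
``-1/(n-1)``, where the statistic's denominator vanishes and the score is
undefined (and explosive just inside the clamp), which would let arbitrary
noise genes masquerade as overwhelming signal.  ``score_rho="estimate"``
restores per-candidate estimation for users who want it.

All orderings are deterministic (sort keys on p-values then gene ids); runs
are reproducible bit for bit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import networkx as nx

from .io_formats import DgeaTable
from .pcombine import CombinedScore

__all__ = [
    "ModulatedSubgraph",
    "SearchConfig",
    "extend_subgraphs",
    "finalize",
    "find_modulated_subgraphs",
    "initialize_subgraphs",
    "merge_subgraphs",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SearchConfig:
    """Tunables of the sub-graph search.

    Parameters
    ----------
    max_extension_len : int
        Maximum number of intermediate genes in an extension path (1-3,
        default 2).
    max_connector_len : int
        Maximum number of bridging genes in a merge connector (0-3,
        default 2; 0 still allows merges across a direct edge).
    report_min_size : int
        Smallest sub-graph size reported (default 2).
    report_alpha : float
        Largest combined p-value reported (default 0.05).
    seed_alpha : float
        Largest individual p-value eligible to seed a new sub-graph
        (default 0.05).
    neighbor_rule : str
        ``"first"`` accepts the first improving neighbour in (p, gene)
        order during initialization; ``"best"`` scans all neighbours and
        takes the one with the best improved score.
    score_rho : float or "estimate"
        Score correlation at which candidates are evaluated (default 0).
    """

    max_extension_len: int = 2
    max_connector_len: int = 2
    report_min_size: int = 2
    report_alpha: float = 0.05
    seed_alpha: float = 0.05
    neighbor_rule: str = "first"
    score_rho: float | str = 0.0

    def __post_init__(self):
        if not 1 <= self.max_extension_len <= 3:
            raise ValueError("max_extension_len must be in {1, 2, 3}")
        if not 0 <= self.max_connector_len <= 3:
            raise ValueError("max_connector_len must be in {0, 1, 2, 3}")
        if self.report_min_size < 1:
            raise ValueError("report_min_size must be >= 1")
        for name in ("report_alpha", "seed_alpha"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.neighbor_rule not in ("first", "best"):
            raise ValueError("neighbor_rule must be 'first' or 'best'")
        if self.score_rho != "estimate":
            r = float(self.score_rho)
            if not -1.0 < r < 1.0:
                raise ValueError("fixed score_rho must lie in (-1, 1)")


@dataclass(frozen=True)
class ModulatedSubgraph:
    """A reported sub-graph: a connected gene set with its joint score."""

    id: int
    genes: tuple[str, ...]
    induced_edges: frozenset[tuple[str, str]]
    score: CombinedScore


class _Scorer:
    """Incremental combined-statistic evaluation over gene sets.

    With equal unit weights the statistic only needs the sum ``S`` and the
    sum of squares ``Q`` of the member normal scores; both update in O(1)
    per added gene.  The combined p-value is the upper normal tail of the
    statistic; comparisons are made on the statistic itself (monotone in
    the p-value, immune to deep-tail underflow).
    """

    def __init__(self, dgea: DgeaTable, cfg: SearchConfig):
        self.t = {g: dgea.score(g) for g in dgea.scored_genes()}
        self.p = {g: dgea.p(g) for g in dgea.scored_genes()}
        self.rho = cfg.score_rho

    def stat(self, n: int, S: float, Q: float) -> float | None:
        """Statistic of a gene set from its score moments; None if the
        denominator is degenerate (possible only with estimated rho)."""
        if n == 1:
            return S
        if self.rho == "estimate":
            var = (Q - S * S / n) / (n - 1)
            rho = min(max(1.0 - var, -1.0 / (n - 1)), 1.0)
        else:
            rho = self.rho
        denom_sq = n * (1.0 + rho * (n - 1))
        if denom_sq <= 1e-12:
            return None
        return S / math.sqrt(denom_sq)

    def stat_of(self, genes) -> float | None:
        S = sum(self.t[g] for g in genes)
        Q = sum(self.t[g] * self.t[g] for g in genes)
        return self.stat(len(genes), S, Q)

    def rho_used(self, genes) -> float:
        if len(genes) == 1:
            return 0.0
        if self.rho == "estimate":
            S = sum(self.t[g] for g in genes)
            Q = sum(self.t[g] * self.t[g] for g in genes)
            n = len(genes)
            var = (Q - S * S / n) / (n - 1)
            return min(max(1.0 - var, -1.0 / (n - 1)), 1.0)
        return float(self.rho)


def _sf(x: float) -> float:
    """Standard normal upper tail, fast scalar path."""
    return 0.5 * math.erfc(x / math.sqrt(2.0))


@dataclass
class _Work:
    """Mutable sub-graph under construction."""

    genes: set[str]
    S: float
    Q: float
    stat: float

    @property
    def key(self) -> tuple:
        return (-self.stat, tuple(sorted(self.genes)))

    def add(self, genes, scorer: _Scorer, stat: float) -> None:
        for g in genes:
            t = scorer.t[g]
            self.genes.add(g)
            self.S += t
            self.Q += t * t
        self.stat = stat

    def trial_stat(self, genes, scorer: _Scorer) -> float | None:
        S, Q = self.S, self.Q
        for g in genes:
            t = scorer.t[g]
            S += t
            Q += t * t
        return scorer.stat(len(self.genes) + len(genes), S, Q)


def _undirected_adjacency(network: nx.DiGraph, genes: set[str]) -> dict:
    """Sorted undirected neighbour lists restricted to scored genes."""
    adj = {}
    for g in genes:
        if g not in network:
            continue
        nbrs = (set(network.predecessors(g)) | set(network.successors(g))) & genes
        nbrs.discard(g)
        adj[g] = sorted(nbrs)
    return adj


class _State:
    """Shared search state across the four steps."""

    def __init__(self, network: nx.DiGraph, dgea: DgeaTable, cfg: SearchConfig):
        self.network = network
        self.dgea = dgea
        self.cfg = cfg
        self.scorer = _Scorer(dgea, cfg)
        self.scored = dgea.scored_genes() & set(network.nodes())
        self.adj = _undirected_adjacency(network, self.scored)

    def work_from(self, sg_genes) -> _Work:
        genes = set(sg_genes)
        S = sum(self.scorer.t[g] for g in genes)
        Q = sum(self.scorer.t[g] ** 2 for g in genes)
        stat = self.scorer.stat(len(genes), S, Q)
        if stat is None:
            raise ValueError("sub-graph has a degenerate combined score")
        return _Work(genes=genes, S=S, Q=Q, stat=stat)


def _export(works: list[_Work], state: _State) -> list[ModulatedSubgraph]:
    """Freeze working sub-graphs (ids provisional, no induced edges yet)."""
    out = []
    for i, w in enumerate(sorted(works, key=lambda w: w.key), start=1):
        genes = tuple(sorted(w.genes))
        combined_p = (
            state.dgea.p(genes[0]) if len(genes) == 1 else _sf(w.stat)
        )
        score = CombinedScore(
            statistic=w.stat,
            rho_hat=state.scorer.rho_used(genes),
            combined_p=combined_p,
            n=len(genes),
            weights=tuple([1.0] * len(genes)),
        )
        out.append(
            ModulatedSubgraph(
                id=i, genes=genes, induced_edges=frozenset(), score=score
            )
        )
    return out


def _grow(work: _Work, unassigned: set[str], state: _State) -> None:
    """Greedy neighbour additions while the score strictly improves."""
    scorer, adj, p = state.scorer, state.adj, state.scorer.p
    while True:
        frontier = set()
        for g in work.genes:
            frontier.update(adj.get(g, ()))
        frontier &= unassigned
        frontier -= work.genes
        if not frontier:
            return
        candidates = sorted(frontier, key=lambda g: (p[g], g))
        best_gene, best_stat = None, work.stat
        for g in candidates:
            cand = work.trial_stat((g,), scorer)
            if cand is not None and cand > best_stat:
                best_gene, best_stat = g, cand
                if state.cfg.neighbor_rule == "first":
                    break
        if best_gene is None:
            return
        work.add((best_gene,), scorer, best_stat)
        unassigned.discard(best_gene)


def initialize_subgraphs(
    network: nx.DiGraph, dgea: DgeaTable, cfg: SearchConfig | None = None
) -> list[ModulatedSubgraph]:
    """Step 1: seed and greedily grow sub-graphs from significant genes."""
    cfg = cfg or SearchConfig()
    state = _State(network, dgea, cfg)
    works = _initialize(state)
    return _export(works, state)


def _initialize(state: _State) -> list[_Work]:
    if not state.scored:
        logger.warning("network and DGEA table share no scored genes")
        return []
    cfg, p = state.cfg, state.scorer.p
    unassigned = set(state.scored)
    works: list[_Work] = []
    while True:
        seeds = [g for g in unassigned if p[g] <= cfg.seed_alpha]
        if not seeds:
            break
        seed = min(seeds, key=lambda g: (p[g], g))
        work = state.work_from([seed])
        unassigned.discard(seed)
        _grow(work, unassigned, state)
        works.append(work)
    logger.info("initialization: %d sub-graph(s)", len(works))
    return works


def _candidate_paths(work: _Work, unassigned: set[str], state: _State):
    """All simple paths of 1..max_extension_len unassigned genes anchored
    at member nodes, deduplicated by gene set (keeping the lexicographically
    smallest sequence)."""
    adj, max_len = state.adj, state.cfg.max_extension_len
    found: dict[frozenset, tuple] = {}

    def record(path: tuple) -> None:
        key = frozenset(path)
        prev = found.get(key)
        if prev is None or path < prev:
            found[key] = path

    def dfs(path: list) -> None:
        record(tuple(path))
        if len(path) >= max_len:
            return
        for nxt in adj.get(path[-1], ()):
            if nxt in unassigned and nxt not in path:
                path.append(nxt)
                dfs(path)
                path.pop()

    anchors = set()
    for m in work.genes:
        anchors.update(adj.get(m, ()))
    for start in sorted(anchors & unassigned):
        dfs([start])
    return list(found.values())


def extend_subgraphs(
    subgraphs: list[ModulatedSubgraph],
    network: nx.DiGraph,
    dgea: DgeaTable,
    cfg: SearchConfig | None = None,
) -> list[ModulatedSubgraph]:
    """Step 2: bridge small gaps by adding whole paths of unassigned genes."""
    cfg = cfg or SearchConfig()
    state = _State(network, dgea, cfg)
    works = [state.work_from(sg.genes) for sg in subgraphs]
    _extend(works, state)
    return _export(works, state)


def _extend(works: list[_Work], state: _State) -> None:
    scorer = state.scorer
    assigned = set().union(*(w.genes for w in works)) if works else set()
    unassigned = state.scored - assigned
    n_added = 0
    changed = True
    while changed:
        changed = False
        for work in sorted(works, key=lambda w: w.key):
            while True:
                accepted = False
                paths = _candidate_paths(work, unassigned, state)
                scored_paths = []
                for path in paths:
                    own = scorer.stat_of(path)
                    if own is None:
                        continue
                    own_p = (
                        scorer.p[path[0]] if len(path) == 1 else _sf(own)
                    )
                    scored_paths.append((own_p, path))
                scored_paths.sort(key=lambda item: (item[0], item[1]))
                for _, path in scored_paths:
                    cand = work.trial_stat(path, scorer)
                    if cand is not None and cand > work.stat:
                        work.add(path, scorer, cand)
                        unassigned.difference_update(path)
                        n_added += len(path)
                        accepted = True
                        changed = True
                        break
                if not accepted:
                    break
    logger.info("extension: %d gene(s) added via gap-bridging paths", n_added)


def _connectors(a: _Work, b: _Work, unassigned: set[str], state: _State):
    """All connector paths of 0..max_connector_len unassigned genes joining
    a member of ``a`` to a member of ``b`` (undirected view)."""
    adj, max_len = state.adj, state.cfg.max_connector_len
    found: dict[frozenset, tuple] = {}

    def touches_b(gene: str) -> bool:
        return any(nb in b.genes for nb in adj.get(gene, ()))

    if any(touches_b(g) for g in a.genes):
        found[frozenset()] = ()

    def record(path: tuple) -> None:
        key = frozenset(path)
        prev = found.get(key)
        if prev is None or (len(path), path) < (len(prev), prev):
            found[key] = path

    def dfs(path: list) -> None:
        if touches_b(path[-1]):
            record(tuple(path))
        if len(path) >= max_len:
            return
        for nxt in adj.get(path[-1], ()):
            if nxt in unassigned and nxt not in path:
                path.append(nxt)
                dfs(path)
                path.pop()

    starts = set()
    for g in a.genes:
        starts.update(adj.get(g, ()))
    for start in sorted(starts & unassigned):
        dfs([start])
    return list(found.values())


def merge_subgraphs(
    subgraphs: list[ModulatedSubgraph],
    network: nx.DiGraph,
    dgea: DgeaTable,
    cfg: SearchConfig | None = None,
) -> list[ModulatedSubgraph]:
    """Step 3: merge sub-graph pairs through short connectors when the
    merged score strictly beats both parents."""
    cfg = cfg or SearchConfig()
    state = _State(network, dgea, cfg)
    works = [state.work_from(sg.genes) for sg in subgraphs]
    _merge(works, state)
    return _export(works, state)


def _merge(works: list[_Work], state: _State) -> None:
    scorer = state.scorer
    n_merges = 0
    while True:
        assigned = set().union(*(w.genes for w in works)) if works else set()
        unassigned = state.scored - assigned
        # pairs in ascending order of the better parent's p (higher stat)
        order = sorted(range(len(works)), key=lambda i: works[i].key)
        merged = False
        for ii in range(len(order)):
            for jj in range(ii + 1, len(order)):
                a, b = works[order[ii]], works[order[jj]]
                best = None  # (-stat, len(path), path)
                for path in _connectors(a, b, unassigned, state):
                    union = a.genes | b.genes | set(path)
                    cand = scorer.stat_of(union)
                    if cand is None:
                        continue
                    key = (-cand, len(path), path)
                    if best is None or key < best[0]:
                        best = (key, cand, path)
                if best is None:
                    continue
                _, stat, path = best
                if stat > a.stat and stat > b.stat:
                    new = _Work(genes=set(), S=0.0, Q=0.0, stat=0.0)
                    new.add(a.genes | b.genes | set(path), scorer, stat)
                    works[:] = [
                        w for w in works if w is not a and w is not b
                    ] + [new]
                    n_merges += 1
                    merged = True
                    break
            if merged:
                break
        if not merged:
            break
    logger.info("merging: %d merge(s) accepted", n_merges)


def finalize(
    subgraphs: list[ModulatedSubgraph],
    network: nx.DiGraph,
    cfg: SearchConfig | None = None,
) -> list[ModulatedSubgraph]:
    """Step 4 (reporting): filter by size and significance, renumber by
    ascending combined p-value, attach directed induced edge sets."""
    cfg = cfg or SearchConfig()
    kept = [
        sg
        for sg in subgraphs
        if len(sg.genes) >= cfg.report_min_size
        and sg.score.combined_p <= cfg.report_alpha
    ]
    kept.sort(key=lambda sg: (sg.score.combined_p, sg.genes))
    out = []
    for i, sg in enumerate(kept, start=1):
        members = set(sg.genes)
        edges = frozenset(
            (u, v)
            for u, v in network.edges(members)
            if u in members and v in members
        )
        out.append(replace(sg, id=i, induced_edges=edges))
    return out


def find_modulated_subgraphs(
    network: nx.DiGraph,
    dgea: DgeaTable,
    cfg: SearchConfig | None = None,
) -> list[ModulatedSubgraph]:
    """Run the full four-step search and return the reported sub-graphs."""
    cfg = cfg or SearchConfig()
    state = _State(network, dgea, cfg)
    works = _initialize(state)
    _extend(works, state)
    _merge(works, state)
    return finalize(_export(works, state), network, cfg)
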