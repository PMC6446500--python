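import networkx as nx
import pytest

from msfinder.io_formats import DgeaTable, GeneStat
from msfinder.pcombine import CombinedScore, clamp_pvalue
from msfinder.search import ModulatedSubgraph


def make_table(pvalues: dict, log_fc: dict | None = None) -> DgeaTable:
    """Build a DgeaTable directly from {gene: p}."""
    log_fc = log_fc or {}
    return DgeaTable(
        {
            g: GeneStat(g, clamp_pvalue(p), log_fc.get(g))
            for g, p in pvalues.items()
        }
    )


def make_subgraph(genes, edges=(), sg_id=1) -> ModulatedSubgraph:
    """Build a ModulatedSubgraph shell (score placeholder) for unit tests."""
    return ModulatedSubgraph(
        id=sg_id,
        genes=tuple(sorted(genes)),
        induced_edges=frozenset(edges),
        score=CombinedScore(0.0, 0.0, 1.0, len(genes), ()),
    )


@pytest.fixture
def chain_instance():
    """The worked gap-bridging chain: a(.001)-b(.002)-x(.6)-c(.0005)."""
    network = nx.DiGraph([("a", "b"), ("b", "x"), ("x", "c")])
    dgea = make_table({"a": 0.001, "b": 0.002, "x": 0.6, "c": 0.0005})
    return network, dgea
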