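"""Unit and property tests for the seed-extend-merge search."""

import math

import networkx as nx
import pytest
from scipy.stats import norm

from msfinder.search import (
    SearchConfig,
    extend_subgraphs,
    finalize,
    find_modulated_subgraphs,
    initialize_subgraphs,
    merge_subgraphs,
)
from msfinder.simulate import generate_instance

from conftest import make_subgraph, make_table


def stouffer_p(pvalues):
    """Independent closed-form oracle for the default (rho=0) sub-graph
    score: upper tail of sum(Phi^{-1}(1-p)) / sqrt(n)."""
    scores = [float(norm.isf(p)) for p in pvalues]
    return float(norm.sf(sum(scores) / math.sqrt(len(scores))))


class TestSearchConfig:
    @pytest.mark.parametrize(
        "kw",
        [
            {"max_extension_len": 0},
            {"max_extension_len": 4},
            {"max_connector_len": 5},
            {"report_min_size": 0},
            {"report_alpha": 0.0},
            {"seed_alpha": 1.5},
            {"neighbor_rule": "random"},
            {"score_rho": 1.0},
        ],
    )
    def test_invalid_rejected(self, kw):
        with pytest.raises(ValueError):
            SearchConfig(**kw)


class TestInitialize:
    def test_chain_grows_then_stops(self):
        net = nx.DiGraph([("a", "b"), ("b", "c")])
        dgea = make_table({"a": 0.001, "b": 0.002, "c": 0.9})
        out = initialize_subgraphs(net, dgea, SearchConfig())
        assert [sg.genes for sg in out] == [("a", "b")]
        # {a,b} beats {a} alone and {a,b,c} would be worse (oracle check)
        assert out[0].score.combined_p == pytest.approx(
            stouffer_p([0.001, 0.002]), rel=1e-9
        )
        assert stouffer_p([0.001, 0.002, 0.9]) > out[0].score.combined_p

    def test_isolated_significant_gene_is_singleton(self):
        net = nx.DiGraph()
        net.add_node("g")
        dgea = make_table({"g": 0.01})
        out = initialize_subgraphs(net, dgea, SearchConfig())
        assert [sg.genes for sg in out] == [("g",)]
        assert out[0].score.combined_p == pytest.approx(0.01)

    def test_no_eligible_seed_yields_nothing(self):
        net = nx.DiGraph([("a", "b")])
        dgea = make_table({"a": 0.5, "b": 0.5})
        assert initialize_subgraphs(net, dgea, SearchConfig()) == []

    def test_no_shared_genes_yields_nothing(self):
        net = nx.DiGraph([("x", "y")])
        dgea = make_table({"a": 0.001})
        assert initialize_subgraphs(net, dgea, SearchConfig()) == []

    def test_first_vs_best_neighbor_rule(self):
        # hub seed with two improving neighbours: "first" takes the more
        # significant one first; both rules must still improve the score
        net = nx.DiGraph([("s", "n1"), ("s", "n2")])
        dgea = make_table({"s": 0.01, "n1": 0.04, "n2": 0.05})
        for rule in ("first", "best"):
            out = initialize_subgraphs(
                net, dgea, SearchConfig(neighbor_rule=rule)
            )
            assert out[0].score.combined_p < 0.01


class TestExtend:
    def test_two_gene_bridge_accepted_one_gene_rejected(self, chain_instance):
        network, dgea = chain_instance
        base = make_subgraph(["a", "b"])
        out2 = extend_subgraphs([base], network, dgea,
                                SearchConfig(max_extension_len=2))
        assert [sg.genes for sg in out2] == [("a", "b", "c", "x")]
        out1 = extend_subgraphs([base], network, dgea,
                                SearchConfig(max_extension_len=1))
        assert [sg.genes for sg in out1] == [("a", "b")]
        # oracle: the bridge improves the score, the lone gap gene does not
        assert stouffer_p([0.001, 0.002, 0.6, 0.0005]) < stouffer_p(
            [0.001, 0.002]
        )
        assert stouffer_p([0.001, 0.002, 0.6]) > stouffer_p([0.001, 0.002])

    def test_no_unassigned_neighbors_unchanged(self):
        net = nx.DiGraph([("a", "b")])
        dgea = make_table({"a": 0.01, "b": 0.02})
        base = make_subgraph(["a", "b"])
        out = extend_subgraphs([base], net, dgea, SearchConfig())
        assert [sg.genes for sg in out] == [("a", "b")]

    def test_extension_cannot_touch_other_subgraph(self):
        # x is significant but belongs to another sub-graph: not a candidate
        net = nx.DiGraph([("a", "b"), ("b", "x")])
        dgea = make_table({"a": 0.01, "b": 0.02, "x": 0.001})
        subs = [make_subgraph(["a", "b"]), make_subgraph(["x"], sg_id=2)]
        out = extend_subgraphs(subs, net, dgea, SearchConfig())
        assert sorted(sg.genes for sg in out) == [("a", "b"), ("x",)]


class TestMerge:
    def test_direct_edge_merge(self):
        net = nx.DiGraph([("a", "b"), ("b", "c"), ("c", "d")])
        dgea = make_table({"a": 0.01, "b": 0.02, "c": 0.01, "d": 0.02})
        out = merge_subgraphs(
            [make_subgraph(["a", "b"]), make_subgraph(["c", "d"], sg_id=2)],
            net, dgea, SearchConfig(),
        )
        assert [sg.genes for sg in out] == [("a", "b", "c", "d")]
        # merged beats both parents (oracle)
        assert stouffer_p([0.01, 0.02, 0.01, 0.02]) < stouffer_p([0.01, 0.02])

    def test_connector_bound_respected(self):
        # three intermediates between A and B, bound allows two
        net = nx.DiGraph(
            [("a", "b"), ("b", "m1"), ("m1", "m2"), ("m2", "m3"), ("m3", "c"),
             ("c", "d")]
        )
        dgea = make_table(
            {"a": 0.001, "b": 0.001, "m1": 0.001, "m2": 0.001, "m3": 0.001,
             "c": 0.001, "d": 0.001}
        )
        out = merge_subgraphs(
            [make_subgraph(["a", "b"]), make_subgraph(["c", "d"], sg_id=2)],
            net, dgea, SearchConfig(max_connector_len=2),
        )
        assert len(out) == 2

    def test_merge_must_beat_both_parents(self):
        # union beats the weak pair but not the strong one -> rejected
        net = nx.DiGraph([("a1", "a2"), ("a2", "b1"), ("b1", "b2")])
        dgea = make_table({"a1": 0.04, "a2": 0.05, "b1": 1e-8, "b2": 1e-8})
        a, b = make_subgraph(["a1", "a2"]), make_subgraph(["b1", "b2"], sg_id=2)
        out = merge_subgraphs([a, b], net, dgea, SearchConfig())
        assert len(out) == 2
        union_p = stouffer_p([0.04, 0.05, 1e-8, 1e-8])
        assert union_p < stouffer_p([0.04, 0.05])  # beats the weak parent
        assert union_p > stouffer_p([1e-8, 1e-8])  # ... but not the strong


class TestFinalize:
    def test_filters_and_renumbers(self):
        net = nx.DiGraph([("a", "b"), ("c", "d")])
        dgea = make_table({"a": 1e-4, "b": 1e-4, "c": 0.01, "d": 0.01,
                           "e": 0.01, "f": 0.4, "g": 0.4})
        sub_weak = initialize_subgraphs(
            nx.DiGraph([("f", "g")]), make_table({"f": 0.04, "g": 0.4}),
            SearchConfig(seed_alpha=0.05),
        )
        subs = (
            initialize_subgraphs(net, dgea, SearchConfig())
            + sub_weak
        )
        out = finalize(subs, net, SearchConfig())
        # singleton (e) and weak/singleton candidates dropped; strongest first
        assert all(len(sg.genes) >= 2 for sg in out)
        assert [sg.id for sg in out] == list(range(1, len(out) + 1))
        ps = [sg.score.combined_p for sg in out]
        assert ps == sorted(ps)
        assert out[0].genes == ("a", "b")

    def test_alpha_filter(self):
        sg = make_subgraph(["a", "b"])
        sg = sg.__class__(
            id=1, genes=sg.genes, induced_edges=sg.induced_edges,
            score=sg.score.__class__(0.84, 0.0, 0.2, 2, (1.0, 1.0)),
        )
        assert finalize([sg], nx.DiGraph(), SearchConfig()) == []


class TestPipelineInvariants:
    @pytest.mark.parametrize("seed", range(12))
    def test_disjoint_connected_and_monotone(self, seed):
        inst = generate_instance(
            n_nodes=60, module_size=8, signal_beta_a=0.2, rng_seed=seed
        )
        cfg = SearchConfig()
        init = initialize_subgraphs(inst.network, inst.dgea, cfg)
        ext = extend_subgraphs(init, inst.network, inst.dgea, cfg)
        merged = merge_subgraphs(ext, inst.network, inst.dgea, cfg)
        final = finalize(merged, inst.network, cfg)

        # monotone improvement: best score never degrades across steps
        def best(subs):
            return min((sg.score.combined_p for sg in subs), default=1.0)

        assert best(ext) <= best(init) + 1e-15
        assert best(merged) <= best(ext) + 1e-15
        # step 3 only reduces the sub-graph count
        assert len(merged) <= len(ext)

        seen = set()
        for sg in final:
            # disjointness
            assert not (set(sg.genes) & seen)
            seen.update(sg.genes)
            # connectivity of the undirected induced view
            g = nx.Graph()
            g.add_nodes_from(sg.genes)
            g.add_edges_from(sg.induced_edges)
            assert nx.is_connected(g)
            assert sg.score.n == len(sg.genes)
            assert sg.score.combined_p <= cfg.report_alpha

    def test_end_to_end_determinism(self):
        inst = generate_instance(n_nodes=80, module_size=10, rng_seed=5)
        a = find_modulated_subgraphs(inst.network, inst.dgea)
        b = find_modulated_subgraphs(inst.network, inst.dgea)
        assert a == b
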