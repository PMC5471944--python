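"""Edge weighting and exact K-shortest-path search, against the oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evidencenet.graph import EvidenceEdge, EvidenceGraph, GraphError
from evidencenet.pathfinding import (
    ChannelWeights,
    WeightedView,
    edge_weight,
    effective_score,
    iter_shortest_paths,
    k_shortest_paths,
    shortest_path,
)

from conftest import label_path, oracle_paths, random_graph


def _edge(channels, combined):
    return EvidenceEdge("9606.A", "9606.B", channels, combined)


class TestEffectiveScore:
    def test_default_weights_pass_through_combined(self):
        edge = _edge({"experimental": 0.5, "textmining": 0.4}, 0.921)
        assert effective_score(edge, ChannelWeights()) == 0.921

    def test_noisy_or_with_silenced_channel(self):
        edge = _edge({"experimental": 0.5, "textmining": 0.5}, 0.9)
        weights = ChannelWeights({"textmining": 0.0})
        assert effective_score(edge, weights) == pytest.approx(0.5)

    def test_only_channel_silenced_gives_zero(self):
        edge = _edge({"textmining": 0.9}, 0.9)
        assert effective_score(edge, ChannelWeights({"textmining": 0.0})) == 0.0

    @given(
        m=st.floats(0, 1),
        s1=st.floats(0, 1),
        s2=st.floats(0, 1),
    )
    @settings(deadline=None)
    def test_monotone_in_multiplier(self, m, s1, s2):
        # the "database" multiplier (channel absent from the edge) keeps all
        # three weightings on the noisy-OR branch: all-default weights would
        # switch to the reported combined score, which is deliberately NOT
        # comparable with the recombination (pass-through discontinuity)
        edge = _edge({"experimental": s1, "textmining": s2}, 0.5)

        def score(mult):
            return effective_score(
                edge, ChannelWeights({"textmining": mult, "database": 0.5})
            )

        assert score(0.0) <= score(m) + 1e-12
        assert score(m) <= score(1.0) + 1e-12

    def test_multiplier_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ChannelWeights({"textmining": 1.5})

    def test_preset_parsing(self):
        w = ChannelWeights.from_specs(
            {"textmining": "NONE", "database": "LOW", "experimental": "0.25"}
        )
        assert w.multipliers == {
            "textmining": 0.0,
            "database": 0.5,
            "experimental": 0.25,
        }


class TestEdgeWeight:
    @pytest.mark.parametrize("s,w", [(1.0, 0.0), (0.0, 1.0), (0.7, 0.3)])
    def test_complement(self, s, w):
        assert edge_weight(s) == pytest.approx(w)

    def test_out_of_range(self):
        with pytest.raises(GraphError):
            edge_weight(1.5)


class TestShortestPath:
    def test_toy1_best_path(self, toy, ids):
        path = shortest_path(toy, ids["D"], ids["M"])
        assert label_path(path.nodes) == "DAM"
        assert path.total_weight == pytest.approx(0.3)

    def test_src_equals_dst(self, toy, ids):
        path = shortest_path(toy, ids["D"], ids["D"])
        assert path.nodes == (ids["D"],) and path.total_weight == 0.0

    def test_disconnected_gives_none(self, toy, ids):
        assert shortest_path(toy, ids["D"], ids["C"]) is None

    def test_unknown_node_raises(self, toy, ids):
        with pytest.raises(KeyError):
            shortest_path(toy, "CIDm99999999", ids["M"])

    def test_lexicographic_tie_break(self):
        # two equal-weight two-hop routes: via P1 and via P2
        g = EvidenceGraph()
        for u, v in [
            ("9606.S", "9606.P1"),
            ("9606.P1", "9606.T"),
            ("9606.S", "9606.P2"),
            ("9606.P2", "9606.T"),
        ]:
            g.add_edge(EvidenceEdge(u, v, {"experimental": 0.5}, 0.5))
        path = shortest_path(g, "9606.S", "9606.T")
        assert path.nodes == ("9606.S", "9606.P1", "9606.T")


class TestKShortestPaths:
    def test_toy1_top3(self, toy, ids):
        paths = k_shortest_paths(toy, ids["D"], ids["M"], 3)
        assert [label_path(p.nodes) for p in paths] == ["DAM", "DBM", "DABM"]
        assert [p.total_weight for p in paths] == pytest.approx([0.3, 0.4, 0.7])

    def test_toy1_exhaustive(self, toy, ids):
        paths = k_shortest_paths(toy, ids["D"], ids["M"], 10)
        assert [label_path(p.nodes) for p in paths] == [
            "DAM", "DBM", "DABM", "DM", "DBAM",
        ]
        assert paths[-1].total_weight == pytest.approx(1.0)

    def test_max_intermediates_filters_within_enumeration(self, toy, ids):
        paths = k_shortest_paths(toy, ids["D"], ids["M"], 10, max_intermediates=1)
        assert [label_path(p.nodes) for p in paths] == ["DAM", "DBM", "DM"]

    def test_k1_equals_shortest_path(self, toy, ids):
        [only] = k_shortest_paths(toy, ids["D"], ids["M"], 1)
        assert only == shortest_path(toy, ids["D"], ids["M"])

    def test_oracle_equivalence_sweep(self, rng):
        """Full enumeration matches brute force on 30 random graphs."""
        for _ in range(30):
            g = random_graph(rng, n_proteins=6, n_chemicals=2, density=0.4)
            chems = g.chemical_nodes()
            prots = g.protein_nodes()
            src, dst = chems[0], prots[-1]
            expected = oracle_paths(g, src, dst)
            got = k_shortest_paths(g, src, dst, k=10**6)
            assert [(p.total_weight, p.nodes) for p in got] == expected

    def test_weights_nondecreasing_and_loopless(self, rng):
        g = random_graph(rng, n_proteins=8, density=0.45)
        paths = k_shortest_paths(g, g.chemical_nodes()[0], g.protein_nodes()[0], 50)
        weights = [p.total_weight for p in paths]
        assert weights == sorted(weights)
        for p in paths:
            assert len(set(p.nodes)) == len(p.nodes)

    def test_weight_sequence_matches_networkx_yen(self, rng):
        """Cross-check path weights against networkx's Yen implementation."""
        import networkx as nx

        for _ in range(5):
            g = random_graph(rng, n_proteins=7, density=0.4)
            src, dst = g.chemical_nodes()[0], g.protein_nodes()[-1]
            G = nx.Graph()
            G.add_nodes_from(g.nodes)
            for e in g.edges:
                G.add_edge(e.u, e.v, w=1.0 - e.reported_combined)
            try:
                nx_paths = list(nx.shortest_simple_paths(G, src, dst, weight="w"))
            except nx.NetworkXNoPath:
                nx_paths = []
            nx_weights = sorted(
                sum(G.edges[a, b]["w"] for a, b in zip(p, p[1:]))
                for p in nx_paths
            )
            mine = k_shortest_paths(g, src, dst, 10**6)
            assert [p.total_weight for p in mine] == pytest.approx(
                nx_weights, abs=1e-9
            )

    def test_zero_weight_edges_handled(self):
        # S = 1 edges cost nothing; lexicographic rule decides
        g = EvidenceGraph()
        for u, v in [("9606.S", "9606.A"), ("9606.A", "9606.T"),
                     ("9606.S", "9606.B"), ("9606.B", "9606.T")]:
            g.add_edge(EvidenceEdge(u, v, {"experimental": 1.0}, 1.0))
        paths = k_shortest_paths(g, "9606.S", "9606.T", 5)
        assert [p.nodes[1] for p in paths[:2]] == ["9606.A", "9606.B"]
        assert all(p.total_weight == 0.0 for p in paths[:2])


def _delete_channel(g: EvidenceGraph, channel: str) -> EvidenceGraph:
    stripped = EvidenceGraph()
    for n in g.nodes:
        stripped.add_node(n)
    for e in g.edges:
        kept = {c: s for c, s in e.channel_scores.items() if c != channel}
        stripped.add_edge(EvidenceEdge(e.u, e.v, kept, e.reported_combined))
    return stripped


class TestChannelWeightPathProperties:
    def test_silencing_equals_channel_deletion(self, rng):
        """Multiplier 0 for a channel gives the same paths as deleting it."""
        weights = ChannelWeights({"textmining": 0.0})
        for _ in range(10):
            g = random_graph(rng, n_proteins=6, density=0.45)
            src, dst = g.chemical_nodes()[0], g.protein_nodes()[-1]
            silenced = k_shortest_paths(g, src, dst, 10**6, weights)
            deleted = k_shortest_paths(
                _delete_channel(g, "textmining"), src, dst, 10**6, weights
            )
            assert [(p.total_weight, p.nodes) for p in silenced] == [
                (p.total_weight, p.nodes) for p in deleted
            ]

    def test_silenced_paths_match_oracle(self, rng):
        """Noisy-OR rescoring agrees with the brute-force oracle."""
        weights = ChannelWeights({"textmining": 0.0, "database": 0.5})
        for _ in range(10):
            g = random_graph(rng, n_proteins=6, density=0.45)
            src, dst = g.chemical_nodes()[0], g.protein_nodes()[-1]
            expected = oracle_paths(
                g, src, dst, multipliers={"textmining": 0.0, "database": 0.5}
            )
            got = k_shortest_paths(g, src, dst, 10**6, weights)
            assert [(p.total_weight, p.nodes) for p in got] == expected

    def test_monotone_shortest_path_weight(self, rng):
        """Raising a multiplier never increases the shortest-path weight."""
        g = random_graph(rng, n_proteins=7, density=0.5)
        src, dst = g.chemical_nodes()[0], g.protein_nodes()[-1]
        prev = None
        for m in [0.0, 0.25, 0.5, 0.75, 1.0]:
            weights = ChannelWeights({"experimental": m, "textmining": 0.999})
            path = shortest_path(g, src, dst, weights)
            if path is None:
                continue
            if prev is not None:
                assert path.total_weight <= prev + 1e-9
            prev = path.total_weight
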