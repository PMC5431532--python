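"""Typed regulatory network assembly, metrics, FFL motifs and null models."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from _oracles import brute_force_betweenness, brute_force_cpm, brute_force_ffls
from fibrosysmap.network import (
    NullModelConfig,
    TypedRegNetwork,
    assemble_grn,
    clique_percolation,
    enumerate_ffls,
    ffl_significance,
    identify_hubs,
    network_metrics,
    random_typed_network,
    randomize_preserving_degree,
    summarize_network,
)


def edge_frame(edges):
    rows = []
    for src, tgt, etype in edges:
        rows.append({"source": src, "target": tgt, "edge_type": etype,
                     "evidence": "test"})
    return pd.DataFrame(rows)


CLASSES = {"t1": "TF", "t2": "TF", "m1": "miRNA", "m2": "miRNA",
           "g1": "gene", "g2": "gene", "g3": "gene"}


class TestAssemble:
    def test_counts(self):
        net = assemble_grn(edge_frame([
            ("t1", "g1", "TF->gene"), ("t1", "m1", "TF->miRNA"),
            ("m1", "g2", "miRNA->gene"),
        ]), CLASSES)
        assert net.n_nodes == 4 and net.n_edges == 3

    def test_duplicate_rows_collapse(self):
        net = assemble_grn(edge_frame([
            ("t1", "g1", "TF->gene"), ("t1", "g1", "TF->gene"),
        ]), CLASSES)
        assert net.n_edges == 1

    def test_type_contradiction_rejected(self):
        with pytest.raises(ValueError, match="t1->g1"):
            assemble_grn(edge_frame([("t1", "g1", "miRNA->gene")]), CLASSES)

    def test_per_type_tallies_match_input(self):
        net = random_typed_network(5, 5, 12, 0.3, seed=3)
        summary = summarize_network(net)
        for etype, n in summary["edges_per_type"].items():
            assert n == len(net.edges_of_type(etype))
        assert sum(summary["edges_per_type"].values()) == net.n_edges


class TestMetrics:
    def test_path_betweenness(self):
        net = assemble_grn(edge_frame([
            ("t1", "m1", "TF->miRNA"), ("m1", "g1", "miRNA->gene"),
        ]), CLASSES)
        metrics = network_metrics(net)
        assert metrics.loc["m1", "betweenness"] == pytest.approx(1.0)

    def test_isolated_node_all_zero(self):
        g = nx.DiGraph()
        g.add_node("x", klass="gene")
        metrics = network_metrics(TypedRegNetwork(g))
        row = metrics.loc["x"]
        assert row["in_degree"] == row["out_degree"] == 0
        assert row["betweenness"] == 0 and row["closeness"] == 0

    def test_betweenness_matches_shortest_path_oracle(self):
        net = random_typed_network(8, 8, 14, 0.15, seed=11)
        metrics = network_metrics(net)
        oracle = brute_force_betweenness(net.graph)
        for node, expect in oracle.items():
            assert metrics.loc[node, "betweenness"] == pytest.approx(expect, abs=1e-9)


class TestHubs:
    def test_star_tf_is_top_hub(self):
        edges = [("t1", g, "TF->gene") for g in ("g1", "g2", "g3")]
        edges += [("t2", "g1", "TF->gene"), ("m1", "g1", "miRNA->gene")]
        net = assemble_grn(edge_frame(edges), CLASSES)
        hubs = identify_hubs(net)
        assert hubs["tf_hubs"][0] == "t1"
        assert hubs["gene_hubs"][0] == "g1"  # in-degree 3

    def test_matches_direct_degree_sort(self):
        net = random_typed_network(6, 6, 10, 0.25, seed=5)
        hubs = identify_hubs(net, top_n=3)
        g = net.graph
        expect = sorted(net.nodes_of_class("TF"),
                        key=lambda n: (-g.out_degree(n), n))[:3]
        assert hubs["tf_hubs"] == expect


class TestEnumerateFFLs:
    def test_tf_ffl_definition(self):
        net = assemble_grn(edge_frame([
            ("t1", "g1", "TF->gene"), ("t1", "m1", "TF->miRNA"),
            ("m1", "g1", "miRNA->gene"),
        ]), CLASSES)
        motifs = enumerate_ffls(net)
        assert len(motifs) == 1
        assert motifs[0].motif_class == "TF-FFL"
        assert motifs[0].nodes == ("t1", "m1", "g1")

    def test_mirna_ffl_definition(self):
        net = assemble_grn(edge_frame([
            ("m1", "t1", "miRNA->TF"), ("m1", "g1", "miRNA->gene"),
            ("t1", "g1", "TF->gene"),
        ]), CLASSES)
        motifs = enumerate_ffls(net)
        assert [m.motif_class for m in motifs] == ["miRNA-FFL"]

    def test_composite_four_node(self):
        net = assemble_grn(edge_frame([
            ("t1", "m1", "TF->miRNA"),
            ("t1", "g1", "TF->gene"), ("t1", "g2", "TF->gene"),
            ("m1", "g1", "miRNA->gene"), ("m1", "g2", "miRNA->gene"),
        ]), CLASSES)
        classes = sorted(m.motif_class for m in enumerate_ffls(net))
        assert classes == ["TF-FFL", "TF-FFL", "composite-4"]

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_scan(self, seed):
        net = random_typed_network(6, 6, 12, 0.2, seed=seed)
        got = {(m.motif_class, m.nodes) for m in enumerate_ffls(net)}
        assert got == brute_force_ffls(net)


class TestCliquePercolation:
    def _net_from_undirected(self, edges):
        g = nx.DiGraph()
        nodes = {n for e in edges for n in e}
        for n in nodes:
            g.add_node(n, klass="gene")
        for u, v in edges:
            g.add_edge(u, v, edge_type="x")
        return TypedRegNetwork(g)

    def test_shared_edge_merges_triangles(self):
        net = self._net_from_undirected(
            [("a", "b"), ("b", "c"), ("a", "c"), ("b", "d"), ("c", "d")])
        modules = clique_percolation(net, k=3)
        assert modules == [frozenset({"a", "b", "c", "d"})]

    def test_shared_node_keeps_modules_apart(self):
        net = self._net_from_undirected(
            [("a", "b"), ("b", "c"), ("a", "c"),
             ("c", "d"), ("d", "e"), ("c", "e")])
        modules = clique_percolation(net, k=3)
        assert sorted(sorted(m) for m in modules) == [["a", "b", "c"], ["c", "d", "e"]]

    def test_k_below_three_rejected(self):
        net = self._net_from_undirected([("a", "b")])
        with pytest.raises(ValueError):
            clique_percolation(net, k=2)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_clique_graph_components(self, seed):
        net = random_typed_network(8, 8, 16, 0.18, seed=seed)
        und = net.graph.to_undirected()
        got = sorted(clique_percolation(net, k=3), key=lambda c: sorted(c))
        assert got == brute_force_cpm(und, 3)

    def test_modules_cover_triangle_nodes(self):
        net = random_typed_network(6, 6, 12, 0.25, seed=2)
        und = net.graph.to_undirected()
        triangle_nodes = {n for clique in nx.enumerate_all_cliques(und)
                          if len(clique) == 3 for n in clique}
        module_nodes = set().union(*clique_percolation(net, 3), frozenset())
        assert module_nodes == triangle_nodes


class TestRandomization:
    def test_per_type_degrees_preserved(self):
        net = random_typed_network(8, 8, 20, 0.25, seed=1)
        cfg = NullModelConfig(n_random=1, seed=9)
        for seed in range(5):
            rnd = randomize_preserving_degree(
                net, cfg, rng=np.random.default_rng(seed))
            before = net.per_type_degree_table()
            after = rnd.per_type_degree_table()
            pd.testing.assert_frame_equal(before, after)

    def test_edge_overlap_declines_with_swapping(self):
        net = random_typed_network(10, 10, 30, 0.25, seed=4)
        original = net.edge_set()
        overlaps = []
        for q in (1, 20):
            cfg = NullModelConfig(n_random=1, swap_multiplier=q, seed=0)
            sims = [
                len(randomize_preserving_degree(
                    net, cfg, rng=np.random.default_rng(s)).edge_set() & original)
                for s in range(10)
            ]
            overlaps.append(np.mean(sims))
        assert overlaps[1] < overlaps[0] < len(original)

    def test_two_edge_type_yields_valid_graph(self):
        edges = edge_frame([("t1", "g1", "TF->gene"), ("t2", "g2", "TF->gene")])
        net = assemble_grn(edges, CLASSES)
        cfg = NullModelConfig(n_random=1, seed=0)
        rnd = randomize_preserving_degree(net, cfg)
        assert rnd.edge_set() in (
            frozenset({("t1", "g1"), ("t2", "g2")}),
            frozenset({("t1", "g2"), ("t2", "g1")}),
        )


class TestSignificance:
    def test_p_bounds_and_monotone_alpha(self):
        net = random_typed_network(6, 6, 12, 0.3, seed=7)
        motifs = enumerate_ffls(net)
        cfg = NullModelConfig(n_random=50, seed=0)
        annotated, retained_05 = ffl_significance(net, motifs, cfg)
        lo = 1 / (cfg.n_random + 1)
        for m in annotated:
            assert lo <= m.p_empirical <= 1.0
        cfg_strict = NullModelConfig(n_random=50, seed=0, alpha=0.01)
        _, retained_01 = ffl_significance(net, motifs, cfg_strict)
        keys = lambda ms: {(m.motif_class, m.nodes) for m in ms}  # noqa: E731
        assert keys(retained_01) <= keys(retained_05)

    def test_minimum_attainable_p(self):
        # a motif whose edges are the only ones of their types cannot be
        # destroyed by swapping: present in every null, p = 1
        net = assemble_grn(edge_frame([
            ("t1", "g1", "TF->gene"), ("t1", "m1", "TF->miRNA"),
            ("m1", "g1", "miRNA->gene"),
        ]), CLASSES)
        motifs = enumerate_ffls(net)
        cfg = NullModelConfig(n_random=100, seed=0)
        annotated, _ = ffl_significance(net, motifs, cfg)
        assert annotated[0].p_empirical == pytest.approx(1.0)

    def test_planted_ffl_in_sparse_network_is_significant(self):
        net = random_typed_network(10, 10, 60, 0.02, seed=3)
        g = net.graph
        for n, klass in (("TFP", "TF"), ("MIRP", "miRNA"), ("GP", "gene")):
            g.add_node(n, klass=klass)
        g.add_edge("TFP", "MIRP", edge_type="TF->miRNA")
        g.add_edge("TFP", "GP", edge_type="TF->gene")
        g.add_edge("MIRP", "GP", edge_type="miRNA->gene")
        motifs = enumerate_ffls(net)
        planted = [m for m in motifs
                   if m.nodes == ("TFP", "MIRP", "GP")]
        assert planted, "planted circuit must be enumerated"
        cfg = NullModelConfig(n_random=200, seed=1)
        annotated, retained = ffl_significance(net, motifs, cfg)
        keys = {(m.motif_class, m.nodes) for m in retained}
        assert ("TF-FFL", ("TFP", "MIRP", "GP")) in keys
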