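"""Gene-set network: edge typing, PageRank, nulls, correction cascade."""

import networkx as nx
import numpy as np
import pytest

from setrank import (GeneSet, GeneSetCollection, RankedGeneList, holm,
                     make_figure_case, pagerank)
from setrank import elimination as el
from setrank import network as nm
from oracles import holm_reference, pagerank_linear_solve


def pipeline(case):
    coll, ranked, _ = make_figure_case(case)
    sig = el.initial_significant_sets(coll, ranked, 0.05)
    disc, ret, mut, evals = el.eliminate_false_positives(coll, ranked, sig,
                                                         0.05, 0.01)
    net = nm.build_network(ret, evals, coll, sig, mut)
    return net, evals, sig


def subset_both_retained_network():
    """A ⊊ B where the superset keeps its own signal: both retained."""
    genes = np.array([f"g{k}" for k in range(500)], dtype=object)
    pvals = np.concatenate([np.full(8, 1e-6), np.linspace(0.02, 1, 492)])
    ranked = RankedGeneList(genes, pvals)
    a = GeneSet("A", "a", "db", frozenset(genes[:4]))
    b = GeneSet("B", "b", "db", frozenset(genes[:8]) | frozenset(genes[100:104]))
    coll = GeneSetCollection([a, b])
    sig = el.initial_significant_sets(coll, ranked, 0.05)
    disc, ret, mut, evals = el.eliminate_false_positives(coll, ranked, sig,
                                                         0.05, 0.01)
    assert ret == {"A", "B"}
    return nm.build_network(ret, evals, coll, sig, mut), evals, sig


class TestBuildNetwork:
    def test_subset_edge_directed_subset_to_superset(self):
        net, _, _ = subset_both_retained_network()
        assert net.graph.has_edge("A", "B")
        assert net.graph.edges["A", "B"]["edge_type"] == nm.EDGE_SUBSET

    def test_mutual_pair_gets_undirected_intersection_edge(self):
        net, _, _ = pipeline("fig2_intersection")
        (edge,) = list(net.graph.edges(data=True))
        assert edge[2]["edge_type"] == nm.EDGE_INTERSECTION
        assert edge[2]["directed"] is False
        assert net.graph.nodes["A"]["intersection_only"]

    def test_overlap_edge_points_to_stronger_p_prime(self):
        ev = el.PairEvaluation("A", "B", 3, 1e-4, p_prime_a=0.001,
                               p_prime_b=0.04, verdict=el.NONE)
        coll = GeneSetCollection([
            GeneSet("A", "a", "db", frozenset({"g1", "g2", "g3", "g4"})),
            GeneSet("B", "b", "db", frozenset({"g2", "g3", "g4", "g5"})),
        ])
        net = nm.build_network({"A", "B"}, [ev], coll, {"A": 0.01, "B": 0.02})
        assert net.graph.has_edge("B", "A")
        assert net.graph.edges["B", "A"]["edge_type"] == nm.EDGE_OVERLAP

    def test_jaccard_matches_membership(self):
        net, _, _ = pipeline("fig1")
        a_genes = {"S1", "S2", "S3", "S4", "S5", "nA1", "nA2", "nA3"}
        # B was discarded in fig1; rebuild an overlap network by hand instead
        net2, _, _ = pipeline("fig2_intersection")
        (u, v, d) = list(net2.graph.edges(data=True))[0]
        assert d["jaccard"] == pytest.approx(5 / 15)


class TestPageRank:
    def test_isolated_nodes_share_mass(self):
        g = nx.DiGraph()
        g.add_nodes_from(range(4))
        scores = pagerank(g)
        assert all(v == pytest.approx(0.25) for v in scores.values())

    def test_two_node_chain_closed_form(self):
        g = nx.DiGraph([(0, 1)])
        scores = pagerank(g, damping=0.85)
        oracle = pagerank_linear_solve([(0, 1)], 2, 0.85)
        assert scores[0] == pytest.approx(oracle[0], abs=1e-12)
        assert scores[1] == pytest.approx(oracle[1], abs=1e-12)
        assert scores[1] > scores[0]

    def test_hub_outranks_equal_sources(self):
        g = nx.DiGraph([(k, 9) for k in range(9)])
        scores = pagerank(g)
        assert scores[9] == max(scores.values())

    def test_matches_linear_solve_on_random_digraphs(self, rng):
        for _ in range(60):
            n = int(rng.integers(2, 9))
            edges = [(int(u), int(v)) for u in range(n) for v in range(n)
                     if u != v and rng.random() < 0.3]
            g = nx.DiGraph()
            g.add_nodes_from(range(n))
            g.add_edges_from(edges)
            scores = pagerank(g)
            oracle = pagerank_linear_solve(edges, n)
            assert sum(scores.values()) == pytest.approx(1.0, abs=1e-10)
            for k in range(n):
                assert scores[k] == pytest.approx(oracle[k], abs=1e-10)

    def test_agrees_with_networkx(self, rng):
        g = nx.gnp_random_graph(12, 0.25, directed=True, seed=5)
        ours = pagerank(g)
        theirs = nx.pagerank(g, alpha=0.85, tol=1e-12, max_iter=1000)
        for node in g:
            assert ours[node] == pytest.approx(theirs[node], abs=1e-8)


class TestSetRankPvalues:
    def test_edgeless_network_is_uninformative(self):
        net = nm.GeneSetNetwork()
        for k in range(4):
            net.graph.add_node(f"S{k}", p_primary=0.01)
        nm.setrank_values(net)
        pvals = nm.setrank_pvalues(net, n_random=10, seed=0)
        # every node equals the null mean; zero variance -> p = 1
        assert all(p == 1.0 for p in pvals.values())

    def test_hub_of_star_graph_has_minimum_p(self):
        net = nm.GeneSetNetwork()
        sets = {f"S{k}" for k in range(6)}
        for sid in sets:
            net.graph.add_node(sid, p_primary=0.01)
        for k in range(5):
            net.graph.add_edge(f"S{k}", "S5", edge_type=nm.EDGE_OVERLAP,
                               jaccard=0.5, directed=True,
                               intersection_size=2)
        nm.setrank_values(net)
        pvals = nm.setrank_pvalues(net, n_random=50, seed=3)
        assert min(pvals, key=pvals.get) == "S5"

    def test_reproducible_under_fixed_seed(self):
        def run():
            net = nm.GeneSetNetwork()
            for k in range(5):
                net.graph.add_node(f"S{k}", p_primary=0.01)
            net.graph.add_edge("S0", "S1", edge_type=nm.EDGE_OVERLAP,
                               jaccard=0.5, directed=True, intersection_size=2)
            net.graph.add_edge("S2", "S1", edge_type=nm.EDGE_OVERLAP,
                               jaccard=0.5, directed=True, intersection_size=2)
            nm.setrank_values(net)
            return nm.setrank_pvalues(net, n_random=25, seed=11)
        assert run() == run()

    def test_scores_sum_to_one(self):
        net, _, _ = subset_both_retained_network()
        scores = nm.setrank_values(net)
        assert sum(scores.values()) == pytest.approx(1.0, abs=1e-10)


class TestHolm:
    def test_reference_example(self):
        assert holm([0.01, 0.02, 0.5]) == pytest.approx([0.03, 0.04, 0.5])

    def test_matches_reference_on_random_vectors(self, rng):
        for _ in range(200):
            p = rng.uniform(0, 1, int(rng.integers(1, 25)))
            got = holm(p)
            ref = holm_reference(p)
            assert np.allclose(got, ref, atol=1e-12)
            assert np.all(got >= p - 1e-15) and np.all(got <= 1.0)

    def test_monotone_in_raw_order(self, rng):
        p = np.sort(rng.uniform(0, 1, 15))
        adj = holm(p)
        assert np.all(np.diff(adj) >= -1e-15)


class TestCorrectionCascade:
    def test_isolated_node_keeps_primary_p(self):
        net = nm.GeneSetNetwork()
        net.graph.add_node("A", p_primary=0.013)
        out = nm.corrected_pvalues(net, [])
        assert out == {"A": 0.013}

    def test_max_over_neighbour_p_primes(self):
        net = nm.GeneSetNetwork()
        for sid in "ABC":
            net.graph.add_node(sid, p_primary=0.001)
        net.graph.add_edge("B", "A", edge_type=nm.EDGE_OVERLAP, jaccard=0.5,
                           directed=True, intersection_size=1)
        net.graph.add_edge("C", "A", edge_type=nm.EDGE_OVERLAP, jaccard=0.5,
                           directed=True, intersection_size=1)
        evals = [el.PairEvaluation("A", "B", 1, 1e-4, 0.001, 0.02, el.NONE),
                 el.PairEvaluation("A", "C", 1, 1e-4, 0.03, 0.01, el.NONE)]
        out = nm.corrected_pvalues(net, evals)
        assert out["A"] == pytest.approx(0.03)
        assert out["B"] == pytest.approx(0.02)

    def test_component_holm_inherited_and_filtered(self):
        net = nm.GeneSetNetwork()
        # three components with corrected p 0.01, 0.02, 0.5
        for sid, p in [("A", 0.01), ("B", 0.02), ("C", 0.5)]:
            net.graph.add_node(sid, p_primary=p, p_corrected=p)
        out = nm.component_correction(net, fdr_cutoff=0.05)
        assert out["A"] == pytest.approx(0.03)
        assert out["B"] == pytest.approx(0.04)
        assert out["C"] == pytest.approx(0.5)
        assert net.graph.nodes["C"]["component_passes_fdr"] is False

    def test_single_component_min_rule(self):
        net, evals, sig = pipeline("fig2_intersection")
        nm.corrected_pvalues(net, evals)
        out = nm.component_correction(net, 0.05)
        expected = min(net.graph.nodes[v]["p_corrected"] for v in net.graph)
        assert all(v == pytest.approx(expected) for v in out.values())


class TestOrderingAndExport:
    def fitted_net(self):
        net = nm.GeneSetNetwork()
        rows = [("A", 0.2, 0.4, 0.01), ("B", 0.1, 0.3, 0.02),
                ("C", 0.1, 0.2, 0.03)]
        for sid, ps, psh, pc in rows:
            net.graph.add_node(sid, name=sid.lower(), db="db", size=5,
                               p_primary=pc, p_corrected=pc, p_setrank=ps,
                               p_setrank_holm=psh, setrank_value=0.3,
                               component_id=0, p_component_holm=0.01,
                               component_passes_fdr=True)
        return net

    def test_three_key_sort(self):
        df = nm.order_results(self.fitted_net())
        assert df["set_id"].tolist() == ["C", "B", "A"]
        assert df["rank"].tolist() == [1, 2, 3]

    def test_stable_on_full_ties(self):
        net = nm.GeneSetNetwork()
        for sid in ["Z", "M", "A"]:  # insertion order must survive
            net.graph.add_node(sid, name=sid, db="db", size=3, p_primary=0.01,
                               p_corrected=0.01, p_setrank=0.5,
                               p_setrank_holm=1.0, setrank_value=0.33,
                               component_id=0, p_component_holm=0.01,
                               component_passes_fdr=True)
        assert nm.order_results(net)["set_id"].tolist() == ["Z", "M", "A"]

    def test_graphml_round_trip(self, tmp_path):
        net, evals, sig = pipeline("fig2_intersection")
        nm.setrank_values(net)
        nm.setrank_pvalues(net, n_random=5, seed=0)
        nm.corrected_pvalues(net, evals)
        nm.component_correction(net, 0.05)
        path = tmp_path / "net.graphml"
        nm.export_graphml(net, path)
        back = nm.load_graphml(path)
        assert set(back.graph.nodes) == set(net.graph.nodes)
        assert set(back.graph.edges) == set(net.graph.edges)
        for node in net.graph:
            for key in ("name", "db", "size", "p_primary", "p_corrected"):
                assert back.graph.nodes[node][key] == \
                    pytest.approx(net.graph.nodes[node][key]) \
                    if isinstance(net.graph.nodes[node][key], float) \
                    else back.graph.nodes[node][key] == net.graph.nodes[node][key]
        for u, v in net.graph.edges:
            assert back.graph.edges[u, v]["edge_type"] == \
                net.graph.edges[u, v]["edge_type"]
            assert float(back.graph.edges[u, v]["jaccard"]) == \
                pytest.approx(net.graph.edges[u, v]["jaccard"])

    def test_empty_network_exports(self, tmp_path):
        net = nm.GeneSetNetwork()
        path = tmp_path / "empty.graphml"
        nm.export_graphml(net, path)
        assert len(nm.load_graphml(path)) == 0
        df = nm.order_results(net)
        assert len(df) == 0 and "rank" in df.columns

    def test_tsv_mirrors_order(self, tmp_path):
        import pandas as pd

        net = self.fitted_net()
        path = tmp_path / "res.tsv"
        nm.export_tsv(net, path)
        df = pd.read_csv(path, sep="\t")
        assert df["set_id"].tolist() == ["C", "B", "A"]
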