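import math
import random

import networkx as nx
import pytest

from summash.concept_mapping import map_article
from summash.corpus_io import Sentence
from summash.graph_summarizer import (
    Cluster,
    GraphParams,
    build_document_graph,
    build_sentence_graph,
    cluster_graph,
    salience,
    score_sentence_graph,
    select_top_sentences,
    sentence_cluster_similarity,
    summarize_graph,
)
from summash.knowledge import Concept, KnowledgeSource

from .conftest import make_article
from .oracles import oracle_cluster, oracle_score


def graph_from(edges, nodes=()):
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for a, b, w in edges:
        g.add_edge(a, b, weight=w, relation="other_related")
    return g


class TestSentenceGraph:
    def test_chain_weights_and_level_removal(self, chain_ks):
        g = build_sentence_graph(chain_ks, {"c"})
        assert set(g.nodes) == {"b", "c"}
        assert g.edges["b", "c"]["weight"] == pytest.approx(3 / 4)

    def test_shared_ancestor_merges(self, chain_ks):
        chain_ks.concepts["c2"] = Concept("c2", "ventricle", "anatomy")
        chain_ks.isa_edges.append(("b", "c2"))
        chain_ks._parents = chain_ks._depths = None
        g = build_sentence_graph(chain_ks, {"c", "c2"})
        assert set(g.nodes) == {"b", "c", "c2"}
        assert g.degree["b"] == 2

    def test_empty_sentence(self, chain_ks):
        g = build_sentence_graph(chain_ks, set())
        assert g.number_of_nodes() == 0


def two_chain_ks():
    """Two disjoint depth-4 chains joined at the root, plus related edges."""
    ks = KnowledgeSource()
    ids = ["root", "a1", "b1", "c1", "a2", "b2", "c2"]
    for c in ids:
        ks.concepts[c] = Concept(c, c, "t")
    ks.isa_edges = [("root", "a1"), ("a1", "b1"), ("b1", "c1"),
                    ("root", "a2"), ("a2", "b2"), ("b2", "c2")]
    ks.lexicon = {c: [c] for c in ids}
    return ks


class TestDocumentGraph:
    def test_related_edge_bridges_leaves(self):
        ks = two_chain_ks()
        ks.related_edges = [("c1", "c2", "other_related")]
        art = make_article(["x", "y"])
        art.body_sentences()[0].concepts = {"c1"}
        art.body_sentences()[1].concepts = {"c2"}
        dg = build_document_graph(ks, art)
        assert nx.is_connected(dg.graph)
        assert dg.graph.edges["c1", "c2"]["weight"] == 1.0

    def test_related_edge_to_nonleaf_not_added(self):
        ks = two_chain_ks()
        ks.related_edges = [("b1", "c2", "other_related")]  # b1 has isa child c1
        art = make_article(["x", "y"])
        art.body_sentences()[0].concepts = {"c1"}
        art.body_sentences()[1].concepts = {"c2"}
        dg = build_document_graph(ks, art)
        assert not dg.graph.has_edge("b1", "c2")

    def test_single_sentence_equals_sentence_graph(self, chain_ks):
        art = make_article(["x"])
        art.body_sentences()[0].concepts = {"c"}
        dg = build_document_graph(chain_ks, art)
        sg = build_sentence_graph(chain_ks, {"c"})
        assert set(dg.graph.nodes) == set(sg.nodes)
        assert set(map(frozenset, dg.graph.edges)) == set(map(frozenset, sg.edges))
        assert dg.sentence_vertex_map == {0: {"b", "c"}}


class TestSalienceAndClustering:
    def test_salience_values(self):
        g = graph_from([("a", "b", 0.5), ("a", "c", 1.0)], nodes=["d"])
        assert salience(g, "d") == 0.0
        assert salience(g, "a") == pytest.approx(1.5)

    def test_handshake_identity(self):
        rng = random.Random(0)
        g = graph_from(
            [(f"v{i}", f"v{j}", rng.random()) for i in range(6) for j in range(i + 1, 6)
             if rng.random() < 0.6]
        )
        total_w = sum(d["weight"] for _, _, d in g.edges(data=True))
        assert sum(salience(g, v) for v in g.nodes) == pytest.approx(2 * total_w)

    def test_two_components_give_two_clusters(self):
        g = graph_from([
            ("a", "b", 1.0), ("a", "c", 1.0), ("b", "c", 0.5),
            ("d", "e", 1.0), ("d", "f", 1.0), ("e", "f", 0.5),
        ])
        clusters = cluster_graph(g, GraphParams(hub_ratio=1 / 3, compression_rate=0.3))
        members = sorted(sorted(c.members) for c in clusters)
        assert members == [["a", "b", "c"], ["d", "e", "f"]]

    def test_complete_uniform_graph_single_cluster(self):
        g = graph_from([("a", "b", 1.0), ("a", "c", 1.0), ("a", "d", 1.0),
                        ("b", "c", 1.0), ("b", "d", 1.0), ("c", "d", 1.0)])
        clusters = cluster_graph(g, GraphParams(hub_ratio=0.5, compression_rate=0.3))
        assert len(clusters) == 1
        assert clusters[0].members == {"a", "b", "c", "d"}

    def test_singleton_graph(self):
        g = nx.Graph()
        g.add_node("only")
        clusters = cluster_graph(g, GraphParams(hub_ratio=0.2, compression_rate=0.3))
        assert len(clusters) == 1
        assert clusters[0].members == clusters[0].hvs == {"only"}

    def test_empty_graph_errors(self):
        with pytest.raises(ValueError):
            cluster_graph(nx.Graph(), GraphParams())

    def test_clusters_partition_clustered_vertices(self):
        rng = random.Random(5)
        g = graph_from(
            [(f"v{i}", f"v{j}", round(rng.random(), 3))
             for i in range(9) for j in range(i + 1, 9) if rng.random() < 0.4]
        )
        clusters = cluster_graph(g, GraphParams(hub_ratio=0.3, compression_rate=0.3))
        seen: set[str] = set()
        for c in clusters:
            assert c.hvs and c.hvs <= c.members
            assert not (c.members & seen)
            seen |= c.members
        assert seen <= set(g.nodes)

    @pytest.mark.parametrize("seed", range(8))
    def test_oracle_equivalence_small_graphs(self, seed):
        """Clusters and sentence scores match a brute-force reimplementation
        of the greedy rules on random graphs of up to 10 vertices."""
        rng = random.Random(seed)
        n = rng.randint(2, 10)
        nodes = [f"v{i}" for i in range(n)]
        edges = [
            (a, b, round(rng.uniform(0.1, 1.0), 3))
            for i, a in enumerate(nodes)
            for b in nodes[i + 1 :]
            if rng.random() < 0.5
        ]
        hub_ratio = rng.choice([0.2, 0.4, 0.7])
        got = cluster_graph(graph_from(edges, nodes), GraphParams(hub_ratio=hub_ratio))
        expected = oracle_cluster(nodes, edges, hub_ratio)
        assert [(sorted(c.members), sorted(c.hvs)) for c in got] == [
            (sorted(m), sorted(h)) for m, h in expected
        ]
        sent = set(rng.sample(nodes, k=rng.randint(1, n)))
        assert score_sentence_graph(got, sent) == pytest.approx(
            oracle_score(expected, sent)
        )


class TestScoring:
    def test_vote_weights(self):
        cl = Cluster(members={"h1", "h2", "m1"}, hvs={"h1", "h2"})
        assert sentence_cluster_similarity(cl, {"h1", "h2", "m1", "out"}) == 2.5
        assert sentence_cluster_similarity(cl, {"x", "y"}) == 0.0
        assert sentence_cluster_similarity(cl, {"h1", "h2"}) == 2.0

    def test_score_adjusts_by_cluster_size(self):
        big = Cluster(members={f"b{i}" for i in range(8)}, hvs={"b0", "b1", "b2", "b3"})
        small = Cluster(members={"s0", "s1"}, hvs=set(["s0"]))
        sent = {"b0", "b1", "b2", "b3", "s0", "s1"}
        # 4 full votes to big (size 8), 1 + 0.5 votes to small (size 2)
        assert score_sentence_graph([big, small], sent) == pytest.approx(4 / 8 + 1.5 / 2)

    def test_no_overlap_scores_zero(self):
        cl = Cluster(members={"a"}, hvs={"a"})
        assert score_sentence_graph([cl], {"z"}) == 0.0

    def test_score_bounded_by_cluster_count(self):
        clusters = [
            Cluster(members={"a", "b"}, hvs={"a"}),
            Cluster(members={"c"}, hvs={"c"}),
        ]
        assert score_sentence_graph(clusters, {"a", "b", "c"}) <= len(clusters)


class TestSummarize:
    def test_ceil_rule(self):
        scores = {i: float(i) for i in range(40)}
        assert len(select_top_sentences(scores, 40, 0.15)) == 6

    def test_rate_one_returns_all_in_order(self):
        scores = {0: 0.1, 1: 5.0, 2: 3.0}
        assert select_top_sentences(scores, 3, 1.0) == [0, 1, 2]

    def test_ties_prefer_earlier_sentence(self):
        scores = {0: 1.0, 1: 1.0, 2: 1.0}
        assert select_top_sentences(scores, 3, 1 / 3) == [0]

    def test_hvs_rich_sentence_ranked_first(self):
        ks = two_chain_ks()
        art = make_article(["c1 b1 here.", "c2 alone here.", "nothing here."])
        map_article(ks, art, parts={"body"})
        params = GraphParams(hub_ratio=0.5, compression_rate=1 / 3)
        chosen = summarize_graph(ks, art, params, premapped=True)
        assert chosen == [0]

    @pytest.mark.parametrize("r1,r2", [(0.15, 0.30), (0.30, 0.50), (0.15, 0.50)])
    def test_nested_summaries(self, toy_world, r1, r2):
        ks, articles, _, _ = toy_world
        for art in articles:
            map_article(ks, art, parts={"body"})
            s1 = summarize_graph(ks, art, GraphParams(compression_rate=r1), premapped=True)
            s2 = summarize_graph(ks, art, GraphParams(compression_rate=r2), premapped=True)
            assert set(s1) <= set(s2)

    def test_summary_size(self, toy_world):
        ks, articles, _, _ = toy_world
        art = articles[0]
        map_article(ks, art, parts={"body"})
        n = len(art.body_sentences())
        got = summarize_graph(ks, art, GraphParams(compression_rate=0.3), premapped=True)
        assert len(got) == math.ceil(0.3 * n)

    def test_edge_weights_in_unit_interval(self, toy_world):
        ks, articles, _, _ = toy_world
        art = map_article(ks, articles[0], parts={"body"})
        dg = build_document_graph(ks, art)
        for _, _, d in dg.graph.edges(data=True):
            assert 0 < d["weight"] <= 1
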