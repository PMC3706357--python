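"""Graph-based extractive summarizer.

The document is represented as a weighted concept graph: each sentence's
concepts are extended with their hypernym closure (the two broadest levels
removed) and merged into a sentence graph; sentence graphs are merged into a
document graph, which is then extended with *other related* and *associated
with* edges between leaf vertices.  An is_a edge between a parent ``v_i``
and child ``v_j`` weighs ``depth(v_i)/depth(v_j)``; non-hierarchical edges
between leaves weigh 1.

Topic recognition ranks vertices by *salience* (sum of incident edge
weights), labels the top fraction as hub vertices, greedily groups the hubs
into hub vertex sets (HVS) and assigns the remaining vertices to the cluster
they are most connected to.  Sentences are scored by a non-democratic vote:
a sentence vertex contributes a full vote to a cluster if it lies in the
cluster's HVS, half a vote if it lies in the cluster outside the HVS, and
nothing otherwise; the sentence score is the sum over clusters of its
similarity divided by the cluster size.  The top-scoring sentences up to the
compression rate form the summary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx

from .concept_mapping import map_article
from .corpus_io import Article
from .knowledge import KnowledgeSource


@dataclass
class GraphParams:
    """Tunables of the graph summarizer.

    ``hub_ratio`` — fraction of vertices labeled as hubs (the number of hub
    vertices is ``max(1, round(hub_ratio * |V|))``).  ``compression_rate`` —
    summary length as a fraction of body sentences.
    """

    hub_ratio: float = 0.2
    compression_rate: float = 0.3

    def __post_init__(self) -> None:
        if not (0 < self.hub_ratio <= 1) or not (0 < self.compression_rate <= 1):
            raise ValueError("hub_ratio and compression_rate must lie in (0, 1]")


@dataclass
class Cluster:
    members: set[str]
    hvs: set[str] = field(default_factory=set)


@dataclass
class DocumentGraph:
    graph: nx.Graph
    sentence_vertex_map: dict[int, set[str]]


def build_sentence_graph(ks: KnowledgeSource, concepts: set[str]) -> nx.Graph:
    """Merged hypernym hierarchies of a sentence's concepts.

    Vertices are the union of hypernym closures; edges are is_a pairs
    present among the vertices, weighted depth(parent)/depth(child).
    """
    g = nx.Graph()
    vertices: set[str] = set()
    for c in concepts:
        vertices |= ks.hypernym_closure(c)
    g.add_nodes_from(vertices)
    for parent, child in ks.isa_edges:
        if parent in vertices and child in vertices:
            g.add_edge(
                parent,
                child,
                weight=ks.depth(parent) / ks.depth(child),
                relation="isa",
                parent=parent,
            )
    return g


def build_document_graph(ks: KnowledgeSource, article: Article) -> DocumentGraph:
    """Union of all body sentence graphs plus leaf-to-leaf relation edges.

    A *leaf* is a vertex with no is_a child inside the document graph.
    Every knowledge-source related/associated edge whose both endpoints are
    leaves is added with weight 1; relation edges never touch inner vertices.
    """
    g = nx.Graph()
    svm: dict[int, set[str]] = {}
    for s in article.body_sentences():
        sg = build_sentence_graph(ks, s.concepts)
        svm[s.position] = set(sg.nodes)
        g.add_nodes_from(sg.nodes)
        g.add_edges_from(sg.edges(data=True))
    has_isa_child = {
        d["parent"] for _, _, d in g.edges(data=True) if d["relation"] == "isa"
    }
    leaves = set(g.nodes) - has_isa_child
    for a, b, tag in ks.related_edges:
        if a in leaves and b in leaves and a != b and not g.has_edge(a, b):
            g.add_edge(a, b, weight=1.0, relation=tag)
    return DocumentGraph(graph=g, sentence_vertex_map=svm)


def salience(g: nx.Graph, v: str) -> float:
    """Sum of the weights of the edges incident to ``v``."""
    return sum(d["weight"] for _, _, d in g.edges(v, data=True))


def _connectivity(g: nx.Graph, v: str, members: set[str]) -> float:
    return sum(
        d["weight"] for _, u, d in g.edges(v, data=True) if u in members
    )


def cluster_graph(dg: DocumentGraph | nx.Graph, params: GraphParams) -> list[Cluster]:
    """Greedy hub-vertex-set clustering of the document graph.

    The top ``max(1, round(hub_ratio * |V|))`` vertices by (salience desc,
    id asc) are hubs.  Hubs are scanned in that order: each joins the
    existing HVS to which its total edge weight is maximal and positive
    (ties favor the earliest-created HVS), otherwise it seeds a new HVS.
    The remaining vertices are scanned in the same global order and each
    joins the cluster with maximal positive connectivity to the current
    cluster members; vertices with no positive connectivity stay
    unclustered and never vote.
    """
    g = dg.graph if isinstance(dg, DocumentGraph) else dg
    if g.number_of_nodes() == 0:
        raise ValueError("cannot cluster an empty document graph")
    order = sorted(g.nodes, key=lambda v: (-salience(g, v), v))
    n_hubs = max(1, round(params.hub_ratio * g.number_of_nodes()))
    hubs = order[:n_hubs]

    clusters: list[Cluster] = []
    for h in hubs:
        best_i, best_w = None, 0.0
        for i, cl in enumerate(clusters):
            w = _connectivity(g, h, cl.hvs)
            if w > best_w:
                best_i, best_w = i, w
        if best_i is None:
            clusters.append(Cluster(members={h}, hvs={h}))
        else:
            clusters[best_i].hvs.add(h)
            clusters[best_i].members.add(h)

    for v in order[n_hubs:]:
        best_i, best_w = None, 0.0
        for i, cl in enumerate(clusters):
            w = _connectivity(g, v, cl.members)
            if w > best_w:
                best_i, best_w = i, w
        if best_i is not None:
            clusters[best_i].members.add(v)
    return clusters


def sentence_cluster_similarity(cluster: Cluster, sentence_vertices: set[str]) -> float:
    """Non-democratic vote: 1 per HVS vertex, 0.5 per other member, else 0."""
    score = 0.0
    for v in sentence_vertices:
        if v in cluster.hvs:
            score += 1.0
        elif v in cluster.members:
            score += 0.5
    return score


def score_sentence_graph(clusters: list[Cluster], sentence_vertices: set[str]) -> float:
    """Sentence score: sum over clusters of similarity / cluster size."""
    if not clusters:
        raise ValueError("clusters must be nonempty")
    return sum(
        sentence_cluster_similarity(cl, sentence_vertices) / len(cl.members)
        for cl in clusters
    )


def select_top_sentences(scores: dict[int, float], n_body: int, rate: float) -> list[int]:
    """Stable top-N selection: N = ceil(rate * n_body), ties favor the
    earlier sentence; the result is emitted in document order."""
    n = math.ceil(rate * n_body)
    ranked = sorted(scores, key=lambda p: (-scores[p], p))
    return sorted(ranked[:n])


def score_sentences_graph(
    ks: KnowledgeSource, article: Article, params: GraphParams
) -> dict[int, float]:
    """Per-sentence scores of the graph summarizer (body must be mapped)."""
    dg = build_document_graph(ks, article)
    if dg.graph.number_of_nodes() == 0:
        # no concept ever mapped: every sentence scores 0
        return {p: 0.0 for p in dg.sentence_vertex_map}
    clusters = cluster_graph(dg, params)
    return {
        pos: score_sentence_graph(clusters, verts)
        for pos, verts in dg.sentence_vertex_map.items()
    }


def summarize_graph(
    ks: KnowledgeSource, article: Article, params: GraphParams, *, premapped: bool = False
) -> list[int]:
    """Summary sentence positions for an article at the given compression.

    Maps the body (unless ``premapped``), scores every body sentence and
    returns the top ``ceil(rate * n)`` positions in document order.
    """
    if not premapped:
        map_article(ks, article, parts={"body"})
    scores = score_sentences_graph(ks, article, params)
    return select_top_sentences(scores, len(scores), params.compression_rate)
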