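"""End-to-end experiment: fixtures -> summarize -> index -> evaluate.

Runs the whole study design on a synthetic corpus: generate a knowledge
source and gold-indexed corpus, produce summaries with both summarizers at
the requested compression rates, index each document representation with
the dictionary indexer, the k-NN voter and their merged combination, and
evaluate every (representation, indexer) cell against the gold indexing.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

from .cf_summarizer import CFWeights, summarize_cf
from .concept_mapping import map_article
from .corpus_io import Article, GoldIndex
from .evaluation import EvalReport, evaluate_indexing
from .graph_summarizer import GraphParams, summarize_graph
from .indexing import (
    IndexingResult,
    KnnMeshIndexer,
    ReferenceCorpus,
    dictionary_index,
    merge_results,
)
from .knowledge import KnowledgeSource
from .synthetic_fixtures import FixtureSpec, generate_corpus, generate_knowledge

DEFAULT_RATES = (0.15, 0.30, 0.50)


@dataclass
class ExperimentResult:
    """Evaluation reports keyed by representation then indexer name."""

    reports: dict[str, dict[str, EvalReport]] = field(default_factory=dict)
    summaries: dict[str, dict[str, list[int]]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            rep: {method: report.to_dict() for method, report in cell.items()}
            for rep, cell in self.reports.items()
        }


def summary_text(article: Article, positions: list[int]) -> str:
    by_pos = {s.position: s.text for s in article.body_sentences()}
    return " ".join(by_pos[p] for p in positions)


def representation_texts(
    ks: KnowledgeSource,
    articles: list[Article],
    rates: tuple[float, ...] = DEFAULT_RATES,
    weights: CFWeights | None = None,
    graph_params: GraphParams | None = None,
) -> tuple[dict[str, dict[str, str]], dict[str, dict[str, list[int]]]]:
    """Build every document representation for every article.

    Returns (texts, summaries): ``texts[rep][doc_id]`` is the text of the
    representation (fulltext, medline, gr_sum_XX, cf_sum_XX), and
    ``summaries`` records the selected sentence positions per summarizer.
    """
    weights = weights or CFWeights()
    graph_params = graph_params or GraphParams()
    texts: dict[str, dict[str, str]] = {"fulltext": {}, "medline": {}}
    summaries: dict[str, dict[str, list[int]]] = {}
    for rate in rates:
        texts[f"gr_sum_{round(rate * 100):02d}"] = {}
        texts[f"cf_sum_{round(rate * 100):02d}"] = {}

    for art in articles:
        body_text = " ".join(s.text for s in art.body_sentences())
        texts["fulltext"][art.doc_id] = body_text
        texts["medline"][art.doc_id] = " ".join(
            s.text for s in art.title + art.abstract
        )
        graph_art = map_article(ks, copy.deepcopy(art), parts={"body"})
        cf_art = map_article(ks, copy.deepcopy(art))
        for rate in rates:
            tag = f"{round(rate * 100):02d}"
            gp = GraphParams(hub_ratio=graph_params.hub_ratio, compression_rate=rate)
            positions = summarize_graph(ks, graph_art, gp, premapped=True)
            texts[f"gr_sum_{tag}"][art.doc_id] = summary_text(art, positions)
            summaries.setdefault(f"gr_sum_{tag}", {})[art.doc_id] = positions

            w = copy.copy(weights)
            w.compression_rate = rate
            positions = summarize_cf(ks, cf_art, w, premapped=True)
            texts[f"cf_sum_{tag}"][art.doc_id] = summary_text(art, positions)
            summaries.setdefault(f"cf_sum_{tag}", {})[art.doc_id] = positions
    return texts, summaries


def index_representation(
    ks: KnowledgeSource,
    texts: dict[str, str],
    ref: ReferenceCorpus,
    k: int = 10,
    vote_min: int = 4,
    lam: float = 0.5,
) -> dict[str, dict[str, IndexingResult]]:
    """Run all three indexers over one representation's texts."""
    knn = KnnMeshIndexer(k=k, vote_min=vote_min).fit(ref)
    out: dict[str, dict[str, IndexingResult]] = {"dict": {}, "knn": {}, "merged": {}}
    for doc_id, text in texts.items():
        d = dictionary_index(ks, text)
        d.doc_id = doc_id
        n = knn.predict(text, doc_id=doc_id)
        out["dict"][doc_id] = d
        out["knn"][doc_id] = n
        out["merged"][doc_id] = merge_results(d, n, lam)
    return out


def run_experiment(
    spec: FixtureSpec,
    rates: tuple[float, ...] = DEFAULT_RATES,
    weights: CFWeights | None = None,
    graph_params: GraphParams | None = None,
    k: int = 10,
    vote_min: int = 4,
    lam: float = 0.5,
) -> tuple[ExperimentResult, KnowledgeSource, list[Article], GoldIndex]:
    """Full synthetic experiment; deterministic under the spec's seed."""
    ks = generate_knowledge(spec)
    articles, gold, ref = generate_corpus(spec, ks)
    texts, summaries = representation_texts(ks, articles, rates, weights, graph_params)
    result = ExperimentResult(summaries=summaries)
    for rep, rep_texts in texts.items():
        indexed = index_representation(ks, rep_texts, ref, k, vote_min, lam)
        result.reports[rep] = {
            method: evaluate_indexing(res, gold, ks.mesh_tree)
            for method, res in indexed.items()
        }
    return result, ks, articles, gold
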