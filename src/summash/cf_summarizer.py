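"""Concept-frequency extractive summarizer.

A statistical summarizer over the concept-mapped article: each sentence is
scored by a weighted combination of

* ``CF`` — the summed document frequency of the sentence's concept
  occurrences (Luhn's frequency hypothesis, at the concept level),
  normalized by the per-document maximum so it is commensurable with the
  similarity terms;
* ``Title`` / ``Abstract`` — Jaccard overlap between the sentence's concept
  set and the title / abstract concept sets;
* ``Position`` — a section-based score rewarding Background, the central
  Methods/Results/Discussion block, and Conclusions with separate weights.

Score(S) = alpha*CF + beta*Title + gamma*Abstract + delta*Position; the top
sentences up to the compression rate form the summary.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .concept_mapping import map_article
from .corpus_io import Article, SectionLabel, Sentence
from .graph_summarizer import select_top_sentences
from .knowledge import KnowledgeSource


@dataclass
class CFWeights:
    """Mixing weights; defaults are the tuned values (grid-searched against
    abstracts with ROUGE): alpha=0.5, beta=0.1, gamma=0.2, delta=0.2 for the
    combination and sigma=0.2, rho=0.7, theta=0.1 for the position score."""

    alpha: float = 0.5
    beta: float = 0.1
    gamma: float = 0.2
    delta: float = 0.2
    sigma: float = 0.2
    rho: float = 0.7
    theta: float = 0.1
    compression_rate: float = 0.3

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma", "delta", "sigma", "rho", "theta"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not (0 < self.compression_rate <= 1):
            raise ValueError("compression_rate must lie in (0, 1]")


ConceptVector = dict[str, int]


def body_concept_vector(article: Article) -> ConceptVector:
    """Occurrence count of each concept over the mapped body."""
    counts: Counter[str] = Counter()
    for s in article.body_sentences():
        counts.update(s.concept_counts)
    return dict(counts)


def part_concept_set(sentences: list[Sentence]) -> set[str]:
    out: set[str] = set()
    for s in sentences:
        out |= s.concepts
    return out


def raw_cf(body_vector: ConceptVector, sentence: Sentence) -> float:
    """Unnormalized CF: each concept occurrence adds its document frequency."""
    return float(
        sum(n * body_vector.get(c, 0) for c, n in sentence.concept_counts.items())
    )


def cf_scores(body_vector: ConceptVector, sentences: list[Sentence]) -> dict[int, float]:
    """CF score per sentence, normalized by the per-document maximum raw
    score (all zeros stay zero)."""
    raw = {s.position: raw_cf(body_vector, s) for s in sentences}
    top = max(raw.values(), default=0.0)
    if top == 0.0:
        return {p: 0.0 for p in raw}
    return {p: v / top for p, v in raw.items()}


def jaccard(a: set[str], b: set[str]) -> float:
    if not a and not b:
        return 0.0
    union = a | b
    return len(a & b) / len(union) if union else 0.0


def title_similarity(sentence_concepts: set[str], title_concepts: set[str]) -> float:
    """Proportion of concepts shared with the title (Jaccard)."""
    return jaccard(sentence_concepts, title_concepts)


def abstract_similarity(sentence_concepts: set[str], abstract_concepts: set[str]) -> float:
    """Proportion of concepts shared with the abstract (Jaccard)."""
    return jaccard(sentence_concepts, abstract_concepts)


def position_score(label: SectionLabel, w: CFWeights) -> float:
    """sigma if Background/Intro, rho if Methods/Results/Discussion,
    theta if Conclusions, 0 otherwise."""
    if label == SectionLabel.INTRO:
        return w.sigma
    if label in (SectionLabel.METHODS, SectionLabel.RESULTS, SectionLabel.DISCUSSION):
        return w.rho
    if label == SectionLabel.CONCLUSIONS:
        return w.theta
    return 0.0


def combined_score(cf: float, title: float, abstract: float, position: float, w: CFWeights) -> float:
    return w.alpha * cf + w.beta * title + w.gamma * abstract + w.delta * position


def score_sentences_cf(article: Article, w: CFWeights) -> dict[int, float]:
    """Combined score per body sentence (title/abstract/body must be mapped)."""
    sentences = article.body_sentences()
    body_vec = body_concept_vector(article)
    cf = cf_scores(body_vec, sentences)
    title_set = part_concept_set(article.title)
    abstract_set = part_concept_set(article.abstract)
    scores = {}
    for sec in article.body:
        for s in sec.sentences:
            scores[s.position] = combined_score(
                cf[s.position],
                title_similarity(s.concepts, title_set),
                abstract_similarity(s.concepts, abstract_set),
                position_score(sec.label, w),
                w,
            )
    return scores


def summarize_cf(
    ks: KnowledgeSource, article: Article, w: CFWeights, *, premapped: bool = False
) -> list[int]:
    """Summary sentence positions under the concept-frequency scorer.

    Maps title, abstract and body (unless ``premapped``), scores every body
    sentence and returns the top ``ceil(rate * n)`` positions in document
    order (ties favor the earlier sentence).
    """
    if not premapped:
        map_article(ks, article, parts={"title", "abstract", "body"})
    scores = score_sentences_cf(article, w)
    return select_top_sentences(scores, len(scores), w.compression_rate)
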