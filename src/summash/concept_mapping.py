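"""Deterministic dictionary-based concept identification.

Maps sentence text to knowledge-source concepts by a case-insensitive
longest-match-first scan over token boundaries.  Ambiguous terms (several
candidate concepts) are resolved by a document-level frequency heuristic:
the candidate with the most unambiguous mentions elsewhere in the same
document wins, with lexicon order and then concept id as tie-breaks.
Concepts of very general semantic types are discarded after resolution.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass

from .corpus_io import Article, Sentence
from .knowledge import KnowledgeSource

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+")

ALL_PARTS = frozenset({"title", "abstract", "body"})


@dataclass(frozen=True)
class ConceptMention:
    """An accepted concept match within a sentence.

    ``span`` is a half-open character-offset pair into the sentence text.
    """

    sentence_position: int
    span: tuple[int, int]
    concept_id: str
    term: str


def _tokenize(text: str) -> list[tuple[int, int, str]]:
    return [(m.start(), m.end(), m.group(0).lower()) for m in _TOKEN_RE.finditer(text)]


def _lexicon_index(ks: KnowledgeSource) -> dict[tuple[str, ...], str]:
    """Map token tuples of lexicon terms to the term string."""
    index = {}
    for term in ks.lexicon:
        toks = tuple(t for _, _, t in _tokenize(term))
        if toks:
            index[toks] = term
    return index


def find_candidate_matches(
    ks: KnowledgeSource, sentence_text: str
) -> list[tuple[tuple[int, int], str, list[str]]]:
    """Longest-match-first scan; returns (span, term, candidate concepts).

    Matches never overlap: after accepting a match the scan resumes at the
    first token past it.  At each position the longest matching term wins.
    """
    tokens = _tokenize(sentence_text)
    index = _lexicon_index(ks)
    max_len = max((len(k) for k in index), default=0)
    out = []
    i = 0
    while i < len(tokens):
        matched = False
        for n in range(min(max_len, len(tokens) - i), 0, -1):
            key = tuple(t for _, _, t in tokens[i : i + n])
            term = index.get(key)
            if term is not None:
                span = (tokens[i][0], tokens[i + n - 1][1])
                out.append((span, term, list(ks.lexicon[term])))
                i += n
                matched = True
                break
        if not matched:
            i += 1
    return out


def disambiguate(candidates: list[str], doc_concept_counts: dict[str, int]) -> str:
    """Pick one concept from an ordered candidate list.

    Highest count of unambiguous mentions elsewhere in the document wins;
    ties break by lexicon order, then lexicographic concept id.  Fully
    deterministic.
    """
    if not candidates:
        raise ValueError("candidates must be nonempty")
    best = None
    for rank, c in enumerate(candidates):
        key = (-doc_concept_counts.get(c, 0), rank, c)
        if best is None or key < best[0]:
            best = (key, c)
    return best[1]


def map_sentence(
    ks: KnowledgeSource,
    sentence_text: str,
    sentence_position: int = 0,
    doc_concept_counts: dict[str, int] | None = None,
) -> list[ConceptMention]:
    """Identify concept mentions in one sentence.

    ``doc_concept_counts`` supplies the document-level unambiguous-mention
    counts used to resolve ambiguous terms; without it ties fall back to
    lexicon order.  Mentions resolving to a generic semantic type are
    discarded.
    """
    counts = doc_concept_counts or {}
    mentions = []
    for span, term, candidates in find_candidate_matches(ks, sentence_text):
        concept_id = disambiguate(candidates, counts)
        if ks.concepts[concept_id].semantic_type in ks.generic_types:
            continue
        mentions.append(ConceptMention(sentence_position, span, concept_id, term))
    return mentions


def _doc_unambiguous_counts(
    ks: KnowledgeSource, sentences: list[Sentence]
) -> Counter[str]:
    counts: Counter[str] = Counter()
    for s in sentences:
        for _, _, candidates in find_candidate_matches(ks, s.text):
            if len(candidates) == 1:
                counts[candidates[0]] += 1
    return counts


def map_article(
    ks: KnowledgeSource, article: Article, parts: frozenset[str] | set[str] = ALL_PARTS
) -> Article:
    """Fill ``Sentence.concepts`` / ``concept_counts`` for the given parts.

    The graph summarizer maps the body only; the concept-frequency summarizer
    maps title, abstract and body.  Disambiguation counts are collected over
    all requested parts of the document (two passes).
    """
    article.validate()
    unknown = set(parts) - ALL_PARTS
    if unknown:
        raise ValueError(f"unknown parts {sorted(unknown)}")
    groups: list[list[Sentence]] = []
    if "title" in parts:
        groups.append(article.title)
    if "abstract" in parts:
        groups.append(article.abstract)
    if "body" in parts:
        groups.append(article.body_sentences())
    all_sents = [s for g in groups for s in g]
    counts = _doc_unambiguous_counts(ks, all_sents)
    for s in all_sents:
        mentions = map_sentence(ks, s.text, s.position, counts)
        s.concept_counts = dict(Counter(m.concept_id for m in mentions))
        s.concepts = set(s.concept_counts)
    return article
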