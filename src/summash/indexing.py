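"""MeSH indexers: dictionary matcher, k-NN citation voter, score merger.

Three simple indexers over a knowledge source and a gold-indexed reference
corpus:

* :func:`dictionary_index` — concept-recognition indexing: map the text to
  concepts, restrict them to MeSH headings, rank by supporting mention count.
* :class:`KnnMeshIndexer` / :func:`knn_index` — a k-nearest-neighbours voter
  over TF-IDF cosine similarity: a heading is suggested when at least
  ``vote_min`` of the top ``k`` most similar reference citations are
  gold-indexed with it (defaults k=10, vote_min=4).
* :func:`merge_results` — linear combination of two indexers' confidences.

An optional trigger-rule table (``pattern<TAB>heading`` TSV) can force
headings from surface text after merging; it is disabled by default.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.feature_extraction.text import TfidfVectorizer

from .concept_mapping import _doc_unambiguous_counts, map_sentence
from .corpus_io import Article, GoldIndex, Sentence
from .knowledge import KnowledgeSource


@dataclass
class IndexingResult:
    """Ranked MeSH suggestions for one document.

    ``suggestions`` is a list of (heading, confidence) with unique headings
    and non-increasing confidences.
    """

    doc_id: str
    suggestions: list[tuple[str, float]] = field(default_factory=list)

    def headings(self) -> list[str]:
        return [h for h, _ in self.suggestions]

    def heading_set(self) -> set[str]:
        return {h for h, _ in self.suggestions}

    def validate(self) -> None:
        confs = [c for _, c in self.suggestions]
        if any(b > a + 1e-12 for a, b in zip(confs, confs[1:])):
            raise ValueError("confidences must be non-increasing")
        if len(set(self.headings())) != len(self.suggestions):
            raise ValueError("duplicate headings in result")


@dataclass
class ReferenceCorpus:
    """Gold-indexed citations used as the k-NN neighbour pool.

    ``texts`` maps doc_id to the text part used for similarity (typically
    title + abstract); ``gold`` maps doc_id to its MeSH heading set.
    """

    texts: dict[str, str]
    gold: dict[str, set[str]]

    def __post_init__(self) -> None:
        missing = set(self.texts) - set(self.gold)
        if missing:
            raise ValueError(f"reference docs without gold labels: {sorted(missing)[:5]}")


def _as_sentences(article_or_text: Article | str | list[str]) -> list[Sentence]:
    if isinstance(article_or_text, Article):
        return list(article_or_text.title) + list(article_or_text.abstract) + article_or_text.body_sentences()
    if isinstance(article_or_text, str):
        return [Sentence(0, article_or_text)]
    return [Sentence(i, t) for i, t in enumerate(article_or_text)]


def dictionary_index(ks: KnowledgeSource, article_or_text: Article | str | list[str]) -> IndexingResult:
    """Concept-recognition indexing of a text, article or summary.

    Identifies concepts, maps them to MeSH headings, and ranks headings by
    the total mention count of their supporting concepts normalized by the
    maximum; ties order alphabetically.
    """
    sentences = _as_sentences(article_or_text)
    doc_id = article_or_text.doc_id if isinstance(article_or_text, Article) else ""
    counts = _doc_unambiguous_counts(ks, sentences)
    concept_mentions: Counter[str] = Counter()
    for s in sentences:
        for m in map_sentence(ks, s.text, s.position, counts):
            concept_mentions[m.concept_id] += 1
    heading_counts: Counter[str] = Counter()
    for c, n in concept_mentions.items():
        heading = ks.mesh_map.get(c)
        if heading is not None:
            heading_counts[heading] += n
    if not heading_counts:
        return IndexingResult(doc_id=doc_id)
    top = max(heading_counts.values())
    ranked = sorted(heading_counts.items(), key=lambda hv: (-hv[1], hv[0]))
    return IndexingResult(doc_id=doc_id, suggestions=[(h, n / top) for h, n in ranked])


class KnnMeshIndexer:
    """k-NN MeSH indexer voting headings from similar gold-indexed citations.

    Follows the scikit-learn estimator idiom: :meth:`fit` builds a TF-IDF
    model (lowercased alphanumeric tokens) over the reference corpus,
    :meth:`predict` retrieves the ``k`` most cosine-similar references
    (ties break by lexicographic doc id) and keeps every heading indexed in
    at least ``vote_min`` of them, at confidence votes/k.  Suggestions rank
    by (votes desc, mean supporting-neighbour similarity desc, heading asc).
    """

    def __init__(self, k: int = 10, vote_min: int = 4):
        if k < 1 or vote_min < 1:
            raise ValueError("k and vote_min must be >= 1")
        self.k = k
        self.vote_min = vote_min

    def get_params(self, deep: bool = True) -> dict:
        return {"k": self.k, "vote_min": self.vote_min}

    def set_params(self, **params) -> "KnnMeshIndexer":
        for key, val in params.items():
            if key not in ("k", "vote_min"):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, val)
        return self

    def fit(self, ref: ReferenceCorpus) -> "KnnMeshIndexer":
        if not ref.texts:
            raise ValueError("reference corpus must be nonempty")
        self.ref_ = ref
        self.doc_ids_ = sorted(ref.texts)
        self.vectorizer_ = TfidfVectorizer(
            lowercase=True, token_pattern=r"(?u)[A-Za-z0-9]+"
        )
        self.matrix_ = self.vectorizer_.fit_transform(
            [ref.texts[d] for d in self.doc_ids_]
        )
        return self

    def predict(self, query_text: str, doc_id: str = "", exclude: set[str] | None = None) -> IndexingResult:
        if not hasattr(self, "ref_"):
            raise ValueError("indexer is not fitted")
        exclude = (exclude or set()) | ({doc_id} if doc_id else set())
        q = self.vectorizer_.transform([query_text])
        sims = np.asarray((self.matrix_ @ q.T).todense()).ravel()
        order = sorted(
            (i for i, d in enumerate(self.doc_ids_) if d not in exclude),
            key=lambda i: (-sims[i], self.doc_ids_[i]),
        )
        top = order[: self.k]
        votes: Counter[str] = Counter()
        sim_sum: Counter[str] = Counter()
        for i in top:
            for heading in self.ref_.gold[self.doc_ids_[i]]:
                votes[heading] += 1
                sim_sum[heading] += float(sims[i])
        kept = [
            (h, v) for h, v in votes.items() if v >= self.vote_min
        ]
        kept.sort(key=lambda hv: (-hv[1], -(sim_sum[hv[0]] / hv[1]), hv[0]))
        return IndexingResult(
            doc_id=doc_id, suggestions=[(h, v / self.k) for h, v in kept]
        )


def knn_index(
    ref: ReferenceCorpus,
    query_text: str,
    k: int = 10,
    vote_min: int = 4,
    doc_id: str = "",
) -> IndexingResult:
    """One-shot k-NN voting; see :class:`KnnMeshIndexer`."""
    return KnnMeshIndexer(k=k, vote_min=vote_min).fit(ref).predict(query_text, doc_id)


def merge_results(a: IndexingResult, b: IndexingResult, lam: float = 0.5) -> IndexingResult:
    """Linear combination of two indexers' confidences.

    merged = lam * conf_a + (1 - lam) * conf_b, with 0 for a heading absent
    from one input; zero-confidence headings are dropped, ranking is by
    (confidence desc, heading asc).
    """
    if a.doc_id != b.doc_id:
        raise ValueError(f"doc_id mismatch: {a.doc_id!r} vs {b.doc_id!r}")
    if not (0.0 <= lam <= 1.0):
        raise ValueError("lambda must lie in [0, 1]")
    conf_a = dict(a.suggestions)
    conf_b = dict(b.suggestions)
    merged = {
        h: lam * conf_a.get(h, 0.0) + (1 - lam) * conf_b.get(h, 0.0)
        for h in set(conf_a) | set(conf_b)
    }
    ranked = sorted(
        ((h, c) for h, c in merged.items() if c > 0.0), key=lambda hc: (-hc[1], hc[0])
    )
    return IndexingResult(doc_id=a.doc_id, suggestions=ranked)


# ---------------------------------------------------------------------------
# trigger rules (optional post-processing)
# ---------------------------------------------------------------------------


def read_trigger_rules(path: str | Path) -> list[tuple[str, str]]:
    """Read a ``pattern<TAB>heading`` TSV of forced-heading rules."""
    rules = []
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not raw.strip():
            continue
        cols = raw.split("\t")
        if len(cols) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
        rules.append((cols[0], cols[1]))
    return rules


def apply_trigger_rules(
    result: IndexingResult, text: str, rules: list[tuple[str, str]]
) -> IndexingResult:
    """Force headings whose pattern occurs in the text (word-boundary,
    case-insensitive).  Forced headings get confidence 1.0 and rank ahead."""
    forced = {
        heading
        for pattern, heading in rules
        if re.search(rf"(?i)\b{re.escape(pattern)}\b", text)
    }
    merged = dict(result.suggestions)
    for h in forced:
        merged[h] = 1.0
    ranked = sorted(merged.items(), key=lambda hc: (-hc[1], hc[0]))
    return IndexingResult(doc_id=result.doc_id, suggestions=ranked)


# ---------------------------------------------------------------------------
# TSV round-trip, consumed by the evaluation module
# ---------------------------------------------------------------------------


def write_results(results: list[IndexingResult], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in results:
            for heading, conf in r.suggestions:
                fh.write(f"{r.doc_id}\t{heading}\t{conf:.6f}\n")


def read_results(path: str | Path) -> list[IndexingResult]:
    by_doc: dict[str, list[tuple[str, float]]] = {}
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not raw.strip():
            continue
        cols = raw.split("\t")
        if len(cols) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 tab-separated columns")
        by_doc.setdefault(cols[0], []).append((cols[1], float(cols[2])))
    out = []
    for doc_id, suggestions in by_doc.items():
        suggestions.sort(key=lambda hc: (-hc[1], hc[0]))
        out.append(IndexingResult(doc_id=doc_id, suggestions=suggestions))
    return out
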