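"""Seeded generators for toy knowledge sources and corpora.

Every module in the package is exercisable without licensed resources: the
generators build a small concept hierarchy with topic subtrees, a lexicon of
synthetic surface terms, a concept-to-MeSH map spanning several tree
branches, and a corpus of sectioned articles whose bodies sample planted
topic terms (frequency-weighted, so a Luhn-style concept-frequency signal
exists) plus noise.  Abstracts and titles are built from each article's most
frequent terms, making them usable as ROUGE models and giving the
title/abstract similarity features real signal.  Gold headings are the MeSH
images of the planted topics' core concepts; a held-out slice of articles
forms the k-NN reference corpus.

All randomness flows through one ``random.Random(seed)``; identical specs
produce byte-identical outputs.

The generated sentences are token salads, not natural language: they carry
topical vocabulary and section structure but no syntax, discourse or
MetaMap-style ambiguity beyond the planted rate.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .corpus_io import Article, GoldIndex, Section, SectionLabel, Sentence
from .indexing import ReferenceCorpus
from .knowledge import Concept, KnowledgeSource

_BRANCH_LETTERS = "ABCDEFGHIJKLMNZ"

_FILLER = (
    "we", "the", "of", "in", "and", "with", "for", "was", "were",
    "observed", "measured", "compared", "analyzed", "showed", "using",
)

_CONSONANTS = "bdfgklmnprstvz"
_VOWELS = "aeiou"


@dataclass
class FixtureSpec:
    """Shape parameters of the synthetic experiment.

    Defaults keep the full pipeline desk-scale: tens of articles with bodies
    of 16-40 sentences (the range can be scaled toward realistic corpora of
    hundreds of sentences per body), three well-separated topics, mild
    lexical ambiguity and noise.
    """

    seed: int = 0
    n_articles: int = 20
    n_reference: int = 30
    body_sentence_range: tuple[int, int] = (16, 40)
    n_topics: int = 3
    concepts_per_topic: int = 8
    ambiguity_rate: float = 0.1
    noise_rate: float = 0.1

    def __post_init__(self) -> None:
        lo, hi = self.body_sentence_range
        if lo < 1 or hi < lo:
            raise ValueError("body_sentence_range must be a positive (lo, hi) pair")
        for name in ("n_articles", "n_reference", "n_topics", "concepts_per_topic"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("ambiguity_rate", "noise_rate"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")


def _word(rng: random.Random, used: set[str]) -> str:
    while True:
        w = "".join(
            rng.choice(_CONSONANTS) + rng.choice(_VOWELS)
            for _ in range(rng.randint(2, 4))
        )
        if w not in used and w not in _FILLER:
            used.add(w)
            return w


def generate_knowledge(spec: FixtureSpec) -> KnowledgeSource:
    """Build a toy knowledge source with ``n_topics`` topic subtrees.

    The is_a DAG is rooted at a generic entity concept with a layer of
    broad categories at depth 2 (both stripped by the hypernym-closure
    rule); each topic subtree reaches depth >= 5 so upper-level removal is
    exercised.  ``ambiguity_rate`` of lexicon terms map to a second concept
    from the next topic; a handful of generic-type concepts carry lexicon
    terms so the generic-type filter is exercised.  Each topic maps to a
    main and an auxiliary MeSH heading with tree numbers on its own branch
    letter; the first topic's main heading sits on two branches.
    """
    rng = random.Random(spec.seed)
    used: set[str] = set()
    ks = KnowledgeSource()

    root = "C0000"
    ks.concepts[root] = Concept(root, "entity", "generic/entity")
    topic_concepts: list[list[str]] = []

    for t in range(spec.n_topics):
        cat = f"C{t + 1:02d}00"
        ks.concepts[cat] = Concept(cat, f"category {t}", "generic/category")
        ks.isa_edges.append((root, cat))
        ids = []
        for j in range(spec.concepts_per_topic):
            cid = f"C{t + 1:02d}{j + 1:02d}"
            ks.concepts[cid] = Concept(cid, _word(rng, used), f"topic{t}/specific")
            ids.append(cid)
        # chain of length >= 3 below the category (depths 3,4,5), remaining
        # concepts attached round-robin to chain nodes
        chain_len = min(3, len(ids))
        parent = cat
        for cid in ids[:chain_len]:
            ks.isa_edges.append((parent, cid))
            parent = cid
        for i, cid in enumerate(ids[chain_len:]):
            ks.isa_edges.append((ids[i % chain_len], cid))
        topic_concepts.append(ids)

    # generic-type concepts with lexicon entries (must be filtered out)
    ks.generic_types = {"generic/entity", "generic/category", "generic/qualitative"}
    for g in range(2):
        gid = f"C90{g:02d}"
        ks.concepts[gid] = Concept(gid, _word(rng, used), "generic/qualitative")
        ks.isa_edges.append((root, gid))
        ks.lexicon[ks.concepts[gid].preferred_name] = [gid]

    # lexicon: one single-word term per concept; one extra two-word term per
    # topic (longest-match exercise); ambiguity_rate of terms get a second
    # candidate from the next topic
    for t, ids in enumerate(topic_concepts):
        for j, cid in enumerate(ids):
            term = ks.concepts[cid].preferred_name
            targets = [cid]
            if rng.random() < spec.ambiguity_rate:
                other = topic_concepts[(t + 1) % spec.n_topics]
                targets.append(other[j % len(other)])
            ks.lexicon[term] = targets
        first_two = f"{ks.concepts[ids[0]].preferred_name} {ks.concepts[ids[1]].preferred_name}"
        ks.lexicon[first_two] = [ids[2 % len(ids)]]

    # related/associated edges: within-topic and cross-topic
    for t, ids in enumerate(topic_concepts):
        if len(ids) >= 2:
            ks.related_edges.append((ids[-1], ids[-2], "other_related"))
        nxt = topic_concepts[(t + 1) % spec.n_topics]
        ks.related_edges.append((ids[-1], nxt[-1], "associated_with"))

    # MeSH map: core concepts (first half) -> topic main heading, the rest ->
    # auxiliary heading; branch letters cycle, first main heading is dual-branch
    for t, ids in enumerate(topic_concepts):
        letter = _BRANCH_LETTERS[t % len(_BRANCH_LETTERS)]
        main = f"Topic {letter} disease"
        aux = f"Topic {letter} process"
        n_core = max(1, len(ids) // 2)
        for cid in ids[:n_core]:
            ks.mesh_map[cid] = main
        for cid in ids[n_core:]:
            ks.mesh_map[cid] = aux
        ks.mesh_tree[main] = {f"{letter}01.{100 + t}"}
        ks.mesh_tree[aux] = {f"{letter}02.{200 + t}"}
        if t == 0:
            other = _BRANCH_LETTERS[spec.n_topics % len(_BRANCH_LETTERS)]
            ks.mesh_tree[main].add(f"{other}05.{300 + t}")

    ks.validate()
    return ks


def _topic_terms(ks: KnowledgeSource, topic_index: int) -> list[str]:
    prefix = f"C{topic_index + 1:02d}"
    return sorted(
        term
        for term, targets in ks.lexicon.items()
        if targets[0].startswith(prefix) and targets[0] != prefix + "00"
    )


def _core_headings(ks: KnowledgeSource, spec: FixtureSpec, topic_index: int) -> set[str]:
    ids = [
        f"C{topic_index + 1:02d}{j + 1:02d}"
        for j in range(max(1, spec.concepts_per_topic // 2))
    ]
    return {ks.mesh_map[c] for c in ids if c in ks.mesh_map}


_SECTION_PLAN = (
    (SectionLabel.INTRO, "Background", 0.15),
    (SectionLabel.METHODS, "Methods", 0.25),
    (SectionLabel.RESULTS, "Results", 0.25),
    (SectionLabel.DISCUSSION, "Discussion", 0.25),
    (SectionLabel.CONCLUSIONS, "Conclusions", 0.10),
)


def _make_sentence(rng: random.Random, terms: list[str], weights: list[float]) -> str:
    k = rng.randint(2, 4)
    chosen = rng.choices(terms, weights=weights, k=k)
    words = []
    for term in chosen:
        words.append(rng.choice(_FILLER))
        words.append(term)
    return (" ".join(words) + ".").capitalize()


def _generate_article(
    rng: random.Random, ks: KnowledgeSource, spec: FixtureSpec, doc_id: str
) -> tuple[Article, set[str]]:
    n_topics_here = rng.randint(1, min(3, spec.n_topics))
    planted = sorted(rng.sample(range(spec.n_topics), n_topics_here))
    other = [t for t in range(spec.n_topics) if t not in planted]

    n_core = max(1, spec.concepts_per_topic // 2)
    term_pool: list[str] = []
    weight_pool: list[float] = []
    for t in planted:
        for term in _topic_terms(ks, t):
            target = ks.lexicon[term][0]
            term_pool.append(term)
            # core concepts (low within-topic index) dominate -> frequency signal
            weight_pool.append(3.0 if int(target[3:5]) <= n_core else 1.0)
    noise_terms = [term for t in other for term in _topic_terms(ks, t)]

    n_body = rng.randint(*spec.body_sentence_range)
    body_sents: list[str] = []
    usage: dict[str, int] = {}
    for _ in range(n_body):
        if noise_terms and rng.random() < spec.noise_rate:
            text = _make_sentence(rng, noise_terms, [1.0] * len(noise_terms))
        else:
            text = _make_sentence(rng, term_pool, weight_pool)
        body_sents.append(text)
        for term in term_pool:
            if term in text:
                usage[term] = usage.get(term, 0) + 1

    top_terms = sorted(usage, key=lambda t: (-usage[t], t))[:6] or term_pool[:3]
    title = _make_sentence(rng, top_terms, [1.0] * len(top_terms))
    abstract = [
        _make_sentence(rng, top_terms, [1.0] * len(top_terms)) for _ in range(3)
    ]

    article = Article(doc_id=doc_id)
    article.title = [Sentence(0, title)]
    article.abstract = [Sentence(i, t) for i, t in enumerate(abstract)]
    pos = 0
    start = 0
    for label, name, frac in _SECTION_PLAN:
        count = max(1, round(frac * n_body))
        chunk = body_sents[start : start + count]
        if not chunk:
            continue
        sec = Section(label=label, name=name)
        for text in chunk:
            sec.sentences.append(Sentence(pos, text))
            pos += 1
        article.body.append(sec)
        start += count
    # any remainder goes to the last section
    for text in body_sents[start:]:
        article.body[-1].sentences.append(Sentence(pos, text))
        pos += 1

    gold = set()
    for t in planted:
        gold |= _core_headings(ks, spec, t)
    return article, gold


def generate_corpus(
    spec: FixtureSpec, ks: KnowledgeSource
) -> tuple[list[Article], GoldIndex, ReferenceCorpus]:
    """Generate evaluation articles, their gold indexing and a held-out
    reference corpus for the k-NN indexer."""
    rng = random.Random(spec.seed + 1)
    articles: list[Article] = []
    gold: GoldIndex = {}
    for i in range(spec.n_articles):
        doc_id = f"p{i + 1:04d}"
        art, headings = _generate_article(rng, ks, spec, doc_id)
        articles.append(art)
        gold[doc_id] = headings

    ref_texts: dict[str, str] = {}
    ref_gold: dict[str, set[str]] = {}
    for i in range(spec.n_reference):
        doc_id = f"r{i + 1:04d}"
        art, headings = _generate_article(rng, ks, spec, doc_id)
        ref_texts[doc_id] = " ".join(
            s.text for s in art.title + art.abstract
        )
        ref_gold[doc_id] = headings
    return articles, gold, ReferenceCorpus(texts=ref_texts, gold=ref_gold)
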