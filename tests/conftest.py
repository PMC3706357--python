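import pytest

from summash.corpus_io import Article, Section, SectionLabel, Sentence
from summash.knowledge import Concept, KnowledgeSource
from summash.synthetic_fixtures import FixtureSpec, generate_corpus, generate_knowledge


def make_chain_ks() -> KnowledgeSource:
    """Linear hierarchy root -> a -> b -> c (depths 1..4) with lexicon."""
    ks = KnowledgeSource()
    for cid, name in [("root", "thing"), ("a", "organ"), ("b", "heart"), ("c", "atrium")]:
        ks.concepts[cid] = Concept(cid, name, "anatomy")
    ks.isa_edges = [("root", "a"), ("a", "b"), ("b", "c")]
    ks.lexicon = {"heart": ["b"], "atrium": ["c"]}
    ks.mesh_map = {"b": "Heart", "c": "Heart"}
    ks.mesh_tree = {"Heart": {"A07.541"}}
    ks.validate()
    return ks


@pytest.fixture
def chain_ks() -> KnowledgeSource:
    return make_chain_ks()


def make_article(body_texts, doc_id="p1", title="A study.", abstract=("An abstract.",),
                 label=SectionLabel.METHODS) -> Article:
    art = Article(doc_id=doc_id)
    art.title = [Sentence(0, title)]
    art.abstract = [Sentence(i, t) for i, t in enumerate(abstract)]
    sec = Section(label=label, name="Methods")
    sec.sentences = [Sentence(i, t) for i, t in enumerate(body_texts)]
    art.body = [sec]
    return art


@pytest.fixture
def toy_spec() -> FixtureSpec:
    return FixtureSpec(seed=7, n_articles=6, n_reference=12, body_sentence_range=(8, 14))


@pytest.fixture
def toy_world(toy_spec):
    ks = generate_knowledge(toy_spec)
    articles, gold, ref = generate_corpus(toy_spec, ks)
    return ks, articles, gold, ref
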