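"""Article data model and readers/writers for the on-disk corpus formats.

An :class:`Article` is a sectioned scientific document: a title, an abstract
and an ordered body of labeled sections (IMRaD-style).  Two dialects are
supported on disk:

* a small JATS-like XML subset (``<article-title>``, ``<abstract>``,
  ``<body><sec><title>..</title><p>..</p></sec></body>``) — table and figure
  wrappers (``<table-wrap>``, ``<fig>``) are dropped on read, since their
  content is not part of the running text the summarizers operate on;
* a plain-text dialect with ``# TITLE:`` / ``# ABSTRACT:`` / ``# SECTION:``
  headers, one sentence per line.

Gold indexing files are two-column TSV: ``doc_id<TAB>MeSH heading``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

from lxml import etree


class SectionLabel(str, Enum):
    INTRO = "INTRO"
    METHODS = "METHODS"
    RESULTS = "RESULTS"
    DISCUSSION = "DISCUSSION"
    CONCLUSIONS = "CONCLUSIONS"
    OTHER = "OTHER"


#: case-insensitive mapping from section titles found in articles to labels;
#: substring match on the normalized name, unknown names map to OTHER.
_SECTION_NAME_MAP: list[tuple[str, SectionLabel]] = [
    ("background", SectionLabel.INTRO),
    ("introduction", SectionLabel.INTRO),
    ("method", SectionLabel.METHODS),
    ("result", SectionLabel.RESULTS),
    ("discussion", SectionLabel.DISCUSSION),
    ("conclusion", SectionLabel.CONCLUSIONS),
]


def label_for_section_name(name: str) -> SectionLabel:
    """Map a raw section title (e.g. ``"Materials and Methods"``) to a label."""
    low = name.strip().lower()
    for key, label in _SECTION_NAME_MAP:
        if key in low:
            return label
    return SectionLabel.OTHER


@dataclass
class Sentence:
    """One sentence; ``position`` is 0-based within its document part.

    ``concepts`` / ``concept_counts`` stay empty until concept mapping runs.
    """

    position: int
    text: str
    concepts: set[str] = field(default_factory=set)
    concept_counts: dict[str, int] = field(default_factory=dict)


@dataclass
class Section:
    label: SectionLabel
    name: str
    sentences: list[Sentence] = field(default_factory=list)


@dataclass
class Article:
    doc_id: str
    title: list[Sentence] = field(default_factory=list)
    abstract: list[Sentence] = field(default_factory=list)
    body: list[Section] = field(default_factory=list)

    def body_sentences(self) -> list[Sentence]:
        """Body sentences in document order; positions are 0..n-1."""
        return [s for sec in self.body for s in sec.sentences]

    def section_label_of(self, position: int) -> SectionLabel:
        for sec in self.body:
            for s in sec.sentences:
                if s.position == position:
                    return sec.label
        raise KeyError(f"no body sentence at position {position}")

    def validate(self) -> None:
        if not self.doc_id:
            raise ArticleStructureError("doc_id must be nonempty")
        sents = self.body_sentences()
        if not sents:
            raise ArticleStructureError(f"article {self.doc_id!r}: body is empty")
        positions = [s.position for s in sents]
        if positions != list(range(len(sents))):
            raise ArticleStructureError(
                f"article {self.doc_id!r}: body positions must be 0..n-1 in order"
            )


class ArticleStructureError(ValueError):
    """Raised when a parsed article is missing a required part."""


class GoldFormatError(ValueError):
    """Raised for malformed gold indexing files."""


# ---------------------------------------------------------------------------
# sentence segmentation
# ---------------------------------------------------------------------------

#: abbreviations after which a period never ends a sentence
_ABBREVIATIONS = (
    "et al.", "fig.", "figs.", "vs.", "e.g.", "i.e.", "cf.", "dr.", "no.",
    "approx.", "ca.", "resp.", "eq.", "eqs.", "ref.", "refs.",
)

_BOUNDARY_RE = re.compile(r"(?<=[.?!])\s+(?=[A-Z0-9])")


def split_sentences(raw_text: str) -> list[str]:
    """Deterministic rule-based sentence segmentation.

    Splits on ``.``, ``?`` or ``!`` followed by whitespace and an uppercase
    letter or digit, except when the period terminates a protected
    abbreviation (``et al.``, ``Fig.``, ``vs.`` ...).  Never returns empty
    strings; empty input gives an empty list.
    """
    text = raw_text.strip()
    if not text:
        return []
    pieces: list[str] = []
    start = 0
    for m in _BOUNDARY_RE.finditer(text):
        prefix = text[: m.start()].rstrip().lower()
        if any(prefix.endswith(a) for a in _ABBREVIATIONS):
            continue
        piece = text[start : m.start()].strip()
        if piece:
            pieces.append(piece)
        start = m.end()
    tail = text[start:].strip()
    if tail:
        pieces.append(tail)
    return pieces


def _sentences(texts: Iterable[str], start: int = 0) -> list[Sentence]:
    out = []
    pos = start
    for t in texts:
        out.append(Sentence(position=pos, text=t))
        pos += 1
    return out


# ---------------------------------------------------------------------------
# XML dialect
# ---------------------------------------------------------------------------

_DROP_TAGS = {"table-wrap", "fig", "table", "graphic"}


def _collect_paragraph_text(sec_el: etree._Element) -> list[str]:
    """Running text of a <sec>, skipping table/figure wrappers."""
    texts = []
    for p in sec_el.iterchildren("p"):
        # strip dropped wrappers nested inside the paragraph
        for tag in _DROP_TAGS:
            for el in p.findall(f".//{tag}"):
                el.getparent().remove(el)
        t = " ".join("".join(p.itertext()).split())
        if t:
            texts.append(t)
    return texts


def read_article(path: str | Path, format: str = "xml") -> Article:
    """Read an article from ``path`` in the ``xml`` or ``text`` dialect.

    Sections are labeled by their declared titles (case-insensitive:
    background/introduction -> INTRO, methods -> METHODS, and so on, anything
    else -> OTHER).  Table and figure content is dropped.  Raises
    :class:`ArticleStructureError` if the title, abstract or body is missing,
    and a parse error (with line number) for malformed XML.
    """
    path = Path(path)
    if format == "xml":
        return _read_article_xml(path)
    if format == "text":
        return _read_article_text(path)
    raise ValueError(f"unknown article format {format!r}")


def _read_article_xml(path: Path) -> Article:
    tree = etree.parse(str(path))  # raises XMLSyntaxError with line number
    root = tree.getroot()
    doc_id = root.get("id") or path.stem

    title_el = root.find(".//article-title")
    abstract_el = root.find(".//abstract")
    body_el = root.find(".//body")
    for part, el in (("title", title_el), ("abstract", abstract_el), ("body", body_el)):
        if el is None:
            raise ArticleStructureError(f"article {doc_id!r}: missing {part}")

    title_text = " ".join("".join(title_el.itertext()).split())
    abstract_text = " ".join("".join(abstract_el.itertext()).split())

    article = Article(doc_id=doc_id)
    article.title = _sentences(split_sentences(title_text))
    article.abstract = _sentences(split_sentences(abstract_text))

    pos = 0
    for sec_el in body_el.iterchildren("sec"):
        name_el = sec_el.find("title")
        name = "".join(name_el.itertext()).strip() if name_el is not None else ""
        sents: list[str] = []
        for para in _collect_paragraph_text(sec_el):
            sents.extend(split_sentences(para))
        section = Section(label=label_for_section_name(name), name=name)
        section.sentences = _sentences(sents, start=pos)
        pos += len(section.sentences)
        article.body.append(section)

    article.validate()
    return article


def write_article(article: Article, path: str | Path, format: str = "xml") -> None:
    """Write an article in the requested dialect (UTF-8)."""
    path = Path(path)
    if format == "xml":
        root = etree.Element("article", id=article.doc_id)
        front = etree.SubElement(root, "front")
        etree.SubElement(front, "article-title").text = " ".join(
            s.text for s in article.title
        )
        etree.SubElement(front, "abstract").text = " ".join(
            s.text for s in article.abstract
        )
        body = etree.SubElement(root, "body")
        for sec in article.body:
            sec_el = etree.SubElement(body, "sec")
            etree.SubElement(sec_el, "title").text = sec.name
            for s in sec.sentences:
                etree.SubElement(sec_el, "p").text = s.text
        path.write_bytes(
            etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8")
        )
    elif format == "text":
        lines = [f"# DOC: {article.doc_id}", "# TITLE:"]
        lines += [s.text for s in article.title]
        lines.append("# ABSTRACT:")
        lines += [s.text for s in article.abstract]
        for sec in article.body:
            lines.append(f"# SECTION: {sec.name}")
            lines += [s.text for s in sec.sentences]
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown article format {format!r}")


def _read_article_text(path: Path) -> Article:
    article = Article(doc_id=path.stem)
    part = None  # "title" | "abstract" | Section
    pos = 0
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("# DOC:"):
            article.doc_id = line.split(":", 1)[1].strip()
        elif line.startswith("# TITLE"):
            part = "title"
        elif line.startswith("# ABSTRACT"):
            part = "abstract"
        elif line.startswith("# SECTION:"):
            name = line.split(":", 1)[1].strip()
            part = Section(label=label_for_section_name(name), name=name)
            article.body.append(part)
        elif line.startswith("#"):
            raise ArticleStructureError(f"{path}:{lineno}: unknown header {line!r}")
        elif part == "title":
            article.title.append(Sentence(len(article.title), line))
        elif part == "abstract":
            article.abstract.append(Sentence(len(article.abstract), line))
        elif isinstance(part, Section):
            part.sentences.append(Sentence(pos, line))
            pos += 1
        else:
            raise ArticleStructureError(f"{path}:{lineno}: text before any header")
    for name, val in (("title", article.title), ("abstract", article.abstract)):
        if not val:
            raise ArticleStructureError(f"article {article.doc_id!r}: missing {name}")
    article.validate()
    return article


# ---------------------------------------------------------------------------
# gold indexing
# ---------------------------------------------------------------------------

GoldIndex = dict[str, set[str]]


def read_gold(path: str | Path) -> GoldIndex:
    """Read a two-column gold file ``doc_id<TAB>MeSH heading``.

    Repeated lines are deduplicated; heading case is preserved exactly.
    """
    gold: GoldIndex = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) != 2 or not cols[0] or not cols[1]:
                raise GoldFormatError(f"{path}:{lineno}: expected 2 tab-separated columns")
            gold.setdefault(cols[0], set()).add(cols[1])
    return gold


def write_gold(gold: GoldIndex, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc_id in sorted(gold):
            for heading in sorted(gold[doc_id]):
                fh.write(f"{doc_id}\t{heading}\n")
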