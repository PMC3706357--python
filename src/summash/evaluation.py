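"""Indexing and summary evaluation: set metrics, ranking metrics, ROUGE.

Set-based evaluation compares predicted MeSH heading sets with the gold
indexing: micro averaging pools true/false positives over all documents and
headings, macro averaging takes the unweighted mean of per-heading
precision/recall/F1 over the universe of headings seen in gold or
predictions.  Per-branch tables add each heading's counts to every MeSH
tree branch (letter code) it belongs to.

Ranking evaluation follows trec_eval conventions: average precision,
interpolated precision at recall 0, precision at a cutoff; documents with
empty gold are excluded from the means.

Summary evaluation uses natively implemented recall-oriented ROUGE-2
(bigrams) and ROUGE-SU4 (unigrams plus skip-bigrams with at most four
intervening tokens), with lowercase alphanumeric tokenization, no stemming
and no stopword removal.  :func:`tune_weights` grid-searches the
concept-frequency summarizer weights against the articles' abstracts.
"""

from __future__ import annotations

import itertools
import logging
import re
from collections import Counter
from dataclasses import dataclass, field

from .cf_summarizer import CFWeights, summarize_cf
from .corpus_io import Article, GoldIndex
from .indexing import IndexingResult
from .knowledge import KnowledgeSource

logger = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    """Set-retrieval counts; ``positives`` is the gold count, so
    fn = positives - tp."""

    positives: int = 0
    tp: int = 0
    fp: int = 0

    @property
    def fn(self) -> int:
        return self.positives - self.tp

    def add(self, other: "ConfusionCounts") -> None:
        self.positives += other.positives
        self.tp += other.tp
        self.fp += other.fp


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def micro_metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """(precision, recall, F1) from pooled counts; 0/0 conventions to 0."""
    p = _safe_div(c.tp, c.tp + c.fp)
    r = _safe_div(c.tp, c.positives)
    f1 = _safe_div(2 * c.tp, 2 * c.tp + c.fp + c.fn)
    return p, r, f1


def macro_metrics(per_heading: dict[str, ConfusionCounts]) -> tuple[float, float, float]:
    """Unweighted mean of per-heading precision/recall/F1."""
    if not per_heading:
        raise ValueError("macro average needs a nonempty heading universe")
    triples = [micro_metrics(c) for c in per_heading.values()]
    n = len(triples)
    return tuple(sum(t[i] for t in triples) / n for i in range(3))  # type: ignore[return-value]


def confusion_by_heading(
    predictions: dict[str, set[str]], gold: GoldIndex
) -> dict[str, ConfusionCounts]:
    """Per-heading counts over the universe gold ∪ predicted."""
    out: dict[str, ConfusionCounts] = {}
    for doc_id in set(predictions) | set(gold):
        pred = predictions.get(doc_id, set())
        gld = gold.get(doc_id, set())
        for h in pred | gld:
            c = out.setdefault(h, ConfusionCounts())
            if h in gld:
                c.positives += 1
                if h in pred:
                    c.tp += 1
            elif h in pred:
                c.fp += 1
    return out


def branch_aggregate(
    per_heading: dict[str, ConfusionCounts], mesh_tree: dict[str, set[str]]
) -> dict[str, ConfusionCounts]:
    """Add each heading's counts to every branch letter among its tree
    numbers; headings without tree numbers are skipped with a warning."""
    out: dict[str, ConfusionCounts] = {}
    for heading, counts in per_heading.items():
        trees = mesh_tree.get(heading, set())
        if not trees:
            logger.warning("heading %r has no tree number; skipped in branch table", heading)
            continue
        for branch in {t[0] for t in trees}:
            out.setdefault(branch, ConfusionCounts()).add(counts)
    return out


# ---------------------------------------------------------------------------
# ranking metrics (trec_eval conventions)
# ---------------------------------------------------------------------------


def average_precision(ranked: list[str], gold: set[str]) -> float:
    """AP over a duplicate-free ranked list; unretrieved gold contribute 0."""
    if len(set(ranked)) != len(ranked):
        raise ValueError("ranked list must be duplicate-free")
    if not gold:
        raise ValueError("average_precision undefined for empty gold")
    hits = 0
    total = 0.0
    for k, h in enumerate(ranked, 1):
        if h in gold:
            hits += 1
            total += hits / k
    return total / len(gold)


def precision_at_k(ranked: list[str], gold: set[str], k: int) -> float:
    if k < 1:
        raise ValueError("k must be >= 1")
    return len(set(ranked[:k]) & gold) / k


def iprec_at_0(ranked: list[str], gold: set[str]) -> float:
    """Interpolated precision at recall 0: max over cutoffs of P@k."""
    best = 0.0
    hits = 0
    for k, h in enumerate(ranked, 1):
        if h in gold:
            hits += 1
        best = max(best, hits / k)
    return best


def ranking_metrics(
    results: dict[str, IndexingResult], gold: GoldIndex, k: int = 5
) -> tuple[float, float, float]:
    """(MAP, mean interpolated P@0R, mean P@k) over documents with gold;
    documents with empty gold are skipped."""
    aps, p0s, pks = [], [], []
    for doc_id, res in sorted(results.items()):
        gld = gold.get(doc_id, set())
        if not gld:
            logger.info("document %s has no gold headings; skipped in ranking means", doc_id)
            continue
        ranked = res.headings()
        aps.append(average_precision(ranked, gld))
        p0s.append(iprec_at_0(ranked, gld))
        pks.append(precision_at_k(ranked, gld, k))
    if not aps:
        return 0.0, 0.0, 0.0
    n = len(aps)
    return sum(aps) / n, sum(p0s) / n, sum(pks) / n


# ---------------------------------------------------------------------------
# ROUGE
# ---------------------------------------------------------------------------

_ROUGE_TOKEN_RE = re.compile(r"[a-z0-9]+")


def rouge_tokenize(text: str) -> list[str]:
    return _ROUGE_TOKEN_RE.findall(text.lower())


def _clipped_recall(peer_units: Counter, model_units: Counter) -> float:
    total = sum(model_units.values())
    if total == 0:
        return 0.0
    match = sum(min(n, peer_units[u]) for u, n in model_units.items())
    return match / total


def rouge2(peer_tokens: list[str], model_tokens: list[str]) -> float:
    """Recall of model bigrams covered by the peer (clipped counts)."""
    if len(model_tokens) < 2:
        return 0.0
    bigrams = lambda toks: Counter(zip(toks, toks[1:]))
    return _clipped_recall(bigrams(peer_tokens), bigrams(model_tokens))


def _su4_units(tokens: list[str]) -> Counter:
    units: Counter = Counter(tokens)
    for i, a in enumerate(tokens):
        for b in tokens[i + 1 : i + 6]:  # skip distance <= 4 intervening
            units[(a, b)] += 1
    return units


def rouge_su4(peer_tokens: list[str], model_tokens: list[str]) -> float:
    """Recall over unigrams + ordered skip-bigrams with gap <= 4."""
    return _clipped_recall(_su4_units(peer_tokens), _su4_units(model_tokens))


def rouge_scores(peer_text: str, model_text: str) -> tuple[float, float]:
    peer, model = rouge_tokenize(peer_text), rouge_tokenize(model_text)
    return rouge2(peer, model), rouge_su4(peer, model)


# ---------------------------------------------------------------------------
# weight tuning
# ---------------------------------------------------------------------------


def _grid(step: float) -> list[float]:
    n = round(1 / step)
    return [round(i * step, 10) for i in range(n + 1)]


def tune_weights(
    ks: KnowledgeSource,
    dev_articles: list[Article],
    grid_step: float = 0.1,
    metric: str = "mean",
    compression_rate: float = 0.3,
    param_values: dict[str, list[float]] | None = None,
) -> CFWeights:
    """Exhaustive grid search of the CF summarizer weights.

    Every combination of (alpha, beta, gamma, delta) and (sigma, rho, theta)
    on the grid is scored by the mean ROUGE of the generated summaries
    against the articles' abstracts; the argmax is returned, ties going to
    the lexicographically first parameter vector.  ``param_values`` may pin
    or restrict individual parameters to keep the grid tractable.
    """
    if not dev_articles:
        raise ValueError("dev corpus must be nonempty")
    if metric not in ("rouge2", "rouge_su4", "mean"):
        raise ValueError(f"unknown metric {metric!r}")
    names = ("alpha", "beta", "gamma", "delta", "sigma", "rho", "theta")
    values = {n: _grid(grid_step) for n in names}
    if param_values:
        values.update({k: list(v) for k, v in param_values.items()})

    # map once; summarize_cf is then called premapped per candidate
    from .concept_mapping import map_article

    for art in dev_articles:
        map_article(ks, art)
    abstracts = {
        a.doc_id: " ".join(s.text for s in a.abstract) for a in dev_articles
    }
    body_texts = {
        a.doc_id: {s.position: s.text for s in a.body_sentences()} for a in dev_articles
    }

    best: tuple[float, tuple[float, ...]] | None = None
    for combo in itertools.product(*(values[n] for n in names)):
        w = CFWeights(*combo, compression_rate=compression_rate)
        total = 0.0
        for art in dev_articles:
            positions = summarize_cf(ks, art, w, premapped=True)
            peer = " ".join(body_texts[art.doc_id][p] for p in positions)
            r2, su4 = rouge_scores(peer, abstracts[art.doc_id])
            total += {"rouge2": r2, "rouge_su4": su4, "mean": (r2 + su4) / 2}[metric]
        score = total / len(dev_articles)
        if best is None or score > best[0]:
            best = (score, combo)
    return CFWeights(*best[1], compression_rate=compression_rate)


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------


@dataclass
class EvalReport:
    """Micro/macro set metrics, per-heading and per-branch tables, ranking."""

    micro: tuple[float, float, float]
    macro: tuple[float, float, float]
    counts: ConfusionCounts
    per_heading: dict[str, ConfusionCounts]
    per_branch: dict[str, ConfusionCounts]
    map: float = 0.0
    p_at_0r: float = 0.0
    p_at_5: float = 0.0
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def row(c: ConfusionCounts) -> dict:
            p, r, f1 = micro_metrics(c)
            return {
                "positives": c.positives, "tp": c.tp, "fp": c.fp,
                "precision": p, "recall": r, "f1": f1,
            }

        return {
            "positives": self.counts.positives,
            "tp": self.counts.tp,
            "fp": self.counts.fp,
            "micro": dict(zip(("precision", "recall", "f1"), self.micro)),
            "macro": dict(zip(("precision", "recall", "f1"), self.macro)),
            "ranking": {"map": self.map, "p_at_0r": self.p_at_0r, "p_at_5": self.p_at_5},
            "per_heading": {h: row(c) for h, c in sorted(self.per_heading.items())},
            "per_branch": {b: row(c) for b, c in sorted(self.per_branch.items())},
            **self.extras,
        }

    def to_tsv(self) -> str:
        lines = ["row\tpositives\ttp\tfp\tmicro_p\tmicro_r\tmicro_f1\tmacro_p\tmacro_r\tmacro_f1"]
        lines.append(
            "overall\t%d\t%d\t%d\t%.4f\t%.4f\t%.4f\t%.4f\t%.4f\t%.4f"
            % (self.counts.positives, self.counts.tp, self.counts.fp, *self.micro, *self.macro)
        )
        for branch, c in sorted(self.per_branch.items()):
            p, r, f1 = micro_metrics(c)
            lines.append(
                "branch:%s\t%d\t%d\t%d\t%.4f\t%.4f\t%.4f\t\t\t" % (branch, c.positives, c.tp, c.fp, p, r, f1)
            )
        lines.append("ranking\tmap=%.4f\tp_at_0r=%.4f\tp_at_5=%.4f\t\t\t\t\t\t" % (self.map, self.p_at_0r, self.p_at_5))
        return "\n".join(lines) + "\n"


def evaluate_indexing(
    results: dict[str, IndexingResult],
    gold: GoldIndex,
    mesh_tree: dict[str, set[str]] | None = None,
) -> EvalReport:
    """Full evaluation of indexing results against gold headings."""
    predictions = {d: r.heading_set() for d, r in results.items()}
    per_heading = confusion_by_heading(predictions, gold)
    totals = ConfusionCounts()
    for c in per_heading.values():
        totals.add(c)
    per_branch = branch_aggregate(per_heading, mesh_tree or {})
    mapv, p0, p5 = ranking_metrics(results, gold)
    return EvalReport(
        micro=micro_metrics(totals),
        macro=macro_metrics(per_heading) if per_heading else (0.0, 0.0, 0.0),
        counts=totals,
        per_heading=per_heading,
        per_branch=per_branch,
        map=mapv,
        p_at_0r=p0,
        p_at_5=p5,
    )
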