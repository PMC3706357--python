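# Methods

This note documents the models implemented in `summash`, the free design
choices that had to be frozen, and what the synthetic fixtures do and do not
show about behavior on real literature.

## Document model and segmentation

An article is a title, an abstract and an ordered body of labeled sections
(`INTRO`, `METHODS`, `RESULTS`, `DISCUSSION`, `CONCLUSIONS`, `OTHER`).
Section titles are mapped case-insensitively by substring ("materials and
methods" → `METHODS`); unknown titles map to `OTHER`, which the position
score treats as zero. Table and figure content is excluded from the running
text. Sentence segmentation is a frozen deterministic rule — split at
`[.?!]` followed by whitespace and an uppercase letter or digit, protecting
a fixed abbreviation list (`et al.`, `Fig.`, `vs.`, `e.g.`, …) — so that
sentence counts, and hence compression-rate arithmetic, are reproducible.
Any segmenter disagrees with any other at the margins; counts derived from
real corpora with other tools will differ slightly.

## Knowledge source

The UMLS-like knowledge source is a self-contained JSON file: concepts with
semantic types, a single-rooted is_a DAG, undirected *other related* /
*associated with* edges, a surface lexicon (term → ordered candidate
concepts), a set of generic semantic types to discard, and a concept→MeSH
map with tree numbers. Conventions that the source material leaves open and
that are frozen here:

* **Depth** — root has depth 1; under multiple inheritance a concept's
  depth is the shortest is_a path from the root. This keeps is_a edge
  weights `depth(parent)/depth(child)` inside (0, 1] and well-defined.
* **"Two upper levels"** — the hypernym closure removes concepts of depth
  ≤ 2, i.e. the root counts as the first level. Removal is applied when the
  closure is computed, before any graph merging.
* **Restrict-to-MeSH** — realized as an explicit lookup table rather than
  the published semantic-relation algorithm; adequate for experiments where
  the table is the ground truth, a documented stand-in otherwise.
* **Generic semantic types** — an explicit list in the knowledge file; no
  canonical list is bundled.

## Concept mapping

Dictionary matching replaces a MetaMap-style analyzer: a case-insensitive
longest-match-first scan over alphanumeric token boundaries; accepted
matches never overlap (the scan resumes after each match). Ambiguous terms
are resolved by a document-level heuristic standing in for corpus-trained
word-sense disambiguation: the candidate with the most *unambiguous*
mentions elsewhere in the same document wins; ties fall back to lexicon
order, then concept id. The matcher does no stemming — the lexicon must
list variants — and models no mapping scores. These substitutions make the
pipeline deterministic and auditable, at the cost of any claim to MetaMap's
coverage on real text.

## Graph summarizer

Per-sentence hypernym closures are merged into a document graph; *other
related* and *associated with* edges are then added at weight 1 between
**leaf** vertices, a leaf being a vertex with no is_a child *within the
document graph*. Salience is the sum of incident edge weights (degree-based,
not an iterative fixpoint). Free choices frozen here:

* **Hub count** — the number of hub vertices is `max(1, round(hub_ratio ·
  |V|))` with `hub_ratio` defaulting to 0.2; the original formulation gives
  only "the n most salient".
* **HVS formation** — hubs are scanned in (salience desc, id asc) order;
  each joins the existing HVS to which its total edge weight is maximal and
  positive (ties → earliest HVS), otherwise seeds a new one. This greedy
  rule realizes "strongly connected concept sets" deterministically.
* **Assignment of non-hubs** — a single pass in the same global order, each
  vertex joining the cluster with maximal positive connectivity to the
  members accumulated so far; assignments are visible to later vertices.
  Vertices with no positive connectivity stay unclustered and contribute no
  votes. A fixpoint iteration would be equally defensible; the single pass
  was chosen for reproducibility.
* **Selection** — summary size is `ceil(rate · n)`; ties in sentence score
  go to the earlier sentence. Top-N selection is stable, so summaries nest
  across rates (15% ⊆ 30% ⊆ 50%).

On graphs of up to 10 vertices the clustering and scoring are verified
against an independent brute-force implementation of the same rules.

## Concept-frequency summarizer

`Score = α·CF + β·Title + γ·Abstract + δ·Position`, with `Position =
σ·[Intro] + ρ·[Methods/Results/Discussion] + θ·[Conclusions]`. The CF term
sums, over concept occurrences in the sentence, the concept's body-wide
occurrence count; repeated occurrences in one sentence each count. **CF is
normalized by the per-document maximum raw score** — the most consequential
free choice in the module: the similarity and position terms live in
[0, 1], and an unnormalized CF (which grows with document length) would
swamp them in the weighted sum. Title/Abstract similarities are Jaccard
indices between the sentence's concept set and the concept set of the whole
title/abstract (not a per-sentence alignment). Defaults α=0.5, β=0.1,
γ=0.2, δ=0.2, σ=0.2, ρ=0.7, θ=0.1 are the tuned values for compression
rates 15/30/50%. No sentence-length normalization is applied, so the method
retains its known bias toward long sentences.

`tune_weights` grid-searches all seven weights against the articles'
abstracts (ROUGE-2, ROUGE-SU4 or their mean), step 0.1 by default. The full
7-dimensional 0.1-grid has ~19 M points; `param_values` lets callers pin or
coarsen individual parameters, which the CLI and tests do. Ties return the
lexicographically first parameter vector.

## Indexers

* **Dictionary indexer** — concepts of the text, restricted to MeSH;
  confidence is a heading's supporting mention count divided by the
  maximum; ties alphabetical.
* **k-NN voter** — TF-IDF (lowercased alphanumeric tokens) cosine retrieval
  of the `k` most similar gold-indexed citations (ties → lexicographic doc
  id, the query's own id excluded); headings with ≥ `vote_min` votes are
  kept at confidence votes/k, ranked by (votes, mean supporting-neighbour
  similarity, heading). Defaults k=10, vote_min=4 mirror the production
  voting rule this component emulates; the retrieval model is plain TF-IDF
  cosine, not the citation-network similarity of the original system.
* **Merger** — `λ·conf_a + (1−λ)·conf_b` with absent headings at 0 and
  zero-confidence entries dropped; λ defaults to 0.5. An optional
  trigger-rule TSV (`pattern<TAB>heading`) can force headings (confidence
  1.0) from surface text after merging; no rule set is bundled and the
  mechanism is off by default.

## Evaluation

Micro metrics pool tp/fp/fn over all (document, heading) pairs; macro
metrics average per-heading P/R/F1 over the universe of headings appearing
in gold **or** predictions (an averaging-universe choice that had to be
fixed; using gold-only would ignore spurious headings entirely). All 0/0
cases are defined as 0. Per-branch tables add a heading's counts to every
tree branch letter it belongs to, so branch totals can exceed micro totals.
Ranking metrics follow trec_eval conventions: AP with unretrieved gold
counting 0, interpolated precision at recall 0 as the max precision over
cutoffs, P@k divided by k even for shorter lists; documents with empty gold
are excluded from the means. ROUGE-2 and ROUGE-SU4 are implemented natively
as clipped-count recall against a single model summary, with lowercase
alphanumeric tokenization, no stemming and no stopword removal; scores are
therefore not numerically interchangeable with the classic Perl toolkit's
output, though they agree on identity and ordering in the cases tested.

## Synthetic fixtures

The generator emulates the *structure* of an open-access evaluation corpus:
sectioned articles whose bodies are 16–40 sentences by default (scalable
toward realistic lengths, mean ≈ 178), 1–3 planted topics per article with
frequency-weighted core terms (so a Luhn-style CF signal exists), titles
and abstracts built from each article's most frequent terms (valid ROUGE
models, informative title/abstract similarity), gold headings equal to the
MeSH images of the planted topics' core concepts, and a held-out reference
corpus for the k-NN voter. The knowledge source has topic subtrees of depth
≥ 5 (exercising upper-level removal), a configurable share of ambiguous
terms, generic-type decoys, and MeSH tree numbers spanning several branch
letters. All randomness flows through one seeded generator; outputs are
byte-identical across runs.

The sentences are token salads: no syntax, discourse structure, anaphora,
acronym ambiguity or MetaMap error modes. Passing tests therefore establish
the *mechanics* — determinism, selection rules, metric arithmetic, the
relative behavior of the indexers on separable topics — not indexing
quality on real articles, which additionally depends on licensed
vocabularies and the components these modules stand in for.

## Problem sizes

Default experiment scale is tens of articles with bodies of a few dozen
sentences and a reference corpus of 30 citations; the full pipeline runs in
seconds and the property suite (including the brute-force clustering
oracle on random ≤10-vertex graphs and the 100-sentence weighted-sum check)
in well under a minute. `FixtureSpec` accepts larger shapes for profiling.

## Known limitations

* Dictionary matching and the frequency disambiguation heuristic are
  deliberate simplifications; absolute indexing scores on real corpora are
  not reproducible with them.
* The k-NN voter's retrieval model is TF-IDF cosine, not a related-citations
  network.
* Macro averaging and CF normalization are documented choices among several
  defensible readings; both are isolated behind single functions.
* ROUGE numbers are internally consistent but not toolkit-identical.
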