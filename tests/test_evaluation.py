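import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from summash.cf_summarizer import CFWeights
from summash.evaluation import (
    ConfusionCounts,
    average_precision,
    branch_aggregate,
    confusion_by_heading,
    evaluate_indexing,
    iprec_at_0,
    macro_metrics,
    micro_metrics,
    precision_at_k,
    rouge2,
    rouge_scores,
    rouge_su4,
    rouge_tokenize,
    tune_weights,
)
from summash.indexing import IndexingResult

from .conftest import make_article
from .test_cf_summarizer import word_ks


class TestMicroMacro:
    def test_degenerate_zero_counts(self):
        assert micro_metrics(ConfusionCounts(positives=5, tp=0, fp=0)) == (0, 0, 0)

    def test_f1_matches_harmonic_mean(self):
        c = ConfusionCounts(positives=10, tp=6, fp=4)
        p, r, f1 = micro_metrics(c)
        assert f1 == pytest.approx(2 * p * r / (p + r))

    def test_macro_is_unweighted_mean(self):
        per = {
            "A": ConfusionCounts(positives=1, tp=1, fp=0),   # P=1
            "B": ConfusionCounts(positives=2, tp=1, fp=1),   # P=0.5
        }
        assert macro_metrics(per)[0] == pytest.approx(0.75)

    def test_single_heading_macro_equals_micro(self):
        per = {"A": ConfusionCounts(positives=3, tp=2, fp=1)}
        assert macro_metrics(per) == pytest.approx(micro_metrics(per["A"]))

    def test_macro_matches_arithmetic_oracle(self):
        rng = random.Random(3)
        per = {
            f"H{i}": ConfusionCounts(
                positives=rng.randint(1, 9), tp=0, fp=rng.randint(0, 5)
            )
            for i in range(5)
        }
        for c in per.values():
            c.tp = rng.randint(0, c.positives)
        got = macro_metrics(per)
        triples = [micro_metrics(c) for c in per.values()]
        for i in range(3):
            assert got[i] == pytest.approx(sum(t[i] for t in triples) / 5)

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError):
            macro_metrics({})

    def test_confusion_by_heading(self):
        predictions = {"p1": {"A", "B"}, "p2": {"A"}}
        gold = {"p1": {"A"}, "p2": {"C"}}
        per = confusion_by_heading(predictions, gold)
        assert per["A"].tp == 1 and per["A"].fp == 1 and per["A"].positives == 1
        assert per["B"].fp == 1 and per["B"].positives == 0
        assert per["C"].positives == 1 and per["C"].tp == 0


class TestBranchAggregate:
    def test_multi_branch_heading_counts_in_both(self):
        per = {"Cohort-like": ConfusionCounts(positives=3, tp=2, fp=1)}
        tree = {"Cohort-like": {"E03.1", "N05.2"}}
        branches = branch_aggregate(per, tree)
        assert branches["E"].tp == 2 and branches["N"].tp == 2

    def test_single_branch_equals_totals(self):
        per = {
            "A1": ConfusionCounts(positives=2, tp=1, fp=1),
            "A2": ConfusionCounts(positives=1, tp=1, fp=0),
        }
        tree = {"A1": {"C01.1"}, "A2": {"C02.5"}}
        branches = branch_aggregate(per, tree)
        assert set(branches) == {"C"}
        assert (branches["C"].positives, branches["C"].tp, branches["C"].fp) == (3, 2, 1)

    def test_matches_double_loop_oracle(self):
        rng = random.Random(1)
        headings = [f"H{i}" for i in range(3)]
        per = {
            h: ConfusionCounts(positives=rng.randint(0, 5), tp=0, fp=rng.randint(0, 5))
            for h in headings
        }
        tree = {"H0": {"A01", "B01"}, "H1": {"B02"}, "H2": {"C03", "A02"}}
        got = branch_aggregate(per, tree)
        expected: dict[str, list[int]] = {}
        for h, trees in tree.items():
            for letter in {t[0] for t in trees}:
                acc = expected.setdefault(letter, [0, 0, 0])
                acc[0] += per[h].positives
                acc[1] += per[h].tp
                acc[2] += per[h].fp
        assert {
            b: (c.positives, c.tp, c.fp) for b, c in got.items()
        } == {b: tuple(v) for b, v in expected.items()}

    def test_heading_without_tree_skipped(self, caplog):
        per = {"Ghost": ConfusionCounts(positives=1, tp=1, fp=0)}
        assert branch_aggregate(per, {}) == {}

    def test_branch_tp_at_least_micro_tp(self, toy_world):
        ks, _, gold, _ = toy_world
        predictions = {d: set(h) for d, h in gold.items()}
        per = confusion_by_heading(predictions, gold)
        branches = branch_aggregate(per, ks.mesh_tree)
        micro_tp = sum(c.tp for c in per.values())
        assert sum(c.tp for c in branches.values()) >= micro_tp


class TestRankingMetrics:
    def test_ap_hand_case(self):
        assert average_precision(["rel1", "non", "rel2"], {"rel1", "rel2"}) == pytest.approx(
            (1 / 1 + 2 / 3) / 2
        )

    def test_perfect_ranking(self):
        assert average_precision(["a", "b"], {"a", "b"}) == 1.0

    def test_nothing_retrieved(self):
        assert average_precision(["x", "y"], {"a"}) == 0.0

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError):
            average_precision(["a", "a"], {"a"})

    def test_precision_at_k(self):
        ranked = ["a", "b", "c", "d", "e"]
        assert precision_at_k(ranked, {"a", "c", "e"}, 5) == pytest.approx(0.6)
        assert precision_at_k(["a"], {"a", "b"}, 5) == pytest.approx(0.2)

    def test_iprec_at_0(self):
        assert iprec_at_0(["rel", "non"], {"rel"}) == 1.0
        assert iprec_at_0(["non", "rel"], {"rel"}) == 0.5
        assert iprec_at_0(["non"], {"rel"}) == 0.0

    def test_ap_one_iff_gold_ranked_first(self):
        assert average_precision(["g1", "g2", "n"], {"g1", "g2"}) == 1.0
        assert average_precision(["g1", "n", "g2"], {"g1", "g2"}) < 1.0


class TestRouge:
    def test_bigram_hand_case(self):
        assert rouge2("a b c d".split(), "a b x d".split()) == pytest.approx(1 / 3)

    def test_identity_is_one(self):
        toks = "p53 activates the apoptosis cascade".split()
        assert rouge2(toks, toks) == 1.0
        assert rouge_su4(toks, toks) == 1.0

    def test_disjoint_vocabulary_zero(self):
        assert rouge2("a b".split(), "x y".split()) == 0.0
        assert rouge_su4("a b".split(), "x y".split()) == 0.0

    def test_short_model_zero(self):
        assert rouge2("a b".split(), ["a"]) == 0.0

    def test_su4_hand_case(self):
        # model "a b c": units a, b, c, (a,b), (a,c), (b,c); peer "a c"
        # matches a, c, (a,c) -> 3/6
        assert rouge_su4("a c".split(), "a b c".split()) == pytest.approx(0.5)

    def test_empty_peer_zero(self):
        assert rouge_su4([], "a b c".split()) == 0.0

    def test_tokenizer_lowercases_and_splits_nonalnum(self):
        assert rouge_tokenize("P53-mediated, Apoptosis!") == ["p53", "mediated", "apoptosis"]

    @given(st.lists(st.sampled_from("abcd"), min_size=2, max_size=8))
    @settings(max_examples=40, derandomize=True)
    def test_identity_property(self, toks):
        assert rouge2(toks, toks) == 1.0
        assert rouge_su4(toks, toks) == 1.0


class TestTuneWeights:
    def test_corner_grid_size_and_types(self):
        ks = word_ks(["alpha", "beta"])
        art = make_article(
            ["alpha beta here.", "nothing at all."],
            title="alpha.", abstract=("alpha beta here.",),
        )
        w = tune_weights(ks, [art], grid_step=1.0, compression_rate=0.5)
        assert isinstance(w, CFWeights)

    def test_recovers_known_optimum(self):
        ks = word_ks(["alpha", "beta", "gamma"])
        # abstract copied verbatim into the body; concept-rich sentences are
        # exactly the abstract sentences, so a CF-only weighting scores 1.0
        abstract = ("alpha beta gamma now.", "beta gamma alpha then.")
        art = make_article(
            [abstract[0], "filler text one.", abstract[1], "filler text two."],
            title="alpha.", abstract=abstract,
        )
        w = tune_weights(
            ks,
            [art],
            compression_rate=0.5,
            param_values={
                "alpha": [0.0, 1.0], "beta": [0.0], "gamma": [0.0, 1.0],
                "delta": [0.0], "sigma": [0.0], "rho": [0.0], "theta": [0.0],
            },
        )
        from summash.cf_summarizer import summarize_cf

        positions = summarize_cf(ks, art, w, premapped=True)
        peer = " ".join(
            {s.position: s.text for s in art.body_sentences()}[p] for p in positions
        )
        r2, su4 = rouge_scores(peer, " ".join(abstract))
        assert positions == [0, 2]
        assert r2 == 1.0 and su4 == 1.0

    def test_empty_corpus_errors(self, chain_ks):
        with pytest.raises(ValueError):
            tune_weights(chain_ks, [])


class TestEvaluateIndexing:
    def test_report_shape_and_ranges(self, toy_world):
        ks, _, gold, _ = toy_world
        results = {
            d: IndexingResult(d, [(h, 1.0 - i * 0.01) for i, h in enumerate(sorted(hs))])
            for d, hs in gold.items()
        }
        report = evaluate_indexing(results, gold, ks.mesh_tree)
        assert report.micro == pytest.approx((1.0, 1.0, 1.0))
        for val in (*report.macro, report.map, report.p_at_0r, report.p_at_5):
            assert 0.0 <= val <= 1.0
        assert report.per_branch
        data = report.to_dict()
        assert set(data["micro"]) == {"precision", "recall", "f1"}
        assert report.to_tsv().startswith("row\t")
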