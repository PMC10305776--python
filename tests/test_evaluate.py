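"""Strict/lenient span matching and corpus scoring."""

import itertools

import networkx as nx
import pytest

from strokener.evaluate import agreement, indict_partition, match_spans, score_corpus
from strokener.simulate import (
    CorpusConfig,
    NoiseConfig,
    generate_corpus,
    perturb_annotations,
    split_patients,
)
from strokener.dictionary import compile_dictionary, predict
from strokener.standoff import AnnotatedDocument, EntitySpan


def span(s, e, lab="x"):
    return EntitySpan(s, e, lab, "?" * (e - s))


def doc(doc_id, text, spans):
    return AnnotatedDocument(
        doc_id, "p", "FDL", text,
        tuple(EntitySpan(s, e, lab, text[s:e]) for s, e, lab in spans),
    )


def max_matching_size(gold, pred, mode):
    """Independent oracle: maximum bipartite matching via networkx."""
    g = nx.Graph()
    g.add_nodes_from(("g", i) for i in range(len(gold)))
    g.add_nodes_from(("p", i) for i in range(len(pred)))
    for i, gs in enumerate(gold):
        for j, ps in enumerate(pred):
            if gs.label != ps.label:
                continue
            ok = (
                gs.start == ps.start and gs.end == ps.end
                if mode == "strict"
                else gs.overlap_chars(ps) > 0
            )
            if ok:
                g.add_edge(("g", i), ("p", j))
    return len(
        nx.bipartite.maximum_matching(g, top_nodes=[("g", i) for i in range(len(gold))])
    ) // 2


class TestMatchSpans:
    def test_worked_example_lenient_match_only(self):
        """Boundary-shifted prediction: a lenient but not a strict match."""
        gold = [span(11, 19, "warfarin")]
        pred = [span(8, 19, "warfarin")]
        lenient = match_spans(gold, pred, "lenient")
        strict = match_spans(gold, pred, "strict")
        assert (lenient.tp, lenient.fp, lenient.fn) == (1, 0, 0)
        assert (strict.tp, strict.fp, strict.fn) == (0, 1, 1)

    def test_identical_sets_fully_paired_in_both_modes(self):
        spans = [span(0, 4), span(10, 14, "y")]
        for mode in ("strict", "lenient"):
            m = match_spans(spans, list(spans), mode)
            assert m.tp == 2 and m.fp == m.fn == 0

    def test_one_to_one_with_two_predictions_on_one_gold(self):
        gold = [span(10, 20)]
        pred = [span(8, 15), span(15, 22)]
        m = match_spans(gold, pred, "lenient")
        assert (m.tp, m.fp, m.fn) == (1, 1, 0)

    def test_labels_must_match_even_leniently(self):
        m = match_spans([span(0, 5, "a")], [span(0, 5, "b")], "lenient")
        assert m.tp == 0 and m.fp == 1 and m.fn == 1

    def test_counts_partition_both_sides(self):
        gold = [span(0, 5), span(6, 9), span(20, 25, "y")]
        pred = [span(1, 4), span(30, 33)]
        for mode in ("strict", "lenient"):
            m = match_spans(gold, pred, mode)
            assert m.tp + m.fn == len(gold)
            assert m.tp + m.fp == len(pred)

    def test_strict_pairs_subset_of_lenient_pairs(self, small_corpus):
        preds = perturb_annotations(
            small_corpus, NoiseConfig(jitter_prob=0.5, deletion_prob=0.1), seed=9
        )
        for g, p in zip(small_corpus, preds):
            strict = set(match_spans(g.spans, p.spans, "strict").pairs)
            lenient = set(match_spans(g.spans, p.spans, "lenient").pairs)
            assert strict <= lenient

    def test_greedy_agrees_with_exhaustive_matching_on_small_documents(self):
        """Fixture documents with <=6 spans: greedy pair count equals the
        maximum bipartite matching, for hand-made and simulator inputs."""
        hand_cases = [
            ([span(10, 20)], [span(8, 15), span(15, 22)]),
            ([span(0, 5), span(5, 10)], [span(3, 7)]),
            ([span(0, 4), span(6, 9, "y")], [span(0, 4), span(6, 9, "y"), span(20, 24)]),
            ([span(0, 10), span(12, 20)], [span(9, 13), span(0, 3)]),
        ]
        for gold, pred in hand_cases:
            for mode in ("strict", "lenient"):
                assert match_spans(gold, pred, mode).tp == max_matching_size(gold, pred, mode)
        docs = generate_corpus(CorpusConfig(seed=21, n_patients=30, total_spans=300))
        noisy = perturb_annotations(
            docs, NoiseConfig(jitter_prob=0.7, deletion_prob=0.1, spurious_rate=0.5), seed=22
        )
        checked = 0
        for g, p in zip(docs, noisy):
            if len(g.spans) > 6 or len(p.spans) > 6:
                continue
            for mode in ("strict", "lenient"):
                assert match_spans(g.spans, p.spans, mode).tp == max_matching_size(
                    g.spans, p.spans, mode
                )
            checked += 1
        assert checked >= 10


class TestScoreCorpus:
    FIXTURE_GOLD = [
        doc("a", "aspirin and warfarin now", [(0, 7, "aspirin"), (12, 20, "warfarin")]),
        doc("b", "warfarin stopped, aspirin started", [(0, 8, "warfarin"), (18, 25, "aspirin")]),
        doc("c", "no medication change today", []),
    ]
    # predictions: doc a misses warfarin, hits aspirin exactly; doc b hits
    # warfarin with a boundary shift, false-positive aspirin twice; doc c one FP.
    FIXTURE_PRED = [
        doc("a", "aspirin and warfarin now", [(0, 7, "aspirin")]),
        doc("b", "warfarin stopped, aspirin started", [(0, 16, "warfarin"), (18, 25, "aspirin"), (26, 33, "aspirin")]),
        doc("c", "no medication change today", [(3, 13, "aspirin")]),
    ]

    def test_hand_counted_fixture_lenient(self):
        """Lenient hand count: aspirin TP=2 FP=2 FN=0; warfarin TP=1 FP=0 FN=1."""
        rep = score_corpus(self.FIXTURE_GOLD, self.FIXTURE_PRED, "lenient")
        asp = rep.per_label.loc["aspirin"]
        war = rep.per_label.loc["warfarin"]
        assert (asp.tp, asp.fp, asp.fn) == (2, 2, 0)
        assert (war.tp, war.fp, war.fn) == (1, 0, 1)
        assert rep.micro.precision == 3 / 5
        assert rep.micro.recall == 3 / 4
        # macro = mean of per-label metrics
        assert rep.macro.precision == pytest.approx((2 / 4 + 1 / 1) / 2)
        assert rep.macro.recall == pytest.approx((2 / 2 + 1 / 2) / 2)

    def test_hand_counted_fixture_strict(self):
        """Strictly the shifted warfarin prediction becomes FP+FN."""
        rep = score_corpus(self.FIXTURE_GOLD, self.FIXTURE_PRED, "strict")
        war = rep.per_label.loc["warfarin"]
        assert (war.tp, war.fp, war.fn) == (0, 1, 2)

    def test_micro_counts_are_sums_of_per_label_counts(self):
        rep = score_corpus(self.FIXTURE_GOLD, self.FIXTURE_PRED, "lenient")
        tp, fp, fn = rep.per_label[["tp", "fp", "fn"]].sum()
        assert rep.micro.precision == tp / (tp + fp)
        assert rep.micro.recall == tp / (tp + fn)

    def test_perfect_predictions_score_one(self, small_corpus):
        docs = small_corpus[:20]
        for mode in ("strict", "lenient"):
            rep = score_corpus(docs, docs, mode)
            assert rep.micro.f1 == rep.macro.f1 == 1.0

    def test_no_predictions_zero_convention(self):
        gold = [doc("a", "aspirin", [(0, 7, "aspirin")])]
        pred = [doc("a", "aspirin", [])]
        rep = score_corpus(gold, pred, "lenient")
        assert rep.micro.precision == 0.0 and rep.micro.recall == 0.0 and rep.micro.f1 == 0.0

    def test_swapping_sides_swaps_precision_and_recall(self, small_corpus):
        docs = small_corpus[:30]
        noisy = perturb_annotations(
            docs, NoiseConfig(deletion_prob=0.2, spurious_rate=0.5, jitter_prob=0.3), seed=5
        )
        for mode in ("strict", "lenient"):
            fwd = score_corpus(docs, noisy, mode)
            rev = score_corpus(noisy, docs, mode)
            assert fwd.micro.precision == pytest.approx(rev.micro.recall)
            assert fwd.micro.recall == pytest.approx(rev.micro.precision)

    def test_mismatched_document_ids_rejected(self):
        with pytest.raises(ValueError):
            score_corpus(self.FIXTURE_GOLD, self.FIXTURE_PRED[:2], "strict")


class TestAgreement:
    def test_identical_annotator_scores_one(self, small_corpus):
        rep = agreement(small_corpus[:10], small_corpus[:10], "strict")
        assert rep.micro.f1 == 1.0

    def test_half_missed_spans_give_half_recall(self):
        gold = [doc("a", "aspirin and warfarin", [(0, 7, "aspirin"), (12, 20, "warfarin")])]
        annot = [doc("a", "aspirin and warfarin", [(0, 7, "aspirin")])]
        assert agreement(annot, gold, "strict").micro.recall == 0.5


class TestInDictPartition:
    def test_hand_partitioned_fixture(self):
        train = [doc("t", "on aspirin today", [(3, 10, "aspirin")])]
        gold = [doc("a", "aspirin or coumadin", [(0, 7, "aspirin"), (11, 19, "warfarin")])]
        pred = [doc("a", "aspirin or coumadin", [(0, 7, "aspirin")])]
        r_in, r_out = indict_partition(train, gold, pred, "strict")
        assert r_in == 1.0 and r_out == 0.0

    def test_empty_out_dict_class_is_undefined(self):
        train = [doc("t", "on aspirin today", [(3, 10, "aspirin")])]
        gold = [doc("a", "aspirin now", [(0, 7, "aspirin")])]
        r_in, r_out = indict_partition(train, gold, gold, "strict")
        assert r_in == 1.0 and r_out is None

    def test_dictionary_baseline_has_zero_out_dict_recall(self):
        """String search can only ever find training surfaces."""
        docs = generate_corpus(CorpusConfig(seed=8, n_patients=80, total_spans=1500))
        train, test, _ = split_patients(docs, 0.4, 5, seed=8)
        d = compile_dictionary(train)
        preds = [dc.with_spans(predict(dc, d)) for dc in test]
        r_in, r_out = indict_partition(train, test, preds, "strict")
        assert r_out == 0.0
        assert r_in is not None and r_in > 0.95
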