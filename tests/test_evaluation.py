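"""Covering-mode scoring, metric rounding, narrative recall, fixtures."""

import numpy as np
import pytest

from namedeid.corpus_io import AnnotatedNarrative, Narrative, Span
from namedeid.evaluation import (
    Cell,
    ConfusionCounts,
    compute_metrics,
    evaluate_corpus,
    evaluate_covering,
    make_confusion_fixture,
    metrics_report,
    narrative_recall,
)

from conftest import brute_force_covering, random_covering_instance


def _counts(text, gold, pred, nid="n1"):
    ann = AnnotatedNarrative(Narrative(nid, text),
                             [Span(a, b) for a, b in gold])
    return evaluate_covering(ann, [Span(a, b) for a, b in pred])


class TestCoveringRules:
    TEXT = "abcd Name xy zabcde rest"
    #       0-4  5-9 10-12 13-19

    def test_full_encapsulation_is_tp(self):
        c = _counts("padding Namex more", [(8, 13)], [(5, 16)])
        assert (c.all.tp, c.all.fn) == (1, 0)

    def test_partial_coverage_of_name_is_fn(self):
        c = _counts("padding Namex more", [(8, 13)], [(8, 11)])
        assert (c.all.tp, c.all.fn) == (0, 1)

    def test_fully_covered_non_name_forgiven_next_to_covered_name(self):
        # span (5,16) covers NON-NAME "xy" fully and NAME fully
        c = _counts("padd ab Name etc", [(8, 12)], [(5, 12)])
        assert c.all.fp == 0
        assert c.all.tp == 1

    def test_partially_covered_non_name_is_fp_even_next_to_name(self):
        c = _counts("padd Name other etc", [(5, 9)], [(5, 12)])
        # "other" partially covered (chars 10-12 of 10-15)
        assert c.all.tp == 1
        assert c.all.fp == 1

    def test_spurious_full_cover_is_fp(self):
        c = _counts("plain words here", [], [(0, 5)])
        assert c.all.fp == 1
        assert c.all.tn == 2

    def test_out_of_bounds_prediction_raises(self):
        with pytest.raises(ValueError, match="out of bounds"):
            _counts("short", [], [(0, 99)])


def test_agrees_with_brute_force_oracle_on_random_instances():
    rng = np.random.default_rng(20240501)
    for _ in range(300):
        text, gold, pred = random_covering_instance(rng)
        ann = AnnotatedNarrative(Narrative("r", text),
                                 [Span(a, b) for a, b in gold])
        got = evaluate_covering(ann, [Span(a, b) for a, b in pred])
        want = brute_force_covering(text, gold, pred)
        for stratum in ("all", "long", "short"):
            c = got.stratum(stratum)
            assert (c.tp, c.fp, c.fn, c.tn) == want[stratum], (text, gold, pred)


def test_adding_a_span_never_increases_fn():
    rng = np.random.default_rng(7)
    for _ in range(50):
        text, gold, pred = random_covering_instance(rng)
        ann = AnnotatedNarrative(Narrative("r", text),
                                 [Span(a, b) for a, b in gold])
        base = evaluate_covering(ann, [Span(a, b) for a, b in pred])
        if len(text) < 2:
            continue
        a = int(rng.integers(0, len(text) - 1))
        extra = Span(a, int(rng.integers(a + 1, len(text) + 1)))
        more = evaluate_covering(ann, [Span(a, b) for a, b in pred] + [extra])
        assert more.all.fn <= base.all.fn


class TestComputeMetrics:
    def test_reference_confusion_counts(self):
        """155/179 recall, 155/282 precision, 127 fps over 263,272 non-names."""
        counts = ConfusionCounts(all=Cell(155, 127, 24, 263_145),
                                 long=Cell(102, 73, 6, 162_509),
                                 short=Cell(53, 54, 18, 100_636))
        m = compute_metrics(counts)
        assert (m["all"].precision, m["all"].recall, m["all"].f1,
                m["all"].fpr) == (55, 87, 67, 0.05)
        assert (m["long"].precision, m["long"].recall) == (58, 94)

    def test_empty_counts_are_undefined_not_zero(self):
        m = compute_metrics(ConfusionCounts())
        assert m["all"].precision is None
        assert m["all"].recall is None

    def test_rounding_is_half_up(self):
        # 62.5% must round to 63, not banker's 62
        m = compute_metrics(ConfusionCounts(
            all=Cell(5, 3, 3, 0), long=Cell(5, 3, 3, 0), short=Cell()))
        assert m["all"].precision == 63
        assert m["all"].recall == 63

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            Cell(tp=-1)

    def test_stratum_additivity_enforced(self):
        with pytest.raises(ValueError, match="additivity"):
            ConfusionCounts(all=Cell(2, 0, 0, 0), long=Cell(1, 0, 0, 0),
                            short=Cell())


class TestNarrativeRecall:
    @staticmethod
    def _corpus(n_bearing, n_leaked, word="Alice"):
        corpus, preds = [], {}
        for i in range(n_bearing):
            text = f"seen by {word} today"
            ann = AnnotatedNarrative(Narrative(f"n{i}", text),
                                     [Span(8, 8 + len(word))])
            corpus.append(ann)
            preds[ann.id] = [] if i < n_leaked else [Span(8, 8 + len(word))]
        return corpus, preds

    def test_82_percent_for_13_of_71_leaked(self):
        corpus, preds = self._corpus(71, 13)
        assert narrative_recall(corpus, preds) == 82

    def test_91_percent_for_39_of_43_long(self):
        corpus, preds = self._corpus(43, 4)
        assert narrative_recall(corpus, preds, "long") == 91

    def test_all_leaked_gives_zero(self):
        corpus, preds = self._corpus(5, 5)
        assert narrative_recall(corpus, preds) == 0

    def test_undefined_without_name_bearing_narratives(self):
        corpus = [AnnotatedNarrative(Narrative("a", "no names"), [])]
        assert narrative_recall(corpus, {"a": []}) is None

    def test_stratum_denominator_only_counts_its_tokens(self):
        # narrative bearing only a short name never enters the long stratum
        ann = AnnotatedNarrative(Narrative("s", "initials SB here"),
                                 [Span(9, 11)])
        assert narrative_recall([ann], {"s": []}, "long") is None
        assert narrative_recall([ann], {"s": []}, "short") == 0


class TestConfusionFixture:
    def test_minimal_tp(self):
        target = ConfusionCounts(all=Cell(tp=1), long=Cell(tp=1), short=Cell())
        corpus, preds = make_confusion_fixture(target)
        assert evaluate_corpus(corpus, preds) == target

    def test_round_trip_random_targets(self):
        rng = np.random.default_rng(99)
        for _ in range(25):
            long = Cell(*(int(x) for x in rng.integers(0, 8, size=4)))
            short = Cell(*(int(x) for x in rng.integers(0, 8, size=4)))
            target = ConfusionCounts(long + short, long, short)
            corpus, preds = make_confusion_fixture(target)
            assert evaluate_corpus(corpus, preds) == target

    def test_full_scale_reference_counts(self):
        target = ConfusionCounts(all=Cell(155, 127, 24, 263_145),
                                 long=Cell(102, 73, 6, 162_509),
                                 short=Cell(53, 54, 18, 100_636))
        corpus, preds = make_confusion_fixture(target)
        assert evaluate_corpus(corpus, preds) == target


def test_metrics_report_touched_count():
    corpus = [AnnotatedNarrative(Narrative(f"n{i}", "seen by Alice"), [])
              for i in range(4)]
    preds = {"n0": [Span(8, 13)], "n1": [], "n2": [Span(0, 4)], "n3": []}
    report = metrics_report(corpus, preds)
    assert report.touched_narratives == 2
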