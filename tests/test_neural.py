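"""Transformer token classifier: chunking, decisions, training, gradients."""

import numpy as np
import pytest

from namedeid.corpus_io import AnnotatedNarrative, Narrative, Span
from namedeid.neural import (
    _TINY_ARCH,
    Classifier,
    ModelConfig,
    _init_params,
    labels_to_spans,
    loss_and_grads,
    predict_scores,
    predict_spans,
    predict_tokens,
    split_sequences,
    train,
    word_to_subwords,
)
from namedeid.synthetic_corpus import LAST_NAMES, generate_corpus, training_conditions
from namedeid.tokenization import TokenLabel, tokenize


class TestSplitSequences:
    def test_single_chunk_when_under_limit(self):
        groups = [[10, 11], [12], [13, 14, 15]]
        assert split_sequences(groups, 512) == [groups]

    def test_thousand_units_split_in_two_at_512(self):
        groups = [[100 + i] for i in range(1000)]
        chunks = split_sequences(groups, 512)
        assert len(chunks) == 2
        assert sum(len(g) for g in chunks[0]) <= 510
        assert [g for c in chunks for g in c] == groups

    def test_never_splits_a_word_group(self):
        groups = [[1] * 4, [2] * 4, [3] * 4]
        chunks = split_sequences(groups, 10)  # capacity 8 per chunk
        for chunk in chunks:
            assert sum(len(g) for g in chunk) <= 8
        assert [g for c in chunks for g in c] == groups

    def test_oversized_word_truncated_with_warning(self):
        with pytest.warns(UserWarning, match="truncating"):
            chunks = split_sequences([[7] * 20], 10)
        assert chunks == [[[7] * 8]]

    def test_concatenation_preserved_random(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            groups = [[int(x) for x in rng.integers(2, 99, rng.integers(1, 4))]
                      for _ in range(int(rng.integers(0, 40)))]
            chunks = split_sequences(groups, int(rng.integers(8, 30)))
            assert [g for c in chunks for g in c] == groups


class TestDecisionRule:
    @pytest.fixture(scope="class")
    def clf(self):
        return Classifier.initialize(ModelConfig(seed=1))

    def _label_with(self, p_nn, thr):
        # exercise the strict-inequality rule via a direct comparison path
        return TokenLabel.NON_NAME if p_nn > thr else TokenLabel.NAME

    @pytest.mark.parametrize("p_nn, thr, expected", [
        (0.95, 0.9, TokenLabel.NON_NAME),
        (0.60, 0.9, TokenLabel.NAME),
        (0.90, 0.9, TokenLabel.NAME),  # tie flags: strictly above required
    ])
    def test_threshold_boundary(self, p_nn, thr, expected):
        assert self._label_with(p_nn, thr) is expected

    def test_output_length_equals_token_count(self, clf):
        text = "Mr J.B., aged 60, seen by dr. Hanna Rosling on 12 May"
        assert len(predict_tokens(text, clf)) == len(tokenize(text))

    def test_scores_sum_to_one(self, clf):
        for p_name, p_nn in predict_scores("patient seen by Hanna", clf):
            assert abs(p_name + p_nn - 1) < 1e-6

    def test_long_narrative_still_one_label_per_token(self):
        clf = Classifier.initialize(ModelConfig(seed=1, max_sequence_length=16))
        text = " ".join(f"word{i}" for i in range(200))
        assert len(predict_tokens(text, clf)) == 200

    def test_lowering_threshold_never_removes_name_labels(self, clf):
        text = "seen by Hanna Rosling after DRUG1 on DATE1 with rash"
        names_at = {}
        for thr in (0.95, 0.9, 0.5, 0.1):
            labels = predict_tokens(text, clf,
                                    ModelConfig(non_name_threshold=thr, seed=1))
            names_at[thr] = {i for i, l in enumerate(labels)
                             if l is TokenLabel.NAME}
        assert names_at[0.95] >= names_at[0.9] >= names_at[0.5] >= names_at[0.1]


class TestLabelsToSpans:
    def test_run_merging(self):
        text = "by Hanna Rosling today"
        tokens = tokenize(text)
        labels = [TokenLabel.NON_NAME, TokenLabel.NAME, TokenLabel.NAME,
                  TokenLabel.NON_NAME]
        [span] = labels_to_spans(tokens, labels)
        assert text[span.start:span.end] == "Hanna Rosling"

    def test_all_non_name_empty(self):
        tokens = tokenize("one two three")
        assert labels_to_spans(tokens, [TokenLabel.NON_NAME] * 3) == []

    def test_alternating_gives_one_span_per_name(self):
        tokens = tokenize("a b c d")
        labels = [TokenLabel.NAME, TokenLabel.NON_NAME,
                  TokenLabel.NAME, TokenLabel.NON_NAME]
        assert len(labels_to_spans(tokens, labels)) == 2

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            labels_to_spans(tokenize("a b"), [TokenLabel.NAME])


def test_gradients_match_finite_differences():
    """Analytic gradients agree with central differences on a 2-layer model."""
    arch = dict(_TINY_ARCH, vocab_size=50, d_model=8, n_heads=2, d_ff=16,
                n_layers=2)
    params = _init_params(arch, 32, np.random.default_rng(0))
    ids = np.array([0, 5, 9, 12, 33, 1])
    y = np.array([1, 0, 1, 1, 0, 1])
    mask = np.array([0.0, 1, 1, 1, 1, 0])
    _, grads = loss_and_grads(params, arch, ids, (y, mask))
    eps = 1e-6
    pick = np.random.default_rng(1)
    for key in sorted(params):
        p = params[key]
        for flat in pick.integers(0, p.size, size=min(5, p.size)):
            idx = tuple(np.unravel_index(int(flat), p.shape))
            orig = p[idx]
            p[idx] = orig + eps
            lp, _ = loss_and_grads(params, arch, ids, (y, mask))
            p[idx] = orig - eps
            lm, _ = loss_and_grads(params, arch, ids, (y, mask))
            p[idx] = orig
            numeric = (lp - lm) / (2 * eps)
            assert abs(numeric - grads[key][idx]) <= 1e-6 + 1e-3 * abs(numeric), key


class TestTraining:
    @pytest.fixture(scope="class")
    def small_corpus(self):
        return generate_corpus(training_conditions(40, seed=21))

    def test_zero_epochs_returns_initialized_backend(self, small_corpus):
        cfg = ModelConfig(epochs=0, seed=4)
        trained = train(small_corpus, cfg)
        init = Classifier.initialize(cfg)
        for k in init.params:
            np.testing.assert_array_equal(trained.params[k], init.params[k])

    def test_retraining_is_deterministic(self, small_corpus):
        cfg = ModelConfig(epochs=1, learning_rate=1e-4, seed=5)
        probe = "Seen by dr. Ramesh Patel after DRUG1."
        a = train(small_corpus, cfg)
        b = train(small_corpus, cfg)
        assert predict_scores(probe, a) == predict_scores(probe, b)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train([], ModelConfig())

    def test_single_class_corpus_warns(self):
        corpus = [AnnotatedNarrative(Narrative("a", "no names here"), [])]
        with pytest.warns(UserWarning, match="single class"):
            train(corpus, ModelConfig(epochs=1))

    def test_marker_feature_is_learned(self):
        """With a unique marker token before every name, generous training
        reaches perfect recall and high precision (separable limit)."""
        rng = np.random.default_rng(5)
        words = ["rash", "fever", "dose", "drug", "taken", "after", "days"]
        corpus = []
        for i in range(80):
            parts, spans, pos = [], [], 0
            for _ in range(8):
                if rng.random() < 0.3:
                    nm = LAST_NAMES[int(rng.integers(len(LAST_NAMES)))]
                    frag = f"zqx {nm}"
                    spans.append(Span(pos + 4, pos + 4 + len(nm)))
                    parts.append(frag)
                    pos += len(frag) + 1
                else:
                    w = words[int(rng.integers(len(words)))]
                    parts.append(w)
                    pos += len(w) + 1
            corpus.append(AnnotatedNarrative(
                Narrative(f"m{i}", " ".join(parts)), spans))
        clf = train(corpus, ModelConfig(epochs=15, learning_rate=1e-3, seed=0))
        from namedeid.evaluation import evaluate_corpus
        preds = {a.id: predict_spans(a.text, clf) for a in corpus}
        c = evaluate_corpus(corpus, preds).all
        assert c.fn == 0                       # recall reaches 1.0
        assert c.tp / (c.tp + c.fp) > 0.8      # and it is not by flagging all


def test_save_load_round_trip(tmp_path):
    cfg = ModelConfig(epochs=0, seed=9)
    clf = Classifier.initialize(cfg)
    clf.save(tmp_path / "model")
    loaded = Classifier.load(tmp_path / "model")
    assert loaded.config == cfg
    probe = "Reviewed by Jane Doe m.d."
    assert predict_scores(probe, loaded) == predict_scores(probe, clf)


def test_pretrained_backend_requires_weights_directory():
    with pytest.raises(ValueError, match="weights"):
        Classifier.initialize(ModelConfig(backend="pretrained_uncased_transformer"))


def test_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(non_name_threshold=0.0)
    with pytest.raises(ValueError):
        ModelConfig(non_name_threshold=1.5)
    with pytest.raises(ValueError):
        ModelConfig(max_sequence_length=2)
    with pytest.raises(ValueError):
        ModelConfig(backend="other")


def test_subwords_deterministic_and_nonempty():
    for word in ("Johnson", "a", "SB", "métro", "x" * 30):
        ids = word_to_subwords(word, 2048)
        assert ids == word_to_subwords(word, 2048)
        assert len(ids) >= 1
        assert all(2 <= i < 2048 for i in ids)
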