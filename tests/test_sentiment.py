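import numpy as np
import pytest

from operand import (
    CooccurrenceModel,
    ParadigmSets,
    RuleBasedLemmatizer,
    RuleBasedTagger,
    build_cooccurrence_model,
    filter_and_lemmatize,
    make_toy_corpus,
    score_text,
    semantic_distance,
    semantic_orientation,
    text_to_series,
)
from operand.errors import OutOfVocabularyError

TOY_TEXT = (
    "It was a sunny day and the friendly child travelled in the green yard. "
    "Suddenly he heard a frightening voice and noticed that a vicious looking "
    "and violent dog is barking behind the fence."
)

EXPECTED_LEMMAS = [
    "sunny", "day", "friendly", "child", "travel", "green", "yard",
    "suddenly", "hear", "frighten", "voice", "notice", "vicious",
    "look", "violent", "dog", "bark", "fence",
]


def test_toy_sentences_retained_and_lemmatized():
    tokens = filter_and_lemmatize(TOY_TEXT)
    assert len(tokens) == 18
    assert [t.lemma for t in tokens] == EXPECTED_LEMMAS
    mapping = {t.surface.lower(): t.lemma for t in tokens}
    assert mapping["travelled"] == "travel"
    assert mapping["heard"] == "hear"
    assert mapping["frightening"] == "frighten"
    assert mapping["barking"] == "bark"


def test_stopword_only_text_empty():
    assert filter_and_lemmatize("and the, of!") == []


def test_lemmatization_idempotent_on_base_forms():
    lem = RuleBasedLemmatizer()
    for w in ("travel", "hear", "frighten", "bark", "dog", "fence"):
        assert lem(w) == w


def test_lemmatizer_cases():
    lem = RuleBasedLemmatizer()
    assert lem("noticed") == "notice"
    assert lem("carried") == "carry"
    assert lem("dogs") == "dog"
    assert lem("boxes") == "box"
    assert lem("stories") == "story"
    assert lem("glass") == "glass"  # -ss guard


def test_tagger_categories():
    tag = RuleBasedTagger()
    assert tag("the") is None
    assert tag("quickly") == "adv"
    assert tag("barking") == "verb"
    assert tag("vicious") == "adj"
    assert tag("fence") == "noun"
    assert tag("heard") == "verb"  # irregular, no suffix


def test_failing_components_pass_tokens_through():
    def bad_tagger(word):
        raise RuntimeError("boom")

    def bad_lemmatizer(word):
        raise RuntimeError("boom")

    tokens = filter_and_lemmatize("dog fence", tagger=bad_tagger, lemmatizer=bad_lemmatizer)
    assert [t.lemma for t in tokens] == ["dog", "fence"]


def test_empty_text_rejected():
    with pytest.raises(ValueError):
        filter_and_lemmatize("   ")


def _model(rows):
    """Model from a dict word -> context-count row over a fixed context list."""
    contexts = sorted({c for row in rows.values() for c in row})
    words = tuple(sorted(rows))
    probs = np.zeros((len(words), len(contexts)))
    for i, w in enumerate(words):
        for j, c in enumerate(contexts):
            probs[i, j] = rows[w].get(c, 0.0)
    probs /= probs.sum()
    return CooccurrenceModel(row_words=words, context_words=tuple(contexts), probs=probs)


def test_semantic_distance_examples():
    model = _model({"a": {"x": 1, "y": 1}, "b": {"x": 1, "y": 1}, "c": {"z": 1}, "d": {"x": 1, "z": 1}})
    assert semantic_distance("a", "b", model) == pytest.approx(1.0)
    assert semantic_distance("a", "c", model) == pytest.approx(0.0)
    # v1=(1,1,0), v2=(1,0,1) -> cos = 0.5
    assert semantic_distance("a", "d", model) == pytest.approx(0.5)


def test_oov_raises():
    model = _model({"a": {"x": 1}})
    with pytest.raises(OutOfVocabularyError):
        model.vector("zzz")
    with pytest.raises(OutOfVocabularyError):
        semantic_distance("a", "zzz", model)


def test_so_construction_and_antisymmetry():
    paradigms = ParadigmSets(positives=frozenset({"p1", "p2"}), negatives=frozenset({"n1"}))
    model = _model(
        {
            "p1": {"cx": 1.0},
            "p2": {"cy": 1.0},
            "n1": {"cz": 1.0},
            "w": {"cx": 1.0, "cy": 1.0},  # equals the positive sum, orthogonal to negative
            "e": {"cx": 1.0, "cz": np.sqrt(2) / 2 * 2},  # handled below
        }
    )
    assert semantic_orientation("w", paradigms, model) == pytest.approx(1.0)
    swapped = ParadigmSets(positives=frozenset({"n1"}), negatives=frozenset({"p1", "p2"}))
    for word in ("w", "e"):
        assert semantic_orientation(word, paradigms, model) == pytest.approx(
            -semantic_orientation(word, swapped, model)
        )


def test_so_scale_invariance():
    paradigms = ParadigmSets(positives=frozenset({"p"}), negatives=frozenset({"n"}))
    base = {"p": {"cx": 1.0}, "n": {"cy": 1.0}, "w": {"cx": 2.0, "cy": 1.0}}
    scaled = {"p": {"cx": 1.0}, "n": {"cy": 1.0}, "w": {"cx": 20.0, "cy": 10.0}}
    assert semantic_orientation("w", paradigms, _model(base)) == pytest.approx(
        semantic_orientation("w", paradigms, _model(scaled))
    )


def test_build_cooccurrence_counts():
    model = build_cooccurrence_model(["a", "b", "a"], window=1)
    # pairs: (a,b) x2 directions, (b,a) x2 -> 4 ordered co-occurrences
    assert model.probs.sum() == pytest.approx(1.0)
    va = model.vector("a")
    vb = model.vector("b")
    assert va[model.context_words.index("b")] == pytest.approx(0.5)
    assert vb[model.context_words.index("a")] == pytest.approx(0.5)


def test_build_respects_sentence_boundaries():
    flat = build_cooccurrence_model(["a", "b", "c", "d"], window=2)
    split = build_cooccurrence_model([["a", "b"], ["c", "d"]], window=2)
    assert flat.probs[flat.row_words.index("b"), flat.context_words.index("c")] > 0
    assert split.probs[split.row_words.index("b"), split.context_words.index("c")] == 0


def test_score_text_and_series_alignment():
    _, model, paradigms, labels = make_toy_corpus(2, 2, docs=4, seed=3)
    text = "brightlema gloomlema brightlemb gloomlemb"
    scored = score_text(text, paradigms, model)
    assert len(scored) == 4
    signs = [np.sign(t.so_score) for t in scored.tokens]
    assert signs == [1.0, -1.0, 1.0, -1.0]
    series = text_to_series(text, paradigms, model)
    assert len(series) == 4


def test_oov_policies():
    _, model, paradigms, _ = make_toy_corpus(1, 1, docs=2, seed=0)
    text = "brightlema flurbish gloomlema"
    zero = score_text(text, paradigms, model, oov_policy="zero")
    assert zero.oov_count == 1 and len(zero) == 3
    assert zero.tokens[1].so_score == 0.0
    drop = score_text(text, paradigms, model, oov_policy="drop")
    assert drop.oov_count == 1 and len(drop) == 2
    with pytest.raises(ValueError):
        score_text(text, paradigms, model, oov_policy="ignore")


def test_paradigm_sets_validation():
    with pytest.raises(ValueError):
        ParadigmSets(positives=frozenset(), negatives=frozenset({"bad"}))
    with pytest.raises(ValueError):
        ParadigmSets(positives=frozenset({"good"}), negatives=frozenset({"good"}))
    default = ParadigmSets.default()
    assert len(default.positives) == 7 and len(default.negatives) == 7


def test_model_tsv_and_csv_roundtrip(tmp_path):
    _, model, _, _ = make_toy_corpus(2, 2, docs=3, seed=1)
    t = tmp_path / "m.tsv"
    model.to_tsv(t)
    back = CooccurrenceModel.from_tsv(t)
    assert back.row_words == model.row_words
    assert np.array_equal(back.probs, model.probs)
    c = tmp_path / "m.csv"
    model.to_dense_csv(c)
    back2 = CooccurrenceModel.from_dense_csv(c)
    assert back2.row_words == model.row_words
    assert np.array_equal(back2.probs, model.probs)


def test_single_retained_word_series():
    _, model, paradigms, _ = make_toy_corpus(1, 1, docs=2, seed=0)
    series = text_to_series("the brightlema!", paradigms, model)
    assert len(series) == 1
    assert series[0] == pytest.approx(
        semantic_orientation("brightlema", paradigms, model)
    )
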