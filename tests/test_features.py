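"""Feature families: shapes, orthography, corpus-derived resources."""

import pytest
from hypothesis import given, settings, strategies as st

from nervote.corpus import Corpus
from nervote.features import (FeatureTemplate, build_informative_word_lists,
                              build_resources, extract_content_word_vocab,
                              extract_features, ne_weight, normalize_stem,
                              orthographic_flags, word_class, word_shape)

from conftest import corpus_from_labels


class TestWordShape:
    @pytest.mark.parametrize(
        "word, shape",
        [("IL", "AA"), ("IL-2", "AA-0"), ("IL-88", "AA-0"),
         ("p53", "a0"), ("NF-kappa", "AA-aaaaa"), ("123", "0")],
    )
    def test_examples(self, word, shape):
        assert word_shape(word) == shape

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            word_shape("")

    @settings(max_examples=50, deadline=None)
    @given(st.text(min_size=1, max_size=12))
    def test_never_longer_and_idempotent_on_shape_alphabet(self, w):
        s = word_shape(w)
        assert len(s) <= len(w)
        assert word_shape(s) == s  # 'A', 'a', '0' are fixed points


class TestWordClass:
    @pytest.mark.parametrize(
        "word, cls",
        [("IL23R", "AOA"), ("mRNA", "aA"), ("A", "A"),
         ("IL-2", "A-O"), ("kinase", "a")],
    )
    def test_examples(self, word, cls):
        assert word_class(word) == cls

    @settings(max_examples=50, deadline=None)
    @given(st.text(min_size=1, max_size=12))
    def test_squeezed_and_never_longer(self, w):
        c = word_class(w)
        assert len(c) <= len(w)
        assert all(a != b for a, b in zip(c, c[1:]))
        assert set(c) <= {"A", "a", "O", "-"}


class TestOrthographic:
    @pytest.mark.parametrize(
        "word, category",
        [
            ("Src", "InitCap"), ("EBNA", "AllCaps"), ("mAb", "InCap"),
            ("NFkappaB", "CapMixAlpha"), ("EpoR", "CapMixAlpha"),
            ("123", "DigitOnly"), ("12-3", "DigitSpecial"),
            ("2A", "DigitAlpha"), ("IL23R", "AlphaDigitAlpha"),
            ("IL-2", "Hyphen"), ("Ras", "CapLowAlpha"),
            ("32Dc13", "CapsAndDigits"), ("II", "RomanNumeral"),
            ("at", "StopWord"), ("CCGCCC", "ATGCSeq"), ("ATAGAT", "ATGCSeq"),
            ("p50", "AlphaDigit"), ("1,28", "DigitCommaDigit"),
            ("alpha", "GreekLetter"), ("mRNA", "LowMixAlpha"),
        ],
    )
    def test_named_category_fires(self, word, category):
        assert orthographic_flags(word)[category] == 1

    def test_digit_comma_digit_is_not_digit_only(self):
        flags = orthographic_flags("1,28")
        assert flags["DigitCommaDigit"] == 1 and flags["DigitOnly"] == 0

    def test_flags_are_binary(self):
        for w in ("IL-2", "p53", "the", "ATG"):
            assert set(orthographic_flags(w).values()) <= {0, 1}


class TestNeWeight:
    @pytest.mark.parametrize(
        "inside, total, expected",
        [(3, 4, 0.75), (0, 7, 0.0), (5, 5, 1.0)],
    )
    def test_ratio(self, inside, total, expected):
        assert ne_weight("w", inside, total) == expected

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            ne_weight("w", 0, 0)

    @settings(max_examples=40, deadline=None)
    @given(st.integers(1, 50), st.integers(0, 50))
    def test_range_and_monotonicity(self, total, inside):
        inside = min(inside, total)
        w = ne_weight("x", inside, total)
        assert 0.0 <= w <= 1.0
        if inside < total:
            assert ne_weight("x", inside + 1, total) >= w


def _weighted_fixture():
    """Five candidate words engineered to one NEweight per bin.

    Each word appears inside a multiword entity ``k`` times out of 20
    total occurrences, giving weights 0.1/0.3/0.5/0.7/0.9 with inside
    counts all above the >= 2 cutoff.
    """
    rows, surfaces = [], []
    words = ["wa", "wb", "wc", "wd", "we"]
    inside = [2, 6, 10, 14, 18]
    for w, k in zip(words, inside):
        for _ in range(k):  # inside a two-token entity with anchor token
            surfaces.append([w, "anchor"])
            rows.append(["B-protein", "I-protein"])
        for _ in range(20 - k):  # outside occurrences
            surfaces.append([w, "filler"])
            rows.append(["O", "O"])
    return corpus_from_labels(rows, surfaces=surfaces)


class TestInformativeWords:
    def test_low_inside_count_excluded(self):
        c = corpus_from_labels(
            [["B-protein", "I-protein"], ["O", "O"]],
            surfaces=[["rare", "anchor"], ["rare", "rare"]],
        )
        lists, weights = build_informative_word_lists(c)
        assert all("rare" not in s for s in lists)
        assert "rare" not in weights

    def test_no_multiword_entities_gives_empty_lists(self):
        c = corpus_from_labels([["B-protein", "O"]])
        lists, weights = build_informative_word_lists(c)
        assert all(not s for s in lists) and not weights

    def test_equal_width_binning_places_one_word_per_bin(self):
        lists, weights = build_informative_word_lists(_weighted_fixture())
        expected_w = {"wa": 0.1, "wb": 0.3, "wc": 0.5, "wd": 0.7, "we": 0.9}
        for w, nw in expected_w.items():
            assert weights[w] == pytest.approx(nw)
        assert weights["anchor"] == 1.0  # the always-inside anchor token
        expected = [{"wa"}, {"wb"}, {"wc"}, {"wd"}, {"we"}]
        got = [set(s) - {"anchor"} for s in lists]
        assert got == expected

    def test_digit_and_symbol_tokens_excluded(self):
        c = corpus_from_labels(
            [["B-protein", "I-protein", "I-protein"]] * 2,
            surfaces=[["kin", "42", "+"]] * 2,
        )
        lists, weights = build_informative_word_lists(c)
        assert "42" not in weights and "+" not in weights
        assert "kin" in weights


class TestContentWords:
    def test_most_frequent_context_word_first(self):
        rows, surfaces = [], []
        for _ in range(12):
            surfaces.append(["factor", "42"])
            rows.append(["O", "B-protein"])
        for _ in range(5):
            surfaces.append(["other", "42"])
            rows.append(["O", "B-protein"])
        c = corpus_from_labels(rows, surfaces=surfaces)
        vocab = extract_content_word_vocab(c, window=1)
        assert vocab[0] == "factor"

    def test_no_entities_warns_and_empty(self):
        c = corpus_from_labels([["O", "O"]])
        with pytest.warns(UserWarning):
            assert extract_content_word_vocab(c) == []

    def test_stopword_only_contexts_empty(self):
        c = corpus_from_labels(
            [["O", "B-protein", "O"]], surfaces=[["the", "42", "of"]]
        )
        with pytest.warns(UserWarning):
            vocab = extract_content_word_vocab(c, window=1)
        assert vocab == []


class TestResources:
    def test_head_noun_bigram_from_entity_tail(self):
        rows = [["B-protein", "I-protein", "I-protein", "I-protein"]] * 2
        surfaces = [["NF-kappa", "B", "transcription", "factor"]] * 2
        res = build_resources(corpus_from_labels(rows, surfaces=surfaces))
        assert ("transcription", "factor") in res.head_noun_bigrams
        assert "factor" in res.head_noun_unigrams

    def test_trigger_extracted_above_min_freq(self):
        rows, surfaces = [], []
        for _ in range(4):
            surfaces.append(["binds", "XYZ2"])
            rows.append(["O", "B-protein"])
        surfaces.append(["cleaves", "XYZ2"])
        rows.append(["O", "B-protein"])
        res = build_resources(corpus_from_labels(rows, surfaces=surfaces))
        assert "binds" in res.trigger_verbs
        assert "cleaves" not in res.trigger_verbs  # below min frequency 2

    def test_empty_like_corpus_gives_empty_resources(self):
        res = build_resources(corpus_from_labels([["O"]]))
        assert not res.head_noun_unigrams and not res.trigger_verbs
        assert res.content_vocab == ()

    def test_thresholds_default_to_paperless_constants(self):
        res = build_resources(corpus_from_labels([["O"]]))
        assert res.length_threshold == 5
        assert res.infrequent_threshold == 10


class TestExtractFeatures:
    @pytest.fixture()
    def setup(self):
        rows = [["O", "B-protein", "O"]]
        surfaces = [["binds", "interleukin", "receptors"]]
        c = corpus_from_labels(rows, surfaces=surfaces)
        return c, build_resources(c)

    def test_length_indicator_fires_above_threshold(self, setup):
        c, res = setup
        t = FeatureTemplate()
        feats = extract_features(c.sentences[0], 1, t, res)
        assert feats["long"] == 1  # len('interleukin') = 11 > 5
        assert extract_features(c.sentences[0], 0, t, res)["long"] == 0

    def test_affixes_of_current_word(self):
        c = corpus_from_labels([["B-protein"]], surfaces=[["IL-2"]])
        res = build_resources(c)
        feats = extract_features(
            c.sentences[0], 0, FeatureTemplate(affix_len=3), res
        )
        assert (feats["pre1"], feats["pre2"], feats["pre3"]) == (
            "I", "IL", "IL-"
        )
        assert (feats["suf1"], feats["suf2"], feats["suf3"]) == (
            "2", "-2", "L-2"
        )

    def test_unknown_token_flag_at_test_time(self, setup):
        c, res = setup
        other = corpus_from_labels([["O"]], surfaces=[["novelword"]])
        feats = extract_features(
            other.sentences[0], 0, FeatureTemplate(), res
        )
        assert feats["unknown"] == 1
        feats = extract_features(c.sentences[0], 0, FeatureTemplate(), res)
        assert feats["unknown"] == 0

    def test_training_unknown_bit_deterministic(self, setup):
        c, res = setup
        t = FeatureTemplate()
        a = extract_features(c.sentences[0], 1, t, res, training=True)
        b = extract_features(c.sentences[0], 1, t, res, training=True)
        assert a == b

    def test_context_window_and_boundaries(self, setup):
        c, res = setup
        t = FeatureTemplate(word_window=2)
        feats = extract_features(c.sentences[0], 0, t, res)
        assert feats["w[-1]"] == "<s>" and feats["w[2]"] == "receptors"
        assert feats["w[0]|w[1]"] == "binds|interleukin"

    def test_dynamic_tags_use_previous_only(self, setup):
        c, res = setup
        t = FeatureTemplate(dynamic_depth=2)
        feats = extract_features(
            c.sentences[0], 2, t, res, previous_tags=["O", "B-protein"]
        )
        assert feats["dyn1"] == "B-protein"
        assert feats["dyn2"] == "O|B-protein"

    def test_trigger_and_stem_features(self, setup):
        c, res = setup
        # 'binds' precedes only one mention here, below min frequency
        feats = extract_features(c.sentences[0], 0, FeatureTemplate(), res)
        assert feats["trigger"] == 0
        assert feats["stem"] == normalize_stem("binds") == "bind"

    def test_invalid_position_rejected(self, setup):
        c, res = setup
        with pytest.raises(IndexError):
            extract_features(c.sentences[0], 9, FeatureTemplate(), res)

    def test_content_flag_requires_vocab(self, setup):
        c, _ = setup
        res = build_resources(corpus_from_labels([["O"]]))
        with pytest.raises(ValueError):
            extract_features(
                c.sentences[0], 0, FeatureTemplate(content_words=True), res
            )

    def test_determinism(self, setup):
        c, res = setup
        t = FeatureTemplate(dynamic_depth=1, pos_window=1)
        kw = dict(previous_tags=["O"], training=False)
        assert extract_features(c.sentences[0], 1, t, res, **kw) == \
            extract_features(c.sentences[0], 1, t, res, **kw)


def test_template_invariants_enforced():
    with pytest.raises(ValueError):
        FeatureTemplate(word_window=4)
    with pytest.raises(ValueError):
        FeatureTemplate(ngram_order=3)
    with pytest.raises(ValueError):
        FeatureTemplate(affix_len=5)
    with pytest.raises(ValueError):
        FeatureTemplate(dynamic_depth=4)
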