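import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from openvocab.corpus import AuthorCorpus, Message
from openvocab.features import (
    FeatureMatrix,
    NgramVectorizer,
    anscombe,
    build_feature_matrix,
    collocation_filter,
    extract_ngrams,
    min_usage_filter,
    pmi,
    relative_frequency,
)
from openvocab.tokenizer import tokenize


class TestExtractNgrams:
    def test_full_enumeration(self):
        grams = extract_ngrams(["i", "love", "you"])
        assert set(grams) == {
            ("i",), ("love",), ("you",),
            ("i", "love"), ("love", "you"), ("i", "love", "you"),
        }
        assert all(c == 1 for c in grams.values())

    def test_short_message(self):
        assert set(extract_ngrams(["hi"], n_max=3)) == {("hi",)}

    def test_no_spanning_across_messages(self):
        # extraction is per message; the union over two messages has no cross bigram
        grams = extract_ngrams(["a", "b"]) + extract_ngrams(["c"])
        assert ("b", "c") not in grams


class TestPmi:
    def test_independent_words_give_zero(self):
        assert pmi(0.01, [0.1, 0.1]) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_ratio(self):
        # 0.02 / (0.02 * 0.04) = 25
        assert pmi(0.02, [0.02, 0.04]) == pytest.approx(math.log(25), abs=1e-12)

    def test_ratio_e_gives_one(self):
        assert pmi(0.1 * 0.2 * math.e, [0.1, 0.2]) == pytest.approx(1.0, abs=1e-12)

    def test_unseen_phrase_is_neg_inf(self):
        assert pmi(0.0, [0.1, 0.1]) == float("-inf")

    def test_word_order_does_not_change_independence_product(self):
        assert pmi(0.01, [0.1, 0.02]) == pytest.approx(pmi(0.01, [0.02, 0.1]))


class TestCollocationFilter:
    def test_independent_bigram_dropped_unigram_kept(self):
        counts = {("a",): 50, ("b",): 50, ("a", "b"): 25}
        kept = collocation_filter(counts, {1: 100, 2: 100})
        assert ("a",) in kept and ("b",) in kept
        assert ("a", "b") not in kept  # pmi = 0

    def test_deterministic_collocation_passes_default_threshold(self):
        # p(xy)=p(x)=p(y)=0.01 -> pmi = ln 100 ~ 4.6 > 2*2
        counts = {("new",): 10, ("york",): 10, ("w",): 980, ("new", "york"): 10}
        kept = collocation_filter(counts, {1: 1000, 2: 1000})
        assert ("new", "york") in kept

    def test_threshold_function_respected(self):
        counts = {("new",): 10, ("york",): 10, ("w",): 980, ("new", "york"): 10}
        kept = collocation_filter(counts, {1: 1000, 2: 1000}, lambda n: 5.0)
        assert ("new", "york") not in kept  # ln 100 < 5


class TestRelativeFrequencyAndAnscombe:
    def test_relative_frequency_and_phrase_denominator(self):
        rel = relative_frequency(Counter({("w",): 2, ("w", "v"): 3}), 100)
        assert rel[("w",)] == 0.02 and rel[("w", "v")] == 0.03

    def test_unigram_relative_frequencies_sum_to_one(self):
        counts = Counter({("a",): 2, ("b",): 1, ("c",): 1})
        rel = relative_frequency(counts, 4)
        assert sum(rel.values()) == pytest.approx(1.0)

    def test_zero_word_author_is_error(self):
        with pytest.raises(ValueError):
            relative_frequency(Counter(), 0)

    def test_anscombe_closed_forms(self):
        assert anscombe(0) == pytest.approx(2 * math.sqrt(3 / 8), abs=1e-12)
        assert anscombe(1) == pytest.approx(2 * math.sqrt(11 / 8), abs=1e-12)

    def test_anscombe_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            anscombe(-0.01)
        with pytest.raises(ValueError):
            anscombe(1.01)

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_anscombe_monotone(self, p1, p2):
        if p1 < p2:
            assert anscombe(p1) <= anscombe(p2)
        if p2 - p1 > 1e-12:  # strictly, once the gap is representable
            assert anscombe(p1) < anscombe(p2)


class TestMinUsageFilter:
    def _matrix(self, n_used):
        n_authors, m = 200, len(n_used)
        return FeatureMatrix(
            [f"a{i}" for i in range(n_authors)],
            [f"f{j}" for j in range(m)],
            np.full((n_authors, m), anscombe(0.0)),
            "anscombe_relfreq",
            n_authors_used=np.asarray(n_used),
        )

    def test_below_one_percent_dropped(self):
        out = min_usage_filter(self._matrix([1, 2, 200]), 0.01)
        assert out.features == ["f1", "f2"]  # need ceil(0.01*200)=2

    def test_zero_fraction_is_identity(self):
        m = self._matrix([0, 1, 5])
        assert min_usage_filter(m, 0.0).features == m.features

    def test_requires_usage_provenance(self):
        m = self._matrix([1])
        m.n_authors_used = None
        with pytest.raises(ValueError, match="provenance"):
            min_usage_filter(m, 0.01)


class TestBuildFeatureMatrix:
    def test_absent_feature_cell_is_anscombe_zero(self, tiny_corpus):
        mat = build_feature_matrix(tiny_corpus, [("love",), ("happy",)])
        frame = mat.to_frame()
        assert frame.loc["c", "love"] == pytest.approx(anscombe(0.0))
        assert frame.loc["b", "happy"] == pytest.approx(anscombe(1 / 3))

    def test_shape_and_row_semantics(self, tiny_corpus):
        mat = build_feature_matrix(tiny_corpus, [("the",), ("day",)])
        assert mat.shape == (3, 2)
        # author c: "the the the day" -> the 3/4, day 1/4
        frame = mat.to_frame()
        assert frame.loc["c", "the"] == pytest.approx(anscombe(0.75))
        assert frame.loc["c", "day"] == pytest.approx(anscombe(0.25))

    def test_values_within_anscombe_range(self, tiny_corpus):
        mat = build_feature_matrix(tiny_corpus, [("love",), ("the", "day")])
        assert np.all(mat.values >= anscombe(0.0) - 1e-12)
        assert np.all(mat.values <= anscombe(1.0) + 1e-12)


class TestNgramVectorizer:
    def _corpus(self, texts_by_author):
        corpus = AuthorCorpus()
        for aid, texts in texts_by_author.items():
            for i, t in enumerate(texts):
                corpus.add(Message(aid, t, f"m{i}"), tokenize(t))
        return corpus

    def test_matches_reference_build_on_unigrams(self):
        corpus = self._corpus(
            {"a": ["x y x", "y z"], "b": ["z z x", "y"], "c": ["x x y z"]}
        )
        vec = NgramVectorizer(n_max=1, min_author_fraction=0.0)
        fast = vec.fit_transform(corpus)
        ref = build_feature_matrix(corpus, [(w,) for w in ["x", "y", "z"]], 1)
        assert fast.features == ref.features
        np.testing.assert_allclose(fast.values, ref.values, atol=1e-12)

    def test_single_word_messages_produce_no_phrases(self):
        corpus = self._corpus({"a": ["x", "y", "x"], "b": ["y", "z"]})
        mat = NgramVectorizer(min_author_fraction=0.0).fit_transform(corpus)
        assert all("_" not in f for f in mat.features)

    def test_collocation_and_usage_filters_commute(self):
        corpus = self._corpus(
            {
                f"a{i}": ["new york trip", "the new york", "other words here"]
                for i in range(10)
            }
        )
        # filters applied in either conceptual order give the same phrase set:
        # usage-then-pmi == pmi-then-usage because both are per-feature predicates
        both = NgramVectorizer(min_author_fraction=0.5).fit_transform(corpus)
        pmi_only = NgramVectorizer(min_author_fraction=0.0).fit_transform(corpus)
        usage_on_pmi = min_usage_filter(pmi_only, 0.5)
        assert sorted(both.features) == sorted(usage_on_pmi.features)

    def test_transform_frozen_on_unseen_authors(self):
        corpus = self._corpus({"a": ["p q p q"], "b": ["p q r"], "c": ["p p q"]})
        vec = NgramVectorizer(min_author_fraction=0.0).fit(corpus)
        new = self._corpus({"z": ["p brandnew q"]})
        mat = vec.transform(new)
        assert mat.features == vec.feature_names_  # no new features appear
        # 'brandnew' is OOV: contributes to the denominator only
        j = mat.features.index("p")
        assert mat.values[0, j] == pytest.approx(anscombe(1 / 3))
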