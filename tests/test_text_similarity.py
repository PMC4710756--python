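import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dictmap.blocking import CandidatePair
from dictmap.dictionary_model import ElementMetadata, MetadataStore
from dictmap.text_similarity import (
    TextModels,
    levenshtein,
    rank_targets,
    tokenize,
    word_edit_distance,
)

from .conftest import element


def _hand_tfidf_cosine(docs: list[list[str]], i: int, j: int) -> float:
    """Independent tf-idf cosine: tf·(ln((1+n)/(1+df))+1), l2-normalised."""
    n = len(docs)
    vocab = sorted({t for d in docs for t in d})
    df = {t: sum(t in d for d in docs) for t in vocab}

    def vec(d):
        v = [d.count(t) * (math.log((1 + n) / (1 + df[t])) + 1.0) for t in vocab]
        norm = math.sqrt(sum(x * x for x in v))
        return [x / norm for x in v]

    vi, vj = vec(docs[i]), vec(docs[j])
    return sum(a * b for a, b in zip(vi, vj))


class TestTfidf:
    def test_vocabulary_matches_hand_enumeration(self, toy_corpus_store):
        m = TextModels(toy_corpus_store, ("a", "b"), topic_count=2, seed=0)
        assert m.vocabulary() == [
            "blood", "memory", "pressure", "reading", "recall", "score", "total",
        ]

    def test_cosine_equals_hand_computation(self, toy_corpus_store):
        m = TextModels(toy_corpus_store, ("a", "b"), topic_count=2, seed=0)
        docs = [
            ["memory", "recall", "score"],
            ["memory", "score", "total"],
            ["blood", "pressure", "reading"],
        ]
        got = m.tfidf_similarity(("a", "t", "e1"), ("b", "t", "f1"))
        assert got == pytest.approx(_hand_tfidf_cosine(docs, 0, 1), abs=1e-9)
        assert m.tfidf_similarity(("a", "t", "e1"), ("b", "t", "f2")) == pytest.approx(
            _hand_tfidf_cosine(docs, 0, 2), abs=1e-9
        )

    def test_identical_and_disjoint_descriptions(self):
        store = MetadataStore(
            [
                element("a", "X", short="delayed recall trial"),
                element("b", "Y", short="delayed recall trial"),
                element("b", "Z", short="systolic blood pressure"),
            ]
        )
        m = TextModels(store, ("a", "b"), topic_count=2, seed=0)
        assert m.tfidf_similarity(("a", "t", "x"), ("b", "t", "y")) == pytest.approx(1.0)
        assert m.tfidf_similarity(("a", "t", "x"), ("b", "t", "z")) == 0.0

    def test_empty_description_scores_zero(self):
        store = MetadataStore(
            [
                element("a", "X", short=""),
                element("b", "Y", short="memory score"),
                element("b", "Z", short="recall total"),
            ]
        )
        m = TextModels(store, ("a", "b"), topic_count=2, seed=0)
        assert m.tfidf_similarity(("a", "t", "x"), ("b", "t", "y")) == 0.0
        assert m.topic_similarity(("a", "t", "x"), ("b", "t", "y")) == 0.0

    def test_symmetry(self, toy_corpus_store):
        m = TextModels(toy_corpus_store, ("a", "b"), topic_count=2, seed=0)
        k1, k2 = ("a", "t", "e1"), ("b", "t", "f1")
        assert m.tfidf_similarity(k1, k2) == m.tfidf_similarity(k2, k1)
        assert m.topic_similarity(k1, k2) == m.topic_similarity(k2, k1)

    def test_unknown_element_errors(self, toy_corpus_store):
        m = TextModels(toy_corpus_store, ("a", "b"), topic_count=2, seed=0)
        with pytest.raises(KeyError, match="not in the fitted corpus"):
            m.tfidf_similarity(("a", "t", "ghost"), ("b", "t", "f1"))

    def test_all_empty_corpus_rejected(self):
        store = MetadataStore([element("a", "X"), element("b", "Y")])
        with pytest.raises(ValueError, match="empty"):
            TextModels(store, ("a", "b"), topic_count=2, seed=0)


class TestTopicModel:
    def test_self_similarity_is_one(self, toy_corpus_store):
        m = TextModels(toy_corpus_store, ("a", "b"), topic_count=2, seed=0)
        assert m.topic_similarity(("a", "t", "e1"), ("a", "t", "e1")) == pytest.approx(1.0)

    def test_fixed_seed_reproduces_bit_identical_topics(self, small_pair):
        storeS, storeT, _ = small_pair
        store = storeS.merge(storeT)
        sources = (next(iter(storeS)).source_id, next(iter(storeT)).source_id)
        m1 = TextModels(store, sources, topic_count=5, seed=7)
        m2 = TextModels(store, sources, topic_count=5, seed=7)
        assert np.array_equal(m1.topic_matrix, m2.topic_matrix)

    def test_within_vocabulary_similarity_exceeds_cross(self):
        """Two disjoint description vocabularies should separate in topic space."""
        bank_a = ["memory recall score", "recall trial total", "memory score errors"]
        bank_b = ["blood pressure reading", "systolic pressure value", "blood reading seated"]
        within, cross = [], []
        for seed in range(5):
            elems = [element("a", f"A{i}", short=d) for i, d in enumerate(bank_a)]
            elems += [element("b", f"B{i}", short=d) for i, d in enumerate(bank_b)]
            m = TextModels(MetadataStore(elems), ("a", "b"), topic_count=2, seed=seed)
            ka = [e.key for e in elems[:3]]
            kb = [e.key for e in elems[3:]]
            within += [m.topic_similarity(ka[0], ka[i]) for i in (1, 2)]
            within += [m.topic_similarity(kb[0], kb[i]) for i in (1, 2)]
            cross += [m.topic_similarity(x, y) for x in ka for y in kb]
        assert np.mean(within) > np.mean(cross)


class TestWordEditDistance:
    @pytest.mark.parametrize(
        "d1, d2, expected",
        [
            ("ability to pay bills", "ability to pay bills", 0),
            ("", "one two three four", 4),
            ("ability to pay bills", "ability paying bills", 2),
        ],
    )
    def test_examples(self, d1, d2, expected):
        assert word_edit_distance(d1, d2) == expected

    def test_matches_edlib_on_random_pairs(self):
        """Cross-check the DP against edlib over token sequences."""
        edlib = pytest.importorskip("edlib")
        import random

        rng = random.Random(42)
        words = ["memory", "recall", "score", "blood", "pressure", "daily", "total"]
        for _ in range(200):
            a = [rng.choice(words) for _ in range(rng.randint(0, 10))]
            b = [rng.choice(words) for _ in range(rng.randint(0, 10))]
            enc = {w: chr(65 + i) for i, w in enumerate(words)}
            ea, eb = "".join(enc[w] for w in a), "".join(enc[w] for w in b)
            expected = 0 if not (ea or eb) else edlib.align(ea, eb)["editDistance"]
            assert levenshtein(a, b) == expected

    @settings(max_examples=100, derandomize=True)
    @given(
        st.lists(st.sampled_from("abc"), max_size=6),
        st.lists(st.sampled_from("abc"), max_size=6),
        st.lists(st.sampled_from("abc"), max_size=6),
    )
    def test_metric_properties(self, a, b, c):
        assert levenshtein(a, b) == levenshtein(b, a)
        assert levenshtein(a, b) <= levenshtein(a, c) + levenshtein(c, b)
        assert (levenshtein(a, b) == 0) == (a == b)


class TestRanking:
    def _pairs(self, scores: dict[str, float]):
        q = element("a", "Q", short="x")
        out = []
        for name, s in scores.items():
            c = CandidatePair(query=q, target=element("b", name, short="y"))
            c.evidence.tfidf_score = s
            out.append(c)
        return q, out

    def test_two_element_ordering(self):
        q, cands = self._pairs({"A": 0.9, "B": 0.5})
        ordered = rank_targets(q, cands)
        assert [(c.target.element_name, c.evidence.tfidf_rank) for c in ordered] == [
            ("A", 1), ("B", 2),
        ]

    def test_ties_break_by_name_and_are_stable(self):
        q, cands = self._pairs({"C": 0.5, "A": 0.5, "B": 0.5})
        first = [c.target.element_name for c in rank_targets(q, cands)]
        second = [c.target.element_name for c in rank_targets(q, list(reversed(cands)))]
        assert first == second == ["A", "B", "C"]

    def test_empty_candidate_list_errors(self):
        with pytest.raises(ValueError, match="empty"):
            rank_targets(element("a", "Q"), [])


def test_tokenizer_drops_stopwords_and_lowercases():
    from dictmap.text_similarity import DEFAULT_STOPWORDS

    assert tokenize("The Ability to Pay BILLS!", DEFAULT_STOPWORDS) == ["ability", "pay", "bills"]
    assert tokenize("ability to pay bills") == ["ability", "to", "pay", "bills"]
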