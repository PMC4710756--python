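import math
import random

import numpy as np
import pytest

from dictmap.blocking import CandidatePair
from dictmap.dictionary_model import CODED, MetadataStore
from dictmap.features import (
    FEATURE_NAMES,
    build_training_set,
    extract_features,
    feature_matrix,
    per_pair_table_score,
    table_correspondence_scores,
)
from dictmap.text_similarity import TextModels

from .conftest import element


def _layout(rng: random.Random, n_s: int, n_t: int, n_tables: int):
    """Random table layout plus a random best-match map for brute forcing."""
    es = [element("a", f"S{i}", table=f"ts{rng.randrange(n_tables)}") for i in range(n_s)]
    et = [element("b", f"T{i}", table=f"tt{rng.randrange(n_tables)}") for i in range(n_t)]
    best = {}
    for e in es:
        if rng.random() < 0.8:
            best[e.key] = rng.choice(et).key
    return es, et, best


def _brute_force_tcs(es, et, best):
    sizes_s = {}
    sizes_t = {}
    for e in es:
        sizes_s[e.key[1]] = sizes_s.get(e.key[1], 0) + 1
    for e in et:
        sizes_t[e.key[1]] = sizes_t.get(e.key[1], 0) + 1
    counts = {}
    for e in es:
        bm = best.get(e.key)
        if bm is not None:
            counts[(e.key[1], bm[1])] = counts.get((e.key[1], bm[1]), 0) + 1
    return {
        pair: min(c / min(sizes_s[pair[0]], sizes_t[pair[1]]), 1.0)
        for pair, c in counts.items()
    }


class TestTableCorrespondence:
    def test_worked_example_three_quarters(self):
        """4-element source table, 6-element target table, 3 best matches cross."""
        es = [element("a", f"S{i}", table="x") for i in range(4)]
        et = [element("b", f"T{i}", table="y") for i in range(6)]
        best = {es[i].key: et[i].key for i in range(3)}
        scores = table_correspondence_scores(es, et, best)
        assert scores[("x", "y")] == pytest.approx(0.75)

    def test_no_crossing_matches_scores_zero(self):
        es = [element("a", "S0", table="x")]
        et = [element("b", "T0", table="y")]
        assert table_correspondence_scores(es, et, {}).get(("x", "y"), 0.0) == 0.0

    def test_full_cover_of_smaller_table_scores_one(self):
        es = [element("a", f"S{i}", table="x") for i in range(2)]
        et = [element("b", f"T{i}", table="y") for i in range(5)]
        best = {es[i].key: et[i].key for i in range(2)}
        assert table_correspondence_scores(es, et, best)[("x", "y")] == 1.0

    def test_matches_brute_force_on_random_layouts(self):
        rng = random.Random(11)
        for _ in range(30):
            es, et, best = _layout(rng, rng.randint(3, 20), rng.randint(3, 20), rng.randint(1, 4))
            got = table_correspondence_scores(es, et, best)
            expected = _brute_force_tcs(es, et, best)
            assert got == pytest.approx(expected)
            assert all(0.0 <= v <= 1.0 for v in got.values())

    def test_invariant_under_element_permutation(self):
        rng = random.Random(5)
        es, et, best = _layout(rng, 12, 9, 3)
        base = table_correspondence_scores(es, et, best)
        shuffled = table_correspondence_scores(list(reversed(es)), et, best)
        assert base == shuffled

    def test_literal_per_pair_variant(self):
        es = [element("a", f"S{i}", table="x") for i in range(4)]
        et = [element("b", f"T{i}", table="y") for i in range(6)]
        best = {es[0].key: et[0].key}
        pair = CandidatePair(query=es[0], target=et[1])
        assert per_pair_table_score(pair, best, es, et) == pytest.approx(1 / 4)
        assert per_pair_table_score(CandidatePair(query=es[1], target=et[0]), best, es, et) == 0.0


class TestExtractFeatures:
    @pytest.fixture()
    def self_pair_setup(self):
        e1 = element(
            "a", "BILLS", table="adl", short="pay bills",
            long="ability to handle bills and finances",
            value_kind=CODED, allowed_values=frozenset({"0", "1", "2", "3", "8"}),
        )
        e2 = element(
            "b", "BILLS", table="adl", short="pay bills",
            long="ability to handle bills and finances",
            value_kind=CODED, allowed_values=frozenset({"0", "1", "2", "3", "8"}),
        )
        filler = element("b", "OTHER", table="misc", short="blood pressure reading")
        store = MetadataStore([e1, e2, filler])
        models = TextModels(store, ("a", "b"), topic_count=2, seed=0)
        return e1, e2, models

    def test_self_pair_extremes(self, self_pair_setup):
        e1, e2, models = self_pair_setup
        pair = CandidatePair(query=e1, target=e2)
        pair.evidence.tfidf_rank = 1
        pair.evidence.topic_rank = 1
        fv = extract_features(pair, models, {("adl", "adl"): 1.0})
        assert fv.tfidf_score == pytest.approx(1.0)
        assert fv.edit_distance == 0
        assert fv.name_score == 1.0 and fv.name_match_applicable
        assert fv.tfidf_rank == fv.topic_rank == 1
        assert fv.source_cardinality == 5 and fv.target_cardinality == 5
        assert math.isnan(fv.source_min) and math.isnan(fv.target_max)
        assert fv.table_score == 1.0

    def test_requires_precomputed_ranks(self, self_pair_setup):
        e1, e2, models = self_pair_setup
        with pytest.raises(ValueError, match="rank"):
            extract_features(CandidatePair(query=e1, target=e2), models, {})

    def test_array_order_matches_documented_names(self, self_pair_setup):
        e1, e2, models = self_pair_setup
        pair = CandidatePair(query=e1, target=e2)
        pair.evidence.tfidf_rank = pair.evidence.topic_rank = 1
        fv = extract_features(pair, models, {})
        arr = fv.to_array()
        assert arr.shape == (len(FEATURE_NAMES),)
        assert arr[FEATURE_NAMES.index("source_cardinality")] == 5.0
        assert np.isnan(arr[FEATURE_NAMES.index("target_min")])


class TestTrainingSet:
    def test_sampling_arithmetic_and_determinism(self, small_pair, small_pipeline):
        _, _, truth = small_pair
        positives = [(q, t, True) for q, t in list(truth.items())[:10]]
        X1, y1 = build_training_set(positives, small_pipeline, negative_ratio=3, seed=4)
        assert sum(y1) == 10 and len(y1) == 40
        X2, y2 = build_training_set(positives, small_pipeline, negative_ratio=3, seed=4)
        assert y1 == y2
        assert np.array_equal(feature_matrix(X1), feature_matrix(X2), equal_nan=True)

    def test_rejected_suggestions_appear_exactly_once(self, small_pair, small_pipeline):
        _, _, truth = small_pair
        (q, t), (q2, t2) = list(truth.items())[:2]
        rejected_target = small_pipeline.unblocked_targets(q)[0]
        if rejected_target == t:
            rejected_target = small_pipeline.unblocked_targets(q)[1]
        labeled = [(q, t, True), (q2, t2, True), (q, rejected_target, False), (q, rejected_target, False)]
        X, y = build_training_set(labeled, small_pipeline, negative_ratio=0, seed=0)
        assert y.count(False) == 1 and y.count(True) == 2

    def test_requires_a_positive(self, small_pipeline):
        with pytest.raises(ValueError, match="at least one"):
            build_training_set([], small_pipeline)
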