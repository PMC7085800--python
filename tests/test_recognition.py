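import random

import pytest
from hypothesis import given, settings, strategies as st

from duoact.casas_io import ActivityInstance
from duoact.clustering import kmeans
from duoact.recognition import (
    RecognitionConfig,
    levenshtein_ratio,
    recognize,
    similarity,
)

from oracles import edit_distance_recursive

SENSORS = [f"M{i:03d}" for i in range(1, 9)]


def _act(sq, bt=5, et=6, label="X"):
    return ActivityInstance(bt=bt, et=et, sq=tuple(sq), label=label)


class TestLevenshteinRatio:
    def test_identical_sequences(self):
        assert levenshtein_ratio(["A", "B", "C"], ["A", "B", "C"]) == 1.0

    @pytest.mark.parametrize("m, n", [(1, 1), (3, 5), (4, 4)])
    def test_disjoint_alphabets_give_zero(self, m, n):
        sq1, sq2 = ["A"] * m, ["B"] * n
        assert levenshtein_ratio(sq1, sq2) == 0.0

    def test_worked_example_pair_matches_oracle(self, table1_instances):
        bed, sleep = table1_instances
        ldist = edit_distance_recursive(bed.sq, sleep.sq)
        total = len(bed.sq) + len(sleep.sq)
        assert levenshtein_ratio(bed.sq, sleep.sq) == pytest.approx(
            (total - ldist) / total
        )

    @pytest.mark.parametrize("sub_cost", [1, 2])
    def test_agrees_with_recursive_oracle_on_200_random_pairs(self, sub_cost):
        rng = random.Random(7)
        for _ in range(200):
            sq1 = [rng.choice(SENSORS) for _ in range(rng.randint(1, 12))]
            sq2 = [rng.choice(SENSORS) for _ in range(rng.randint(1, 12))]
            ldist = edit_distance_recursive(sq1, sq2, sub_cost)
            total = len(sq1) + len(sq2)
            assert levenshtein_ratio(sq1, sq2, sub_cost) == pytest.approx(
                (total - ldist) / total
            )

    def test_tokens_not_characters(self):
        # whole-ID tokens: M004 vs M005 are simply different symbols
        assert levenshtein_ratio(["M004"], ["M005"]) == 0.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            levenshtein_ratio([], ["A"])


class TestSimilarity:
    def test_self_similarity_is_one_for_any_valid_config(self):
        a = _act(["A", "B"], bt=3, et=4)
        for w1 in (0.0, 0.05, 0.1, 0.15):
            cfg = RecognitionConfig(w1=w1, w2=1 - 2 * w1, n=3)
            assert similarity(a, a, cfg) == pytest.approx(2 * w1 + cfg.w2)
            assert similarity(a, a, cfg) == pytest.approx(1.0)

    def test_twelve_hour_offset_disjoint_sequences(self):
        cfg = RecognitionConfig(w1=0.15, w2=0.7)
        a = _act(["A", "A"], bt=0, et=1)
        t = _act(["B", "B"], bt=12, et=13)
        assert similarity(a, t, cfg) == pytest.approx(2 * 0.15 * (12 / 24))
        assert similarity(a, t, cfg) == pytest.approx(0.15)

    def test_monotone_in_begin_time_gap(self):
        cfg = RecognitionConfig()
        t = _act(["A"], bt=0, et=0)
        ratios = [similarity(_act(["A"], bt=g, et=0), t, cfg) for g in range(0, 24, 3)]
        assert ratios == sorted(ratios, reverse=True)

    @settings(derandomize=True, deadline=None, max_examples=80)
    @given(
        bt1=st.integers(0, 23), et1=st.integers(0, 23),
        bt2=st.integers(0, 23), et2=st.integers(0, 23),
        sq1=st.lists(st.sampled_from(SENSORS), min_size=1, max_size=8),
        sq2=st.lists(st.sampled_from(SENSORS), min_size=1, max_size=8),
    )
    def test_symmetric_and_bounded(self, bt1, et1, bt2, et2, sq1, sq2):
        cfg = RecognitionConfig()
        a = _act(sq1, bt=bt1, et=et1)
        t = _act(sq2, bt=bt2, et=et2)
        r = similarity(a, t, cfg)
        assert r == pytest.approx(similarity(t, a, cfg))
        assert 0.0 <= r <= 1.0 + 1e-12

    @pytest.mark.parametrize(
        "w1, w2, n",
        [(0.2, 0.7, 3), (0.15, 0.8, 3), (0.3, 0.4, 3), (0.15, 0.7, 0)],
    )
    def test_invalid_configs_rejected(self, w1, w2, n):
        with pytest.raises(ValueError):
            RecognitionConfig(w1=w1, w2=w2, n=n)


def _fit(train):
    points = [(float(a.bt), float(a.et)) for a in train]
    k = min(2, len({p for p in points}))
    model = kmeans(points, k, seed=0)
    return list(zip(train, model.assignment.tolist())), model


class TestRecognize:
    def test_exact_copy_wins_with_n1(self):
        train = [
            _act(["A", "B"], bt=5, et=5, label="Wake"),
            _act(["C", "D"], bt=5, et=6, label="Wash"),
            _act(["E", "F"], bt=20, et=21, label="Sleep"),
        ]
        indexed, model = _fit(train)
        query = _act(["C", "D"], bt=5, et=6, label="?")
        cfg = RecognitionConfig(n=1)
        assert recognize(indexed, model, query, cfg) == "Wash"

    def test_disjoint_classes_recognized_perfectly(self):
        rng = random.Random(1)
        vocab = {"Morning": ["A", "B"], "Noon": ["C", "D"], "Night": ["E", "F"]}
        hours = {"Morning": 6, "Noon": 12, "Night": 21}
        train = [
            _act(
                [rng.choice(vocab[lb]) for _ in range(4)],
                bt=hours[lb], et=hours[lb] + 1, label=lb,
            )
            for lb in vocab for _ in range(10)
        ]
        points = [(float(a.bt), float(a.et)) for a in train]
        model = kmeans(points, 3, seed=0)
        indexed = list(zip(train, model.assignment.tolist()))
        cfg = RecognitionConfig(n=2)
        for lb in vocab:
            query = _act(
                [rng.choice(vocab[lb]) for _ in range(4)],
                bt=hours[lb], et=hours[lb] + 1, label=lb,
            )
            assert recognize(indexed, model, query, cfg) == lb

    def test_vote_tie_broken_by_summed_similarity(self):
        # two labels, two votes each; "Close" instances are more similar
        train = [
            _act(["A", "B", "C"], bt=5, et=5, label="Close"),
            _act(["A", "B", "D"], bt=5, et=5, label="Close"),
            _act(["A", "E", "F"], bt=5, et=5, label="Far"),
            _act(["A", "E", "G"], bt=5, et=5, label="Far"),
        ]
        model = kmeans([(5.0, 5.0)] * 4, 1, seed=0)
        indexed = list(zip(train, model.assignment.tolist()))
        query = _act(["A", "B", "C"], bt=5, et=5)
        cfg = RecognitionConfig(n=4)
        assert recognize(indexed, model, query, cfg) == "Close"

    def test_empty_cluster_falls_back_to_full_training_set(self):
        train = [_act(["A", "B"], bt=5, et=5, label="Wake")] * 3
        model = kmeans([(5.0, 5.0), (20.0, 20.0)], 2, seed=0)
        query = _act(["A", "B"], bt=20, et=20)
        # park every training instance in the cluster the query is NOT in
        other = 1 - model.predict((20.0, 20.0))
        indexed = [(a, other) for a in train]
        with pytest.warns(UserWarning, match="no training instance"):
            assert recognize(indexed, model, query, RecognitionConfig(n=1)) == "Wake"

    def test_fewer_than_n_instances_all_vote(self):
        train = [
            _act(["A", "B"], bt=5, et=5, label="Wake"),
            _act(["C", "D"], bt=5, et=6, label="Wash"),
        ]
        model = kmeans([(5.0, 5.0), (5.0, 6.0)], 1, seed=0)
        indexed = list(zip(train, model.assignment.tolist()))
        query = _act(["A", "B"], bt=5, et=5)
        assert recognize(indexed, model, query, RecognitionConfig(n=5)) == "Wake"

    def test_deterministic(self, table1_instances):
        train = list(table1_instances) * 3
        model = kmeans([(float(a.bt), float(a.et)) for a in train], 1, seed=0)
        indexed = list(zip(train, model.assignment.tolist()))
        query = table1_instances[0]
        preds = {recognize(indexed, model, query, RecognitionConfig(n=3)) for _ in range(5)}
        assert preds == {"Bed_to_Toilet"}
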