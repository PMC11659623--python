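import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mixodor import owsum
from mixodor.chem_features import InputError
from mixodor.owsum import (
    FitError,
    PresenceScaler,
    conditional_probability,
    descriptor_dissimilarity,
    fit_counts,
    influence_difference,
    influence_table,
    predict,
    scaled_presence,
    score_sample,
    tfidf_weight,
)

TOY = [
    ({"a", "b"}, "A"),
    ({"b", "c"}, "A"),
    ({"b"}, "B"),
    ({"c", "d"}, "B"),
]


@st.composite
def random_corpus(draw):
    n_classes = draw(st.integers(2, 4))
    n_features = draw(st.integers(2, 6))
    classes = [f"C{i}" for i in range(n_classes)]
    features = [f"f{i}" for i in range(n_features)]
    samples = []
    for _ in range(draw(st.integers(n_classes, 12))):
        feats = draw(st.sets(st.sampled_from(features), min_size=1))
        label = draw(st.sampled_from(classes))
        samples.append((feats, label))
    # make sure every class occurs
    for c in classes:
        samples.append(({features[0]}, c))
    return samples


class TestCounts:
    def test_direct_tally(self):
        counts = fit_counts([({"a", "b"}, "A"), ({"b"}, "B")])
        assert counts.get("A", "a") == 1
        assert counts.get("A", "b") == 1
        assert counts.get("B", "b") == 1
        assert counts.class_totals == {"A": 2, "B": 1}

    def test_multilabel_sample_counts_into_each_class(self):
        counts = fit_counts([({"a"}, {"A", "B"})])
        assert counts.get("A", "a") == counts.get("B", "a") == 1

    def test_unseen_feature_absent(self):
        counts = fit_counts(TOY)
        assert "z" not in counts.features
        assert counts.get("A", "z") == 0

    def test_empty_training_set_rejected(self):
        with pytest.raises(FitError):
            fit_counts([])


class TestConditionalProbability:
    def test_exclusive_feature_has_cp1_one(self):
        counts = fit_counts(TOY)
        assert conditional_probability(counts, "cp1", "A", "a") == 1.0

    def test_cp1_ratio(self):
        counts = fit_counts([({"f"}, "A")] + [({"f"}, "B")] * 3)
        assert conditional_probability(counts, "cp1", "A", "f") == pytest.approx(0.25)

    def test_cp2_ratio(self):
        samples = [({"f", "x1", "x2", "x3"}, "A"), ({"f", "x1", "x2", "x3"}, "A")]
        counts = fit_counts(samples)  # occ(A,f)=2, len(A)=8
        assert conditional_probability(counts, "cp2", "A", "f") == pytest.approx(0.25)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(random_corpus())
    def test_cp1_columns_and_cp2_rows_normalize(self, samples):
        counts = fit_counts(samples)
        for f in counts.features:
            col = sum(conditional_probability(counts, "cp1", c, f) for c in counts.classes)
            assert col == pytest.approx(1.0)
        for c in counts.classes:
            row = sum(conditional_probability(counts, "cp2", c, f) for f in counts.features)
            assert row == pytest.approx(1.0)


class TestTfidf:
    def test_feature_in_every_class_gets_zero(self):
        counts = fit_counts([({"b"}, "A"), ({"b"}, "B")])
        assert tfidf_weight(counts, "A", "b") == 0.0

    def test_formula_value(self):
        # occ(f,A)=3, len(A)=6, f exclusive to A, |C|=2
        samples = [({"f", "x"}, "A")] * 3 + [({"y"}, "B")]
        counts = fit_counts(samples)
        assert counts.class_totals["A"] == 6
        assert tfidf_weight(counts, "A", "f") == pytest.approx(0.5 * math.log10(2))

    def test_linear_in_term_frequency(self):
        one = fit_counts([({"f"}, "A"), ({"x"}, "A"), ({"y"}, "B")])
        two = fit_counts([({"f"}, "A"), ({"f"}, "A"), ({"y"}, "B"), ({"y"}, "B")])
        # len(A) is 2 in both corpora; occ doubles
        assert tfidf_weight(two, "A", "f") == pytest.approx(2 * tfidf_weight(one, "A", "f"))

    def test_unknown_feature_zero(self):
        assert tfidf_weight(fit_counts(TOY), "A", "nope") == 0.0


class TestInfluenceTable:
    def test_same_weighted_cp1_columns_sum_to_one(self):
        table = influence_table(fit_counts(TOY), "cp1", "same")
        for f in table.features:
            assert sum(table.value(c, f) for c in table.classes) == pytest.approx(1.0)

    def test_values_equal_hand_computed_products(self):
        """Spreadsheet-style oracle: tally counts and form products by hand."""
        counts = fit_counts(TOY)
        table = influence_table(counts, "cp2", "tfidf")
        for c in counts.classes:
            for f in counts.features:
                occ = sum(1 for feats, lab in TOY if lab == c and f in feats)
                total = sum(len(feats) for feats, lab in TOY if lab == c)
                presence = sum(
                    1
                    for cls in counts.classes
                    if any(f in feats for feats, lab in TOY if lab == cls)
                )
                expected = (occ / total) * math.log10(counts.n_classes / presence) * (
                    occ / total
                )
                assert table.value(c, f) == pytest.approx(expected, abs=1e-12)

    def test_json_roundtrip(self):
        table = influence_table(fit_counts(TOY), "cp1", "tfidf")
        back = owsum.InfluenceTable.from_json(table.to_json())
        assert back.values == table.values and back.variant == table.variant


class TestScaledPresence:
    def test_rare_present_feature_is_present(self):
        m = np.zeros((10, 1))
        m[:2, 0] = 1.0  # present in 2 of 10 training rows
        scaler = PresenceScaler.fit(m, ["f"])
        assert scaled_presence(np.array([[1.0]]), scaler, 0) == {"f"}

    def test_constant_feature_never_present(self):
        m = np.ones((5, 1))
        scaler = PresenceScaler.fit(m, ["f"])
        assert scaled_presence(np.array([[1.0]]), scaler, 0) == set()

    def test_absent_feature_not_present(self):
        m = np.zeros((10, 1))
        m[:3, 0] = 1.0
        scaler = PresenceScaler.fit(m, ["f"])
        assert scaled_presence(np.array([[0.0]]), scaler, 0) == set()

    def test_dimension_mismatch_rejected(self):
        scaler = PresenceScaler.fit(np.zeros((3, 2)), ["a", "b"])
        with pytest.raises(InputError):
            scaled_presence(np.zeros((1, 3)), scaler, 0)


class TestScoringAndPrediction:
    def test_empty_feature_set_scores_zero(self):
        table = influence_table(fit_counts(TOY), "cp1", "same")
        scores = score_sample(table, set())
        assert all(v == 0 for v in scores.values())

    def test_exclusive_feature_wins(self):
        table = influence_table(fit_counts(TOY), "cp1", "same")
        scores = score_sample(table, {"a"})
        assert scores["A"] == 1.0 and scores["B"] == 0.0
        (top,), warn = predict(scores, k=1)
        assert top == "A" and not warn

    def test_sum_matches_manual_addition(self):
        table = influence_table(fit_counts(TOY), "cp2", "same")
        scores = score_sample(table, {"b", "c", "unknown"})
        for c in table.classes:
            assert scores[c] == pytest.approx(table.value(c, "b") + table.value(c, "c"))

    def test_topk_ordering_and_ties(self):
        scores = {"f": 6, "e": 5, "d": 4, "c": 3, "b": 2, "a": 2}
        labels, _ = predict(scores, k=5)
        assert labels == ["f", "e", "d", "c", "a"]  # tie at rank 5: name ascending

    def test_all_zero_scores_flagged(self):
        labels, warn = predict({"b": 0.0, "a": 0.0, "c": 0.0}, k=2)
        assert warn and labels == ["a", "b"]

    def test_k_exceeding_classes_rejected(self):
        with pytest.raises(InputError):
            predict({"a": 1.0}, k=2)

    def test_positive_scaling_invariance(self):
        table = influence_table(fit_counts(TOY), "cp2", "tfidf")
        scores = score_sample(table, {"b", "c"})
        scaled = {c: 7.3 * v for c, v in scores.items()}
        assert predict(scores, k=2)[0] == predict(scaled, k=2)[0]


class TestInterpretability:
    def test_influence_difference_antisymmetric(self):
        table = influence_table(fit_counts(TOY), "cp1", "same")
        d = influence_difference(table, "b", "A", "B")
        assert influence_difference(table, "b", "B", "A") == pytest.approx(-d)

    def test_exclusive_feature_difference_is_one(self):
        table = influence_table(fit_counts(TOY), "cp1", "same")
        assert influence_difference(table, "a", "A", "B") == pytest.approx(1.0)

    def test_dissimilarity_symmetric_and_zero_on_self(self):
        table = influence_table(fit_counts(TOY), "cp2", "same")
        d_ab, arc_ab = descriptor_dissimilarity(table, "A", "B")
        d_ba, _ = descriptor_dissimilarity(table, "B", "A")
        assert d_ab == pytest.approx(d_ba)
        assert descriptor_dissimilarity(table, "A", "A") == (0.0, 1.0)
        expected = sum(
            abs(table.value("A", f) - table.value("B", f)) for f in table.features
        )
        assert d_ab == pytest.approx(expected)
        assert arc_ab == pytest.approx(1.1 ** (d_ab * 1000))
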