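import numpy as np
import pytest

from mixodor.baselines import FoldPrediction, educated_guess, ovr_baseline, subject_x_metrics
from mixodor.chem_features import InputError
from mixodor.io_cli import load_study_descriptor_occurrence
from mixodor.labels import LabelSet, RataTable
from mixodor.evaluation import loo_folds, multilabel_metrics


def label_sets_from_counts(counts: dict[str, int]) -> list[LabelSet]:
    """Label sets realizing given per-descriptor top-5 occurrence counts."""
    n = sum(counts.values()) // 5
    remaining = dict(counts)
    sets = []
    for i in range(n):
        chosen = sorted(remaining, key=lambda d: (-remaining[d], d))[:5]
        for d in chosen:
            remaining[d] -= 1
        sets.append(LabelSet(f"s{i}", frozenset(chosen), 0))
    assert all(v == 0 for v in remaining.values())
    return sets


class TestEducatedGuess:
    def test_study_frequency_table_gives_named_five(self):
        """On the published 16-whisky occurrence counts the guess is the five
        most frequent panel descriptors."""
        occ = load_study_descriptor_occurrence()
        counts = dict(zip(occ["descriptor"], occ["top5_occurrence"]))
        sets = label_sets_from_counts(counts)
        guess = educated_guess(sets, sorted(counts))
        assert set(guess.predicted) == {
            "solvent-like",
            "apple-like",
            "fruity",
            "caramel-like",
            "pear-like",
        }

    def test_uniform_frequencies_fall_back_to_lexicographic(self):
        sets = [LabelSet("s", frozenset(["a", "b", "c", "d", "e"]), 0)]
        guess = educated_guess(sets, ["g", "f", "e", "d", "c", "b", "a"])
        assert guess.predicted == ["a", "b", "c", "d", "e"]

    def test_loo_frequency_shift_bounded_by_one(self, default_dataset):
        vocab = default_dataset.descriptors
        full = educated_guess(default_dataset.label_sets, vocab).score_vector
        loo = educated_guess(default_dataset.label_sets[1:], vocab).score_vector
        assert np.abs(full - loo).max() <= 1

    def test_held_out_labels_never_counted(self, default_dataset):
        """Leakage guard: the guess for a fold ignores the held-out sample."""
        vocab = default_dataset.descriptors
        train = default_dataset.label_sets[:-1]
        held = default_dataset.label_sets[-1]
        base = educated_guess(train, vocab)
        mutated = LabelSet(held.sample_id, frozenset(list(sorted(vocab))[:5]), 0)
        again = educated_guess(train, vocab)
        assert base.predicted == again.predicted
        assert np.array_equal(base.score_vector, again.score_vector)


class TestSubjectX:
    def _table(self, ratings, n_desc=6):
        panelists = sorted({k[0] for k in ratings})
        samples = sorted({k[1] for k in ratings})
        descriptors = [f"d{i}" for i in range(n_desc)]
        return RataTable(panelists, samples, descriptors, ratings)

    def test_identical_panelists_agree_perfectly(self):
        ratings = {}
        for p in ("p0", "p1"):
            for d, r in [("d0", 3), ("d1", 2), ("d2", 5), ("d3", 1), ("d4", 4)]:
                ratings[(p, "s", d)] = r
        report = subject_x_metrics(self._table(ratings))
        assert all(m["f1"] == 1.0 for m in report["per_panelist"])

    def test_panelist_order_invariance(self, default_dataset):
        rata = default_dataset.rata
        reordered = RataTable(
            panelists=rata.panelists[::-1],
            samples=rata.samples,
            descriptors=rata.descriptors,
            ratings=dict(rata.ratings),
        )
        a = subject_x_metrics(rata, seed=3)["mean"]
        b = subject_x_metrics(reordered, seed=3)["mean"]
        assert a == b

    def test_three_panelist_hand_check(self):
        """Two agreeing panelists and one dissenter: the dissenter's top-5
        shares exactly 2 descriptors with the consensus of the other two."""
        agree = [("d0", 5), ("d1", 4), ("d2", 3), ("d3", 2), ("d4", 1)]
        dissent = [("d0", 5), ("d1", 4), ("d5", 3), ("d6", 2), ("d7", 1)]
        ratings = {}
        for p in ("p0", "p1"):
            for d, r in agree:
                ratings[(p, "s", d)] = r
        for d, r in dissent:
            ratings[("p2", "s", d)] = r
        report = subject_x_metrics(self._table(ratings, n_desc=8))
        by_p = {m["panelist"]: m for m in report["per_panelist"]}
        assert by_p["p2"]["f1"] == pytest.approx(2 * 2 / 10)

    def test_needs_two_panelists(self):
        with pytest.raises(InputError):
            subject_x_metrics(self._table({("p0", "s", "d0"): 1}))


class TestOvrBaselines:
    def _separable(self, rng, n=12, n_desc=6):
        """Presence features that literally encode the labels: descriptor j is
        in the top-5 set iff marker molecule j is present."""
        descriptors = [f"d{j}" for j in range(n_desc)]
        presence, labels = {}, {}
        for i in range(n):
            chosen = rng.choice(n_desc, size=5, replace=False)
            v = np.zeros(n_desc + 10)
            v[n_desc:] = rng.random(10) > 0.5  # distractor molecules
            for j in chosen:
                v[j] = 1.0
            presence[f"s{i}"] = v
            labels[f"s{i}"] = LabelSet(f"s{i}", frozenset(descriptors[j] for j in chosen), 0)
        return presence, labels, descriptors

    @pytest.mark.parametrize("kind", ["svm", "rf"])
    def test_separable_data_high_f1(self, kind, rng):
        presence, labels, descriptors = self._separable(rng)
        folds = loo_folds(sorted(presence))
        preds = ovr_baseline(kind, folds, presence, labels, descriptors, seed=0)
        true = np.array([[d in labels[p.sample_id].labels for d in descriptors] for p in preds])
        pred = np.array([[d in p.predicted for d in descriptors] for p in preds])
        assert multilabel_metrics(true, pred)["f1"] >= 0.9

    def test_all_zero_features_deterministic(self, rng):
        _, labels, descriptors = self._separable(rng)
        presence = {s: np.zeros(4) for s in labels}
        folds = loo_folds(sorted(presence))
        a = ovr_baseline("rf", folds, presence, labels, descriptors, seed=1)
        b = ovr_baseline("rf", folds, presence, labels, descriptors, seed=1)
        assert [p.predicted for p in a] == [p.predicted for p in b]

    def test_single_class_descriptor_warns_not_crashes(self, rng):
        presence, labels, descriptors = self._separable(rng, n=6)
        # force descriptor d0 into every label set
        forced = {
            s: LabelSet(s, frozenset(sorted(ls.labels - {"d0"})[:4] + ["d0"]), 0)
            for s, ls in labels.items()
        }
        with pytest.warns(UserWarning):
            preds = ovr_baseline("svm", loo_folds(sorted(presence)), presence, forced, descriptors)
        assert all(len(p.predicted) == 5 for p in preds)

    def test_rf_seeded_reproducibility(self, rng):
        presence, labels, descriptors = self._separable(rng, n=8)
        folds = loo_folds(sorted(presence))
        a = ovr_baseline("rf", folds, presence, labels, descriptors, seed=7)
        b = ovr_baseline("rf", folds, presence, labels, descriptors, seed=7)
        assert [p.predicted for p in a] == [p.predicted for p in b]
        assert all(np.array_equal(x.score_vector, y.score_vector) for x, y in zip(a, b))
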