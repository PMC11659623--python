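"""Reference predictors: educated top-5 guessing, inter-panelist agreement
(Subject X), and one-vs-rest linear-SVM / random-forest top-5 classifiers.

These anchor the evaluation: a useful structure-aware model should beat the
five-most-frequent-descriptors guess, which in turn tends to beat the
agreement of a single panelist with the rest of the panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .chem_features import ConfigError, InputError
from .labels import ConsensusScores, LabelSet, RataTable, sum_rata, top5_labels

__all__ = [
    "FoldPrediction",
    "educated_guess",
    "subject_x_metrics",
    "ovr_baseline",
]


@dataclass
class FoldPrediction:
    """Top-5 prediction for one held-out sample, with per-class scores."""

    sample_id: str
    predicted: list[str]
    score_vector: np.ndarray  # aligned with the class vocabulary

    def __post_init__(self) -> None:
        if len(self.predicted) != 5:
            raise InputError("a fold prediction carries exactly 5 labels")


def educated_guess(
    train_label_sets: Sequence[LabelSet], descriptors: Sequence[str]
) -> FoldPrediction:
    """The five most frequent descriptors across the training label sets.

    Frequencies double as the score vector (for ranking metrics); ties at the
    fifth place are broken lexicographically.
    """
    if len(descriptors) < 5:
        raise InputError("need >= 5 descriptors")
    freq = {d: sum(1 for ls in train_label_sets if d in ls.labels) for d in descriptors}
    ordered = sorted(descriptors, key=lambda d: (-freq[d], d))
    return FoldPrediction(
        sample_id="<template>",
        predicted=ordered[:5],
        score_vector=np.array([freq[d] for d in descriptors], dtype=float),
    )


def _panelist_consensus(rata: RataTable, panelists: Sequence[str]) -> ConsensusScores:
    sub = RataTable(
        panelists=list(panelists),
        samples=list(rata.samples),
        descriptors=list(rata.descriptors),
        ratings={
            (p, s, d): r for (p, s, d), r in rata.ratings.items() if p in set(panelists)
        },
    )
    return sum_rata(sub)


def subject_x_metrics(rata: RataTable, seed: int = 0) -> dict:
    """Average inter-panelist agreement, one panelist against the rest.

    For each panelist X, X's own per-sample top-5 is treated as the
    prediction and the top-5 of the summed ratings of all other panelists as
    the ground truth; metrics are computed per panelist over all samples and
    then averaged.  Returns a report dict with per-panelist and mean micro
    F1 / MCC and micro precision.
    """
    from .evaluation import multilabel_metrics

    if len(rata.panelists) < 2:
        raise InputError("need >= 2 panelists")
    descriptors = list(rata.descriptors)
    per_panelist = []
    for p in rata.panelists:
        own = _panelist_consensus(rata, [p])
        others = _panelist_consensus(rata, [q for q in rata.panelists if q != p])
        pred = np.zeros((len(rata.samples), len(descriptors)), dtype=int)
        true = np.zeros_like(pred)
        for i, s in enumerate(rata.samples):
            if all(v == 0 for v in own.sample_scores(s).values()):
                warnings.warn(f"panelist {p!r} has all-zero ratings for sample {s!r}")
            pred_labels = top5_labels(own, s, seed=seed).labels
            true_labels = top5_labels(others, s, seed=seed).labels
            for j, d in enumerate(descriptors):
                pred[i, j] = d in pred_labels
                true[i, j] = d in true_labels
        m = multilabel_metrics(true, pred)
        tp = int((pred & true).sum())
        m["precision"] = tp / int(pred.sum()) if pred.sum() else 0.0
        m["panelist"] = p
        per_panelist.append(m)

    mean = {
        key: float(np.mean([m[key] for m in per_panelist]))
        for key in ("f1", "mcc", "accuracy", "precision")
    }
    return {"per_panelist": per_panelist, "mean": mean}


def ovr_baseline(
    kind: Literal["svm", "rf"],
    folds: Sequence[tuple[list[str], str]],
    presence: Mapping[str, np.ndarray],
    labels: Mapping[str, LabelSet],
    descriptors: Sequence[str],
    seed: int = 0,
) -> list[FoldPrediction]:
    """One-vs-rest top-5 baseline over per-fold binary classifiers.

    Each descriptor is a binary problem per fold; SVM features are
    standardized with a scaler fitted on the fold's training rows only, and
    predictions are the five descriptors with the highest decision score
    (SVM) or positive-class probability (RF).  A descriptor whose fold
    training labels are single-class yields a constant score with a warning.
    """
    if kind not in ("svm", "rf"):
        raise ConfigError(f"unknown baseline kind: {kind!r}")
    predictions = []
    for train_ids, test_id in folds:
        x_train = np.vstack([presence[s] for s in train_ids])
        x_test = np.asarray(presence[test_id])[None, :]
        if kind == "svm":
            scaler = StandardScaler().fit(x_train)
            x_train = scaler.transform(x_train)
            x_test = scaler.transform(x_test)
        scores = np.zeros(len(descriptors))
        for j, d in enumerate(descriptors):
            y = np.array([d in labels[s].labels for s in train_ids], dtype=int)
            if y.min() == y.max():
                warnings.warn(
                    f"descriptor {d!r} is single-class in fold {test_id!r}; constant score"
                )
                scores[j] = float(y[0])
                continue
            if kind == "svm":
                clf = LinearSVC(max_iter=200)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    clf.fit(x_train, y)
                scores[j] = float(clf.decision_function(x_test)[0])
            else:
                clf = RandomForestClassifier(n_estimators=100, random_state=seed & 0x7FFFFFFF)
                clf.fit(x_train, y)
                proba = clf.predict_proba(x_test)[0]
                scores[j] = float(proba[list(clf.classes_).index(1)])
        order = sorted(range(len(descriptors)), key=lambda j: (-scores[j], descriptors[j]))
        predictions.append(
            FoldPrediction(
                sample_id=test_id,
                predicted=[descriptors[j] for j in order[:5]],
                score_vector=scores,
            )
        )
    return predictions
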