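"""OWSum: an interpretable linear classifier over qualitative feature sets.

A sample is a set of features (detected molecules, or odor descriptors).
Training tallies how often each feature occurs in each class; an *influence
value* per (class, feature) is a conditional probability, optionally scaled by
a tf-idf weight computed from the same counts.  Prediction sums the influence
values of a sample's features per class and returns the top class (binary
tasks) or the five top-scoring classes (descriptor tasks).  Because influence
values are plain per-feature numbers, the model's decisions decompose exactly
into per-feature contributions, which is the basis of the interpretability
outputs (influence differences and class dissimilarities).

Two conditional-probability variants exist:

* CP1 — class given feature: ``occ(C_i, F_j) / sum_n occ(C_n, F_j)``.
* CP2 — feature given class: ``occ(C_i, F_j) / len(C_i)`` where ``len(C_i)``
  is the total feature count of class ``C_i``.

The tf-idf weight for feature j in class i is

    tf_idf(i, j) = occ(F_j, C_i) / len(C_i) * log10(|C| / n_classes_with_F_j)

so features present in every class get weight exactly 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .chem_features import ConfigError, InputError

Variant = Literal["cp1", "cp2"]
Weighting = Literal["same", "tfidf"]

__all__ = [
    "FeatureClassCounts",
    "InfluenceTable",
    "PresenceScaler",
    "fit_counts",
    "conditional_probability",
    "tfidf_weight",
    "influence_table",
    "scaled_presence",
    "score_sample",
    "predict",
    "influence_difference",
    "descriptor_dissimilarity",
]


class FitError(ValueError):
    """Raised when training inputs cannot support a fit."""


@dataclass
class FeatureClassCounts:
    """Per-(class, feature) occurrence counts from a training set.

    ``occ[c][f]`` counts training samples labeled ``c`` whose feature set
    contains ``f`` (binary per sample); ``class_totals[c]`` is the total
    feature count of class ``c`` (the ``len(C_i)`` normalizer); and
    ``feature_class_presence[f]`` is the number of classes in which ``f``
    occurs at least once (the idf denominator).
    """

    classes: list[str]
    features: list[str]
    occ: dict[str, dict[str, int]]
    class_totals: dict[str, int]
    feature_class_presence: dict[str, int]

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def get(self, class_id: str, feature: str) -> int:
        return self.occ.get(class_id, {}).get(feature, 0)


def fit_counts(
    train_samples: Sequence[tuple[Iterable[str], Iterable[str] | str]],
) -> FeatureClassCounts:
    """Tally feature occurrences per class over (feature set, label(s)) pairs.

    Labels may be a single class (type task) or a set of classes (descriptor
    task); a multi-label sample contributes its features to every one of its
    classes.
    """
    if not train_samples:
        raise FitError("empty training set")
    occ: dict[str, dict[str, int]] = {}
    for features, labels in train_samples:
        feature_set = set(features)
        label_set = {labels} if isinstance(labels, str) else set(labels)
        if not label_set:
            raise FitError("sample with no class labels")
        for label in label_set:
            class_occ = occ.setdefault(label, {})
            for f in feature_set:
                class_occ[f] = class_occ.get(f, 0) + 1

    for label, class_occ in occ.items():
        if sum(class_occ.values()) == 0:
            raise FitError(f"class {label!r} has no feature occurrences")

    features = sorted({f for class_occ in occ.values() for f in class_occ})
    presence = {
        f: sum(1 for class_occ in occ.values() if class_occ.get(f, 0) > 0) for f in features
    }
    return FeatureClassCounts(
        classes=sorted(occ),
        features=features,
        occ=occ,
        class_totals={c: sum(occ[c].values()) for c in occ},
        feature_class_presence=presence,
    )


def conditional_probability(
    counts: FeatureClassCounts, variant: Variant, class_id: str, feature: str
) -> float:
    """CP1 (class given feature) or CP2 (feature given class); unknown feature -> 0."""
    if variant not in ("cp1", "cp2"):
        raise ConfigError(f"unknown variant: {variant!r}")
    k = counts.get(class_id, feature)
    if k == 0:
        return 0.0
    if variant == "cp1":
        total = sum(counts.get(c, feature) for c in counts.classes)
        return k / total
    return k / counts.class_totals[class_id]


def tfidf_weight(
    counts: FeatureClassCounts, class_id: str, feature: str, log_base: float = 10.0
) -> float:
    """Term-frequency x inverse-document-frequency weight of a feature in a class.

    tf is the class-relative occurrence frequency; idf is the log of the
    number of classes over the number of classes containing the feature.  A
    feature present in all classes gets 0; a feature present in none gets 0.
    """
    presence = counts.feature_class_presence.get(feature, 0)
    if presence == 0:
        return 0.0
    tf = counts.get(class_id, feature) / counts.class_totals[class_id]
    idf = math.log(counts.n_classes / presence) / math.log(log_base)
    return tf * idf


@dataclass
class InfluenceTable:
    """Per (class, feature) influence values: weight x conditional probability."""

    variant: Variant
    weighting: Weighting
    classes: list[str]
    features: list[str]
    values: dict[str, dict[str, float]]

    def value(self, class_id: str, feature: str) -> float:
        return self.values.get(class_id, {}).get(feature, 0.0)

    def to_json(self) -> str:
        return json.dumps(
            {
                "schema": "mixodor.influence_table/1",
                "variant": self.variant,
                "weighting": self.weighting,
                "classes": self.classes,
                "features": self.features,
                "values": self.values,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "InfluenceTable":
        doc = json.loads(text)
        return cls(
            variant=doc["variant"],
            weighting=doc["weighting"],
            classes=doc["classes"],
            features=doc["features"],
            values=doc["values"],
        )


def influence_table(
    counts: FeatureClassCounts,
    variant: Variant = "cp1",
    weighting: Weighting = "same",
    log_base: float = 10.0,
) -> InfluenceTable:
    """Build the influence table for one variant/weighting combination."""
    if weighting not in ("same", "tfidf"):
        raise ConfigError(f"unknown weighting: {weighting!r}")
    values: dict[str, dict[str, float]] = {}
    for c in counts.classes:
        row: dict[str, float] = {}
        for f in counts.features:
            cp = conditional_probability(counts, variant, c, f)
            w = 1.0 if weighting == "same" else tfidf_weight(counts, c, f, log_base)
            v = w * cp
            if v != 0.0 or counts.get(c, f) > 0:
                row[f] = v
        values[c] = row
    return InfluenceTable(
        variant=variant,
        weighting=weighting,
        classes=list(counts.classes),
        features=list(counts.features),
        values=values,
    )


@dataclass
class PresenceScaler:
    """Feature standardization fitted on a fold's training presence matrix.

    Mirrors scikit-learn's StandardScaler (population standard deviation).
    After scaling, a feature standardized to a positive value counts as
    present for the sample; non-positive (or zero-variance) features count as
    non-present.
    """

    mean: np.ndarray
    std: np.ndarray
    features: list[str]

    @classmethod
    def fit(cls, presence_matrix: np.ndarray, features: Sequence[str]) -> "PresenceScaler":
        m = np.asarray(presence_matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != len(features):
            raise InputError(
                f"presence matrix shape {m.shape} does not match {len(features)} features"
            )
        return cls(mean=m.mean(axis=0), std=m.std(axis=0), features=list(features))


def scaled_presence(
    presence_matrix: np.ndarray, scaler: PresenceScaler, sample_row: int
) -> set[str]:
    """Features of one sample whose standardized presence value is > 0.

    Zero-variance features (constant in the training fold) are never present.
    """
    row = np.asarray(presence_matrix, dtype=float)[sample_row]
    if row.shape[0] != len(scaler.features):
        raise InputError(
            f"sample has {row.shape[0]} features, scaler expects {len(scaler.features)}"
        )
    present: set[str] = set()
    for j, name in enumerate(scaler.features):
        if scaler.std[j] > 0 and (row[j] - scaler.mean[j]) / scaler.std[j] > 0:
            present.add(name)
    return present


def score_sample(table: InfluenceTable, features: Iterable[str]) -> dict[str, float]:
    """Per-class sum of influence values of the sample's features.

    Features unseen in training contribute 0; a sample sharing no feature with
    the training vocabulary scores 0 for every class.
    """
    feature_set = set(features)
    return {
        c: sum(table.values[c].get(f, 0.0) for f in feature_set) for c in table.classes
    }


def predict(scores: Mapping[str, float], k: int = 1) -> tuple[list[str], bool]:
    """Top-k classes by score, deterministically tie-broken.

    Ties are broken by descending score then ascending class name.  Returns
    the ordered label list and a flag that is True when every score was zero
    (the prediction then degenerates to the k alphabetically first classes).
    """
    if k > len(scores):
        raise InputError(f"k={k} exceeds number of classes ({len(scores)})")
    ordered = sorted(scores, key=lambda c: (-scores[c], c))
    all_zero = all(v == 0 for v in scores.values())
    return ordered[:k], all_zero


def influence_difference(
    table: InfluenceTable, feature: str, class_a: str, class_b: str
) -> float:
    """Signed influence gap of one feature between two classes (a minus b)."""
    for c in (class_a, class_b):
        if c not in table.values:
            raise InputError(f"unknown class: {c!r}")
    return table.value(class_a, feature) - table.value(class_b, feature)


def descriptor_dissimilarity(
    table: InfluenceTable, class_a: str, class_b: str
) -> tuple[float, float]:
    """Class dissimilarity as summed absolute influence differences.

    Returns ``(dissimilarity, arc_width)`` where
    ``arc_width = 1.1 ** (dissimilarity * 1000)`` — the transform used to draw
    dissimilarity arcs with visible width differences.  Symmetric in the two
    classes; a class compared with itself gives (0, 1).
    """
    for c in (class_a, class_b):
        if c not in table.values:
            raise InputError(f"unknown class: {c!r}")
    features = set(table.values[class_a]) | set(table.values[class_b])
    d = sum(abs(table.value(class_a, f) - table.value(class_b, f)) for f in features)
    return d, 1.1 ** (d * 1000.0)
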