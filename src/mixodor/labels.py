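"""Consensus odor-descriptor labels from rate-all-that-apply (RATA) panels.

Each panelist rates the intensity of at most five applicable descriptors per
sample on an integer scale; everything unrated counts as 0.  The consensus
score of a (sample, descriptor) pair is the plain sum of ratings over
panelists, and a sample's label set is the five descriptors with the highest
consensus score.  Ties across the fifth-place boundary are resolved by a
seeded uniform draw so labels are reproducible across runs.

Class weights for imbalance-aware training are derived per cross-validation
fold:  ``w = 0`` if the descriptor never occurs in the fold's training labels,
else ``w = log(1 + y/x)`` with ``x`` the fold frequency and ``y`` the overall
frequency (natural log).  Rare descriptors thus get large weights, descriptors
absent from a fold contribute nothing.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .chem_features import ConfigError, InputError

__all__ = [
    "RataTable",
    "ConsensusScores",
    "LabelSet",
    "sum_rata",
    "top5_labels",
    "remove_class",
    "fold_class_weights",
    "TOP_K",
]

TOP_K = 5  # descriptors per label set, matching the RATA cap


@dataclass
class RataTable:
    """Panelist x sample x descriptor integer intensity ratings (absent = 0)."""

    panelists: list[str]
    samples: list[str]
    descriptors: list[str]
    ratings: dict[tuple[str, str, str], int]

    def __post_init__(self) -> None:
        for (p, s, d), r in self.ratings.items():
            if r < 0 or int(r) != r:
                raise InputError(f"rating for ({p}, {s}, {d}) must be a non-negative integer")
        for p in self.panelists:
            for s in self.samples:
                nonzero = sum(
                    1 for d in self.descriptors if self.ratings.get((p, s, d), 0) > 0
                )
                if nonzero > TOP_K:
                    raise InputError(
                        f"panelist {p!r} rated {nonzero} descriptors for sample {s!r}; "
                        f"the RATA protocol allows at most {TOP_K}"
                    )

    def rating(self, panelist: str, sample: str, descriptor: str) -> int:
        return self.ratings.get((panelist, sample, descriptor), 0)

    def panelist_scores(self, panelist: str, sample: str) -> dict[str, int]:
        return {d: self.rating(panelist, sample, d) for d in self.descriptors}


@dataclass
class ConsensusScores:
    """Summed panel ratings per (sample, descriptor)."""

    samples: list[str]
    descriptors: list[str]
    scores: dict[tuple[str, str], int]

    def sample_scores(self, sample: str) -> dict[str, int]:
        return {d: self.scores.get((sample, d), 0) for d in self.descriptors}


@dataclass(frozen=True)
class LabelSet:
    """The five consensus descriptors of one sample."""

    sample_id: str
    labels: frozenset[str]
    tie_seed: int

    def __post_init__(self) -> None:
        if len(self.labels) != TOP_K:
            raise InputError(f"label set must contain exactly {TOP_K} descriptors")


def sum_rata(table: RataTable) -> ConsensusScores:
    """Sum ratings over panelists; descriptors never rated get 0."""
    scores: dict[tuple[str, str], int] = {
        (s, d): 0 for s in table.samples for d in table.descriptors
    }
    for (p, s, d), r in table.ratings.items():
        scores[(s, d)] += int(r)
    return ConsensusScores(
        samples=list(table.samples), descriptors=list(table.descriptors), scores=scores
    )


def _sample_rng(seed: int, sample: str) -> np.random.Generator:
    # one independent, reproducible stream per (seed, sample)
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(sample.encode())])


def top5_labels(scores: ConsensusScores, sample: str, seed: int = 0) -> LabelSet:
    """The five highest-consensus descriptors of one sample.

    Descriptors strictly above the fifth-place score are always chosen; the
    remaining slots are filled by a seeded uniform draw (without replacement)
    among the descriptors tied at the boundary.
    """
    if len(scores.descriptors) < TOP_K:
        raise InputError(
            f"need >= {TOP_K} descriptors in the vocabulary, got {len(scores.descriptors)}"
        )
    per = scores.sample_scores(sample)
    ordered = sorted(scores.descriptors, key=lambda d: (-per[d], d))
    cut_score = per[ordered[TOP_K - 1]]
    above = [d for d in scores.descriptors if per[d] > cut_score]
    tied = sorted(d for d in scores.descriptors if per[d] == cut_score)
    n_needed = TOP_K - len(above)
    if len(tied) == n_needed:
        chosen = tied
    else:
        rng = _sample_rng(seed, sample)
        chosen = list(rng.choice(tied, size=n_needed, replace=False))
    return LabelSet(sample_id=sample, labels=frozenset(above) | frozenset(chosen), tie_seed=seed)


def remove_class(
    label_sets: Sequence[LabelSet],
    descriptors: Sequence[str],
    descriptor: str,
) -> tuple[list[LabelSet], list[str]]:
    """Drop a descriptor from the classification vocabulary.

    Only descriptors that ended up in no label set may be removed (removing a
    used descriptor would silently corrupt the label sets); regression keeps
    the full vocabulary and never calls this.  Removing an unknown descriptor
    is a no-op.
    """
    if descriptor not in descriptors:
        import warnings

        warnings.warn(f"descriptor {descriptor!r} not in vocabulary; nothing removed")
        return list(label_sets), list(descriptors)
    if any(descriptor in ls.labels for ls in label_sets):
        raise ConfigError(
            f"descriptor {descriptor!r} occurs in computed label sets and cannot be removed"
        )
    return list(label_sets), [d for d in descriptors if d != descriptor]


def fold_class_weights(
    train_label_sets: Sequence[LabelSet],
    all_label_sets: Sequence[LabelSet],
    descriptors: Sequence[str],
    log_base: float | None = None,
) -> dict[str, float]:
    """Inverted class weights for one fold: 0 if absent, else log(1 + y/x).

    ``x`` is the descriptor's frequency in the fold's training label sets and
    ``y`` its frequency over all label sets.  Natural log by default.
    """
    weights: dict[str, float] = {}
    for d in descriptors:
        x = sum(1 for ls in train_label_sets if d in ls.labels)
        y = sum(1 for ls in all_label_sets if d in ls.labels)
        if x == 0:
            weights[d] = 0.0
        else:
            w = math.log(1 + y / x)
            if log_base is not None:
                w /= math.log(log_base)
            weights[d] = w
    return weights
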