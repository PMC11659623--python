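"""Leave-one-out harness, re-creation evaluation, and the shared metrics.

Multi-label predictions (top-5 descriptor sets) are scored with micro-pooled
metrics — micro F1, micro Matthews correlation, and micro ROCAUC over the
flattened (sample, class) matrix — because per-class metrics are unstable
under heavy class imbalance at 16-sample scale.  Regression is scored with
the Pearson correlation of the flattened predicted and true score matrices
across all held-out folds.

``run_experiment`` orchestrates everything: it builds the folds, fits every
per-fold artifact (presence scalers, tf-idf tables, class weights) on the
fold's training rows only, collects the held-out predictions, and pools the
metrics.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from sklearn.metrics import f1_score, matthews_corrcoef, roc_auc_score

from . import owsum as ow
from .baselines import FoldPrediction, educated_guess, ovr_baseline, subject_x_metrics
from .chem_features import (
    ConfigError,
    InputError,
    build_applicability_matrix,
    pairwise_mcs,
)
from .cnn_model import CnnConfig, SampleFeatureStack, predict_cnn, train_cnn
from .labels import LabelSet, fold_class_weights, sum_rata

__all__ = [
    "MetricsReport",
    "loo_folds",
    "multilabel_metrics",
    "pearson_correlation",
    "run_experiment",
]


@dataclass
class MetricsReport:
    """Per-fold and aggregate metrics of one experiment."""

    method: str
    task: str
    mode: Literal["loo", "recreation"]
    per_fold: list[dict]
    aggregate: dict
    pcc: float | None = None
    config: dict = field(default_factory=dict)
    seed: int = 0

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(type(o))

        doc = {
            "schema": "mixodor.metrics_report/1",
            "method": self.method,
            "task": self.task,
            "mode": self.mode,
            "config": self.config,
            "config_hash": hashlib.sha256(
                json.dumps(self.config, sort_keys=True, default=str).encode()
            ).hexdigest()[:16],
            "seed": self.seed,
            "per_fold": self.per_fold,
            "aggregate": self.aggregate,
            "pcc": self.pcc,
        }
        return json.dumps(doc, indent=2, sort_keys=True, default=default)


def loo_folds(sample_ids: Sequence[str]) -> list[tuple[list[str], str]]:
    """One fold per sample: (all other ids, held-out id)."""
    ids = list(sample_ids)
    if len(ids) != len(set(ids)):
        raise InputError("duplicate sample ids")
    if len(ids) < 2:
        raise InputError("need >= 2 samples for leave-one-out")
    return [([s for s in ids if s != t], t) for t in ids]


def multilabel_metrics(
    true_matrix: np.ndarray,
    pred_matrix: np.ndarray,
    score_matrix: np.ndarray | None = None,
) -> dict:
    """Micro F1 / MCC / accuracy (and ROCAUC when scores are given).

    All metrics are computed on the flattened (sample, class) binary matrix,
    i.e. from pooled confusion counts.  ROCAUC is ``None`` when the flattened
    truth is single-class (it is undefined there, not zero).
    """
    true_matrix = np.asarray(true_matrix)
    pred_matrix = np.asarray(pred_matrix)
    if true_matrix.shape != pred_matrix.shape:
        raise InputError(
            f"shape mismatch: truth {true_matrix.shape} vs prediction {pred_matrix.shape}"
        )
    t = true_matrix.ravel().astype(int)
    p = pred_matrix.ravel().astype(int)
    out = {
        "f1": float(f1_score(t, p, zero_division=0)),
        "mcc": float(matthews_corrcoef(t, p)),
        "accuracy": float((t == p).mean()),
    }
    if score_matrix is not None:
        s = np.asarray(score_matrix, dtype=float).ravel()
        if s.shape != t.shape:
            raise InputError("score matrix shape mismatch")
        out["rocauc"] = float(roc_auc_score(t, s)) if 0 < t.sum() < t.size else None
    return out


def pearson_correlation(pred: np.ndarray, truth: np.ndarray) -> float:
    """Product-moment correlation of the flattened matrices.

    Returns NaN (undefined) when either input is constant.
    """
    from scipy.stats import pearsonr

    p = np.asarray(pred, dtype=float).ravel()
    t = np.asarray(truth, dtype=float).ravel()
    if p.shape != t.shape:
        raise InputError("shape mismatch between prediction and truth")
    if p.size < 2:
        raise InputError("need at least 2 values")
    if p.std() == 0 or t.std() == 0:
        return math.nan
    return float(pearsonr(p, t).statistic)


# ---------------------------------------------------------------------------
# experiment orchestration

_DEFAULTS = dict(
    variant="cp2",
    weighting="tfidf",
    features="molecules",  # type task: "molecules" | "descriptors"
    scaled_presence=None,  # None -> on for descriptor task, off for type task
    applicability_mode="match_count",
    reference_size=12,
    epochs=None,  # None -> CnnConfig default per task
    pool_size=None,  # None -> CnnConfig default
    learning_rate=1e-2,
    feature_scaling=False,
    loss=None,  # None -> weighted_bce (classify) / l1 (regress)
    class_weight_all="train",  # "train" (leakage-free) | "dataset"
)


def _merge_config(config: Mapping | None) -> dict:
    cfg = dict(_DEFAULTS)
    if config:
        unknown = set(config) - set(cfg)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(config)
    return cfg


def _label_map(dataset) -> dict[str, LabelSet]:
    return {ls.sample_id: ls for ls in dataset.label_sets}


def _classification_vocab(dataset) -> list[str]:
    """Descriptors that occur in at least one label set.

    Descriptors never selected into a top-5 set (like a tied-out class at the
    boundary draw) are excluded from classification; regression keeps the full
    vocabulary.
    """
    used = set().union(*(ls.labels for ls in dataset.label_sets))
    return [d for d in dataset.descriptors if d in used]


def _presence_vectors(dataset) -> tuple[dict[str, np.ndarray], list[str]]:
    molecule_vocab = sorted({m for s in dataset.samples for m in s.molecule_ids()})
    index = {m: j for j, m in enumerate(molecule_vocab)}
    vectors = {}
    for s in dataset.samples:
        v = np.zeros(len(molecule_vocab))
        for m in s.molecule_ids():
            v[index[m]] = 1.0
        vectors[s.sample_id] = v
    return vectors, molecule_vocab


def _fold_weights(train_labels, dataset, vocab, cfg) -> dict[str, float]:
    reference = dataset.label_sets if cfg["class_weight_all"] == "dataset" else train_labels
    return fold_class_weights(train_labels, reference, vocab)


def _owsum_fold(dataset, train_ids, test_ids, vocab, cfg, task):
    """Fit OWSum on a fold's training samples and predict the held-out ones."""
    labels = _label_map(dataset)
    presence, molecule_vocab = _presence_vectors(dataset)
    rows = {s.sample_id: i for i, s in enumerate(dataset.samples)}
    matrix = np.vstack([presence[s.sample_id] for s in dataset.samples])

    use_scaled = cfg["scaled_presence"]
    if use_scaled is None:
        use_scaled = task == "descriptors"
    if use_scaled:
        scaler = ow.PresenceScaler.fit(matrix[[rows[s] for s in train_ids]], molecule_vocab)
        feature_sets = {
            sid: ow.scaled_presence(matrix, scaler, rows[sid])
            for sid in list(train_ids) + list(test_ids)
        }
    else:
        scaler = None
        feature_sets = {
            sid: next(s for s in dataset.samples if s.sample_id == sid).molecule_ids()
            for sid in list(train_ids) + list(test_ids)
        }

    if task == "type":
        if cfg["features"] == "descriptors":
            feature_sets = {sid: set(labels[sid].labels) for sid in feature_sets}
        train = [(feature_sets[sid], dataset.truth.type_labels[sid]) for sid in train_ids]
    else:
        train = [(feature_sets[sid], labels[sid].labels & set(vocab)) for sid in train_ids]

    counts = ow.fit_counts(train)
    table = ow.influence_table(counts, variant=cfg["variant"], weighting=cfg["weighting"])
    predictions = []
    for sid in test_ids:
        scores = ow.score_sample(table, feature_sets[sid])
        if task == "type":
            (top,), _ = ow.predict(scores, k=1)
            predictions.append((sid, top, scores))
        else:
            full = {d: scores.get(d, 0.0) for d in vocab}
            top5, _ = ow.predict(full, k=5)
            predictions.append(
                FoldPrediction(
                    sample_id=sid,
                    predicted=top5,
                    score_vector=np.array([full[d] for d in vocab]),
                )
            )
    return predictions, table, scaler


def _cnn_features(dataset, cfg) -> dict[str, SampleFeatureStack]:
    """MCS patterns from the reference pool -> per-sample applicability stacks.

    Feature construction is unsupervised (it sees structures only, never
    labels), so it is computed once and shared across folds.
    """
    from .io_cli import load_reference_pool

    reference = load_reference_pool()[: int(cfg["reference_size"])]
    patterns = pairwise_mcs(reference, min_atoms=2)
    pool = {m.molecule_id: m for s in dataset.samples for m in s.molecules}
    molecules = [pool[mid] for mid in sorted(pool)]
    matrix = build_applicability_matrix(molecules, patterns, mode=cfg["applicability_mode"])
    row_of = {mid: i for i, mid in enumerate(matrix.molecule_ids)}
    stacks = {}
    for s in dataset.samples:
        ordered = sorted(s.molecules, key=lambda m: m.molecule_id)
        rows = matrix.values[[row_of[m.molecule_id] for m in ordered]]
        areas = np.array([m.peak_area if m.peak_area is not None else 1.0 for m in ordered])
        stacks[s.sample_id] = SampleFeatureStack(
            sample_id=s.sample_id, rows=rows, peak_areas=areas
        )
    return stacks


def _cnn_config(cfg, output_size, task, seed) -> CnnConfig:
    loss = cfg["loss"] or ("weighted_bce" if task == "descriptors" else "l1")
    epochs = cfg["epochs"] or (11 if task == "descriptors" else 21)
    extra = {}
    if cfg["pool_size"] is not None:
        extra["pool_size"] = tuple(cfg["pool_size"])
    return CnnConfig(
        output_size=output_size,
        epochs=int(epochs),
        **extra,
        learning_rate=float(cfg["learning_rate"]),
        seed=seed,
        feature_scaling=bool(cfg["feature_scaling"]),
        loss=loss,
    )


def run_experiment(
    dataset,
    method: Literal["owsum", "cnn", "svm", "rf", "guess", "subjectx"],
    task: Literal["type", "descriptors", "regression"] = "descriptors",
    mode: Literal["loo", "recreation"] = "loo",
    config: Mapping | None = None,
    seed: int = 0,
) -> MetricsReport:
    """Run one method on one task and return pooled + per-fold metrics."""
    cfg = _merge_config(config)
    ids = dataset.sample_ids()
    labels = _label_map(dataset)

    if task == "type":
        if method != "owsum":
            raise ConfigError(f"type task supports method 'owsum', not {method!r}")
        folds = loo_folds(ids) if mode == "loo" else [(ids, ids)]
        per_fold, correct = [], []
        for train_ids, test in folds:
            test_ids = [test] if isinstance(test, str) else test
            preds, _, _ = _owsum_fold(dataset, train_ids, test_ids, None, cfg, task)
            for sid, top, scores in preds:
                ok = top == dataset.truth.type_labels[sid]
                correct.append(ok)
                per_fold.append({"sample_id": sid, "predicted": top, "correct": bool(ok)})
        return MetricsReport(
            method=method,
            task=task,
            mode=mode,
            per_fold=per_fold,
            aggregate={"accuracy": float(np.mean(correct))},
            config=dict(cfg),
            seed=seed,
        )

    if task == "regression":
        if method != "cnn":
            raise ConfigError(f"regression task supports method 'cnn', not {method!r}")
        consensus = sum_rata(dataset.rata)
        descriptors = list(dataset.descriptors)
        targets = {
            sid: np.array([consensus.scores[(sid, d)] for d in descriptors], dtype=float)
            for sid in ids
        }
        stacks = _cnn_features(dataset, cfg)
        model_cfg = _cnn_config(cfg, len(descriptors), task, seed)
        folds = loo_folds(ids) if mode == "loo" else [(ids, ids)]
        pred_rows, true_rows, per_fold = [], [], []
        for train_ids, test in folds:
            test_ids = [test] if isinstance(test, str) else test
            model, _ = train_cnn(
                [stacks[s] for s in train_ids],
                np.vstack([targets[s] for s in train_ids]),
                model_cfg,
            )
            for sid in test_ids:
                out = predict_cnn(model, stacks[sid], task="regress")
                pred_rows.append(out)
                true_rows.append(targets[sid])
                per_fold.append({"sample_id": sid})
        pcc = pearson_correlation(np.vstack(pred_rows), np.vstack(true_rows))
        return MetricsReport(
            method=method,
            task=task,
            mode=mode,
            per_fold=per_fold,
            aggregate={"pcc": pcc},
            pcc=pcc,
            config=dict(cfg),
            seed=seed,
        )

    # descriptor classification
    vocab = _classification_vocab(dataset)

    if method == "subjectx":
        report = subject_x_metrics(dataset.rata, seed=seed)
        return MetricsReport(
            method=method,
            task=task,
            mode=mode,
            per_fold=report["per_panelist"],
            aggregate=report["mean"],
            config=dict(cfg),
            seed=seed,
        )

    folds = loo_folds(ids) if mode == "loo" else [(ids, ids)]
    predictions: list[FoldPrediction] = []
    if method == "owsum":
        for train_ids, test in folds:
            test_ids = [test] if isinstance(test, str) else test
            preds, _, _ = _owsum_fold(dataset, train_ids, test_ids, vocab, cfg, task)
            predictions.extend(preds)
    elif method == "guess":
        for train_ids, test in folds:
            test_ids = [test] if isinstance(test, str) else test
            template = educated_guess([labels[s] for s in train_ids], vocab)
            for sid in test_ids:
                predictions.append(
                    FoldPrediction(
                        sample_id=sid,
                        predicted=list(template.predicted),
                        score_vector=template.score_vector.copy(),
                    )
                )
    elif method in ("svm", "rf"):
        presence, _ = _presence_vectors(dataset)
        flat_folds = []
        for train_ids, test in folds:
            for sid in [test] if isinstance(test, str) else test:
                flat_folds.append((list(train_ids), sid))
        predictions = ovr_baseline(method, flat_folds, presence, labels, vocab, seed=seed)
    elif method == "cnn":
        stacks = _cnn_features(dataset, cfg)
        model_cfg = _cnn_config(cfg, len(vocab), task, seed)
        for train_ids, test in folds:
            test_ids = [test] if isinstance(test, str) else test
            train_labels = [labels[s] for s in train_ids]
            weights = _fold_weights(train_labels, dataset, vocab, cfg)
            y = np.array(
                [[d in labels[s].labels for d in vocab] for s in train_ids], dtype=float
            )
            model, _ = train_cnn(
                [stacks[s] for s in train_ids],
                y,
                model_cfg,
                class_weights=[weights[d] for d in vocab],
            )
            for sid in test_ids:
                top5, out = predict_cnn(model, stacks[sid], task="classify", class_names=vocab)
                predictions.append(
                    FoldPrediction(sample_id=sid, predicted=top5, score_vector=out)
                )
    else:
        raise ConfigError(f"unknown method: {method!r}")

    true = np.array(
        [[d in labels[p.sample_id].labels for d in vocab] for p in predictions], dtype=int
    )
    pred = np.array([[d in p.predicted for d in vocab] for p in predictions], dtype=int)
    scores = np.vstack([p.score_vector for p in predictions])
    per_fold = []
    for i, p in enumerate(predictions):
        entry = {"sample_id": p.sample_id, "predicted": list(p.predicted)}
        entry.update(multilabel_metrics(true[i : i + 1], pred[i : i + 1]))
        per_fold.append(entry)
    aggregate = multilabel_metrics(true, pred, scores)
    return MetricsReport(
        method=method,
        task=task,
        mode=mode,
        per_fold=per_fold,
        aggregate=aggregate,
        config=dict(cfg),
        seed=seed,
    )
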