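"""Balanced sampling, random-forest training, cross-validation, ranking.

Known lncRNA-disease pairs are the positive class; an equal number of
unlabeled pairs, drawn uniformly at random without replacement, form the
negative class.  A pair is represented by the concatenation of its
encoded lncRNA and disease feature vectors.  The classifier is a random
forest whose score for a pair is the fraction of trees voting positive.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    accuracy_score,
    auc,
    f1_score,
    precision_recall_curve,
    recall_score,
    roc_auc_score,
    roc_curve,
)
from sklearn.model_selection import StratifiedKFold

from .features import FeatureTable
from .network import BipartiteAdjacency


class PredictorError(ValueError):
    pass


@dataclass
class SampleSet:
    """Balanced positive/negative pair sample set with pair features."""

    pairs: list[tuple[int, int]]
    features: np.ndarray
    labels: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        if len(self.pairs) != len(self.labels) or len(self.pairs) != len(self.features):
            raise PredictorError("pairs, features and labels must align")

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class ForestParams:
    """Random-forest hyperparameters.

    ntree=500 and mtry=floor(sqrt(feature width)) are the classical
    random-forest classification defaults.
    """

    ntree: int = 500
    mtry: int | None = None  # None -> floor(sqrt(feature width))
    seed: int = 0

    def resolve_mtry(self, n_features: int) -> int:
        mtry = self.mtry if self.mtry is not None else int(math.sqrt(n_features))
        mtry = max(1, mtry)
        if mtry > n_features:
            raise PredictorError(f"mtry ({mtry}) exceeds feature width ({n_features})")
        return mtry


@dataclass
class EvaluationReport:
    """Per-fold and averaged cross-validation metrics."""

    fold_metrics: list[dict[str, float]]
    fold_assignments: np.ndarray
    roc_points: np.ndarray  # (n, 2): fpr, tpr over pooled held-out scores
    pr_points: np.ndarray  # (n, 2): recall, precision
    pooled_scores: np.ndarray | None = None  # held-out score per sample
    params: dict = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    @property
    def mean_metrics(self) -> dict[str, float]:
        keys = self.fold_metrics[0].keys()
        return {
            k: float(np.mean([fm[k] for fm in self.fold_metrics])) for k in keys
        }

    def to_dict(self) -> dict:
        return {
            "fold_metrics": self.fold_metrics,
            "mean_metrics": self.mean_metrics,
            "fold_assignments": self.fold_assignments.tolist(),
            "params": self.params,
            "notes": self.notes,
        }

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
        return path


@dataclass
class RankedPredictions:
    """Scored unlabeled candidates, best first; name tie-breaks."""

    disease: str
    entries: list[tuple[str, str, float]]  # (lncRNA, disease, score)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        lines = ["lncRNA\tdisease\tscore"]
        lines += [f"{l}\t{d}\t{s:.6f}" for l, d, s in self.entries]
        path.write_text("\n".join(lines) + "\n")
        return path


def _pair_features(
    pairs: Sequence[tuple[int, int]],
    lnc_enc: FeatureTable,
    dis_enc: FeatureTable,
) -> np.ndarray:
    idx = np.asarray(pairs, dtype=int).reshape(-1, 2)
    return np.hstack([lnc_enc.values[idx[:, 0]], dis_enc.values[idx[:, 1]]])


def build_samples(
    ld: BipartiteAdjacency,
    lnc_enc: FeatureTable,
    dis_enc: FeatureTable,
    seed: int = 0,
) -> SampleSet:
    """All observed pairs as positives plus an equal-size random draw of
    unlabeled pairs as negatives; reproducible under ``seed``."""
    if len(lnc_enc.registry) != ld.shape[0] or len(dis_enc.registry) != ld.shape[1]:
        raise PredictorError("encoded tables do not cover the LD matrix entities")
    pos = np.argwhere(ld.values == 1)
    neg_pool = np.argwhere(ld.values == 0)
    if len(pos) == 0:
        raise PredictorError("LD matrix has no positive associations")
    if len(neg_pool) < len(pos):
        raise PredictorError(
            f"only {len(neg_pool)} unlabeled pairs available for "
            f"{len(pos)} positives"
        )
    rng = np.random.default_rng(seed)
    neg = neg_pool[rng.choice(len(neg_pool), size=len(pos), replace=False)]
    pairs = [tuple(p) for p in pos] + [tuple(p) for p in neg]
    labels = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))]).astype(int)
    feats = _pair_features(pairs, lnc_enc, dis_enc)
    return SampleSet(pairs=pairs, features=feats, labels=labels, seed=seed)


def _make_forest(params: ForestParams, n_features: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=params.ntree,
        max_features=params.resolve_mtry(n_features),
        random_state=params.seed,
        n_jobs=None,
    )


def train_forest(samples: SampleSet, params: ForestParams) -> RandomForestClassifier:
    """Fit the forest on the full sample set."""
    if len(samples) == 0:
        raise PredictorError("empty sample set")
    if len(np.unique(samples.labels)) < 2:
        raise PredictorError("sample set must contain both classes")
    clf = _make_forest(params, samples.features.shape[1])
    clf.fit(samples.features, samples.labels)
    return clf


def score_pairs(clf: RandomForestClassifier, features: np.ndarray) -> np.ndarray:
    """Vote-fraction scores in [0, 1] for the positive class."""
    pos_col = int(np.argmax(clf.classes_ == 1))
    return clf.predict_proba(features)[:, pos_col]


def _fold_metrics(y: np.ndarray, scores: np.ndarray) -> dict[str, float]:
    pred = (scores >= 0.5).astype(int)
    prec, rec, _ = precision_recall_curve(y, scores)
    return {
        "auc": float(roc_auc_score(y, scores)),
        "aupr": float(auc(rec, prec)),
        "recall": float(recall_score(y, pred, zero_division=0)),
        "accuracy": float(accuracy_score(y, pred)),
        "f1": float(f1_score(y, pred, zero_division=0)),
    }


def cross_validate(
    samples: SampleSet,
    params: ForestParams,
    k: int = 5,
    seed: int = 0,
) -> EvaluationReport:
    """Stratified k-fold cross-validation of the forest.

    Each fold's model is trained on the other k-1 folds and scored on
    the held-out fold; AUC is the rank statistic over held-out scores,
    AUPR the precision-recall integral, and recall/accuracy/F1 use a
    0.5 score cutoff.  The reported means are fold averages.
    """
    if k < 2:
        raise PredictorError("k must be at least 2")
    counts = np.bincount(samples.labels, minlength=2)
    if counts.min() < k:
        raise PredictorError(
            f"k={k} exceeds the smaller class count ({counts.min()})"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignments = np.full(len(samples), -1, dtype=int)
    fold_metrics: list[dict[str, float]] = []
    pooled_scores = np.zeros(len(samples))
    for fold, (train_idx, test_idx) in enumerate(
        skf.split(samples.features, samples.labels)
    ):
        clf = _make_forest(
            ForestParams(params.ntree, params.mtry, params.seed + fold),
            samples.features.shape[1],
        )
        clf.fit(samples.features[train_idx], samples.labels[train_idx])
        scores = score_pairs(clf, samples.features[test_idx])
        pooled_scores[test_idx] = scores
        assignments[test_idx] = fold
        fold_metrics.append(_fold_metrics(samples.labels[test_idx], scores))
    fpr, tpr, _ = roc_curve(samples.labels, pooled_scores)
    prec, rec, _ = precision_recall_curve(samples.labels, pooled_scores)
    return EvaluationReport(
        fold_metrics=fold_metrics,
        fold_assignments=assignments,
        roc_points=np.column_stack([fpr, tpr]),
        pr_points=np.column_stack([rec, prec]),
        pooled_scores=pooled_scores,
        params={
            "ntree": params.ntree,
            "mtry": params.resolve_mtry(samples.features.shape[1]),
            "k": k,
            "cv_seed": seed,
            "sampling_seed": samples.seed,
        },
    )


def rank_candidates(
    clf: RandomForestClassifier,
    ld: BipartiteAdjacency,
    lnc_enc: FeatureTable,
    dis_enc: FeatureTable,
    disease: str,
    top_n: int = 20,
) -> RankedPredictions:
    """Score and rank all lncRNAs not yet linked to ``disease``.

    Ties are broken deterministically by (lncRNA name, disease name).
    """
    j = ld.col_registry.position(disease)
    candidates = np.flatnonzero(ld.values[:, j] == 0)
    if len(candidates) == 0:
        return RankedPredictions(disease=disease, entries=[])
    feats = _pair_features([(i, j) for i in candidates], lnc_enc, dis_enc)
    scores = score_pairs(clf, feats)
    order = sorted(
        range(len(candidates)),
        key=lambda q: (-scores[q], ld.row_registry.names[candidates[q]], disease),
    )
    entries = [
        (ld.row_registry.names[candidates[q]], disease, float(scores[q]))
        for q in order[:top_n]
    ]
    return RankedPredictions(disease=disease, entries=entries)
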