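"""Classifier training, evaluation metrics and candidate ranking.

The association model is a gradient-boosted tree ensemble (XGBoost). It is
wrapped in the sklearn-style :class:`AssociationClassifier`, which pins the
feature-name contract: prediction requires exactly the columns seen at fit
time, in order.

Evaluation reports AUC (rank statistic, ties averaged), MCC, balanced
accuracy and F1; thresholded metrics use 0.5 by default. Cross-validation
uses seeded stratified folds and aggregates per-fold metrics as mean +/- sd.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import (
    balanced_accuracy_score,
    f1_score,
    matthews_corrcoef,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.utils.validation import check_is_fitted
from xgboost import XGBClassifier

from .dataio import PredictionTable
from .features import FeatureTable

logger = logging.getLogger(__name__)

__all__ = [
    "MetricsReport",
    "EvaluationReport",
    "AssociationClassifier",
    "ModelArtifact",
    "compute_metrics",
    "train_classifier",
    "cross_validate",
    "blind_test",
    "rank_candidates",
]

DEFAULT_XGB_PARAMS: dict = {
    "n_estimators": 100,
    "max_depth": 6,
    "learning_rate": 0.3,
    "tree_method": "hist",
    "n_jobs": 1,
    "eval_metric": "logloss",
}


@dataclass
class MetricsReport:
    auc: float
    mcc: float
    bacc: float
    f1: float
    per_fold: pd.DataFrame | None = None
    mean_sd: dict[str, tuple[float, float]] | None = None

    def as_dict(self) -> dict[str, float]:
        return {"auc": self.auc, "mcc": self.mcc, "bacc": self.bacc, "f1": self.f1}


@dataclass
class EvaluationReport:
    scheme: str  # cv5 | cv10 | cv20 | blind
    metrics: MetricsReport
    confusion: dict[str, int]  # tp/fp/tn/fn at the threshold
    seed: int
    n_samples: int

    def to_frame(self) -> pd.DataFrame:
        row = {"scheme": self.scheme, "seed": self.seed, "n_samples": self.n_samples}
        row.update(self.metrics.as_dict())
        if self.metrics.mean_sd:
            for k, (m, s) in self.metrics.mean_sd.items():
                row[f"{k}_mean"] = m
                row[f"{k}_sd"] = s
        row.update(self.confusion)
        return pd.DataFrame([row])


def _confusion(labels: np.ndarray, scores: np.ndarray, threshold: float):
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    return pred, {"tp": tp, "fp": fp, "tn": tn, "fn": fn}


def compute_metrics(
    labels: Sequence[int] | np.ndarray,
    scores: Sequence[float] | np.ndarray,
    threshold: float = 0.5,
) -> MetricsReport:
    """AUC / MCC / bACC / F1 for binary labels and real-valued scores.

    AUC is the Mann-Whitney rank statistic with ties averaged; the other
    three come from the confusion matrix at ``threshold``. Both classes must
    be present (AUC and MCC are undefined otherwise).
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must align")
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC/MCC require both classes present")
    pred, _ = _confusion(labels, scores, threshold)
    return MetricsReport(
        auc=float(roc_auc_score(labels, scores)),
        mcc=float(matthews_corrcoef(labels, pred)),
        bacc=float(balanced_accuracy_score(labels, pred)),
        f1=float(f1_score(labels, pred, zero_division=0)),
    )


class AssociationClassifier(BaseEstimator, ClassifierMixin):
    """Gradient-boosted-tree association classifier with a feature contract.

    Thin wrapper over :class:`xgboost.XGBClassifier` that records the
    feature names used at fit time and refuses to score inputs whose columns
    differ. Hyperparameters default to the library defaults and are fully
    exposed through ``xgb_params``.
    """

    def __init__(self, xgb_params: dict | None = None, random_state: int = 0):
        self.xgb_params = xgb_params
        self.random_state = random_state

    def _make_booster(self) -> XGBClassifier:
        params = dict(DEFAULT_XGB_PARAMS)
        if self.xgb_params:
            params.update(self.xgb_params)
        params.setdefault("random_state", self.random_state)
        model = XGBClassifier(**params)
        # newer sklearn mixins no longer set _estimator_type, which
        # xgboost's save/load path still requires
        model._estimator_type = "classifier"
        return model

    def fit(self, X, y, feature_names: Sequence[str] | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        self.booster_ = self._make_booster()
        self.booster_.fit(X, y)
        self.classes_ = np.unique(y)
        self.feature_names_ = (
            list(feature_names)
            if feature_names is not None
            else [f"f{i}" for i in range(X.shape[1])]
        )
        self.n_features_in_ = X.shape[1]
        return self

    def _check_features(self, feature_names: Sequence[str] | None, n_cols: int):
        check_is_fitted(self, "booster_")
        if n_cols != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {n_cols}"
            )
        if feature_names is not None and list(feature_names) != self.feature_names_:
            raise ValueError(
                "feature names/order differ from those used at fit time"
            )

    def predict_proba(self, X, feature_names: Sequence[str] | None = None):
        X = np.asarray(X, dtype=float)
        self._check_features(feature_names, X.shape[1])
        return self.booster_.predict_proba(X)

    def predict(self, X, feature_names: Sequence[str] | None = None):
        return (self.predict_proba(X, feature_names)[:, 1] >= 0.5).astype(int)

    def score_pairs(self, table: FeatureTable) -> np.ndarray:
        """Association scores for a feature table (enforces the contract)."""
        return self.predict_proba(table.matrix, table.feature_names)[:, 1]


@dataclass
class ModelArtifact:
    """Trained classifier plus the metadata needed to reuse it safely."""

    classifier: AssociationClassifier
    feature_names: list[str]
    metadata: dict = field(default_factory=dict)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.classifier.booster_.save_model(directory / "model.json")
        meta = dict(self.metadata)
        meta["feature_names"] = self.feature_names
        with open(directory / "metadata.json", "w") as fh:
            json.dump(meta, fh, indent=2)

    @classmethod
    def load(cls, directory: str | Path) -> "ModelArtifact":
        directory = Path(directory)
        with open(directory / "metadata.json") as fh:
            meta = json.load(fh)
        feature_names = meta.pop("feature_names")
        clf = AssociationClassifier()
        clf.booster_ = clf._make_booster()
        clf.booster_.load_model(directory / "model.json")
        clf.classes_ = np.array([0, 1])
        clf.feature_names_ = list(feature_names)
        clf.n_features_in_ = len(feature_names)
        return cls(clf, list(feature_names), meta)


def _data_hash(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(np.ascontiguousarray(y).tobytes())
    return h.hexdigest()[:16]


def train_classifier(
    dataset: FeatureTable, params: dict | None = None, seed: int = 0
) -> ModelArtifact:
    """Fit the gradient-boosted model on a labeled feature table."""
    if dataset.labels is None:
        raise ValueError("dataset has no labels")
    clf = AssociationClassifier(xgb_params=params, random_state=seed)
    clf.fit(dataset.matrix, dataset.labels, feature_names=dataset.feature_names)
    meta = {
        "seed": seed,
        "params": params or {},
        "trained_at": datetime.now(timezone.utc).isoformat(timespec="seconds"),
        "data_hash": _data_hash(dataset.matrix, np.asarray(dataset.labels)),
        "n_samples": len(dataset),
    }
    return ModelArtifact(clf, list(dataset.feature_names), meta)


def cross_validate(
    dataset: FeatureTable,
    k: int,
    seed: int = 0,
    params: dict | None = None,
    threshold: float = 0.5,
) -> EvaluationReport:
    """Seeded stratified k-fold cross-validation with mean +/- sd metrics."""
    if dataset.labels is None:
        raise ValueError("dataset has no labels")
    y = np.asarray(dataset.labels, dtype=int)
    min_class = min(np.bincount(y))
    if k > min_class:
        raise ValueError(f"k={k} exceeds the minority class count {min_class}")
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_rows = []
    confusion = {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
    for fold, (train, test) in enumerate(cv.split(dataset.matrix, y)):
        clf = AssociationClassifier(xgb_params=params, random_state=seed)
        clf.fit(dataset.matrix[train], y[train])
        scores = clf.predict_proba(dataset.matrix[test])[:, 1]
        rep = compute_metrics(y[test], scores, threshold)
        _, conf = _confusion(y[test], scores, threshold)
        for key in confusion:
            confusion[key] += conf[key]
        fold_rows.append({"fold": fold, **rep.as_dict()})
    per_fold = pd.DataFrame(fold_rows)
    mean_sd = {
        m: (float(per_fold[m].mean()), float(per_fold[m].std(ddof=1)))
        for m in ("auc", "mcc", "bacc", "f1")
    }
    metrics = MetricsReport(
        auc=mean_sd["auc"][0],
        mcc=mean_sd["mcc"][0],
        bacc=mean_sd["bacc"][0],
        f1=mean_sd["f1"][0],
        per_fold=per_fold,
        mean_sd=mean_sd,
    )
    return EvaluationReport(
        scheme=f"cv{k}",
        metrics=metrics,
        confusion=confusion,
        seed=seed,
        n_samples=len(dataset),
    )


def blind_test(
    dataset: FeatureTable,
    holdout_fraction: float = 0.2,
    seed: int = 0,
    params: dict | None = None,
    threshold: float = 0.5,
) -> EvaluationReport:
    """Stratified holdout evaluation: train on the remainder, score holdout."""
    if not 0.0 < holdout_fraction < 1.0:
        raise ValueError("holdout_fraction must be in (0, 1)")
    if dataset.labels is None:
        raise ValueError("dataset has no labels")
    y = np.asarray(dataset.labels, dtype=int)
    idx_train, idx_test = train_test_split(
        np.arange(len(dataset)),
        test_size=holdout_fraction,
        stratify=y,
        random_state=seed,
    )
    clf = AssociationClassifier(xgb_params=params, random_state=seed)
    clf.fit(dataset.matrix[idx_train], y[idx_train])
    scores = clf.predict_proba(dataset.matrix[idx_test])[:, 1]
    rep = compute_metrics(y[idx_test], scores, threshold)
    _, conf = _confusion(y[idx_test], scores, threshold)
    return EvaluationReport(
        scheme="blind",
        metrics=rep,
        confusion=conf,
        seed=seed,
        n_samples=len(idx_test),
    )


def rank_candidates(
    model: AssociationClassifier | ModelArtifact,
    disease_id: str,
    candidates: FeatureTable,
    k: int,
) -> PredictionTable:
    """Top-k candidate miRNAs for one disease, ranked by association score.

    Ties are broken by candidate (registry) order; asking for more
    candidates than exist returns the full ranking with a warning.
    """
    clf = model.classifier if isinstance(model, ModelArtifact) else model
    rows_for_disease = [
        i for i, (_, d) in enumerate(candidates.pair_ids) if d == disease_id
    ]
    if not rows_for_disease:
        raise ValueError(f"no candidates for disease {disease_id!r}")
    sub = candidates.subset(rows_for_disease)
    scores = clf.score_pairs(sub)
    if k > len(sub):
        logger.warning(
            "requested top-%d but only %d candidates; returning all", k, len(sub)
        )
        k = len(sub)
    order = np.argsort(-scores, kind="stable")[:k]
    rows = [
        (sub.pair_ids[i][0], disease_id, float(scores[i]), rank)
        for rank, i in enumerate(order, start=1)
    ]
    return PredictionTable(rows)
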