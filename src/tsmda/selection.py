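"""Two-stage feature selection.

Stage 1 removes redundant features: scanning the columns in a seeded-random
order, a feature is kept only if its absolute Pearson correlation with every
already-kept feature stays at or below a cutoff (default 0.6). Constant
columns, whose correlation is undefined, are dropped with a warning.

Stage 2 is forward stepwise greedy selection: starting from the empty set,
each step adds the feature whose inclusion maximises the mean Matthews
correlation coefficient of a gradient-boosted-tree classifier under seeded
stratified k-fold cross-validation, stopping when the best improvement
falls below an epsilon or a feature budget is reached.

Both stages are sklearn-style transformers (:class:`CorrelationFilter`,
:class:`GreedyForwardSelector`); :func:`correlation_filter` and
:func:`greedy_forward_select` wrap them for :class:`FeatureTable` inputs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin, clone
from sklearn.metrics import matthews_corrcoef
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .features import FeatureTable

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionConfig",
    "SelectionReport",
    "CorrelationFilter",
    "GreedyForwardSelector",
    "correlation_filter",
    "greedy_forward_select",
]


@dataclass
class SelectionConfig:
    pcc_cutoff: float = 0.6
    cv_folds: int = 10
    improvement_epsilon: float = 1e-4
    max_features: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.pcc_cutoff <= 1.0:
            raise ValueError("pcc_cutoff must be in (0, 1]")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class SelectionReport:
    retained_after_correlation: list[str] = field(default_factory=list)
    greedy_order: list[str] = field(default_factory=list)
    mcc_trace: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for step, (name, mcc) in enumerate(zip(self.greedy_order, self.mcc_trace), 1):
            block = name.split("|", 1)[0] if "|" in name else ""
            rows.append(
                {"step": step, "feature_name": name, "source_block": block, "mcc": mcc}
            )
        return pd.DataFrame(rows, columns=["step", "feature_name", "source_block", "mcc"])


class CorrelationFilter(BaseEstimator, TransformerMixin):
    """Greedy redundancy filter on absolute Pearson correlation.

    Features are visited in a seeded-random order; each is retained iff its
    |PCC| with every already-retained feature is <= ``cutoff``. Anticorrelated
    features are treated as redundant too (trees cannot tell them apart).

    Attributes
    ----------
    support_ : boolean mask over input columns
    retained_idx_ : retained column indices in original order
    dropped_pairs_ : list of (dropped_idx, kept_idx, pcc) decisions
    """

    def __init__(self, cutoff: float = 0.6, random_state: int = 0):
        self.cutoff = cutoff
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        n, p = X.shape
        if n < 2:
            raise ValueError("Pearson correlation undefined with < 2 samples")
        stds = X.std(axis=0)
        constant = stds == 0
        if constant.any():
            warnings.warn(
                f"{int(constant.sum())} constant feature(s) dropped "
                "(correlation undefined)",
                stacklevel=2,
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(X, rowvar=False)
        corr = np.atleast_2d(corr)
        rng = np.random.default_rng(self.random_state)
        order = rng.permutation(p)
        retained: list[int] = []
        dropped_pairs: list[tuple[int, int, float]] = []
        for j in order:
            if constant[j]:
                continue
            conflict = None
            for k in retained:
                if abs(corr[j, k]) > self.cutoff:
                    conflict = k
                    break
            if conflict is None:
                retained.append(int(j))
            else:
                dropped_pairs.append((int(j), int(conflict), float(corr[j, conflict])))
        retained.sort()
        self.support_ = np.zeros(p, dtype=bool)
        self.support_[retained] = True
        self.retained_idx_ = np.asarray(retained, dtype=int)
        self.dropped_pairs_ = dropped_pairs
        self.n_features_in_ = p
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        X = np.asarray(X)
        return X[:, self.support_]

    def get_support(self):
        check_is_fitted(self, "support_")
        return self.support_


def _default_cv_estimator(seed: int):
    from xgboost import XGBClassifier

    return XGBClassifier(
        n_estimators=30,
        max_depth=3,
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        eval_metric="logloss",
    )


class GreedyForwardSelector(BaseEstimator, TransformerMixin):
    """Forward stepwise selection scored by cross-validated MCC.

    At each step every unselected feature is evaluated by the mean MCC of
    ``estimator`` over seeded stratified k-fold CV on the selected set plus
    that candidate; the arg-max joins the set (ties broken by lowest column
    index). Selection stops when the best improvement over the current score
    is below ``epsilon`` or ``max_features`` is reached.

    Attributes
    ----------
    support_ : boolean mask over input columns
    selected_idx_ : selected column indices in selection order
    mcc_trace_ : best mean MCC after each accepted step
    """

    def __init__(
        self,
        estimator=None,
        cv_folds: int = 10,
        epsilon: float = 1e-4,
        max_features: int = 30,
        random_state: int = 0,
    ):
        self.estimator = estimator
        self.cv_folds = cv_folds
        self.epsilon = epsilon
        self.max_features = max_features
        self.random_state = random_state

    def _cv_mcc(self, X, y, cols, base) -> float:
        cv = StratifiedKFold(
            n_splits=self.cv_folds, shuffle=True, random_state=self.random_state
        )
        scores = []
        Xs = X[:, cols]
        for train, test in cv.split(Xs, y):
            model = clone(base)
            model.fit(Xs[train], y[train])
            pred = model.predict(Xs[test])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                scores.append(matthews_corrcoef(y[test], pred))
        return float(np.mean(scores))

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.shape[1] == 0:
            raise ValueError("empty feature set")
        base = (
            self.estimator
            if self.estimator is not None
            else _default_cv_estimator(self.random_state)
        )
        p = X.shape[1]
        selected: list[int] = []
        trace: list[float] = []
        current = 0.0
        remaining = list(range(p))
        while remaining and len(selected) < self.max_features:
            best_j, best_mcc = None, -np.inf
            for j in remaining:  # ascending index => lowest-index tie-break
                mcc = self._cv_mcc(X, y, selected + [j], base)
                if mcc > best_mcc:
                    best_j, best_mcc = j, mcc
            if best_mcc - current < self.epsilon:
                break
            selected.append(best_j)
            remaining.remove(best_j)
            trace.append(best_mcc)
            current = best_mcc
        self.support_ = np.zeros(p, dtype=bool)
        self.support_[selected] = True
        self.selected_idx_ = list(selected)
        self.mcc_trace_ = list(trace)
        self.n_features_in_ = p
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        X = np.asarray(X)
        return X[:, self.selected_idx_]

    def get_support(self):
        check_is_fitted(self, "support_")
        return self.support_


def correlation_filter(
    features: FeatureTable, cfg: SelectionConfig
) -> tuple[FeatureTable, SelectionReport]:
    """Apply :class:`CorrelationFilter` to a feature table."""
    filt = CorrelationFilter(cutoff=cfg.pcc_cutoff, random_state=cfg.seed)
    filt.fit(features.matrix)
    names = [features.feature_names[i] for i in filt.retained_idx_]
    report = SelectionReport(retained_after_correlation=names)
    return features.select_columns(names), report


def greedy_forward_select(
    features: FeatureTable,
    labels: np.ndarray,
    cfg: SelectionConfig,
    estimator=None,
    report: SelectionReport | None = None,
) -> SelectionReport:
    """Apply :class:`GreedyForwardSelector` to a labeled feature table."""
    selector = GreedyForwardSelector(
        estimator=estimator,
        cv_folds=cfg.cv_folds,
        epsilon=cfg.improvement_epsilon,
        max_features=cfg.max_features,
        random_state=cfg.seed,
    )
    selector.fit(features.matrix, np.asarray(labels))
    if report is None:
        report = SelectionReport(
            retained_after_correlation=list(features.feature_names)
        )
    report.greedy_order = [features.feature_names[i] for i in selector.selected_idx_]
    report.mcc_trace = list(selector.mcc_trace_)
    return report
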