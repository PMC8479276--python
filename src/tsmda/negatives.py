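"""Reliable negative-sample selection.

Unlabeled miRNA-disease pairs are not trustworthy negatives: some are simply
unconfirmed associations. Two stages distill a reliable negative set.

1. **Tripartite-network filter.** miRNA-gene and gene-disease edges form a
   miRNA-gene-disease network. A pair whose miRNA and disease share at least
   one gene is a *potential* association and is excluded; only pairs sharing
   no gene survive as candidate negatives.

2. **Modified PU-learning pruning.** A random forest is trained repeatedly
   on a held-out fraction of the known positives (class 1) against the
   current candidates (class 0). The first, strict iteration eliminates a
   small fraction of the least negative-confident candidates (those
   classified positive, or negative with probability below a high
   threshold). Later iterations use a deliberately weak forest (few, shallow
   trees) and drop candidates classified positive, shrinking the pool until
   it balances the number of known associations.

The pruner is also exposed as the sklearn-style estimator
:class:`PUNegativeSelector`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

from .dataio import GeneDiseaseTable, InteractionTable
from .features import FeatureTable, Pair

logger = logging.getLogger(__name__)

__all__ = [
    "TripartiteNetwork",
    "PUConfig",
    "PUNegativeSelector",
    "build_tripartite_network",
    "network_filter",
    "split_positive_holdout",
    "pu_prune",
]


@dataclass
class TripartiteNetwork:
    """miRNA-gene and gene-disease edges with adjacency indexes."""

    mirna_gene: set[tuple[str, str]]
    gene_disease: set[tuple[str, str]]
    genes_of_mirna: dict[str, set[str]] = field(default_factory=dict)
    genes_of_disease: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.genes_of_mirna:
            for m, g in self.mirna_gene:
                self.genes_of_mirna.setdefault(m, set()).add(g)
        if not self.genes_of_disease:
            for g, d in self.gene_disease:
                self.genes_of_disease.setdefault(d, set()).add(g)

    def shares_gene(self, mirna_id: str, disease_id: str) -> bool:
        mg = self.genes_of_mirna.get(mirna_id)
        dg = self.genes_of_disease.get(disease_id)
        return bool(mg and dg and not mg.isdisjoint(dg))


def build_tripartite_network(
    mg: InteractionTable, gd: GeneDiseaseTable
) -> TripartiteNetwork:
    """Integrate miRNA-gene and gene-disease edges into one network."""
    net = TripartiteNetwork(set(mg.edges), set(gd.edges))
    logger.info(
        "tripartite network: %d miRNA-gene edges, %d gene-disease edges, "
        "%d miRNAs, %d diseases",
        len(net.mirna_gene),
        len(net.gene_disease),
        len(net.genes_of_mirna),
        len(net.genes_of_disease),
    )
    return net


def network_filter(
    unknown_pairs: Sequence[Pair], net: TripartiteNetwork
) -> list[Pair]:
    """Keep only pairs whose miRNA and disease share no gene in the network.

    Pairs connected through a shared gene are treated as potential
    associations and excluded from the candidate-negative pool.
    """
    return [(m, d) for m, d in unknown_pairs if not net.shares_gene(m, d)]


@dataclass
class PUConfig:
    """Knobs of the modified PU-learning pruner.

    The defaults encode the published procedure: 20% of known associations
    held out as PU positives, a strict first loop removing at most 1% of
    candidates (those classified positive or negative with probability below
    0.95), then weak 20-estimator depth-3 forests removing positives until
    the candidate count balances the known associations.
    """

    positive_holdout_fraction: float = 0.20
    first_loop_prob_threshold: float = 0.95
    first_loop_removal_fraction: float = 0.01
    first_loop_estimators: int = 100
    later_loop_estimators: int = 20
    later_loop_max_depth: int = 3
    max_iterations: int = 500
    class_weight: str | None = "balanced"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("positive_holdout_fraction", "first_loop_removal_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if not 0.5 < self.first_loop_prob_threshold < 1.0:
            raise ValueError("first_loop_prob_threshold must be in (0.5, 1)")


def split_positive_holdout(
    positives: FeatureTable, fraction: float, seed: int
) -> tuple[FeatureTable, FeatureTable]:
    """Seeded split of the positives into (PU holdout, remainder).

    The holdout (size ceil(fraction * n)) is used as the positive class
    during PU pruning so the final classifier is not trained against
    negatives selected by a model that saw all its positives.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    n = len(positives)
    if n < 2:
        raise ValueError("need at least 2 positives to split")
    k = math.ceil(fraction * n)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return positives.subset(np.sort(perm[:k])), positives.subset(np.sort(perm[k:]))


class PUNegativeSelector(BaseEstimator):
    """Iterative PU-learning pruner over candidate negatives.

    Parameters mirror :class:`PUConfig`. ``fit(X, y)`` takes the PU
    positives (y == 1) together with the candidate negatives (y == 0) and a
    ``target_count`` (usually the number of all known associations); after
    fitting, ``support_`` masks the candidates retained as reliable
    negatives.

    Attributes
    ----------
    support_ : bool array over the candidate rows of X
    trace_ : DataFrame with per-iteration candidate/removal counts
    negative_confidence_ : final-model P(class 0) for surviving candidates
    """

    def __init__(
        self,
        target_count: int | None = None,
        first_loop_prob_threshold: float = 0.95,
        first_loop_removal_fraction: float = 0.01,
        first_loop_estimators: int = 100,
        later_loop_estimators: int = 20,
        later_loop_max_depth: int = 3,
        max_iterations: int = 500,
        class_weight: str | None = "balanced",
        random_state: int = 0,
    ):
        self.target_count = target_count
        self.first_loop_prob_threshold = first_loop_prob_threshold
        self.first_loop_removal_fraction = first_loop_removal_fraction
        self.first_loop_estimators = first_loop_estimators
        self.later_loop_estimators = later_loop_estimators
        self.later_loop_max_depth = later_loop_max_depth
        self.max_iterations = max_iterations
        self.class_weight = class_weight
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("y must be binary (1 = PU positive, 0 = candidate)")
        pos = X[y == 1]
        cand_idx = np.nonzero(y == 0)[0]
        cand = X[cand_idx]
        target = self.target_count if self.target_count is not None else len(pos)
        if len(cand) < target:
            raise ValueError(
                f"{len(cand)} candidates < target {target}; provide more "
                "candidates or a smaller target"
            )
        keep = np.arange(len(cand))  # indices into cand, shrinking each loop
        trace: list[dict] = []
        confidence = np.ones(len(cand))
        rng_seed = self.random_state

        for iteration in range(1, self.max_iterations + 1):
            if len(keep) <= target:
                break
            first = iteration == 1
            forest = RandomForestClassifier(
                n_estimators=self.first_loop_estimators
                if first
                else self.later_loop_estimators,
                max_depth=None if first else self.later_loop_max_depth,
                class_weight=self.class_weight,
                random_state=rng_seed + iteration,
                n_jobs=1,
            )
            Xc = cand[keep]
            forest.fit(
                np.vstack([pos, Xc]),
                np.concatenate([np.ones(len(pos)), np.zeros(len(keep))]),
            )
            p_neg = forest.predict_proba(Xc)[:, list(forest.classes_).index(0.0)]
            if first:
                eligible = (p_neg < 0.5) | (p_neg < self.first_loop_prob_threshold)
                cap = max(1, math.floor(self.first_loop_removal_fraction * len(keep)))
                order = np.argsort(p_neg, kind="stable")  # least confident first
                to_remove = [i for i in order if eligible[i]][:cap]
                removed = np.zeros(len(keep), dtype=bool)
                removed[to_remove] = True
            else:
                removed = p_neg < 0.5  # classified positive
                # never shrink past the balance target
                excess = len(keep) - target
                if removed.sum() > excess:
                    order = np.argsort(p_neg, kind="stable")
                    removed = np.zeros(len(keep), dtype=bool)
                    removed[[i for i in order if p_neg[i] < 0.5][:excess]] = True
            n_removed = int(removed.sum())
            trace.append(
                {
                    "iteration": iteration,
                    "n_candidates": len(keep),
                    "n_removed": n_removed,
                }
            )
            if n_removed == 0:
                confidence = p_neg.copy()
                break
            confidence = p_neg[~removed]
            keep = keep[~removed]

        self.support_ = np.zeros(len(cand), dtype=bool)
        self.support_[keep] = True
        self.candidate_indices_ = cand_idx[keep]
        self.trace_ = pd.DataFrame(
            trace, columns=["iteration", "n_candidates", "n_removed"]
        )
        self.negative_confidence_ = np.asarray(confidence, dtype=float)
        self.target_count_ = target
        self.terminated_at_balance_ = len(keep) <= target
        return self

    def get_support(self):
        check_is_fitted(self, "support_")
        return self.support_


def pu_prune(
    candidates: FeatureTable,
    positives: FeatureTable,
    cfg: PUConfig,
    target_count: int,
) -> tuple[FeatureTable, pd.DataFrame]:
    """Prune candidate negatives until they balance the known associations.

    ``positives`` are the PU holdout (class 1); ``target_count`` is the
    balance target, by default the number of *all* known associations. When
    the later loops would overshoot below the target, only the
    least-negative-confident candidates are removed so the loop lands
    exactly on the target. Returns the pruned table (confidence-ordered
    trimming to ``target_count`` when the loop stalls above it) and the
    per-iteration trace.
    """
    if candidates.feature_names != positives.feature_names:
        raise ValueError("candidates and positives have mismatched features")
    selector = PUNegativeSelector(
        target_count=target_count,
        first_loop_prob_threshold=cfg.first_loop_prob_threshold,
        first_loop_removal_fraction=cfg.first_loop_removal_fraction,
        first_loop_estimators=cfg.first_loop_estimators,
        later_loop_estimators=cfg.later_loop_estimators,
        later_loop_max_depth=cfg.later_loop_max_depth,
        max_iterations=cfg.max_iterations,
        class_weight=cfg.class_weight,
        random_state=cfg.seed,
    )
    X = np.vstack([positives.matrix, candidates.matrix])
    y = np.concatenate([np.ones(len(positives)), np.zeros(len(candidates))])
    selector.fit(X, y)
    kept = np.nonzero(selector.support_)[0]
    if len(kept) > target_count and not selector.terminated_at_balance_:
        # stalled above balance: keep the most negative-confident candidates
        order = np.argsort(-selector.negative_confidence_, kind="stable")
        kept = np.sort(kept[order[:target_count]])
        logger.info(
            "pu_prune stalled at %d candidates; trimmed to target %d by "
            "negative-class confidence",
            int(selector.support_.sum()),
            target_count,
        )
    pruned = candidates.subset(kept).with_labels(np.zeros(len(kept), dtype=int))
    return pruned, selector.trace_
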