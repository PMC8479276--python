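"""Per-pair feature assembly.

A miRNA-disease pair (i, j) is described by concatenating three similarity
rows: the functional-similarity (MISIM) row of miRNA i, the target-based
similarity row of miRNA i, and the symptom-based similarity row of disease
j. With nM miRNAs and nD diseases every pair therefore has 2*nM + nD
features, each named after its source block and reference entity so that
selected features remain interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .dataio import AssociationCatalog
from .similarity import SimilarityMatrix

__all__ = ["FeatureTable", "enumerate_pairs", "assemble_feature_table"]

Pair = tuple[str, str]


@dataclass
class FeatureTable:
    """Feature matrix over miRNA-disease pairs with provenance-tagged columns."""

    pair_ids: list[Pair]
    matrix: np.ndarray
    feature_names: list[str]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.matrix.shape[0] != len(self.pair_ids):
            raise ValueError("row count does not match pair count")
        if self.matrix.shape[1] != len(self.feature_names):
            raise ValueError("column count does not match feature names")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (len(self.pair_ids),):
                raise ValueError("labels do not align with pairs")

    def __len__(self) -> int:
        return len(self.pair_ids)

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def subset(self, indices: Sequence[int] | np.ndarray) -> "FeatureTable":
        """Row subset preserving pair identity and labels."""
        indices = np.asarray(indices, dtype=int)
        return FeatureTable(
            [self.pair_ids[i] for i in indices],
            self.matrix[indices],
            list(self.feature_names),
            None if self.labels is None else self.labels[indices],
        )

    def select_columns(self, names: Sequence[str]) -> "FeatureTable":
        """Column subset by feature name, in the given order."""
        pos = {n: i for i, n in enumerate(self.feature_names)}
        idx = [pos[n] for n in names]
        return FeatureTable(
            list(self.pair_ids), self.matrix[:, idx], list(names), self.labels
        )

    def with_labels(self, labels: np.ndarray) -> "FeatureTable":
        return FeatureTable(
            list(self.pair_ids), self.matrix, list(self.feature_names), labels
        )

    @staticmethod
    def concat(tables: Iterable["FeatureTable"]) -> "FeatureTable":
        tables = list(tables)
        names = tables[0].feature_names
        for t in tables[1:]:
            if t.feature_names != names:
                raise ValueError("feature tables have mismatched columns")
        labels = None
        if all(t.labels is not None for t in tables):
            labels = np.concatenate([t.labels for t in tables])
        return FeatureTable(
            [p for t in tables for p in t.pair_ids],
            np.vstack([t.matrix for t in tables]),
            list(names),
            labels,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=self.feature_names)
        df.insert(0, "mirna_id", [m for m, _ in self.pair_ids])
        df.insert(1, "disease_id", [d for _, d in self.pair_ids])
        if self.labels is not None:
            df["label"] = self.labels
        return df


def enumerate_pairs(
    catalog: AssociationCatalog,
    which: Literal["all", "known", "unknown"] = "all",
) -> list[Pair]:
    """List miRNA-disease pairs in registry (row-major) order.

    ``known`` are pairs with a recorded association, ``unknown`` the
    complement; together they partition the nM x nD grid.
    """
    if which not in ("all", "known", "unknown"):
        raise ValueError(f"unknown selector {which!r}")
    mirnas, diseases = catalog.mirna_ids, catalog.disease_ids
    if which == "all":
        return [(m, d) for m in mirnas for d in diseases]
    want = 1 if which == "known" else 0
    rows, cols = np.nonzero(catalog.assoc == want)
    return [(mirnas[i], diseases[j]) for i, j in zip(rows, cols)]


def assemble_feature_table(
    pairs: Sequence[Pair],
    mfs: SimilarityMatrix,
    tms: SimilarityMatrix,
    sds: SimilarityMatrix,
    labels: np.ndarray | Sequence[int] | None = None,
) -> FeatureTable:
    """Concatenate [MFS row i | TMS row i | SDS row j] for each pair (i, j).

    The functional and target matrices must share one miRNA registry; the
    symptom matrix must cover every disease referenced by ``pairs``. Column
    order is fixed: MISIM block, target block, symptom block, each in
    registry order.
    """
    if mfs.entity_ids != tms.entity_ids:
        raise ValueError("functional and target similarity registries differ")
    m_idx = {m: i for i, m in enumerate(mfs.entity_ids)}
    d_idx = {d: j for j, d in enumerate(sds.entity_ids)}
    for m, d in pairs:
        if m not in m_idx:
            raise KeyError(f"unregistered miRNA in pair: {m!r}")
        if d not in d_idx:
            raise KeyError(f"unregistered disease in pair: {d!r}")
    feature_names = (
        [f"MISIM|{m}" for m in mfs.entity_ids]
        + [f"target|{m}" for m in tms.entity_ids]
        + [f"symptom|{d}" for d in sds.entity_ids]
    )
    n = len(pairs)
    matrix = np.empty((n, len(feature_names)))
    n_m = len(mfs.entity_ids)
    for r, (m, d) in enumerate(pairs):
        i, j = m_idx[m], d_idx[d]
        matrix[r, :n_m] = mfs.values[i]
        matrix[r, n_m : 2 * n_m] = tms.values[i]
        matrix[r, 2 * n_m :] = sds.values[j]
    return FeatureTable(
        list(pairs),
        matrix,
        feature_names,
        None if labels is None else np.asarray(labels),
    )
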