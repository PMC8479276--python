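"""Entity similarity matrices.

Two similarity channels are computed here and one is loaded precomputed:

* **TMS** (target-based miRNA similarity) — each miRNA is a weighted profile
  over its validated target genes, the weight of gene *j* being
  ``log2(F_j)`` where ``F_j`` counts how many miRNAs target gene *j* in the
  merged interaction table; similarity is the cosine between profiles.
* **SDS** (symptom-based disease similarity) — each disease is a TF-IDF
  weighted profile over clinical symptoms, ``w_ij = W_ij * log(N / n_j)``
  with ``W_ij`` the absolute disease-symptom co-occurrence count, ``N`` the
  number of diseases and ``n_j`` the number of diseases in which symptom *j*
  appears; similarity is again the cosine.
* **MFS** (miRNA functional similarity, MISIM) — consumed as a precomputed
  square CSV, restricted and reordered to the working miRNA registry.

Profiles are nonnegative, so cosine similarities lie in [0, 1]. Entities
with an all-zero profile (e.g. miRNAs with no recorded targets) get
similarity 0 to everything, including themselves, keeping every matrix
finite.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .dataio import InteractionTable, SymptomCooccurrenceTable, load_similarity_csv

logger = logging.getLogger(__name__)

__all__ = [
    "TargetProfileMatrix",
    "SymptomProfileMatrix",
    "SimilarityMatrix",
    "gene_frequency",
    "build_target_profiles",
    "build_symptom_profiles",
    "cosine_similarity_matrix",
    "load_functional_similarity",
]

#: supported logarithms for the IDF term
_LOG = {"natural": math.log, "log2": math.log2, "log10": math.log10}


@dataclass
class TargetProfileMatrix:
    """miRNA x gene interaction-strength profiles in log2-frequency units."""

    mirna_ids: list[str]
    gene_ids: list[str]
    weights: np.ndarray
    gene_frequencies: dict[str, int]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if (self.weights < 0).any():
            raise ValueError("target profile weights must be nonnegative")


@dataclass
class SymptomProfileMatrix:
    """Disease x symptom TF-IDF profiles."""

    disease_ids: list[str]
    symptom_ids: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if (self.weights < 0).any():
            raise ValueError("symptom profile weights must be nonnegative")


@dataclass
class SimilarityMatrix:
    """Square symmetric entity-similarity matrix with values in [0, 1]."""

    entity_ids: list[str]
    values: np.ndarray
    kind: str  # one of {"functional", "target", "symptom"}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.entity_ids)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix is not square on its registry")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("similarity matrix is not symmetric")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("similarity values outside [0, 1]")
        np.clip(self.values, 0.0, 1.0, out=self.values)

    def row(self, entity_id: str) -> np.ndarray:
        return self.values[self.entity_ids.index(entity_id)]


def gene_frequency(interactions: InteractionTable) -> dict[str, int]:
    """Term frequency F_j: number of interaction edges incident to gene j.

    Counted on the merged, deduplicated edge set.
    """
    if not interactions.edges:
        raise ValueError("interaction table is empty")
    freq: dict[str, int] = {}
    for _, g in interactions.edges:
        freq[g] = freq.get(g, 0) + 1
    return freq


def build_target_profiles(
    interactions: InteractionTable, mirna_ids: Sequence[str]
) -> TargetProfileMatrix:
    """Weighted target profiles: entry is log2(F_j) for an edge, else 0.

    miRNAs in the registry with no recorded target get an all-zero profile.
    Genes with F_j = 1 contribute weight log2(1) = 0, so they carry no signal
    even where an edge exists.
    """
    freq = gene_frequency(interactions)
    gene_ids = interactions.gene_ids
    g_idx = {g: j for j, g in enumerate(gene_ids)}
    m_idx = {m: i for i, m in enumerate(mirna_ids)}
    weights = np.zeros((len(mirna_ids), len(gene_ids)))
    log2f = {g: math.log2(f) for g, f in freq.items()}
    for m, g in interactions.edges:
        if m in m_idx:
            weights[m_idx[m], g_idx[g]] = log2f[g]
    return TargetProfileMatrix(list(mirna_ids), list(gene_ids), weights, freq)


def build_symptom_profiles(
    cooc: SymptomCooccurrenceTable, log_base: str = "natural"
) -> SymptomProfileMatrix:
    """TF-IDF symptom profiles: w_ij = W_ij * log(N / n_j).

    ``n_j`` is the number of diseases with a nonzero count for symptom j;
    symptoms present in every disease (n_j = N) or in none (n_j = 0) yield
    all-zero columns. The logarithm base defaults to natural log.
    """
    if log_base not in _LOG:
        raise ValueError(f"log_base must be one of {sorted(_LOG)}")
    log = _LOG[log_base]
    counts = cooc.counts.astype(float)
    n_diseases = len(cooc.disease_ids)
    if n_diseases < 1:
        raise ValueError("co-occurrence table has no diseases")
    n_j = (counts > 0).sum(axis=0)
    idf = np.zeros(counts.shape[1])
    nonzero = n_j > 0
    idf[nonzero] = [log(n_diseases / nj) for nj in n_j[nonzero]]
    return SymptomProfileMatrix(
        list(cooc.disease_ids), list(cooc.symptom_ids), counts * idf
    )


def cosine_similarity_matrix(
    entity_ids: Sequence[str], profiles: np.ndarray, kind: str
) -> SimilarityMatrix:
    """Pairwise cosine similarity of profile rows.

    Zero rows (entities with an empty profile) get similarity 0 everywhere,
    including the diagonal, rather than NaN.
    """
    profiles = np.asarray(profiles, dtype=float)
    norms = np.linalg.norm(profiles, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    normalized = profiles / safe[:, None]
    values = normalized @ normalized.T
    zero = norms == 0
    values[zero, :] = 0.0
    values[:, zero] = 0.0
    values = (values + values.T) / 2.0  # remove float asymmetry
    np.clip(values, 0.0, 1.0, out=values)
    return SimilarityMatrix(list(entity_ids), values, kind)


def target_similarity(
    interactions: InteractionTable, mirna_ids: Sequence[str]
) -> SimilarityMatrix:
    """Convenience: target profiles then cosine (the TMS matrix)."""
    profiles = build_target_profiles(interactions, mirna_ids)
    return cosine_similarity_matrix(profiles.mirna_ids, profiles.weights, "target")


def symptom_similarity(
    cooc: SymptomCooccurrenceTable, log_base: str = "natural"
) -> SimilarityMatrix:
    """Convenience: TF-IDF symptom profiles then cosine (the SDS matrix)."""
    profiles = build_symptom_profiles(cooc, log_base)
    return cosine_similarity_matrix(profiles.disease_ids, profiles.weights, "symptom")


def load_functional_similarity(
    path: str | Path, mirna_ids: Sequence[str]
) -> SimilarityMatrix:
    """Load a precomputed functional-similarity CSV restricted to a registry.

    The file must cover every registry miRNA; rows/columns are reordered to
    registry order. Asymmetries are averaged away, with a warning when the
    maximum asymmetry exceeds 1e-9.
    """
    file_ids, values = load_similarity_csv(path)
    idx = {m: i for i, m in enumerate(file_ids)}
    missing = [m for m in mirna_ids if m not in idx]
    if missing:
        raise ValueError(
            f"functional similarity file is missing miRNAs: {', '.join(missing)}"
        )
    order = [idx[m] for m in mirna_ids]
    sub = values[np.ix_(order, order)]
    asym = np.abs(sub - sub.T).max() if sub.size else 0.0
    if asym > 1e-9:
        warnings.warn(
            f"functional similarity matrix asymmetric (max {asym:.3g}); "
            "symmetrized by averaging",
            stacklevel=2,
        )
    sub = (sub + sub.T) / 2.0
    return SimilarityMatrix(list(mirna_ids), sub, "functional")
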