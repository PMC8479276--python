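"""Input/output for miRNA-disease association tables.

All tables are plain delimited text: tab-separated pair lists on input,
comma-separated result tables on output. Entity identifiers are kept as
given (whitespace-trimmed, case preserved); no miRBase alias resolution is
attempted. Registries record entities in order of first appearance so that
downstream matrices have a reproducible row/column order.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationCatalog",
    "InteractionTable",
    "GeneDiseaseTable",
    "SymptomCooccurrenceTable",
    "PredictionTable",
    "ParseError",
    "read_association_table",
    "read_interaction_table",
    "read_gene_disease_table",
    "read_cooccurrence_table",
    "write_prediction_table",
    "read_prediction_table",
]


class ParseError(ValueError):
    """Raised when an input table is malformed; carries the line number."""


@dataclass
class AssociationCatalog:
    """Binary miRNA x disease association matrix with ID registries.

    ``assoc[i, j] == 1`` iff miRNA ``mirna_ids[i]`` and disease
    ``disease_ids[j]`` are experimentally associated.
    """

    mirna_ids: list[str]
    disease_ids: list[str]
    assoc: np.ndarray

    def __post_init__(self) -> None:
        self.assoc = np.asarray(self.assoc, dtype=np.uint8)
        if len(set(self.mirna_ids)) != len(self.mirna_ids):
            raise ValueError("duplicate miRNA identifiers in registry")
        if len(set(self.disease_ids)) != len(self.disease_ids):
            raise ValueError("duplicate disease identifiers in registry")
        if self.assoc.shape != (len(self.mirna_ids), len(self.disease_ids)):
            raise ValueError(
                f"association matrix shape {self.assoc.shape} does not match "
                f"registries ({len(self.mirna_ids)}, {len(self.disease_ids)})"
            )
        if not np.isin(self.assoc, (0, 1)).all():
            raise ValueError("association matrix entries must be 0 or 1")

    @property
    def n_mirnas(self) -> int:
        return len(self.mirna_ids)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    @property
    def n_associations(self) -> int:
        return int(self.assoc.sum())

    def mirna_index(self, mirna_id: str) -> int:
        try:
            return self.mirna_ids.index(mirna_id)
        except ValueError:
            raise KeyError(f"unknown miRNA: {mirna_id!r}") from None

    def disease_index(self, disease_id: str) -> int:
        try:
            return self.disease_ids.index(disease_id)
        except ValueError:
            raise KeyError(f"unknown disease: {disease_id!r}") from None

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, str]],
        mirna_ids: Sequence[str] | None = None,
        disease_ids: Sequence[str] | None = None,
    ) -> "AssociationCatalog":
        """Build a catalog from (mirna_id, disease_id) pairs.

        Registries default to first-appearance order over the pairs; explicit
        registries may add entities with no associations.
        """
        pairs = list(pairs)
        if mirna_ids is None:
            mirna_ids = _first_appearance(m for m, _ in pairs)
        if disease_ids is None:
            disease_ids = _first_appearance(d for _, d in pairs)
        m_idx = {m: i for i, m in enumerate(mirna_ids)}
        d_idx = {d: j for j, d in enumerate(disease_ids)}
        assoc = np.zeros((len(mirna_ids), len(disease_ids)), dtype=np.uint8)
        for m, d in pairs:
            assoc[m_idx[m], d_idx[d]] = 1
        return cls(list(mirna_ids), list(disease_ids), assoc)


@dataclass
class InteractionTable:
    """Deduplicated miRNA-target-gene interaction edges."""

    edges: set[tuple[str, str]]
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.gene_ids:
            self.gene_ids = _first_appearance(g for _, g in sorted(self.edges))
        for m, _ in self.edges:
            if not m:
                raise ValueError("empty miRNA identifier in interaction table")

    def merged_with(self, other: "InteractionTable") -> "InteractionTable":
        """Union of two interaction tables (database merge semantics)."""
        return InteractionTable(self.edges | other.edges)

    def restricted_to(self, mirna_ids: Iterable[str]) -> "InteractionTable":
        """Keep only edges whose miRNA is in the given registry."""
        keep = set(mirna_ids)
        return InteractionTable({(m, g) for m, g in self.edges if m in keep})


@dataclass
class GeneDiseaseTable:
    """Deduplicated gene-disease association edges."""

    edges: set[tuple[str, str]]


@dataclass
class SymptomCooccurrenceTable:
    """Disease x symptom absolute co-occurrence counts (nonnegative ints)."""

    disease_ids: list[str]
    symptom_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if len(set(self.disease_ids)) != len(self.disease_ids):
            raise ValueError("duplicate disease identifiers")
        if len(set(self.symptom_ids)) != len(self.symptom_ids):
            raise ValueError("duplicate symptom identifiers")
        if self.counts.shape != (len(self.disease_ids), len(self.symptom_ids)):
            raise ValueError("count matrix shape does not match registries")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                raise ValueError("co-occurrence counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("co-occurrence counts must be nonnegative")


@dataclass
class PredictionTable:
    """Ranked association scores: rows of (mirna_id, disease_id, score, rank)."""

    rows: list[tuple[str, str, float, int]]

    def __post_init__(self) -> None:
        by_disease: dict[str, list[tuple[int, float]]] = {}
        for _, d, score, rank in self.rows:
            by_disease.setdefault(d, []).append((rank, score))
        for d, entries in by_disease.items():
            entries.sort()
            ranks = [r for r, _ in entries]
            if ranks != list(range(1, len(ranks) + 1)):
                raise ValueError(f"ranks for disease {d!r} are not 1..k")
            scores = [s for _, s in entries]
            if any(a < b for a, b in zip(scores, scores[1:])):
                raise ValueError(f"scores for disease {d!r} increase with rank")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows, columns=["mirna_id", "disease_id", "score", "rank"]
        )


def _first_appearance(items: Iterable[str]) -> list[str]:
    seen: dict[str, None] = {}
    for x in items:
        seen.setdefault(x, None)
    return list(seen)


def _iter_pair_rows(
    path: str | Path, n_cols: int, delimiter: str = "\t"
) -> Iterable[tuple[int, list[str]]]:
    """Yield (line_number, fields) for a delimited pair file, header skipped."""
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        first = True
        for lineno, row in enumerate(reader, start=1):
            if not row or all(not c.strip() for c in row):
                continue
            if first:
                first = False
                continue  # header
            if len(row) != n_cols:
                raise ParseError(
                    f"{path}: line {lineno}: expected {n_cols} columns, "
                    f"got {len(row)}"
                )
            yield lineno, [c.strip() for c in row]


def _read_pairs(path: str | Path, delimiter: str = "\t") -> list[tuple[str, str]]:
    pairs = [tuple(fields) for _, fields in _iter_pair_rows(path, 2, delimiter)]
    if not pairs:
        raise ParseError(f"{path}: no data rows")
    return pairs  # type: ignore[return-value]


def read_association_table(
    path: str | Path, delimiter: str = "\t"
) -> AssociationCatalog:
    """Read a two-column (mirna_id, disease_id) association list.

    Duplicate rows collapse to a single association with a logged warning.
    Registries are ordered by first appearance in the file.
    """
    pairs = _read_pairs(path, delimiter)
    if len(set(pairs)) != len(pairs):
        logger.warning(
            "%s: %d duplicate association rows collapsed",
            path,
            len(pairs) - len(set(pairs)),
        )
    mirna_ids = _first_appearance(m for m, _ in pairs)
    disease_ids = _first_appearance(d for _, d in pairs)
    return AssociationCatalog.from_pairs(pairs, mirna_ids, disease_ids)


def read_interaction_table(path: str | Path, delimiter: str = "\t") -> InteractionTable:
    """Read a two-column (mirna_id, gene_id) interaction list, deduplicated."""
    pairs = _read_pairs(path, delimiter)
    return InteractionTable(set(pairs))


def read_gene_disease_table(path: str | Path, delimiter: str = "\t") -> GeneDiseaseTable:
    """Read a two-column (gene_id, disease_id) association list, deduplicated."""
    pairs = _read_pairs(path, delimiter)
    return GeneDiseaseTable(set(pairs))


def read_cooccurrence_table(path: str | Path) -> SymptomCooccurrenceTable:
    """Read disease-symptom co-occurrence counts.

    Two dialects are auto-detected from the header:

    * long TSV with columns (disease_id, symptom_id, count);
    * wide CSV with disease rows and symptom columns.

    Both yield the same internal representation.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    long_format = "\t" in header and len(header.rstrip("\n").split("\t")) == 3
    if long_format:
        triples: list[tuple[str, str, int]] = []
        for lineno, fields in _iter_pair_rows(path, 3, "\t"):
            d, s, raw = fields
            try:
                count = int(raw)
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer count {raw!r}"
                ) from None
            if count < 0:
                raise ParseError(f"{path}: line {lineno}: negative count {count}")
            triples.append((d, s, count))
        disease_ids = _first_appearance(d for d, _, _ in triples)
        symptom_ids = _first_appearance(s for _, s, _ in triples)
        counts = np.zeros((len(disease_ids), len(symptom_ids)), dtype=np.int64)
        d_idx = {d: i for i, d in enumerate(disease_ids)}
        s_idx = {s: j for j, s in enumerate(symptom_ids)}
        for d, s, c in triples:
            counts[d_idx[d], s_idx[s]] = c
        return SymptomCooccurrenceTable(disease_ids, symptom_ids, counts)
    df = pd.read_csv(path, index_col=0)
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number) or np.any(values != np.floor(values)):
        raise ParseError(f"{path}: co-occurrence counts must be integers")
    if (values < 0).any():
        raise ParseError(f"{path}: negative co-occurrence count")
    return SymptomCooccurrenceTable(
        [str(d) for d in df.index],
        [str(s) for s in df.columns],
        values.astype(np.int64),
    )


def write_prediction_table(table: PredictionTable, path: str | Path) -> None:
    """Write predictions as CSV with scores fixed to 6 decimal places."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["mirna_id", "disease_id", "score", "rank"])
        for m, d, score, rank in table.rows:
            writer.writerow([m, d, f"{score:.6f}", rank])


def read_prediction_table(path: str | Path) -> PredictionTable:
    """Read back a prediction CSV written by :func:`write_prediction_table`."""
    rows: list[tuple[str, str, float, int]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != ["mirna_id", "disease_id", "score", "rank"]:
            raise ParseError(f"{path}: unexpected header {header}")
        for row in reader:
            if not row:
                continue
            m, d, score, rank = row
            rows.append((m, d, float(score), int(rank)))
    return PredictionTable(rows)


def load_similarity_csv(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a square similarity CSV (first row/column are entity IDs)."""
    df = pd.read_csv(path, index_col=0)
    ids = [str(x) for x in df.index]
    if [str(c) for c in df.columns] != ids:
        raise ParseError(f"{path}: row and column identifiers differ")
    return ids, df.to_numpy(dtype=float)


def write_similarity_csv(
    entity_ids: Sequence[str], values: np.ndarray, path: str | Path
) -> None:
    pd.DataFrame(values, index=list(entity_ids), columns=list(entity_ids)).to_csv(path)
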