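"""Self-contained synthetic miRNA-disease world with planted signal.

The generator emulates the statistical structure the prediction model
relies on: a latent pathway layer ties everything together. Genes are
partitioned into pathways; every miRNA and every disease is assigned one or
two pathways. miRNA-gene and disease-gene edges fall mostly inside the
entity's own pathways (with a tunable noise rate of uniform rewiring), so
miRNAs sharing a pathway share targets, and pathway-sharing miRNA-disease
pairs tend to share genes. Disease-symptom co-occurrence counts are Poisson
with pathway-specific means, so same-pathway diseases have similar symptom
profiles. Ground-truth associations are planted with high probability for
pathway-sharing pairs and low background probability otherwise; the
*observed* catalog keeps each true association with probability 0.8,
mimicking database incompleteness.

The functional-similarity stand-in (MFS) is a target-based similarity
computed on an independently re-noised copy of the miRNA-gene edges — a
correlated but not identical channel. It is synthetic: the real MISIM
matrix is derived from shared disease associations and is consumed by the
pipeline as an external input.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dataio import (
    AssociationCatalog,
    GeneDiseaseTable,
    InteractionTable,
    SymptomCooccurrenceTable,
    write_similarity_csv,
)
from .similarity import SimilarityMatrix, target_similarity

__all__ = ["SyntheticConfig", "SyntheticWorld", "generate_world", "world_to_files"]


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic world.

    Defaults are the package's reference conditions: 60 miRNAs x 40
    diseases over 300 genes, 50 symptoms and 5 pathways, a strong planted
    association signal within pathways (0.5 vs 0.02 background), ~12 targets
    per miRNA, ~15 genes per disease, Poisson symptom intensity 4.0 and 10%
    edge noise.
    """

    n_mirnas: int = 60
    n_diseases: int = 40
    n_genes: int = 300
    n_symptoms: int = 50
    n_pathways: int = 5
    p_assoc_within_pathway: float = 0.5
    p_assoc_background: float = 0.02
    edges_per_mirna: int = 12
    genes_per_disease: int = 15
    symptom_signal_strength: float = 4.0
    symptom_background: float = 0.3
    noise_rate: float = 0.1
    observability: float = 0.8
    mfs_rewire_rate: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_mirnas,
            self.n_diseases,
            self.n_genes,
            self.n_symptoms,
            self.n_pathways,
        )
        if any(c < 1 for c in counts):
            raise ValueError("all entity counts must be >= 1")
        if not self.p_assoc_within_pathway > self.p_assoc_background:
            raise ValueError(
                "p_assoc_within_pathway must exceed p_assoc_background"
            )
        for name in ("p_assoc_within_pathway", "p_assoc_background", "noise_rate",
                     "observability", "mfs_rewire_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")


@dataclass
class SyntheticWorld:
    catalog: AssociationCatalog  # observed (subsampled from truth)
    truth: np.ndarray  # full binary association matrix, nM x nD
    interactions: InteractionTable
    gene_disease: GeneDiseaseTable
    cooccurrence: SymptomCooccurrenceTable
    mfs: SimilarityMatrix
    mirna_pathways: list[set[int]]
    disease_pathways: list[set[int]]

    def __post_init__(self) -> None:
        if not (self.catalog.assoc <= self.truth).all():
            raise ValueError("observed associations must be a subset of truth")


def _draw_edges(
    rng: np.random.Generator,
    own_genes: np.ndarray,
    all_genes: int,
    n_edges: int,
    noise_rate: float,
) -> set[int]:
    """Draw ~n_edges distinct genes, mostly from own_genes else uniform."""
    chosen: set[int] = set()
    for _ in range(n_edges):
        if len(own_genes) and rng.random() >= noise_rate:
            chosen.add(int(rng.choice(own_genes)))
        else:
            chosen.add(int(rng.integers(all_genes)))
    return chosen


def generate_world(cfg: SyntheticConfig) -> SyntheticWorld:
    """Generate a deterministic synthetic world from the config seed."""
    rng = np.random.default_rng(cfg.seed)
    mirna_ids = [f"syn-mir-{i:03d}" for i in range(cfg.n_mirnas)]
    disease_ids = [f"D{j:06d}" for j in range(cfg.n_diseases)]
    gene_ids = [f"GENE{g:04d}" for g in range(cfg.n_genes)]
    symptom_ids = [f"SYMP{s:03d}" for s in range(cfg.n_symptoms)]

    # pathways partition the genes (and tag the symptoms)
    gene_pathway = rng.integers(cfg.n_pathways, size=cfg.n_genes)
    genes_by_pathway = [
        np.nonzero(gene_pathway == p)[0] for p in range(cfg.n_pathways)
    ]
    symptom_pathway = rng.integers(cfg.n_pathways, size=cfg.n_symptoms)

    def assign_pathways() -> set[int]:
        k = 1 + int(rng.random() < 0.5)  # one or two pathways
        return set(rng.choice(cfg.n_pathways, size=k, replace=False).tolist())

    mirna_pathways = [assign_pathways() for _ in range(cfg.n_mirnas)]
    disease_pathways = [assign_pathways() for _ in range(cfg.n_diseases)]

    def own_gene_pool(pathways: set[int]) -> np.ndarray:
        pools = [genes_by_pathway[p] for p in sorted(pathways)]
        return np.concatenate(pools) if pools else np.array([], dtype=int)

    mirna_gene_edges: set[tuple[str, str]] = set()
    mirna_gene_sets: list[set[int]] = []
    for i in range(cfg.n_mirnas):
        genes = _draw_edges(
            rng, own_gene_pool(mirna_pathways[i]), cfg.n_genes,
            cfg.edges_per_mirna, cfg.noise_rate,
        )
        mirna_gene_sets.append(genes)
        mirna_gene_edges.update((mirna_ids[i], gene_ids[g]) for g in genes)

    gene_disease_edges: set[tuple[str, str]] = set()
    for j in range(cfg.n_diseases):
        genes = _draw_edges(
            rng, own_gene_pool(disease_pathways[j]), cfg.n_genes,
            cfg.genes_per_disease, cfg.noise_rate,
        )
        gene_disease_edges.update((gene_ids[g], disease_ids[j]) for g in genes)

    counts = np.zeros((cfg.n_diseases, cfg.n_symptoms), dtype=np.int64)
    for j in range(cfg.n_diseases):
        in_pathway = np.isin(symptom_pathway, list(disease_pathways[j]))
        means = np.where(
            in_pathway, cfg.symptom_signal_strength, cfg.symptom_background
        )
        counts[j] = rng.poisson(means)

    shares = np.zeros((cfg.n_mirnas, cfg.n_diseases), dtype=bool)
    for i in range(cfg.n_mirnas):
        for j in range(cfg.n_diseases):
            shares[i, j] = bool(mirna_pathways[i] & disease_pathways[j])
    p = np.where(shares, cfg.p_assoc_within_pathway, cfg.p_assoc_background)
    truth = (rng.random(p.shape) < p).astype(np.uint8)
    observed = (truth == 1) & (rng.random(p.shape) < cfg.observability)

    catalog = AssociationCatalog(mirna_ids, disease_ids, observed.astype(np.uint8))
    interactions = InteractionTable(mirna_gene_edges)

    # MFS stand-in: target similarity on an independently rewired edge copy
    rewired: set[tuple[str, str]] = set()
    for i in range(cfg.n_mirnas):
        for g in mirna_gene_sets[i]:
            if rng.random() < cfg.mfs_rewire_rate:
                g = int(rng.integers(cfg.n_genes))
            rewired.add((mirna_ids[i], gene_ids[g]))
    mfs = target_similarity(InteractionTable(rewired), mirna_ids)
    mfs = SimilarityMatrix(mfs.entity_ids, mfs.values, "functional")

    return SyntheticWorld(
        catalog=catalog,
        truth=truth,
        interactions=interactions,
        gene_disease=GeneDiseaseTable(gene_disease_edges),
        cooccurrence=SymptomCooccurrenceTable(disease_ids, symptom_ids, counts),
        mfs=mfs,
        mirna_pathways=mirna_pathways,
        disease_pathways=disease_pathways,
    )


#: file names emitted by world_to_files
WORLD_FILES = {
    "associations": "associations.tsv",
    "interactions": "mirna_gene.tsv",
    "gene_disease": "gene_disease.tsv",
    "cooccurrence": "cooccurrence.csv",
    "mfs": "functional_similarity.csv",
    "truth": "truth.csv",
}


def world_to_files(world: SyntheticWorld, directory: str | Path) -> dict[str, Path]:
    """Write the world in the dialects the readers consume (6 files).

    ``truth.csv`` is ground truth for test assertions only; the pipeline
    never reads it.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {k: directory / v for k, v in WORLD_FILES.items()}

    cat = world.catalog
    with open(paths["associations"], "w") as fh:
        fh.write("mirna_id\tdisease_id\n")
        for i, j in zip(*np.nonzero(cat.assoc)):
            fh.write(f"{cat.mirna_ids[i]}\t{cat.disease_ids[j]}\n")

    with open(paths["interactions"], "w") as fh:
        fh.write("mirna_id\tgene_id\n")
        for m, g in sorted(world.interactions.edges):
            fh.write(f"{m}\t{g}\n")

    with open(paths["gene_disease"], "w") as fh:
        fh.write("gene_id\tdisease_id\n")
        for g, d in sorted(world.gene_disease.edges):
            fh.write(f"{g}\t{d}\n")

    import pandas as pd

    cooc = world.cooccurrence
    # wide dialect keeps the full registries (zero rows/columns included)
    pd.DataFrame(
        cooc.counts, index=cooc.disease_ids, columns=cooc.symptom_ids
    ).to_csv(paths["cooccurrence"])

    write_similarity_csv(world.mfs.entity_ids, world.mfs.values, paths["mfs"])

    pd.DataFrame(
        world.truth, index=cat.mirna_ids, columns=cat.disease_ids
    ).to_csv(paths["truth"])
    return paths
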