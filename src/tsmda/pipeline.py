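"""End-to-end driver: the five-step workflow.

1. Data collection — read (or receive) the association catalog, miRNA-gene
   interactions, gene-disease associations, disease-symptom co-occurrences
   and the precomputed functional-similarity matrix.
2. Feature construction — build the target-based miRNA similarity (TMS) and
   symptom-based disease similarity (SDS), then concatenate
   [MFS | TMS | SDS] rows per pair.
3. Negative selection — tripartite-network filter on the unknown pairs, then
   modified PU-learning pruning down to the number of known associations.
4. Feature selection — correlation redundancy filter then greedy forward
   selection by cross-validated MCC, fitted on the training partition only.
5. Training and evaluation — gradient-boosted trees under cross-validation,
   a blind holdout, ranking and disease-holdout case studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .dataio import (
    AssociationCatalog,
    GeneDiseaseTable,
    InteractionTable,
    PredictionTable,
    SymptomCooccurrenceTable,
    read_association_table,
    read_cooccurrence_table,
    read_gene_disease_table,
    read_interaction_table,
)
from .features import FeatureTable, assemble_feature_table, enumerate_pairs
from .model_eval import (
    EvaluationReport,
    ModelArtifact,
    blind_test,
    cross_validate,
    rank_candidates,
    train_classifier,
)
from .negatives import (
    PUConfig,
    build_tripartite_network,
    network_filter,
    pu_prune,
    split_positive_holdout,
)
from .selection import SelectionConfig, SelectionReport, correlation_filter, greedy_forward_select
from .similarity import (
    SimilarityMatrix,
    load_functional_similarity,
    symptom_similarity,
    target_similarity,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineInputs", "PipelineConfig", "PipelineResult", "TSMDAPipeline"]


@dataclass
class PipelineInputs:
    """In-memory input tables (step 1 output)."""

    catalog: AssociationCatalog
    interactions: InteractionTable
    gene_disease: GeneDiseaseTable
    cooccurrence: SymptomCooccurrenceTable
    mfs: SimilarityMatrix

    @classmethod
    def from_files(
        cls,
        associations: str | Path,
        interactions: str | Path,
        gene_disease: str | Path,
        cooccurrence: str | Path,
        functional_similarity: str | Path,
    ) -> "PipelineInputs":
        catalog = read_association_table(associations)
        mg = read_interaction_table(interactions)
        gd = read_gene_disease_table(gene_disease)
        cooc = read_cooccurrence_table(cooccurrence)
        mfs = load_functional_similarity(functional_similarity, catalog.mirna_ids)
        return cls(catalog, mg, gd, cooc, mfs)


def _default_selection() -> SelectionConfig:
    # feature budget sized for the package's reference problem scale
    return SelectionConfig(max_features=10)


@dataclass
class PipelineConfig:
    pu: PUConfig = field(default_factory=PUConfig)
    selection: SelectionConfig = field(default_factory=_default_selection)
    xgb_params: dict | None = None
    evaluation_scheme: str = "cv5"  # cv5 | cv10 | cv20 | blind
    blind_fraction: float = 0.2
    log_base: str = "natural"
    seed: int = 0

    def __post_init__(self) -> None:
        # one global seed propagates into every stochastic stage
        self.pu = replace(self.pu, seed=self.seed)
        self.selection = replace(self.selection, seed=self.seed)


@dataclass
class PipelineResult:
    model: ModelArtifact
    dataset: FeatureTable  # labeled training table on selected features
    selection_report: SelectionReport
    pu_trace: "object"
    evaluation: EvaluationReport
    tms: SimilarityMatrix
    sds: SimilarityMatrix
    mfs: SimilarityMatrix
    counts: dict[str, int]


class TSMDAPipeline:
    """Configured end-to-end run over one set of input tables."""

    def __init__(self, config: PipelineConfig | None = None):
        self.config = config or PipelineConfig()

    # -- step 2 -------------------------------------------------------
    def build_similarities(
        self, inputs: PipelineInputs
    ) -> tuple[SimilarityMatrix, SimilarityMatrix, SimilarityMatrix]:
        catalog = inputs.catalog
        interactions = inputs.interactions.restricted_to(catalog.mirna_ids)
        tms = target_similarity(interactions, catalog.mirna_ids)
        sds_full = symptom_similarity(inputs.cooccurrence, self.config.log_base)
        # restrict/realign the symptom similarity to the catalog's diseases;
        # diseases absent from the co-occurrence table get zero profiles
        d_idx = {d: j for j, d in enumerate(sds_full.entity_ids)}
        n = catalog.n_diseases
        values = np.zeros((n, n))
        present = [
            (j, d_idx[d]) for j, d in enumerate(catalog.disease_ids) if d in d_idx
        ]
        for a, fa in present:
            for b, fb in present:
                values[a, b] = sds_full.values[fa, fb]
        sds = SimilarityMatrix(list(catalog.disease_ids), values, "symptom")
        if inputs.mfs.entity_ids != catalog.mirna_ids:
            raise ValueError("functional similarity registry must match catalog")
        return inputs.mfs, tms, sds

    # -- steps 2+3 ----------------------------------------------------
    def build_dataset(self, inputs: PipelineInputs):
        """Assemble the labeled training table (positives + reliable negatives)."""
        cfg = self.config
        catalog = inputs.catalog
        mfs, tms, sds = self.build_similarities(inputs)

        known = enumerate_pairs(catalog, "known")
        unknown = enumerate_pairs(catalog, "unknown")
        positives = assemble_feature_table(
            known, mfs, tms, sds, labels=np.ones(len(known), dtype=int)
        )

        net = build_tripartite_network(
            inputs.interactions.restricted_to(catalog.mirna_ids),
            inputs.gene_disease,
        )
        candidates_pairs = network_filter(unknown, net)
        candidates = assemble_feature_table(candidates_pairs, mfs, tms, sds)

        pu_positives, _ = split_positive_holdout(
            positives, cfg.pu.positive_holdout_fraction, cfg.seed
        )
        negatives, trace = pu_prune(
            candidates, pu_positives, cfg.pu, target_count=len(positives)
        )
        dataset = FeatureTable.concat([positives, negatives])
        counts = {
            "n_known": len(known),
            "n_unknown": len(unknown),
            "n_candidates_after_network_filter": len(candidates_pairs),
            "n_reliable_negatives": len(negatives),
        }
        logger.info("dataset counts: %s", counts)
        return dataset, trace, (mfs, tms, sds), counts

    # -- steps 4+5 ----------------------------------------------------
    def _select_features(
        self, train_table: FeatureTable
    ) -> tuple[list[str], SelectionReport]:
        cfg = self.config
        reduced, report = correlation_filter(train_table, cfg.selection)
        report = greedy_forward_select(
            reduced, train_table.labels, cfg.selection, report=report
        )
        selected = report.greedy_order or report.retained_after_correlation
        return list(selected), report

    def fit(self, inputs: PipelineInputs) -> PipelineResult:
        """Run steps 2-5 and return the trained model with its reports."""
        cfg = self.config
        dataset, trace, (mfs, tms, sds), counts = self.build_dataset(inputs)

        if cfg.evaluation_scheme == "blind":
            # holdout never touches feature selection
            from sklearn.model_selection import train_test_split

            idx_train, idx_test = train_test_split(
                np.arange(len(dataset)),
                test_size=cfg.blind_fraction,
                stratify=dataset.labels,
                random_state=cfg.seed,
            )
            train_table = dataset.subset(np.sort(idx_train))
            selected, report = self._select_features(train_table)
            eval_table = dataset.select_columns(selected)
            clf = train_classifier(
                train_table.select_columns(selected), cfg.xgb_params, cfg.seed
            )
            from .model_eval import compute_metrics, _confusion

            test_table = eval_table.subset(np.sort(idx_test))
            scores = clf.classifier.score_pairs(test_table)
            metrics = compute_metrics(test_table.labels, scores)
            _, conf = _confusion(
                np.asarray(test_table.labels), np.asarray(scores), 0.5
            )
            evaluation = EvaluationReport(
                scheme="blind",
                metrics=metrics,
                confusion=conf,
                seed=cfg.seed,
                n_samples=len(test_table),
            )
            final_dataset = eval_table
        else:
            if cfg.evaluation_scheme not in ("cv5", "cv10", "cv20"):
                raise ValueError(
                    f"unknown evaluation scheme {cfg.evaluation_scheme!r}"
                )
            k = int(cfg.evaluation_scheme[2:])
            selected, report = self._select_features(dataset)
            final_dataset = dataset.select_columns(selected)
            evaluation = cross_validate(final_dataset, k, cfg.seed, cfg.xgb_params)

        model = train_classifier(final_dataset, cfg.xgb_params, cfg.seed)
        return PipelineResult(
            model=model,
            dataset=final_dataset,
            selection_report=report,
            pu_trace=trace,
            evaluation=evaluation,
            tms=tms,
            sds=sds,
            mfs=mfs,
            counts=counts,
        )

    # -- prediction / case studies ------------------------------------
    def score_unknown_pairs(
        self, inputs: PipelineInputs, result: PipelineResult
    ) -> FeatureTable:
        """Feature table of all unknown pairs on the selected features."""
        mfs, tms, sds = result.mfs, result.tms, result.sds
        unknown = enumerate_pairs(inputs.catalog, "unknown")
        table = assemble_feature_table(unknown, mfs, tms, sds)
        return table.select_columns(result.dataset.feature_names)

    def rank_disease(
        self,
        inputs: PipelineInputs,
        result: PipelineResult,
        disease_id: str,
        k: int = 50,
        include_known: bool = False,
    ) -> PredictionTable:
        """Top-k candidate miRNAs for one disease."""
        which = "all" if include_known else "unknown"
        pairs = [
            p
            for p in enumerate_pairs(inputs.catalog, which)
            if p[1] == disease_id
        ]
        if not pairs:
            raise ValueError(f"no candidate pairs for disease {disease_id!r}")
        table = assemble_feature_table(
            pairs, result.mfs, result.tms, result.sds
        ).select_columns(result.dataset.feature_names)
        return rank_candidates(result.model, disease_id, table, k)

    def case_study_holdout_disease(
        self, inputs: PipelineInputs, disease_id: str, k: int = 50
    ) -> tuple[PredictionTable, list[str]]:
        """Remove all known associations of one disease, retrain, rank it.

        Returns the ranked predictions for the held-out disease and the list
        of miRNAs whose associations were removed (the recovery targets).
        The removed pairs re-enter the candidate pool as unknowns.
        """
        catalog = inputs.catalog
        j = catalog.disease_index(disease_id)
        removed = [catalog.mirna_ids[i] for i in np.nonzero(catalog.assoc[:, j])[0]]
        if not removed:
            raise ValueError(f"disease {disease_id!r} has no known associations")
        assoc = catalog.assoc.copy()
        assoc[:, j] = 0
        masked = AssociationCatalog(
            list(catalog.mirna_ids), list(catalog.disease_ids), assoc
        )
        masked_inputs = PipelineInputs(
            masked,
            inputs.interactions,
            inputs.gene_disease,
            inputs.cooccurrence,
            inputs.mfs,
        )
        result = self.fit(masked_inputs)
        ranking = self.rank_disease(masked_inputs, result, disease_id, k=k)
        return ranking, removed
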