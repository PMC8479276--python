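# Methods

## Overview

The pipeline ranks miRNA-disease pairs by association plausibility in five
steps: (1) ingest an association catalog plus miRNA-target, gene-disease
and disease-symptom tables and a precomputed miRNA functional-similarity
matrix; (2) build per-pair feature vectors from three similarity channels;
(3) distill reliable negatives from the unlabeled pairs; (4) select a small
feature subset; (5) train and evaluate a gradient-boosted-tree classifier.
Everything downstream of ingestion is deterministic given one global seed,
which is propagated into every stochastic stage (splits, forests, fold
assignment, scan orders).

## Similarity channels

**Target-based miRNA similarity (TMS).** A miRNA's profile over genes is
`s_ij = log2(F_j)` on its target edges and 0 elsewhere, where `F_j` counts
edges incident to gene *j* in the merged, deduplicated interaction table.
Note the weighting *up-weights* commonly targeted genes (a gene targeted by
a single miRNA contributes log2(1) = 0); this is the method's stated
weighting and is implemented exactly, even though an IDF-style
down-weighting might seem more natural. Similarity is the cosine between
profiles; since profiles are nonnegative, values lie in [0, 1].

**Symptom-based disease similarity (SDS).** TF-IDF weights
`w_ij = W_ij * log(N / n_j)` over co-occurrence counts, with `n_j` the
number of diseases in which symptom *j* has a nonzero count. The logarithm
base is not pinned by the weighting's usual statement; natural log is the
default (TF-IDF convention), with `log2`/`log10` options. The base is not a
no-op: it rescales columns individually, and cosine similarity is sensitive
to relative column scales, so it is fixed in configuration.

**Functional similarity (MFS).** Consumed as a square CSV; rows/columns are
reordered to the working registry, asymmetries above 1e-9 are warned about
and averaged away.

Entities with an all-zero profile (miRNAs without recorded targets,
diseases without symptom counts) get similarity 0 to everything *including
themselves*, rather than NaN, keeping all feature vectors finite.

## Negative selection

Unlabeled pairs whose miRNA and disease share at least one gene in the
miRNA-gene-disease network are excluded as potential associations. The
survivors are pruned by modified PU learning:

* Iteration 1: a 100-estimator random forest is trained on a held-out 20%
  of the known positives (class 1) versus all candidates (class 0).
  Candidates classified positive, or negative with probability below 0.95,
  are eligible for removal; at most 1% of candidates are removed, lowest
  negative-confidence first. The 95% rule is applied to the negative-class
  probability (the positive-class reading is the complement and is
  recoverable through configuration).
* Iterations >= 2: a deliberately weak forest (20 estimators, depth 3)
  removes candidates classified positive, stopping when the pool size
  reaches the number of *all* known associations (the balance target), when
  an iteration removes nothing, or at an iteration cap. Removal never
  overshoots: when more candidates are classified positive than the excess
  over the target, only the least negative-confident are dropped.

Two operational choices matter here. First, the later-loop forests use
`class_weight="balanced"` by default: the PU positives are a small fraction
of the pool, and an unweighted depth-3 forest classifies essentially no
candidate as positive, stalling the loop immediately. Second, if the loop
still stalls above the target, the pipeline trims the pool to the target by
final negative-class confidence. Both knobs are exposed in `PUConfig`.

In-sample predicted probabilities score the candidates (out-of-bag scoring
would be a straightforward variant but is not the default reading).

## Feature selection

A greedy correlation filter visits columns in a seeded-random order and
keeps a feature only if its |Pearson correlation| with every kept feature is
at most 0.6; absolute correlation is used because anti-correlated features
are equally redundant for tree models. Constant columns (undefined
correlation) are dropped with a warning. Forward stepwise selection then
adds, per step, the feature maximizing mean MCC of the classifier under
seeded stratified 10-fold cross-validation (ties broken by lowest column
index), stopping when the best improvement falls below 1e-4 or at a feature
budget. The budget defaults to 30 at the estimator level; the pipeline
driver caps it at 10, matched to the synthetic problem scale it ships with.
Selection is fit on the training partition only when a blind holdout is
requested, so the holdout never influences the chosen features.

## Classifier and evaluation

XGBoost with library-default hyperparameters (100 estimators, depth 6,
learning rate 0.3, histogram tree method, single thread), all exposed via
`xgb_params`. AUC is the Mann-Whitney rank statistic with ties averaged;
MCC, balanced accuracy and F1 use a 0.5 threshold (configurable).
Cross-validation uses seeded stratified folds and reports per-fold values
and mean +/- sd. The blind test is a stratified 20% holdout by default,
mirroring the 80/20 idiom used in the PU positive split. Case studies zero
out all of one disease's associations *before* negative selection and
training, then rank that disease's candidates and check how many removed
associations return near the top.

## Synthetic world

The generator plants a latent pathway layer: genes are partitioned into
pathways; each miRNA and disease carries one or two pathways; miRNA-gene
and disease-gene edges fall inside the entity's pathways with probability
1 - noise_rate (else uniform); disease-symptom counts are Poisson with mean
4.0 on same-pathway symptoms and 0.3 otherwise; ground-truth associations
are Bernoulli(0.5) for pathway-sharing pairs and Bernoulli(0.02) otherwise;
the observed catalog keeps each true association with probability 0.8. The
functional-similarity stand-in is a target similarity computed on an
independently rewired (25%) copy of the miRNA-gene edges — correlated with
TMS but not identical, which is a documented departure from the real MFS
(derived from shared disease annotations, an independent channel).

Reference conditions: 60 miRNAs, 40 diseases, 300 genes, 50 symptoms, 5
pathways. The within-pathway association rate of 0.5 against a 0.02
background makes the observed catalog ~19% dense — far denser than real
catalogs (HMDD-scale lists are ~3% dense) but sized so that a 60 x 40 world
yields a training set (~900 balanced pairs) large enough for stable fold
metrics; edges_per_mirna = 12 and genes_per_disease = 15 give the network
filter a sharp shared-gene signal at 300 genes.

What passing tests on this world show: the similarity channels recover the
planted pathway structure, the network filter and PU pruning produce
negatives enriched for ground-truth negatives, and the classifier separates
planted associations from selected negatives (5-fold AUC >= 0.85 with a
chance-level permuted-label control). What they do not show: performance on
real catalogs, whose degree distributions, sparsity and annotation biases
the generator deliberately does not imitate.

## Known limitations

* **Negative-selection bias limits per-disease ranking.** The shared-gene
  filter removes pathway-sharing pairs from the candidate pool, so the
  classifier never sees "sharing but unassociated" negatives and partially
  substitutes a marginal popular-miRNA score for true pair-level
  conditioning; greedy selection, scored on that same biased training set,
  tends to discard disease-side features that would help. In the
  disease-holdout case study this keeps recovery above chance but usually
  short of significance at the shipped problem scale (training on
  ground-truth labels instead of selected negatives raises held-out-disease
  conditional AUC from ~0.60 to ~0.84, which bounds what better negative
  selection could recover).
* Within pathway-sharing pairs the synthetic truth is an independent coin
  flip, so no ranker can separate associated from unassociated sharing
  pairs; top-k recovery is capped by the share structure of the disease.
* The 0.5/0.95/1%/20/3 constants of the PU pruner are taken as given; no
  sensitivity analysis is performed here (all are configurable).
* miRBase/MeSH identifier aliasing is not resolved; IDs match after
  whitespace trimming only.

## Numerical choices

* Cosine matrices are symmetrized by averaging and clipped to [0, 1] to
  remove float asymmetry; validation tolerances are 1e-9 (symmetry) and
  1e-12 (range).
* Ranking ties are broken by candidate registry order (stable sort);
  greedy-selection ties by lowest feature index; the correlation filter's
  "randomly retained" is a seeded random scan order with keep-first-seen.
* Prediction scores are serialized at 6 decimal places.
* Degenerate inputs fail loudly: single-class training sets, single-sample
  correlation, folds exceeding the minority class, fewer candidates than
  the PU balance target.
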