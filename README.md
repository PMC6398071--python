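# modesus

Two-phase multiobjective evolutionary selection of molecular-descriptor
subsets for QSAR modelling.

## The problem

QSAR (Quantitative Structure–Activity Relationship) models predict a
physicochemical or biological property of a chemical compound from numeric
molecular descriptors.  Modern descriptor software emits hundreds to
thousands of descriptors per molecule, but only a small subset is usually
informative for any one property, and models built on small, accurate
subsets are both more reliable and more interpretable.  Picking that subset
is a combinatorial optimisation problem with two competing goals: low
subset **cardinality** and high **predictive accuracy**.

`modesus` implements a wrapper methodology for this problem, organised in
two phases, for both regression and classification targets, plus the
randomization audits needed to rule out chance correlation.

## The method

A candidate subset is a binary vector with one bit per available descriptor.
Two objectives are minimised:

- **F1** — the number of selected descriptors;
- **F2** — the prediction error of a learner trained on the selected
  descriptors and scored on held-out compounds: mean squared error for
  regression, the percentage of misclassified cases (0–100) for
  classification.

**Phase 1** is an evolutionary search (tournament selection, uniform
crossover, gated bit-flip mutation, elitism, stall-based termination) over
these masks in one of three modes:

- *aggregation*: minimise the scalarised fitness

      F_AG = α·F2 + (1−α)·F2·F1/p_m

  where α ∈ [0,1] weights accuracy against parsimony and p_m is the
  maximum admissible cardinality;
- *nsga2*: Pareto ranking by fast nondominated sorting with
  crowding-distance selection;
- *spea2*: strength-Pareto fitness with a density-truncated archive.

Every evaluated subset is archived; a run reports the nondominated front
over everything it evaluated, and multiple independent trials contribute
the nondominated union of their fronts.

**Phase 2** retrains each front subset on the internal compounds with a
robust learner (Random Forest, Random Committee or a multilayer
perceptron), scores it on external compounds never seen by the search,
averages metrics over seed-shifted runs, and ranks subsets by %CC
(percentage of cases correctly classified), MCC (Matthews Correlation
Coefficient) and class-weighted average ROC AUC — or MSE/RMSE/R² for
regression.

**Audits**: `fs-randomization` repeats the final modelling protocol on
random descriptor subsets of the same cardinality; `y-randomization`
permutes the target while keeping the selected descriptors.  Each null
distribution is summarised by its mode (at two decimals), sample variance
and nearest-rank 99th percentile; a selected subset is trustworthy when its
metric beats the 99th percentile of both nulls.

## Worked example

Generate a synthetic dataset with five planted informative descriptors,
then run both phases:

```sh
modesus synth --out data.csv --n-compounds 500 --n-descriptors 100 \
    --n-informative 5 --noise-sd 0.5 --seed 1
modesus run --config config.yaml
```

with `config.yaml`:

```yaml
dataset: {path: data.csv, delimiter: ",", target_column: target, task: classification}
partition: {internal_fraction: 0.75, seed: 1}
search:
  mode: aggregation
  trials: 2
  alpha: 0.8
  pm: 10
  wrapper_learner: knn
  ga: {population_size: 60, max_generations: 60, stall_gens: 15, seed: 1}
validation:
  n_subsets_to_evaluate: 10
  learner: random_forest
  learner_params: {n_estimators: 50}
  n_runs: 10
  seed: 1
output: {search_file: search.json, reports_file: reports.json}
```

The run prints the phase-2 ranking (output of the commands above):

```
phase 1: 375 internal compounds, 100 descriptors, mode=aggregation
phase 1 done: front of 9 subsets (1492 unique evaluations) -> search.json
rank     %CC    ROC    MCC  card  descriptors
   1   82.64  0.922  0.655     5  d004,d012,d029,d077,d094
   2   82.40  0.917  0.651     7  d004,d006,d012,d029,d076,d077,d094
   3   82.32  0.918  0.648     6  d004,d012,d014,d029,d077,d094
   ...
   9   56.80  0.600  0.137     1  d004
phase 2 done: 9 reports -> reports.json
```

Here the top-ranked subset classifies 82.64 % of the 125 external compounds
correctly (MCC 0.655, average ROC 0.922) using 5 of the 100 descriptors —
and `modesus synth` had reported exactly `d004,d012,d029,d077,d094` as the
planted informative descriptors.  The audit

```sh
modesus randomize --config config.yaml --reports-file reports.json --kind fs --out fsnull.json
```

reports the null's mode, variance and 99th percentile, and a verdict line
stating whether the selected subset's %CC exceeds that percentile.

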