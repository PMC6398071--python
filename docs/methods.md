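# Methods

## Problem setting and representation

Given a table of `n` compounds by `p` named molecular descriptors and a
target property (continuous, or a finite label set with at least two
labels), the task is to find descriptor subsets that are simultaneously
small and predictive.  A candidate subset is a binary mask of length `p`;
bit `i` set means descriptor `i` is selected.  Two objectives are
minimised:

- `F1(mask)` — the number of set bits;
- `F2(mask)` — the prediction error of a wrapper learner trained on the
  masked descriptors: mean squared error for regression, the percentage of
  misclassified held-out cases (scale 0–100) for classification.

`F2` is estimated on a single seeded holdout split *inside* the internal
partition (default 75/25, stratified by label for classification).  The
split is drawn once per search and reused for every mask, so fitness values
are comparable across individuals and generations; the alternative of
re-splitting per evaluation would turn the fitness landscape stochastic and
make elitism meaningless.  Evaluations are cached by mask — on a GA run
most offspring are duplicates or revisits, and wrapper training dominates
runtime.

A degenerate evaluation (single-class training fold, learner failure)
yields the worst possible error (100 for classification, +inf for
regression) with a logged warning, so the search simply routes around such
masks.

## Phase 1: evolutionary search

All three modes share the variation pipeline:

- **tournament selection** of size `t` (uniform sample without
  replacement, best wins);
- **uniform crossover** applied with probability `pxo`; each child bit is
  drawn from either parent, so loci where the parents agree are inherited
  unchanged.  Uniform rather than positional crossover because descriptor
  column order is arbitrary — positional linkage would be an artefact.  A
  `single_point` option exists for comparison.
- **mutation** as a per-individual gate with probability `pmut`; a gated
  individual flips each bit independently at `per_bit_rate`, defaulting to
  `1/p` (one expected flip);
- **repair**: a mask with more than `pm` bits has randomly chosen set bits
  cleared down to `pm`; an empty mask gets one random bit.  Every emitted
  individual therefore satisfies `1 <= F1 <= pm`.

Modes:

- `aggregation` minimises `F_AG = alpha*F2 + (1-alpha)*F2*F1/pm` with
  elitism (`elite_size` copies survive unchanged).  Ties in fitness break
  to lower cardinality, then lexicographically smaller mask, making the
  ranking deterministic.
- `nsga2` uses fast nondominated sorting and crowding distance with
  (mu+lambda) environmental selection and binary tournaments on
  (rank, crowding).
- `spea2` uses strength/raw fitness plus a k-nearest-neighbour density
  term (k = sqrt(archive size)) computed on range-normalised objectives,
  an archive of size `population_size`, and lexicographic nearest-neighbour
  truncation when the nondominated set overflows.

`elite_size` is ignored in the Pareto modes; their intrinsic archiving
plays that role (a log line records this).

**Termination.**  A run stops at `max_generations` or when the mean
population fitness fails to improve by at least `stall_threshold` for
`stall_gens` consecutive generations.  The Pareto modes have no scalar
population fitness, so the mean of the error objective `F2` serves as the
stall statistic there; this is a design choice of this package.

**Archive.**  The front reported by a trial is the nondominated set over
*all* masks evaluated in that trial, not just the final population — good
subsets cannot be lost to drift.  A search runs `trials` independent
executions with seeds `seed + trial` (all sharing the same F2 split and
cache) and reports the deduplicated nondominated union of the trial fronts.
"Trials" is thus interpreted as independent restarts; the number of
subsets actually carried into phase 2 is capped separately by
`n_subsets_to_evaluate`.

**GA defaults**: population 100, elite 2, tournament 2, PXO 0.8, PMut 0.1,
100 generations, stall after 10 generations below 1e-3.  These are
conventional wrapper-GA settings; every one is a config key.

## Phase 2: external validation

The compound rows are split once into internal/external partitions
(`internal_fraction`, seeded; stratified per label for classification with
remainders assigned by a seeded draw, plain random for regression).  The
external rows are never visible to phase 1.

Up to `n_subsets_to_evaluate` front subsets (ordered by phase-1 F2, ties to
lower cardinality) are retrained on the internal rows with one of the
robust learners (`random_forest`, `random_committee`, `mlp`) and scored on
the external rows, `n_runs` times with learner seeds `seed..seed+n_runs-1`;
metrics are run-averages, with per-run values retained in the JSON report
for auditability.  Classification reports %CC, MCC and the
class-frequency-weighted mean of one-vs-rest ROC AUCs; MCC uses the
generalised multi-category formula (scikit-learn), which reduces exactly to
`(TP*TN-FP*FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))` for two classes, with a
zero denominator reported as 0.  Regression reports MSE, RMSE and R² (NaN
when the external target is constant).  Reports are ranked best-first:
higher %CC, then higher MCC, then lower cardinality (classification);
lower MSE, then lower cardinality (regression).

## Learners

Standard estimators are scikit-learn behind a registry keyed by identifier:
linear regression, classification/regression trees, kNN (k=3, Euclidean,
standardised on training-fold statistics because the distance is
scale-sensitive), a one-hidden-layer MLP with logistic units (hidden width
`(n_features+n_classes)/2`, linear output for regression) and Random
Forest.  The **Random Committee** is implemented here: `n_members`
randomised trees (random feature candidates at each split) built with seeds
`seed+i`; the committee output is the arithmetic mean of member outputs —
mean class-probability vectors then argmax for classification, mean
prediction for regression.  Every learner is deterministic given its seed.

## Randomization audits

- **fs-randomization**: `n_repeats` random descriptor subsets of exactly
  the selected subset's cardinality (sampled without replacement within a
  subset), each trained/evaluated under the same protocol as the final
  model.
- **y-randomization**: `n_repeats` seeded permutations of the target
  across *all* compounds (training and external alike); descriptors and
  mask untouched; the model is retrained per permutation.  One model fit
  per repeat.

Each metric's null distribution is summarised by the **mode** of values
rounded to two decimals (ties break to the smallest value — the metrics
take finitely many values on a fixed test set, and rounding restores that
discreteness against floating-point noise), the **sample variance**
(n−1 denominator), and the **nearest-rank 99th percentile** (the
`ceil(0.99*n)`-th order statistic).  Failed repeats are excluded and
counted, never imputed.  The verdict compares the reference model's metric
against the 99th percentile.

## Synthetic data generator

The generator emulates the shape of a curated QSAR table: `n_informative`
standard-normal descriptors drive a latent score
`s = effect_size * sum(x_i) + N(0, noise_sd)`; the regression target is
`s`, the classification label thresholds `s` at the empirical quantile
matching `class_balance` (labels `RB`/`NRB`; the lexicographically greater
label is the positive class by convention).  `n_redundant` columns are
informative columns plus N(0, 0.1) noise, `n_constant` columns are
constant, and the remainder are independent noise; column positions are
seed-shuffled and the informative positions returned as a truth mask.

An optional `margin` (classification only) rejects compounds whose latent
score falls within `margin` standard deviations of the class threshold,
leaving an empty band between the classes.  With `noise_sd = 0` and a
positive margin the truth-mask features separate the classes perfectly at
finite sample size, which is what the noiseless test fixtures rely on;
without a margin, boundary-adjacent compounds can defeat local learners
such as kNN even when labels are noise-free.

The default spec (500 compounds x 100 descriptors, 5 informative, effect
size 1.0, noise sd 0.5, balanced labels) is the study condition used by the
planted-recovery and randomization tests and by `scripts/acceptance.py`.
What the generator does **not** emulate: realistic descriptor marginals,
the block-correlation structure of real descriptor families, label noise
from measurement error, and nonlinear structure–activity relationships.
Passing tests therefore demonstrate the machinery's correctness and its
power under a linear planted signal, not performance on real descriptor
tables.

## Problem sizes used in the checks

The exhaustive-equivalence check uses 12 descriptors with `pm = 2` (78
subsets), 150 noiseless compounds, and GA runs of population 30 over up to
25 generations, 10 seeds per mode.  The planted-recovery and audit checks
use the default 500x100 spec with an aggregation search (population 60, up
to 60 generations, 2 trials, alpha 0.8, pm 10, kNN wrapper), Random Forest
(50 trees) for phase 2, and 200-repeat nulls.  These sizes give stable
pass/fail behaviour on a single CPU in minutes.

## Numerical and I/O details

CSV files require a header, `.` decimals, UTF-8, and a comma or semicolon
delimiter; a single-column parse is diagnosed as a wrong delimiter.  Values
are written at 17 significant digits and parsed with a correctly-rounded
parser, so save/load round-trips are bit-exact.  Constant-descriptor
removal uses exact equality — near-constant filtering is deliberately left
to the user.  Partitioning draws `round(internal_fraction * n)` internal
rows.  All randomness flows through seeded `numpy` generators; rerunning
any stage with the same configuration produces byte-identical output files
(no timestamps are written).

## Known limitations

- The phase-1 error estimate rests on a single holdout split; a k-fold
  option would reduce its variance at proportional cost.
- Regression trees use constant leaves; model trees (regression functions
  in the leaves) are a possible extension.
- No applicability-domain assessment; reported metrics assume external
  compounds are drawn from the same distribution as training.
- The aggregation scalarisation cannot reach nonconvex regions of the
  Pareto front; the `nsga2`/`spea2` modes exist for exactly that reason.
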