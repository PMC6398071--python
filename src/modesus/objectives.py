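"""Objective functions, aggregation scalarisation and Pareto dominance.

The wrapper optimises two objectives over binary descriptor masks, both
minimised:

* ``F1`` — the number of selected descriptors (subset cardinality);
* ``F2`` — the prediction error of a learner trained on the selected
  descriptors and scored on held-out compounds: mean squared error for
  regression, percentage of misclassified cases (0–100) for
  classification.

The aggregation mode collapses the pair into a single fitness

    F_AG = alpha * F2 + (1 - alpha) * F2 * F1 / p_m

with ``alpha`` in [0, 1] weighting accuracy against parsimony and ``p_m``
the maximum admissible cardinality.  The Pareto modes keep the objectives
separate and rank by dominance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, NamedTuple, Sequence, TypeVar

import numpy as np

from .dataset_io import CLASSIFICATION, Dataset
from .models import LearnerSpec, fit_predict

logger = logging.getLogger(__name__)

WORST_CLASSIFICATION_ERROR = 100.0


class ObjectiveVector(NamedTuple):
    """(cardinality, prediction error) — both minimised."""

    f1: int
    f2: float


@dataclass(frozen=True)
class AggregationParams:
    """Weight ``alpha`` in [0,1] and maximum cardinality ``pm >= 1``."""

    alpha: float = 0.5
    pm: int = 15

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        if self.pm < 1:
            raise ValueError("pm must be a positive integer")


def f1_cardinality(mask: np.ndarray) -> int:
    """Number of selected descriptors (set bits)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        raise ValueError("empty mask")
    return int(np.count_nonzero(mask))


def aggregate_fitness(f1: int, f2: float, params: AggregationParams) -> float:
    """Scalarised fitness ``alpha*f2 + (1-alpha)*f2*f1/pm`` (lower is better)."""
    return params.alpha * f2 + (1.0 - params.alpha) * f2 * f1 / params.pm


def dominates(u: ObjectiveVector, v: ObjectiveVector) -> bool:
    """True iff u is no worse than v in both objectives and better in one."""
    return u.f1 <= v.f1 and u.f2 <= v.f2 and (u.f1 < v.f1 or u.f2 < v.f2)


_T = TypeVar("_T")


def nondominated_front(
    points: Sequence[_T],
    objectives: Callable[[_T], ObjectiveVector] | None = None,
) -> list[_T]:
    """Extract the nondominated individuals from ``points``.

    Input order is preserved among survivors; individuals with identical
    objective vectors are all retained (equality never dominates).  Runs in
    O(N log N) via a sweep over cardinality-sorted points.
    """
    if len(points) == 0:
        raise ValueError("nondominated_front of an empty collection")
    if objectives is None:
        objectives = lambda p: p  # noqa: E731 - identity for raw vectors
    f1 = np.array([objectives(p).f1 for p in points], dtype=float)
    f2 = np.array([objectives(p).f2 for p in points], dtype=float)
    order = np.lexsort((f2, f1))
    keep = np.zeros(len(points), dtype=bool)
    run_min = np.inf  # best f2 among strictly smaller f1
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and f1[order[j]] == f1[order[i]]:
            j += 1
        group = order[i:j]
        gmin = f2[group].min()
        if gmin < run_min:
            keep[group[f2[group] == gmin]] = True
        run_min = min(run_min, gmin)
        i = j
    return [p for p, k in zip(points, keep) if k]


def _holdout_split(
    ds: Dataset, holdout_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded train/holdout row split (stratified for classification)."""
    from .dataset_io import partition_dataset

    part = partition_dataset(ds, 1.0 - holdout_fraction, seed)
    return part.internal_indices, part.external_indices


class HoldoutEvaluator:
    """Evaluates F2 for masks on one fixed seeded holdout split.

    The split is drawn once from the internal partition (default 75/25)
    and reused for every individual, so fitness values are comparable
    across the whole run.  Results are cached by mask, as wrapper
    evaluation dominates the runtime of the search.
    """

    def __init__(
        self,
        ds_internal: Dataset,
        learner: LearnerSpec,
        eval_seed: int,
        holdout_fraction: float = 0.25,
    ) -> None:
        if ds_internal.n_compounds < 4:
            raise ValueError("need at least 4 internal compounds for a holdout split")
        self.ds = ds_internal
        self.learner = learner
        self.train_idx, self.test_idx = _holdout_split(
            ds_internal, holdout_fraction, eval_seed
        )
        self.worst = (
            WORST_CLASSIFICATION_ERROR if ds_internal.task == CLASSIFICATION else np.inf
        )
        self.cache: dict[bytes, ObjectiveVector] = {}
        self.n_evaluations = 0

    def evaluate(self, mask: np.ndarray) -> ObjectiveVector:
        mask = np.asarray(mask, dtype=bool)
        key = mask.tobytes()
        hit = self.cache.get(key)
        if hit is not None:
            return hit
        f1 = f1_cardinality(mask)
        f2 = self._f2(mask)
        obj = ObjectiveVector(f1, float(f2))
        self.cache[key] = obj
        self.n_evaluations += 1
        return obj

    def _f2(self, mask: np.ndarray) -> float:
        ds = self.ds
        X_train = ds.X[np.ix_(self.train_idx, np.flatnonzero(mask))]
        X_test = ds.X[np.ix_(self.test_idx, np.flatnonzero(mask))]
        y_train = ds.y[self.train_idx]
        y_test = ds.y[self.test_idx]
        if ds.task == CLASSIFICATION and len(set(y_train)) < 2:
            logger.warning("single-class training fold; assigning worst F2")
            return self.worst
        try:
            pred = fit_predict(self.learner, X_train, y_train, X_test, ds.task)
        except Exception as exc:  # noqa: BLE001 - any learner failure => worst fitness
            logger.warning("learner failure (%s); assigning worst F2", exc)
            return self.worst
        if ds.task == CLASSIFICATION:
            miss = np.mean(pred.predictions != y_test)
            return 100.0 * float(miss)
        resid = pred.predictions.astype(float) - y_test.astype(float)
        return float(np.mean(resid**2))


def f2_error(
    mask: np.ndarray,
    ds_internal: Dataset,
    learner: LearnerSpec | str,
    eval_seed: int,
    holdout_fraction: float = 0.25,
) -> float:
    """One-shot F2: train on a seeded holdout split of the internal data
    and return MSE (regression) or % misclassified (classification)."""
    if isinstance(learner, str):
        learner = LearnerSpec(learner, seed=eval_seed)
    ev = HoldoutEvaluator(ds_internal, learner, eval_seed, holdout_fraction)
    return ev.evaluate(mask).f2
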