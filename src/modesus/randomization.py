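"""Chance-correlation audits: fs-randomization and y-randomization.

A selected subset or fitted model is only trustworthy if it beats chance.
fs-randomization retrains the final modelling protocol on many random
descriptor subsets of the same cardinality; y-randomization retrains it on
the true descriptors but with the target values permuted across compounds.
Each experiment yields a null distribution of %CC and MCC (classification)
or MSE and R² (regression), summarised by the mode (after rounding to two
decimals), the sample variance and the nearest-rank 99th percentile.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .dataset_io import CLASSIFICATION, Dataset, Partition
from .models import LearnerSpec
from .validation import _evaluate_mask_once

logger = logging.getLogger(__name__)


@dataclass
class RandomizationConfig:
    """``kind`` is "fs" (random same-cardinality subsets) or "y" (target
    permutation); ``cardinality`` applies to fs only."""

    kind: str
    learner: LearnerSpec
    n_repeats: int = 1000
    cardinality: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("fs", "y"):
            raise ValueError("kind must be 'fs' or 'y'")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.kind == "fs" and (self.cardinality is None or self.cardinality < 1):
            raise ValueError("fs-randomization requires a positive cardinality")


@dataclass
class MetricSummary:
    mode: float
    variance: float
    percentile_99: float
    raw_values: np.ndarray


@dataclass
class RandomizationSummary:
    """Null-distribution summaries per metric, plus the failed-repeat count."""

    kind: str
    metrics: dict[str, MetricSummary]
    n_repeats: int
    n_failed: int = 0

    def exceeds_percentile(self, metric: str, reference: float) -> bool:
        """Does the reference model's metric beat the null's 99th percentile?"""
        return reference > self.metrics[metric].percentile_99

    def to_dict(self) -> dict[str, Any]:
        return {
            "kind": self.kind,
            "n_repeats": self.n_repeats,
            "n_failed": self.n_failed,
            "metrics": {
                k: {
                    "mode": s.mode,
                    "variance": s.variance,
                    "percentile_99": s.percentile_99,
                    "raw_values": [float(v) for v in s.raw_values],
                }
                for k, s in self.metrics.items()
            },
        }


def summarize(values: np.ndarray) -> MetricSummary:
    """Mode (most frequent value after rounding to 2 decimals, ties to the
    smallest), sample variance (n−1 denominator) and nearest-rank 99th
    percentile (the ⌈0.99·n⌉-th order statistic)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty value vector")
    rounded = np.round(values, 2)
    counts = Counter(rounded.tolist())
    top = max(counts.values())
    mode = min(v for v, c in counts.items() if c == top)
    variance = float(np.var(values, ddof=1)) if values.size > 1 else 0.0
    rank = math.ceil(0.99 * values.size)
    percentile_99 = float(np.sort(values)[rank - 1])
    return MetricSummary(float(mode), variance, percentile_99, values)


def _summarise_runs(
    kind: str, runs: list[dict[str, float]], n_repeats: int, n_failed: int
) -> RandomizationSummary:
    keys = runs[0].keys()
    metrics = {
        k: summarize(np.array([r[k] for r in runs if math.isfinite(r[k])]))
        for k in keys
    }
    return RandomizationSummary(kind, metrics, n_repeats, n_failed)


def fs_randomization(
    ds: Dataset, part: Partition, cfg: RandomizationConfig
) -> RandomizationSummary:
    """Retrain the protocol on ``n_repeats`` random descriptor subsets of
    exactly ``cfg.cardinality`` (drawn without replacement within each
    subset, seeded) and summarise the resulting metric distribution."""
    if cfg.kind != "fs":
        raise ValueError("config kind must be 'fs'")
    if cfg.cardinality > ds.n_descriptors:
        raise ValueError("cardinality exceeds the number of descriptors")
    rng = np.random.default_rng(cfg.seed)
    runs: list[dict[str, float]] = []
    n_failed = 0
    for rep in range(cfg.n_repeats):
        cols = rng.choice(ds.n_descriptors, size=cfg.cardinality, replace=False)
        mask = np.zeros(ds.n_descriptors, dtype=bool)
        mask[cols] = True
        try:
            runs.append(_evaluate_mask_once(ds, part, mask, cfg.learner))
        except Exception as exc:  # noqa: BLE001
            n_failed += 1
            logger.warning("fs repeat %d failed: %s", rep, exc)
    return _summarise_runs("fs", runs, cfg.n_repeats, n_failed)


def y_randomization(
    ds: Dataset, part: Partition, mask: np.ndarray, cfg: RandomizationConfig
) -> RandomizationSummary:
    """Permute the target across all compounds (training and external sets
    alike) ``n_repeats`` times, retraining the protocol on the fixed
    descriptor subset each time, and summarise the null distribution."""
    if cfg.kind != "y":
        raise ValueError("config kind must be 'y'")
    rng = np.random.default_rng(cfg.seed)
    runs: list[dict[str, float]] = []
    n_failed = 0
    for rep in range(cfg.n_repeats):
        perm = rng.permutation(ds.n_compounds)
        ds_perm = Dataset(ds.X, list(ds.descriptor_names), ds.y[perm], ds.task)
        try:
            runs.append(_evaluate_mask_once(ds_perm, part, mask, cfg.learner))
        except Exception as exc:  # noqa: BLE001
            n_failed += 1
            logger.warning("y repeat %d failed: %s", rep, exc)
    return _summarise_runs("y", runs, cfg.n_repeats, n_failed)
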