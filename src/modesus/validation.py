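"""Phase-2 external validation of selected descriptor subsets.

Each candidate subset from the phase-1 front is refit on the internal
compounds and scored on the external compounds that the search never saw,
repeated over ``n_runs`` learner seeds and averaged.  Classification
reports %CC (percentage of cases correctly classified), the class-weighted
average one-vs-rest ROC AUC, the Matthews Correlation Coefficient and the
subset cardinality; regression reports MSE, RMSE and R².
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from sklearn.metrics import matthews_corrcoef, roc_auc_score

from .dataset_io import CLASSIFICATION, Dataset, Partition
from .models import PHASE2_LEARNERS, LearnerSpec, fit_predict
from .search import SearchResult

logger = logging.getLogger(__name__)


@dataclass
class ValidationConfig:
    """Phase-2 protocol: how many subsets, which learner, how many runs."""

    n_subsets_to_evaluate: int = 10
    learner: str = "random_forest"
    learner_params: dict[str, Any] = field(default_factory=dict)
    n_runs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learner not in PHASE2_LEARNERS:
            raise ValueError(
                f"phase-2 learner must be one of {PHASE2_LEARNERS}, "
                f"got {self.learner!r}"
            )
        if self.n_subsets_to_evaluate < 1 or self.n_runs < 1:
            raise ValueError("n_subsets_to_evaluate and n_runs must be >= 1")


@dataclass
class SubsetReport:
    """Averaged external-validation metrics for one descriptor subset."""

    descriptor_names: list[str]
    cardinality: int
    metrics: dict[str, float]
    per_run: list[dict[str, float]] = field(default_factory=list)
    phase1_f2: float | None = None

    def __post_init__(self) -> None:
        if self.cardinality != len(self.descriptor_names):
            raise ValueError("cardinality must equal the number of descriptors")

    def to_dict(self) -> dict[str, Any]:
        return {
            "descriptors": self.descriptor_names,
            "cardinality": self.cardinality,
            "metrics": self.metrics,
            "per_run": self.per_run,
            "phase1_f2": self.phase1_f2,
        }


def classification_metrics(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    scores: np.ndarray | None,
    classes: list[str] | None,
) -> tuple[float, float, float]:
    """(%CC, MCC, average ROC AUC) for a label prediction.

    %CC is 100·correct/total.  MCC uses the generalised multi-category
    formula, which reduces to the classical binary
    (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)) for two classes; a zero
    denominator yields 0.  The average ROC is the class-frequency-weighted
    mean of one-vs-rest AUCs computed from the per-class score matrix.
    """
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if len(y_true) != len(y_pred):
        raise ValueError("prediction length mismatch")
    present = sorted(set(y_true))
    if len(present) < 2:
        raise ValueError("need >= 2 classes present in y_true")
    pcc = 100.0 * float(np.mean(y_true == y_pred))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mcc = float(matthews_corrcoef(y_true.astype(str), y_pred.astype(str)))

    avg_roc = float("nan")
    if scores is not None and classes is not None:
        aucs, weights = [], []
        for j, c in enumerate(classes):
            pos = (y_true == c).astype(int)
            if pos.sum() in (0, len(pos)):
                continue
            aucs.append(roc_auc_score(pos, scores[:, j]))
            weights.append(pos.mean())
        if aucs:
            avg_roc = float(np.average(aucs, weights=weights))
    return pcc, mcc, avg_roc


def regression_metrics(
    y_true: np.ndarray, y_pred: np.ndarray
) -> tuple[float, float, float]:
    """(MSE, RMSE, R²); R² is NaN when y_true has zero variance."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_true) != len(y_pred) or len(y_true) < 2:
        raise ValueError("need matching vectors of length >= 2")
    resid = y_true - y_pred
    mse = float(np.mean(resid**2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0.0:
        logger.warning("zero-variance target: R^2 undefined")
        r2 = float("nan")
    else:
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return mse, float(np.sqrt(mse)), r2


def _evaluate_mask_once(
    ds: Dataset,
    part: Partition,
    mask: np.ndarray,
    learner: LearnerSpec,
) -> dict[str, float]:
    cols = np.flatnonzero(np.asarray(mask, dtype=bool))
    X_tr = ds.X[np.ix_(part.internal_indices, cols)]
    X_te = ds.X[np.ix_(part.external_indices, cols)]
    y_tr = ds.y[part.internal_indices]
    y_te = ds.y[part.external_indices]
    pred = fit_predict(learner, X_tr, y_tr, X_te, ds.task)
    if ds.task == CLASSIFICATION:
        pcc, mcc, avg_roc = classification_metrics(
            y_te, pred.predictions, pred.scores, pred.classes
        )
        return {"pcc": pcc, "mcc": mcc, "avg_roc": avg_roc}
    mse, rmse, r2 = regression_metrics(y_te, pred.predictions)
    return {"mse": mse, "rmse": rmse, "r2": r2}


def _report_sort_key(report: SubsetReport, task: str):
    m = report.metrics
    if task == CLASSIFICATION:
        return (-m["pcc"], -m["mcc"], report.cardinality)
    return (m["mse"], report.cardinality)


def validate_subsets(
    result: SearchResult, ds: Dataset, part: Partition, cfg: ValidationConfig
) -> list[SubsetReport]:
    """Externally validate up to ``cfg.n_subsets_to_evaluate`` front subsets.

    Candidates are taken best-first by phase-1 error (lower F2, ties to
    lower cardinality).  Each is retrained on the internal rows and scored
    on the external rows ``n_runs`` times with learner seeds
    ``seed .. seed+n_runs-1``; metrics are run-averages.  Reports are
    returned best-first (classification: higher %CC, then higher MCC, then
    lower cardinality; regression: lower MSE, then lower cardinality).
    """
    if len(part.external_indices) == 0:
        raise ValueError("external partition is empty")
    name_to_col = {n: j for j, n in enumerate(ds.descriptor_names)}
    for ind in result.front:
        for n_sel in [
            n for n, b in zip(result.descriptor_names, ind.mask) if b
        ]:
            if n_sel not in name_to_col:
                raise ValueError(f"descriptor {n_sel!r} not present in dataset")

    candidates = sorted(
        result.front, key=lambda i: (i.objectives.f2, i.objectives.f1, tuple(i.mask))
    )
    if len(candidates) < cfg.n_subsets_to_evaluate:
        logger.info(
            "front has %d subsets; requested %d",
            len(candidates), cfg.n_subsets_to_evaluate,
        )
    candidates = candidates[: cfg.n_subsets_to_evaluate]

    reports: list[SubsetReport] = []
    base = LearnerSpec(cfg.learner, dict(cfg.learner_params))
    for ind in candidates:
        selected = [n for n, b in zip(result.descriptor_names, ind.mask) if b]
        mask = np.zeros(ds.n_descriptors, dtype=bool)
        mask[[name_to_col[n] for n in selected]] = True
        per_run = [
            _evaluate_mask_once(ds, part, mask, base.with_seed(cfg.seed + r))
            for r in range(cfg.n_runs)
        ]
        averaged = {
            k: float(np.mean([run[k] for run in per_run])) for k in per_run[0]
        }
        reports.append(
            SubsetReport(
                descriptor_names=selected,
                cardinality=len(selected),
                metrics=averaged,
                per_run=per_run,
                phase1_f2=float(ind.objectives.f2),
            )
        )
    reports.sort(key=lambda r: _report_sort_key(r, ds.task))
    return reports


def save_reports(
    reports: list[SubsetReport],
    json_path: str | Path | None = None,
    csv_path: str | Path | None = None,
    extra: dict[str, Any] | None = None,
) -> None:
    """Write reports to JSON (with per-run detail) and/or a flat CSV."""
    if json_path is not None:
        payload: dict[str, Any] = {"reports": [r.to_dict() for r in reports]}
        if extra:
            payload.update(extra)
        with open(json_path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)
    if csv_path is not None:
        rows = []
        for rank, r in enumerate(reports, start=1):
            row = {"rank": rank, "cardinality": r.cardinality}
            row.update(r.metrics)
            row["descriptors"] = "|".join(r.descriptor_names)
            rows.append(row)
        pd.DataFrame(rows).to_csv(csv_path, index=False)


def load_reports(path: str | Path) -> list[SubsetReport]:
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    return [
        SubsetReport(
            descriptor_names=d["descriptors"],
            cardinality=d["cardinality"],
            metrics=d["metrics"],
            per_run=d.get("per_run", []),
            phase1_f2=d.get("phase1_f2"),
        )
        for d in payload["reports"]
    ]
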