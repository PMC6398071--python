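"""Loading, sanitising and partitioning of tabular QSAR data.

A QSAR dataset is a compounds-by-descriptors matrix plus a target vector:
a continuous property for regression or a finite label set for
classification.  Files are plain CSV with a mandatory header row, decimal
point ``.`` and either a comma or a semicolon as the delimiter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REGRESSION = "regression"
CLASSIFICATION = "classification"
TASKS = (REGRESSION, CLASSIFICATION)

_DELIMITERS = {",": ",", ";": ";", "comma": ",", "semicolon": ";"}


class DatasetError(ValueError):
    """Raised for malformed input data or invalid dataset operations."""


@dataclass
class Dataset:
    """In-memory QSAR dataset.

    Attributes
    ----------
    X : ndarray of shape (n_compounds, n_descriptors)
        Descriptor values, float64, no missing entries.
    descriptor_names : list of str
        Unique column names aligned with ``X``.
    y : ndarray of shape (n_compounds,)
        Target values: float for regression, string labels for
        classification (at least two distinct labels).
    task : {"regression", "classification"}
    """

    X: np.ndarray
    descriptor_names: list[str]
    y: np.ndarray
    task: str

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise DatasetError("feature matrix must be 2-dimensional")
        if self.X.shape[1] != len(self.descriptor_names):
            raise DatasetError(
                f"{len(self.descriptor_names)} descriptor names for "
                f"{self.X.shape[1]} matrix columns"
            )
        if len(set(self.descriptor_names)) != len(self.descriptor_names):
            dupes = sorted(
                {n for n in self.descriptor_names if self.descriptor_names.count(n) > 1}
            )
            raise DatasetError(f"duplicate descriptor names: {dupes}")
        if not np.isfinite(self.X).all():
            r, c = np.argwhere(~np.isfinite(self.X))[0]
            raise DatasetError(
                f"missing or non-finite value at row {r}, "
                f"column '{self.descriptor_names[c]}'"
            )
        if self.task not in TASKS:
            raise DatasetError(f"task must be one of {TASKS}, got {self.task!r}")
        if self.task == REGRESSION:
            self.y = np.asarray(self.y, dtype=float)
            if not np.isfinite(self.y).all():
                raise DatasetError("missing or non-finite value in target")
        else:
            self.y = np.asarray(self.y, dtype=object)
            self.y = np.array([str(v) for v in self.y], dtype=object)
            if len(set(self.y)) < 2:
                raise DatasetError("classification target needs >=2 distinct labels")
        if len(self.y) != self.X.shape[0]:
            raise DatasetError("target length does not match number of compounds")

    @property
    def n_compounds(self) -> int:
        return self.X.shape[0]

    @property
    def n_descriptors(self) -> int:
        return self.X.shape[1]

    @property
    def labels(self) -> list[str]:
        """Sorted distinct class labels (classification only)."""
        if self.task != CLASSIFICATION:
            raise DatasetError("labels are defined only for classification")
        return sorted(set(self.y))

    def subset_rows(self, indices: np.ndarray) -> "Dataset":
        """Dataset restricted to the given compound rows."""
        idx = np.asarray(indices, dtype=int)
        return Dataset(self.X[idx], list(self.descriptor_names), self.y[idx], self.task)

    def subset_columns(self, mask: np.ndarray) -> "Dataset":
        """Dataset restricted to the descriptors selected by a boolean mask."""
        mask = np.asarray(mask, dtype=bool)
        names = [n for n, keep in zip(self.descriptor_names, mask) if keep]
        return Dataset(self.X[:, mask], names, self.y.copy(), self.task)


@dataclass
class Partition:
    """Disjoint internal/external split of compound rows.

    The internal rows feed the phase-1 wrapper search; the external rows
    are reserved for phase-2 validation and are never seen during search.
    """

    internal_indices: np.ndarray
    external_indices: np.ndarray
    seed: int
    internal_fraction: float

    def __post_init__(self) -> None:
        self.internal_indices = np.asarray(sorted(self.internal_indices), dtype=int)
        self.external_indices = np.asarray(sorted(self.external_indices), dtype=int)
        if np.intersect1d(self.internal_indices, self.external_indices).size:
            raise DatasetError("internal and external indices overlap")


def load_csv(
    path: str | Path,
    delimiter: str = ",",
    target_column: str = "target",
    task: str = CLASSIFICATION,
) -> Dataset:
    """Read a CSV file into a :class:`Dataset`.

    All non-target columns become descriptors, in file order.  Cells must
    parse as reals (the classification target is kept as labels).  Errors
    identify the offending row and column.
    """
    if delimiter not in _DELIMITERS:
        raise DatasetError(f"delimiter must be ',' or ';', got {delimiter!r}")
    sep = _DELIMITERS[delimiter]
    path = Path(path)
    if not path.exists():
        raise DatasetError(f"file not found: {path}")

    with open(path, "r", encoding="utf-8") as fh:
        header_line = fh.readline().rstrip("\n\r")
    header = [h.strip() for h in header_line.split(sep)]
    if len(header) == 1:
        raise DatasetError(
            f"parsed a single column '{header[0]}' — wrong delimiter? "
            f"(expected {sep!r})"
        )
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise DatasetError(f"duplicate column names in header: {dupes}")
    if target_column not in header:
        raise DatasetError(f"target column '{target_column}' not in header {header}")

    df = pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=True)
    df.columns = header

    descriptor_names = [h for h in header if h != target_column]
    n_rows = len(df)
    X = np.empty((n_rows, len(descriptor_names)), dtype=float)
    for j, name in enumerate(descriptor_names):
        col = df[name]
        missing = col.isna() | (col.str.strip() == "")
        if missing.any():
            r = int(np.flatnonzero(missing.to_numpy())[0])
            raise DatasetError(f"empty cell at row {r}, column '{name}'")
        parsed = pd.to_numeric(col, errors="coerce")
        bad = parsed.isna()
        if bad.any():
            r = int(np.flatnonzero(bad.to_numpy())[0])
            raise DatasetError(
                f"unparseable value {col.iloc[r]!r} at row {r}, column '{name}'"
            )
        # numpy's parser is correctly rounded; pd.to_numeric's fast path is not
        X[:, j] = col.to_numpy(dtype=float)

    ycol = df[target_column]
    if (ycol.isna() | (ycol.str.strip() == "")).any():
        r = int(np.flatnonzero((ycol.isna() | (ycol.str.strip() == "")).to_numpy())[0])
        raise DatasetError(f"empty cell at row {r}, column '{target_column}'")
    if task == REGRESSION:
        checked = pd.to_numeric(ycol, errors="coerce")
        if checked.isna().any():
            r = int(np.flatnonzero(checked.isna().to_numpy())[0])
            raise DatasetError(
                f"unparseable target {ycol.iloc[r]!r} at row {r}"
            )
        y = ycol.to_numpy(dtype=float)
    else:
        y = ycol.to_numpy(dtype=object)
    return Dataset(X, descriptor_names, y, task)


def save_csv(
    ds: Dataset,
    path: str | Path,
    delimiter: str = ",",
    target_column: str = "target",
) -> None:
    """Write a Dataset to CSV at full floating-point precision.

    ``load_csv`` on the written file reproduces the dataset bit-for-bit.
    """
    sep = _DELIMITERS[delimiter]
    df = pd.DataFrame(ds.X, columns=ds.descriptor_names)
    df[target_column] = ds.y
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def remove_constant_descriptors(ds: Dataset) -> tuple[Dataset, list[str]]:
    """Drop descriptor columns whose value is identical across all compounds.

    Uses exact equality (no variance tolerance).  Returns the reduced
    dataset and the removed names in original column order.
    """
    constant = np.all(ds.X == ds.X[0:1, :], axis=0)
    removed = [n for n, c in zip(ds.descriptor_names, constant) if c]
    if constant.all():
        raise DatasetError("no informative descriptors remain: all columns constant")
    if not removed:
        return ds, []
    reduced = ds.subset_columns(~constant)
    logger.info("removed %d constant descriptors", len(removed))
    return reduced, removed


def partition_dataset(ds: Dataset, internal_fraction: float, seed: int) -> Partition:
    """Split compounds into internal (phase-1) and external (phase-2) sets.

    ``|internal| = round(internal_fraction * n_compounds)``.  Classification
    splits are stratified: each label contributes proportionally, with the
    remainder allocated by a seeded draw weighted by the fractional quotas.
    Regression splits are plain seeded random draws.  The same seed always
    yields the same partition.
    """
    if not (0 < internal_fraction <= 1):
        raise DatasetError("internal_fraction must lie in (0, 1]")
    n = ds.n_compounds
    n_internal = int(round(internal_fraction * n))
    rng = np.random.default_rng(seed)

    if ds.task == CLASSIFICATION:
        labels = ds.labels
        groups = {lab: np.flatnonzero(ds.y == lab) for lab in labels}
        quotas = np.array([internal_fraction * len(groups[lab]) for lab in labels])
        base = np.floor(quotas).astype(int)
        remainder = n_internal - int(base.sum())
        frac = quotas - base
        if remainder > 0:
            p = frac / frac.sum() if frac.sum() > 0 else None
            extra = rng.choice(len(labels), size=remainder, replace=False, p=p)
            for k in extra:
                base[k] += 1
        internal: list[int] = []
        for k, lab in enumerate(labels):
            picked = rng.permutation(groups[lab])[: base[k]]
            internal.extend(int(i) for i in picked)
        internal_idx = np.asarray(sorted(internal), dtype=int)
    else:
        perm = rng.permutation(n)
        internal_idx = np.asarray(sorted(perm[:n_internal]), dtype=int)

    external_idx = np.setdiff1d(np.arange(n), internal_idx)
    if n_internal == 0 or len(external_idx) == 0:
        logger.warning(
            "partition leaves one side empty (internal=%d, external=%d)",
            n_internal, len(external_idx),
        )
    return Partition(internal_idx, external_idx, seed, internal_fraction)


def partition_from_indices(
    n_compounds: int, internal_indices: np.ndarray
) -> Partition:
    """Build a partition from an explicit internal-index set (e.g. a file
    reproducing a published train/test split)."""
    internal = np.asarray(sorted(internal_indices), dtype=int)
    if internal.size and (internal.min() < 0 or internal.max() >= n_compounds):
        raise DatasetError("internal indices out of range")
    external = np.setdiff1d(np.arange(n_compounds), internal)
    return Partition(internal, external, seed=-1, internal_fraction=len(internal) / n_compounds)
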