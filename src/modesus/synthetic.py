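"""QSAR-shaped synthetic datasets with a planted informative subset.

The generator emulates the shape of descriptor matrices produced by bulk
descriptor-calculation software: hundreds of compounds by hundreds of
descriptors, of which only a small subset carries signal, some columns are
noisy copies of informative ones (redundant), some are constant, and the
rest are independent noise.  The target is a linear score over the
informative descriptors plus Gaussian noise — continuous for regression,
thresholded at the class-balance quantile for binary classification — so
the optimal descriptor subset is known by construction and search recovery
is directly assertable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset_io import CLASSIFICATION, REGRESSION, Dataset

POSITIVE_LABEL = "RB"   # lexicographically greater => positive class
NEGATIVE_LABEL = "NRB"


@dataclass
class SyntheticSpec:
    """Generation parameters.

    Defaults give a binary-classification problem of 500 compounds by 100
    descriptors with 5 informative descriptors of unit effect size and
    moderate noise — a desk-scale analogue of a curated QSAR table.
    """

    n_compounds: int = 500
    n_descriptors: int = 100
    n_informative: int = 5
    n_redundant: int = 0
    n_constant: int = 0
    effect_size: float = 1.0
    noise_sd: float = 0.5
    task: str = CLASSIFICATION
    class_balance: float = 0.5
    margin: float = 0.0  # classification: rejection band half-width around the
    # class threshold, in units of the latent-score sd; a positive margin
    # leaves an empty band between the classes so that local learners can
    # separate them perfectly at finite sample size
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative + self.n_redundant + self.n_constant > self.n_descriptors:
            raise ValueError("planted column counts exceed n_descriptors")
        if self.n_informative < 1:
            raise ValueError("need at least one informative descriptor")
        if self.task not in (REGRESSION, CLASSIFICATION):
            raise ValueError(f"unknown task {self.task!r}")
        if not (0 < self.class_balance < 1):
            raise ValueError("class_balance must lie in (0, 1)")
        if self.margin < 0:
            raise ValueError("margin must be nonnegative")


def generate(spec: SyntheticSpec) -> tuple[Dataset, np.ndarray]:
    """Generate a dataset and the boolean truth mask of informative columns.

    Informative descriptors are standard normal; the latent score is
    ``effect_size`` times their sum plus N(0, noise_sd) noise.  Redundant
    descriptors are informative columns plus small (sd 0.1) noise; constant
    columns hold a fixed value; all remaining descriptors are independent
    standard normal.  Column positions are shuffled by the seed.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_compounds, spec.n_descriptors

    use_margin = spec.task == CLASSIFICATION and spec.margin > 0
    n_draw = 6 * n if use_margin else n
    X_inf = rng.standard_normal((n_draw, spec.n_informative))
    score = spec.effect_size * X_inf.sum(axis=1) + rng.normal(
        0.0, spec.noise_sd, size=n_draw
    )
    if use_margin:
        cut = np.quantile(score, 1.0 - spec.class_balance)
        keep = np.flatnonzero(np.abs(score - cut) > spec.margin * score.std())
        if len(keep) < n:
            raise ValueError("margin too wide: not enough compounds survive")
        keep = keep[:n]
        X_inf, score = X_inf[keep], score[keep]

    blocks = [X_inf]
    if spec.n_redundant:
        src = rng.integers(0, spec.n_informative, size=spec.n_redundant)
        blocks.append(X_inf[:, src] + rng.normal(0.0, 0.1, (n, spec.n_redundant)))
    if spec.n_constant:
        consts = rng.normal(0.0, 1.0, spec.n_constant)
        blocks.append(np.tile(consts, (n, 1)))
    n_noise = p - spec.n_informative - spec.n_redundant - spec.n_constant
    if n_noise:
        blocks.append(rng.standard_normal((n, n_noise)))
    X = np.hstack(blocks)

    order = rng.permutation(p)
    X = X[:, order]
    truth_mask = np.zeros(p, dtype=bool)
    truth_mask[np.flatnonzero(order < spec.n_informative)] = True

    width = len(str(p))
    names = [f"d{j + 1:0{width}d}" for j in range(p)]

    if spec.task == REGRESSION:
        y: np.ndarray = score
    else:
        # threshold at the empirical quantile so the positive fraction
        # matches class_balance up to integer rounding
        if not use_margin:
            cut = np.quantile(score, 1.0 - spec.class_balance)
        y = np.where(score > cut, POSITIVE_LABEL, NEGATIVE_LABEL).astype(object)
    return Dataset(X, names, y, spec.task), truth_mask
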