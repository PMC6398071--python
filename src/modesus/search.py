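"""Phase-1 multiobjective evolutionary wrapper over binary descriptor masks.

One GA individual is a binary vector with one bit per available descriptor;
a set bit selects that descriptor.  Three search modes share the same
variation pipeline (tournament selection, uniform crossover, gated bit-flip
mutation, cardinality repair):

* ``aggregation`` — minimises the scalarised fitness
  ``alpha*F2 + (1-alpha)*F2*F1/pm`` with elitism;
* ``nsga2`` — fast nondominated sorting plus crowding-distance selection;
* ``spea2`` — strength/raw-fitness with k-nearest-neighbour density and a
  truncated archive.

Every evaluated mask is cached and archived, and the reported front of a
trial is the nondominated set over *all* masks evaluated in that trial, so
good subsets cannot be lost to genetic drift.  A search runs ``trials``
independent GA executions (seeds ``seed + trial``) and reports the
deduplicated nondominated union of the per-trial fronts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from .dataset_io import Dataset
from .models import LearnerSpec
from .objectives import (
    AggregationParams,
    HoldoutEvaluator,
    ObjectiveVector,
    aggregate_fitness,
    dominates,
    nondominated_front,
)

logger = logging.getLogger(__name__)

RESULT_FORMAT_VERSION = 1


@dataclass
class GAConfig:
    """Evolutionary-engine parameters.

    ``pmut`` gates mutation per individual; a mutated individual flips each
    bit independently with ``per_bit_rate`` (default 1/n).  The stall
    criterion stops a run once the generation-to-generation improvement in
    mean population fitness stays below ``stall_threshold`` for
    ``stall_gens`` consecutive generations.
    """

    population_size: int = 100
    elite_size: int = 2
    tournament_size: int = 2
    pxo: float = 0.8
    pmut: float = 0.1
    per_bit_rate: float | None = None  # None -> 1/n_descriptors
    crossover: str = "uniform"  # or "single_point"
    max_generations: int = 100
    stall_gens: int = 10
    stall_threshold: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.elite_size >= self.population_size:
            raise ValueError("elite_size must be smaller than population_size")
        if self.tournament_size > self.population_size:
            raise ValueError("tournament_size cannot exceed population_size")
        if not (0 <= self.pxo <= 1 and 0 <= self.pmut <= 1):
            raise ValueError("pxo and pmut must lie in [0, 1]")


@dataclass
class SearchConfig:
    """Full phase-1 configuration: mode, trials, objectives and GA knobs."""

    mode: str = "aggregation"  # aggregation | nsga2 | spea2
    trials: int = 1
    agg: AggregationParams = field(default_factory=AggregationParams)
    wrapper_learner: str = "random_forest"
    wrapper_params: dict[str, Any] = field(default_factory=dict)
    holdout_fraction: float = 0.25
    ga: GAConfig = field(default_factory=GAConfig)

    def __post_init__(self) -> None:
        if self.mode not in ("aggregation", "nsga2", "spea2"):
            raise ValueError(f"unknown search mode {self.mode!r}")
        if self.trials < 1:
            raise ValueError("trials must be >= 1")


@dataclass
class Individual:
    mask: np.ndarray
    objectives: ObjectiveVector
    scalar_fitness: float | None = None
    rank: int | None = None
    density: float | None = None

    def mask_key(self) -> bytes:
        return np.asarray(self.mask, dtype=bool).tobytes()


@dataclass
class TrialLog:
    trial: int
    seed: int
    generations: int
    best_fitness: list[float]
    mean_fitness: list[float]
    stalled: bool


@dataclass
class SearchResult:
    """Union nondominated front plus per-trial fronts and run logs."""

    front: list[Individual]
    trial_fronts: list[list[Individual]]
    logs: list[TrialLog]
    descriptor_names: list[str]
    config: SearchConfig
    n_evaluations: int = 0


# ---------------------------------------------------------------------------
# variation operators


def initialize_population(
    n: int, population_size: int, pm: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Seeded random masks with cardinality uniform on [1, pm]."""
    if not (1 <= pm <= n):
        raise ValueError("need 1 <= pm <= n_descriptors")
    pop = []
    for _ in range(population_size):
        card = int(rng.integers(1, pm + 1))
        mask = np.zeros(n, dtype=bool)
        mask[rng.choice(n, size=card, replace=False)] = True
        pop.append(mask)
    return pop


def tournament_select(
    pop: list[Individual], k: int, rng: np.random.Generator, key=None
) -> Individual:
    """Sample ``k`` distinct individuals uniformly; return the best."""
    if k > len(pop):
        raise ValueError("tournament size exceeds population")
    if key is None:
        key = _aggregation_key
    idx = rng.choice(len(pop), size=k, replace=False)
    return min((pop[i] for i in idx), key=key)


def crossover(
    a: np.ndarray,
    b: np.ndarray,
    pxo: float,
    rng: np.random.Generator,
    method: str = "uniform",
) -> tuple[np.ndarray, np.ndarray]:
    """With probability ``pxo`` recombine two parent masks; otherwise copy.

    Uniform crossover draws each child bit from either parent, so positions
    where the parents agree are preserved in both children.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("parent masks differ in length")
    if rng.random() >= pxo:
        return a.copy(), b.copy()
    if method == "single_point":
        cut = int(rng.integers(1, len(a))) if len(a) > 1 else 0
        c1 = np.concatenate([a[:cut], b[cut:]])
        c2 = np.concatenate([b[:cut], a[cut:]])
        return c1, c2
    take_a = rng.random(len(a)) < 0.5
    return np.where(take_a, a, b), np.where(take_a, b, a)


def mutate(
    m: np.ndarray, pmut: float, per_bit_rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-individual mutation gate; each bit flips with ``per_bit_rate``."""
    m = np.asarray(m, dtype=bool)
    if rng.random() >= pmut:
        return m.copy()
    flips = rng.random(len(m)) < per_bit_rate
    return m ^ flips


def repair(m: np.ndarray, pm: int, rng: np.random.Generator) -> np.ndarray:
    """Enforce 1 <= cardinality <= pm by seeded random bit clears/sets."""
    m = np.asarray(m, dtype=bool).copy()
    card = int(m.sum())
    if card == 0:
        m[int(rng.integers(len(m)))] = True
    elif card > pm:
        on = np.flatnonzero(m)
        drop = rng.choice(on, size=card - pm, replace=False)
        m[drop] = False
    return m


def stall_check(
    mean_fitness_history: list[float], stall_gens: int, stall_threshold: float
) -> bool:
    """True iff the last ``stall_gens`` generation-to-generation improvements
    (previous mean − current mean, minimisation) are all below the
    threshold.  Requires at least ``stall_gens + 1`` recorded generations."""
    if not mean_fitness_history:
        raise ValueError("empty fitness history")
    if len(mean_fitness_history) < stall_gens + 1:
        return False
    tail = mean_fitness_history[-(stall_gens + 1):]
    return all(prev - curr < stall_threshold for prev, curr in zip(tail, tail[1:]))


# ---------------------------------------------------------------------------
# ranking helpers


def _aggregation_key(ind: Individual):
    # ties: lower cardinality, then lexicographically smaller mask
    return (ind.scalar_fitness, ind.objectives.f1, tuple(ind.mask))


def _pareto_key(ind: Individual):
    return (ind.rank, -(ind.density or 0.0), ind.objectives.f1, tuple(ind.mask))


def fast_nondominated_sort(objectives: list[ObjectiveVector]) -> list[int]:
    """NSGA-II nondominated sorting; returns the 0-based front rank of each
    point (rank 0 = nondominated)."""
    n = len(objectives)
    dominated_by: list[list[int]] = [[] for _ in range(n)]
    n_dominating = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            if dominates(objectives[i], objectives[j]):
                dominated_by[i].append(j)
                n_dominating[j] += 1
            elif dominates(objectives[j], objectives[i]):
                dominated_by[j].append(i)
                n_dominating[i] += 1
    ranks = np.zeros(n, dtype=int)
    current = [i for i in range(n) if n_dominating[i] == 0]
    r = 0
    while current:
        nxt = []
        for i in current:
            ranks[i] = r
            for j in dominated_by[i]:
                n_dominating[j] -= 1
                if n_dominating[j] == 0:
                    nxt.append(j)
        current = nxt
        r += 1
    return list(ranks)


def crowding_distance(objectives: list[ObjectiveVector]) -> np.ndarray:
    """NSGA-II crowding distance within one front (larger = less crowded)."""
    n = len(objectives)
    dist = np.zeros(n)
    if n <= 2:
        return np.full(n, np.inf)
    for dim in range(2):
        vals = np.array([obj[dim] for obj in objectives], dtype=float)
        order = np.argsort(vals, kind="stable")
        dist[order[0]] = dist[order[-1]] = np.inf
        span = vals[order[-1]] - vals[order[0]]
        if span == 0:
            continue
        for k in range(1, n - 1):
            dist[order[k]] += (vals[order[k + 1]] - vals[order[k - 1]]) / span
    return dist


# ---------------------------------------------------------------------------
# trial engines


class _TrialContext:
    """Tracks the masks evaluated within one GA execution."""

    def __init__(self, evaluator: HoldoutEvaluator):
        self.evaluator = evaluator
        self.seen: dict[bytes, tuple[np.ndarray, ObjectiveVector]] = {}

    def evaluate(self, mask: np.ndarray) -> ObjectiveVector:
        obj = self.evaluator.evaluate(mask)
        self.seen.setdefault(mask.tobytes(), (mask.copy(), obj))
        return obj

    def archive_front(self) -> list[Individual]:
        inds = [Individual(m, o) for m, o in self.seen.values()]
        return nondominated_front(inds, objectives=lambda i: i.objectives)


def _make_children(
    pop: list[Individual],
    n_children: int,
    cfg: GAConfig,
    pm: int,
    per_bit: float,
    ctx: _TrialContext,
    rng: np.random.Generator,
    key,
) -> list[Individual]:
    children: list[Individual] = []
    while len(children) < n_children:
        p1 = tournament_select(pop, cfg.tournament_size, rng, key=key)
        p2 = tournament_select(pop, cfg.tournament_size, rng, key=key)
        c1, c2 = crossover(p1.mask, p2.mask, cfg.pxo, rng, method=cfg.crossover)
        for c in (c1, c2):
            if len(children) >= n_children:
                break
            c = repair(mutate(c, cfg.pmut, per_bit, rng), pm, rng)
            children.append(Individual(c, ctx.evaluate(c)))
    return children


def _run_trial_aggregation(
    ctx: _TrialContext, n: int, cfg: SearchConfig, rng: np.random.Generator,
    hook=None,
) -> TrialLog:
    ga, agg = cfg.ga, cfg.agg
    per_bit = ga.per_bit_rate if ga.per_bit_rate is not None else 1.0 / n

    def score(ind: Individual) -> None:
        ind.scalar_fitness = aggregate_fitness(
            ind.objectives.f1, ind.objectives.f2, agg
        )

    pop = [
        Individual(m, ctx.evaluate(m))
        for m in initialize_population(n, ga.population_size, agg.pm, rng)
    ]
    for ind in pop:
        score(ind)
    mean_hist = [float(np.mean([i.scalar_fitness for i in pop]))]
    best_hist = [float(min(i.scalar_fitness for i in pop))]
    if hook:
        hook(0, pop)
    stalled = False
    gen = 0
    for gen in range(1, ga.max_generations):
        pop.sort(key=_aggregation_key)
        elites = [
            Individual(i.mask.copy(), i.objectives, i.scalar_fitness)
            for i in pop[: ga.elite_size]
        ]
        children = _make_children(
            pop, ga.population_size - ga.elite_size, ga, agg.pm, per_bit,
            ctx, rng, _aggregation_key,
        )
        for ind in children:
            score(ind)
        pop = elites + children
        mean_hist.append(float(np.mean([i.scalar_fitness for i in pop])))
        best_hist.append(float(min(i.scalar_fitness for i in pop)))
        if hook:
            hook(gen, pop)
        if stall_check(mean_hist, ga.stall_gens, ga.stall_threshold):
            stalled = True
            break
    return TrialLog(-1, -1, gen + 1, best_hist, mean_hist, stalled)


def _assign_nsga2(pop: list[Individual]) -> None:
    ranks = fast_nondominated_sort([i.objectives for i in pop])
    for ind, r in zip(pop, ranks):
        ind.rank = int(r)
    for r in set(ranks):
        front = [i for i, rr in zip(pop, ranks) if rr == r]
        dists = crowding_distance([i.objectives for i in front])
        for ind, d in zip(front, dists):
            ind.density = float(d)


def _f2_stats(pop: list[Individual]) -> tuple[float, float]:
    f2s = [i.objectives.f2 for i in pop]
    return float(np.mean(f2s)), float(min(f2s))


def _run_trial_nsga2(
    ctx: _TrialContext, n: int, cfg: SearchConfig, rng: np.random.Generator,
    hook=None,
) -> TrialLog:
    ga = cfg.ga
    per_bit = ga.per_bit_rate if ga.per_bit_rate is not None else 1.0 / n
    pop = [
        Individual(m, ctx.evaluate(m))
        for m in initialize_population(n, ga.population_size, cfg.agg.pm, rng)
    ]
    _assign_nsga2(pop)
    mean0, best0 = _f2_stats(pop)
    mean_hist, best_hist = [mean0], [best0]
    if hook:
        hook(0, pop)
    stalled = False
    gen = 0
    for gen in range(1, ga.max_generations):
        offspring = _make_children(
            pop, ga.population_size, ga, cfg.agg.pm, per_bit, ctx, rng, _pareto_key
        )
        combined = pop + offspring
        _assign_nsga2(combined)
        combined.sort(key=_pareto_key)
        pop = combined[: ga.population_size]
        _assign_nsga2(pop)
        mean_g, best_g = _f2_stats(pop)
        mean_hist.append(mean_g)
        best_hist.append(best_g)
        if hook:
            hook(gen, pop)
        if stall_check(mean_hist, ga.stall_gens, ga.stall_threshold):
            stalled = True
            break
    return TrialLog(-1, -1, gen + 1, best_hist, mean_hist, stalled)


def _spea2_fitness(union: list[Individual]) -> None:
    """Strength/raw fitness plus k-NN density on range-normalised objectives.

    Stored as ``scalar_fitness`` (lower is better); ``rank`` is 0 for
    nondominated members so Pareto-style tournament keys apply.
    """
    m = len(union)
    objs = [i.objectives for i in union]
    dom = np.zeros((m, m), dtype=bool)
    for i in range(m):
        for j in range(m):
            if i != j and dominates(objs[i], objs[j]):
                dom[i, j] = True
    strength = dom.sum(axis=1)
    raw = np.array([strength[dom[:, j]].sum() for j in range(m)], dtype=float)
    pts = np.array([[o.f1, o.f2] for o in objs], dtype=float)
    rng_span = pts.max(axis=0) - pts.min(axis=0)
    rng_span[rng_span == 0] = 1.0
    pts = pts / rng_span
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    k = max(1, int(np.sqrt(m)))
    sigma_k = np.sqrt(np.sort(d2, axis=1)[:, min(k, m - 1)]) if m > 1 else np.zeros(m)
    density = 1.0 / (sigma_k + 2.0)
    for ind, r, d in zip(union, raw, density):
        ind.scalar_fitness = float(r + d)
        ind.rank = 0 if r == 0 else 1 + int(r)
        ind.density = float(-d)  # higher = less crowded under _pareto_key


def _spea2_truncate(archive: list[Individual], size: int) -> list[Individual]:
    """Iteratively drop the member with the smallest k-NN distance vector."""
    members = list(archive)
    while len(members) > size:
        pts = np.array(
            [[i.objectives.f1, i.objectives.f2] for i in members], dtype=float
        )
        span = pts.max(axis=0) - pts.min(axis=0)
        span[span == 0] = 1.0
        pts = pts / span
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
        np.fill_diagonal(d2, np.inf)
        sorted_d = np.sort(d2, axis=1)
        # lexicographic comparison of sorted distance vectors
        order = np.lexsort(tuple(sorted_d[:, c] for c in range(sorted_d.shape[1] - 1, -1, -1)))
        members.pop(int(order[0]))
    return members


def _run_trial_spea2(
    ctx: _TrialContext, n: int, cfg: SearchConfig, rng: np.random.Generator,
    hook=None,
) -> TrialLog:
    ga = cfg.ga
    per_bit = ga.per_bit_rate if ga.per_bit_rate is not None else 1.0 / n
    archive_size = ga.population_size
    pop = [
        Individual(m, ctx.evaluate(m))
        for m in initialize_population(n, ga.population_size, cfg.agg.pm, rng)
    ]
    archive: list[Individual] = []
    mean0, best0 = _f2_stats(pop)
    mean_hist, best_hist = [mean0], [best0]
    if hook:
        hook(0, pop)
    stalled = False
    gen = 0
    for gen in range(1, ga.max_generations):
        union = pop + archive
        _spea2_fitness(union)
        nondom = [i for i in union if i.rank == 0]
        if len(nondom) > archive_size:
            archive = _spea2_truncate(nondom, archive_size)
        else:
            dominated = sorted(
                (i for i in union if i.rank != 0), key=lambda i: i.scalar_fitness
            )
            archive = nondom + dominated[: archive_size - len(nondom)]
        pop = _make_children(
            archive, ga.population_size, ga, cfg.agg.pm, per_bit, ctx, rng,
            lambda i: (i.scalar_fitness, i.objectives.f1, tuple(i.mask)),
        )
        mean_g, best_g = _f2_stats(pop)
        mean_hist.append(mean_g)
        best_hist.append(best_g)
        if hook:
            hook(gen, pop)
        if stall_check(mean_hist, ga.stall_gens, ga.stall_threshold):
            stalled = True
            break
    return TrialLog(-1, -1, gen + 1, best_hist, mean_hist, stalled)


_TRIAL_ENGINES = {
    "aggregation": _run_trial_aggregation,
    "nsga2": _run_trial_nsga2,
    "spea2": _run_trial_spea2,
}


# ---------------------------------------------------------------------------
# top level


def run_search(
    ds_internal: Dataset,
    cfg: SearchConfig,
    evaluator: HoldoutEvaluator | None = None,
    on_generation=None,
) -> SearchResult:
    """Run ``cfg.trials`` independent GA executions and report the
    deduplicated nondominated union of their fronts.

    Trial ``t`` uses seed ``cfg.ga.seed + t``.  All trials share one fixed
    F2 holdout split (seeded by ``cfg.ga.seed``) and one fitness cache.
    ``evaluator`` may override the default F2 evaluator;
    ``on_generation(trial, gen, population)`` is invoked after every
    generation for progress reporting or inspection.
    """
    n = ds_internal.n_descriptors
    if cfg.agg.pm > n:
        raise ValueError("maximum cardinality pm exceeds descriptor count")
    if cfg.mode != "aggregation" and cfg.ga.elite_size:
        logger.info(
            "elite_size ignored in %s mode (intrinsic archiving applies)", cfg.mode
        )
    if evaluator is None:
        learner = LearnerSpec(
            cfg.wrapper_learner, dict(cfg.wrapper_params), cfg.ga.seed
        )
        evaluator = HoldoutEvaluator(
            ds_internal, learner, cfg.ga.seed, cfg.holdout_fraction
        )
    engine = _TRIAL_ENGINES[cfg.mode]

    trial_fronts: list[list[Individual]] = []
    logs: list[TrialLog] = []
    for trial in range(cfg.trials):
        seed = cfg.ga.seed + trial
        rng = np.random.default_rng(seed)
        ctx = _TrialContext(evaluator)
        hook = (
            (lambda gen, pop, _t=trial: on_generation(_t, gen, pop))
            if on_generation
            else None
        )
        log = engine(ctx, n, cfg, rng, hook)
        log.trial, log.seed = trial, seed
        logs.append(log)
        trial_fronts.append(ctx.archive_front())

    merged: dict[bytes, Individual] = {}
    for front in trial_fronts:
        for ind in front:
            merged.setdefault(ind.mask_key(), ind)
    final = nondominated_front(list(merged.values()), objectives=lambda i: i.objectives)
    return SearchResult(
        front=final,
        trial_fronts=trial_fronts,
        logs=logs,
        descriptor_names=list(ds_internal.descriptor_names),
        config=cfg,
        n_evaluations=evaluator.n_evaluations,
    )


# ---------------------------------------------------------------------------
# serialization


def _mask_to_bits(mask: np.ndarray) -> str:
    return "".join("1" if b else "0" for b in mask)


def _individual_to_dict(ind: Individual, names: list[str]) -> dict[str, Any]:
    return {
        "bits": _mask_to_bits(ind.mask),
        "descriptors": [n for n, b in zip(names, ind.mask) if b],
        "f1": int(ind.objectives.f1),
        "f2": float(ind.objectives.f2),
    }


def _config_to_dict(cfg: SearchConfig) -> dict[str, Any]:
    return {
        "mode": cfg.mode,
        "trials": cfg.trials,
        "alpha": cfg.agg.alpha,
        "pm": cfg.agg.pm,
        "wrapper_learner": cfg.wrapper_learner,
        "wrapper_params": cfg.wrapper_params,
        "holdout_fraction": cfg.holdout_fraction,
        "ga": {
            "population_size": cfg.ga.population_size,
            "elite_size": cfg.ga.elite_size,
            "tournament_size": cfg.ga.tournament_size,
            "pxo": cfg.ga.pxo,
            "pmut": cfg.ga.pmut,
            "per_bit_rate": cfg.ga.per_bit_rate,
            "crossover": cfg.ga.crossover,
            "max_generations": cfg.ga.max_generations,
            "stall_gens": cfg.ga.stall_gens,
            "stall_threshold": cfg.ga.stall_threshold,
            "seed": cfg.ga.seed,
        },
    }


def config_from_dict(d: dict[str, Any]) -> SearchConfig:
    ga = d.get("ga", {})
    return SearchConfig(
        mode=d.get("mode", "aggregation"),
        trials=d.get("trials", 1),
        agg=AggregationParams(alpha=d.get("alpha", 0.5), pm=d.get("pm", 15)),
        wrapper_learner=d.get("wrapper_learner", "random_forest"),
        wrapper_params=d.get("wrapper_params", {}),
        holdout_fraction=d.get("holdout_fraction", 0.25),
        ga=GAConfig(**ga) if ga else GAConfig(),
    )


def save_search_result(
    result: SearchResult, path: str | Path, extra: dict[str, Any] | None = None
) -> None:
    """Serialise a SearchResult to versioned JSON (consumed by phase 2)."""
    names = result.descriptor_names
    payload: dict[str, Any] = {
        "format_version": RESULT_FORMAT_VERSION,
        "config": _config_to_dict(result.config),
        "descriptor_names": names,
        "n_evaluations": result.n_evaluations,
        "front": [_individual_to_dict(i, names) for i in result.front],
        "trial_fronts": [
            [_individual_to_dict(i, names) for i in front]
            for front in result.trial_fronts
        ],
        "logs": [
            {
                "trial": lg.trial,
                "seed": lg.seed,
                "generations": lg.generations,
                "best_fitness": lg.best_fitness,
                "mean_fitness": lg.mean_fitness,
                "stalled": lg.stalled,
            }
            for lg in result.logs
        ],
    }
    if extra:
        payload.update(extra)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)


def _individual_from_dict(d: dict[str, Any]) -> Individual:
    mask = np.array([c == "1" for c in d["bits"]], dtype=bool)
    return Individual(mask, ObjectiveVector(int(d["f1"]), float(d["f2"])))


def load_search_result(path: str | Path) -> tuple[SearchResult, dict[str, Any]]:
    """Load a saved SearchResult; also returns the raw payload (which may
    carry the embedded dataset/partition echo written by the CLI)."""
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    if payload.get("format_version") != RESULT_FORMAT_VERSION:
        raise ValueError("unsupported search-result format version")
    result = SearchResult(
        front=[_individual_from_dict(d) for d in payload["front"]],
        trial_fronts=[
            [_individual_from_dict(d) for d in front]
            for front in payload["trial_fronts"]
        ],
        logs=[
            TrialLog(
                lg["trial"], lg["seed"], lg["generations"],
                lg["best_fitness"], lg["mean_fitness"], lg["stalled"],
            )
            for lg in payload["logs"]
        ],
        descriptor_names=list(payload["descriptor_names"]),
        config=config_from_dict(payload["config"]),
        n_evaluations=payload.get("n_evaluations", 0),
    )
    return result, payload
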