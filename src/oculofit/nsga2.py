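"""NSGA-II engine for the oculomotor fitting problems.

The algorithm follows the standard elitist scheme: binary tournament
selection on (rank, crowding distance), heuristic crossover, adaptive
feasible mutation, merging of parents and offspring, fast non-dominated
sorting and truncation back to the population size.  Runs are fully
reproducible from the seed.

The crossover is the "heuristic" operator: the child lies on the line
through both parents, beyond the better one by a ratio R (default 1.2),
clipped to the bounds.  The mutation takes a Gaussian step whose
per-parameter scale adapts across generations — it grows when mutants
frequently reach ranks at least as good as their parents and shrinks
otherwise — and is reflected at the bounds so every mutant is feasible.
Candidates whose objective evaluation raises are penalised (1e60 on every
objective) and purged by selection as soon as any finite solution exists.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .fitness import ObjectiveVector, PENALTY_VALUE
from .model import Bounds

__all__ = [
    "GAConfig",
    "Individual",
    "ParetoFrontEstimate",
    "GenerationRecord",
    "NSGAResult",
    "dominates",
    "fast_nondominated_sort",
    "crowding_distance",
    "heuristic_crossover",
    "adaptive_mutation",
    "run_nsga2",
    "select_best",
]

BoundsLike = Union[Bounds, Tuple[np.ndarray, np.ndarray]]


def _as_lo_hi(bounds: BoundsLike) -> Tuple[np.ndarray, np.ndarray]:
    if isinstance(bounds, Bounds):
        return bounds.low(), bounds.high()
    lo, hi = bounds
    return np.atleast_1d(np.asarray(lo, float)), np.atleast_1d(np.asarray(hi, float))


@dataclass(frozen=True)
class GAConfig:
    """NSGA-II settings.

    population_size : even, >= 4 (500-8000 at full scale; desk-scale runs
        here use 100-200).
    generations : 100 for saccade/synthetic fits, 200 for experimental
        nystagmus fits at full scale.
    crossover_ratio : heuristic-crossover overshoot ratio R.
    crossover_fraction : fraction of offspring created by crossover, the
        rest by mutation.
    mutation_scale : initial mutation step as a fraction of each
        parameter's range; adapted multiplicatively between
        ``mutation_scale_limits`` based on the mutant success rate.
    distance_measure : 'phenotype' (crowding in objective space, default)
        or 'genotype' (decision space).
    """

    population_size: int = 200
    generations: int = 100
    crossover_ratio: float = 1.2
    crossover_fraction: float = 0.8
    mutation_scale: float = 0.1
    mutation_scale_limits: Tuple[float, float] = (1e-4, 0.5)
    mutation_success_target: float = 0.2
    mutation_grow: float = 1.15
    mutation_shrink: float = 0.85
    tournament_size: int = 2
    distance_measure: str = "phenotype"
    n_objectives_hint: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 4 or self.population_size % 2:
            raise ValueError("population_size must be even and >= 4")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.distance_measure not in ("phenotype", "genotype"):
            raise ValueError("distance_measure must be 'phenotype' or 'genotype'")

    def replace(self, **kw) -> "GAConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class Individual:
    """One population member: decision vector, objectives, sort keys."""

    params: np.ndarray
    objectives: ObjectiveVector
    rank: int
    crowding: float


@dataclass(frozen=True)
class ParetoFrontEstimate:
    """Mutually non-dominated individuals from one run's final population."""

    individuals: Tuple[Individual, ...]

    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self):
        return iter(self.individuals)

    @property
    def decision_matrix(self) -> np.ndarray:
        return np.array([ind.params for ind in self.individuals])

    @property
    def objective_matrix(self) -> np.ndarray:
        return np.array([ind.objectives.as_array() for ind in self.individuals])


@dataclass(frozen=True)
class GenerationRecord:
    generation: int
    front_objectives: np.ndarray
    mutation_scale: float
    n_evaluations: int


@dataclass(frozen=True)
class NSGAResult:
    population: Tuple[Individual, ...]
    front: ParetoFrontEstimate
    history: Tuple[GenerationRecord, ...]


def _objs(a) -> np.ndarray:
    return a.as_array() if isinstance(a, ObjectiveVector) else np.asarray(a, float)


def dominates(a, b) -> bool:
    """Pareto dominance: `a` no worse than `b` everywhere, better somewhere."""
    av, bv = _objs(a), _objs(b)
    if av.shape != bv.shape:
        raise ValueError("objective vectors must have equal length")
    return bool(np.all(av <= bv) and np.any(av < bv))


def fast_nondominated_sort(objs: Sequence) -> np.ndarray:
    """Ranks of each objective vector: 0 for the non-dominated set, k for
    the set non-dominated once ranks < k are removed."""
    F = np.array([_objs(o) for o in objs], dtype=float)
    if F.ndim != 2 or len(F) == 0:
        raise ValueError("need a non-empty sequence of objective vectors")
    n = len(F)
    # pairwise dominance: dom[i, j] True iff i dominates j
    le = np.all(F[:, None, :] <= F[None, :, :], axis=2)
    lt = np.any(F[:, None, :] < F[None, :, :], axis=2)
    dom = le & lt
    n_dominators = dom.sum(axis=0)
    ranks = np.full(n, -1, dtype=int)
    current = np.where(n_dominators == 0)[0]
    k = 0
    while len(current):
        ranks[current] = k
        n_dominators = n_dominators - dom[current].sum(axis=0)
        n_dominators[ranks >= 0] = -1
        current = np.where(n_dominators == 0)[0]
        k += 1
    return ranks


def crowding_distance(front_objs: Sequence) -> np.ndarray:
    """Crowding distances within one front: boundary points get +inf,
    interior points accumulate normalised neighbour gaps per objective;
    zero-range objectives contribute nothing."""
    F = np.array([_objs(o) for o in front_objs], dtype=float)
    n, m = F.shape
    d = np.zeros(n)
    if n <= 2:
        return np.full(n, np.inf)
    for j in range(m):
        order = np.argsort(F[:, j], kind="stable")
        f = F[order, j]
        rng = f[-1] - f[0]
        d[order[0]] = d[order[-1]] = np.inf
        if rng > 0:
            d[order[1:-1]] += (f[2:] - f[:-2]) / rng
    return d


def heuristic_crossover(
    better: np.ndarray,
    worse: np.ndarray,
    ratio: float,
    bounds: BoundsLike,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Child on the parent line, `ratio` of the way past the better parent
    from the worse one, clipped to the bounds."""
    lo, hi = _as_lo_hi(bounds)
    child = np.asarray(worse, float) + ratio * (np.asarray(better, float) - np.asarray(worse, float))
    return np.clip(child, lo, hi)


def _reflect(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Fold values into [lo, hi] by reflection at the boundaries."""
    span = hi - lo
    y = np.mod(x - lo, 2.0 * span)
    y = np.where(y > span, 2.0 * span - y, y)
    return lo + y


def adaptive_mutation(
    parent: np.ndarray,
    scale: np.ndarray,
    bounds: BoundsLike,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gaussian step of per-parameter `scale` (absolute units), reflected
    at the bounds so the mutant is always feasible."""
    lo, hi = _as_lo_hi(bounds)
    step = np.asarray(scale, float) * rng.standard_normal(len(lo))
    return _reflect(np.asarray(parent, float) + step, lo, hi)


def _tournament(rng, ranks, crowd, n):
    i, j = rng.integers(n), rng.integers(n)
    if ranks[i] < ranks[j]:
        return i
    if ranks[j] < ranks[i]:
        return j
    if crowd[i] > crowd[j]:
        return i
    if crowd[j] > crowd[i]:
        return j
    return i


def _crowding_by_front(keys: np.ndarray, ranks: np.ndarray) -> np.ndarray:
    crowd = np.zeros(len(keys))
    for k in np.unique(ranks):
        idx = np.where(ranks == k)[0]
        crowd[idx] = crowding_distance(keys[idx])
    return crowd


def _lexicographic_order(F: np.ndarray) -> np.ndarray:
    """Indices sorted lexicographically by objective components."""
    return np.lexsort(tuple(F[:, j] for j in range(F.shape[1] - 1, -1, -1)))


def run_nsga2(
    objective_fn: Callable[[np.ndarray], ObjectiveVector],
    bounds: BoundsLike,
    cfg: GAConfig,
) -> NSGAResult:
    """Run one NSGA-II optimisation.

    `objective_fn` maps a decision vector to an ObjectiveVector; raising
    inside it penalises that candidate without aborting the run.  Repeated
    decision vectors are evaluated once per run (the objective maps are
    deterministic).  The returned front holds the rank-0 individuals of
    the final population; penalty individuals are excluded unless the
    entire population is penalised.
    """
    lo, hi = _as_lo_hi(bounds)
    d = len(lo)
    n = cfg.population_size
    rng = np.random.default_rng(cfg.seed)
    cache: dict = {}
    n_evals = 0

    def evaluate(x: np.ndarray) -> ObjectiveVector:
        nonlocal n_evals
        key = x.tobytes()
        if key in cache:
            return cache[key]
        n_evals += 1
        try:
            obj = objective_fn(x)
            if not isinstance(obj, ObjectiveVector):
                obj = ObjectiveVector(tuple(np.asarray(obj, float)))
        except Exception:
            obj = ObjectiveVector.penalised(cfg.n_objectives_hint)
        cache[key] = obj
        return obj

    X = lo + rng.uniform(size=(n, d)) * (hi - lo)
    objs = [evaluate(X[i]) for i in range(n)]
    n_obj = len(objs[0])
    F = np.array([o.as_array() for o in objs])
    ranks = fast_nondominated_sort(F)
    crowd = _crowding_by_front(F if cfg.distance_measure == "phenotype" else (X - lo) / (hi - lo), ranks)
    sigma = cfg.mutation_scale * (hi - lo)
    history: List[GenerationRecord] = []

    def record(gen):
        mask = ranks == 0
        history.append(
            GenerationRecord(
                generation=gen,
                front_objectives=F[mask].copy(),
                mutation_scale=float(np.mean(sigma / (hi - lo))),
                n_evaluations=n_evals,
            )
        )

    record(0)

    n_cross = int(round(cfg.crossover_fraction * n))
    for gen in range(1, cfg.generations + 1):
        children = np.empty((n, d))
        mut_parent: List[Tuple[int, int]] = []  # (child index, parent index)
        for c in range(n_cross):
            i = _tournament(rng, ranks, crowd, n)
            j = _tournament(rng, ranks, crowd, n)
            # order parents by tournament keys
            if (ranks[j], -crowd[j], j) < (ranks[i], -crowd[i], i):
                i, j = j, i
            children[c] = heuristic_crossover(X[i], X[j], cfg.crossover_ratio, (lo, hi), rng)
        for c in range(n_cross, n):
            i = _tournament(rng, ranks, crowd, n)
            children[c] = adaptive_mutation(X[i], sigma, (lo, hi), rng)
            mut_parent.append((c, i))

        child_objs = [evaluate(children[i]) for i in range(n)]
        merged_X = np.vstack([X, children])
        merged_objs = objs + child_objs
        merged_F = np.array([o.as_array() for o in merged_objs])
        merged_ranks = fast_nondominated_sort(merged_F)

        # adapt the mutation scale on the mutant success rate
        if mut_parent:
            successes = sum(
                1 for c, i in mut_parent if merged_ranks[n + c] <= merged_ranks[i]
            )
            factor = (
                cfg.mutation_grow
                if successes / len(mut_parent) >= cfg.mutation_success_target
                else cfg.mutation_shrink
            )
            frac = np.clip(
                factor * sigma / (hi - lo),
                cfg.mutation_scale_limits[0],
                cfg.mutation_scale_limits[1],
            )
            sigma = frac * (hi - lo)

        # environmental selection: fill by rank, break the last front by crowding
        merged_keys = (
            merged_F if cfg.distance_measure == "phenotype" else (merged_X - lo) / (hi - lo)
        )
        merged_crowd = _crowding_by_front(merged_keys, merged_ranks)
        order = np.lexsort((np.arange(2 * n), -merged_crowd, merged_ranks))
        keep = order[:n]
        X = merged_X[keep]
        objs = [merged_objs[i] for i in keep]
        F = merged_F[keep]
        ranks = fast_nondominated_sort(F)
        crowd = _crowding_by_front(
            F if cfg.distance_measure == "phenotype" else (X - lo) / (hi - lo), ranks
        )
        record(gen)

    finite = [i for i in range(n) if not objs[i].penalty]
    front_idx = [i for i in range(n) if ranks[i] == 0 and (not objs[i].penalty or not finite)]
    population = tuple(
        Individual(params=X[i].copy(), objectives=objs[i], rank=int(ranks[i]), crowding=float(crowd[i]))
        for i in range(n)
    )
    front = ParetoFrontEstimate(tuple(population[i] for i in front_idx))
    return NSGAResult(population=population, front=front, history=tuple(history))


def select_best(
    front: ParetoFrontEstimate,
    method: str = "min_period",
    objective_index: Optional[int] = None,
) -> Individual:
    """Pick one individual from a Pareto front estimate.

    'min_period' : smallest period-difference component (the last
        objective of the nystagmus bi-objective vector).
    'min_norm' : smallest Euclidean norm of the objective vector, i.e.
        closest to the objective-space origin.
    'best_objective' : smallest value of component `objective_index`.
    Ties are broken toward the individual that comes first when objective
    vectors are sorted lexicographically.
    """
    if len(front) == 0:
        raise ValueError("front is empty")
    F = front.objective_matrix
    if method == "min_period":
        key = F[:, -1]
    elif method == "min_norm":
        key = np.linalg.norm(F, axis=1)
    elif method == "best_objective":
        if objective_index is None:
            raise ValueError("best_objective requires objective_index")
        key = F[:, objective_index]
    else:
        raise ValueError(f"unknown selection method {method!r}")
    best = np.min(key)
    candidates = np.where(key == best)[0]
    if len(candidates) > 1:
        lex = _lexicographic_order(F[candidates])
        candidates = candidates[lex]
    return front.individuals[int(candidates[0])]
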