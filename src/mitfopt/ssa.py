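"""Sparrow search algorithm (SSA) on the unit box.

A swarm of ``n`` candidate positions in ``[0, 1]^d`` is split each
iteration, by ascending fitness (lower is better), into producers (the
best 70%), who explore, and scroungers (the rest), who follow; an
independently drawn 20% of the population additionally act as scouts, who
jump when their position is poor.  Update rules:

producers (rank ``i`` = 1..n1 within producers)::

    x <- x * exp(-i / (alpha * itermax))          if R2 < ST   (alpha ~ U(0,1])
    x <- x + Q                                    otherwise    (Q ~ N(0,1))

scroungers (rank ``i`` = 1..n2 within scroungers)::

    x_j <- Q * exp((xworst_j - x_j) / i^2)        if i > n2/2  (Q ~ N(0,1))
    x   <- xbest + mean_j(r_j * |x_j - xbest_j|)  otherwise    (r_j ~ U(-1,1))

where ``xbest`` is the best producer's position after the producer update,
and the scrounger offset is the scalar mean over dimensions.

scouts (per selected sparrow with fitness ``fi``)::

    x <- xbest + beta * (x - xbest)                       if fi != fg  (beta ~ N(0,1))
    x <- x + K * (x - xworst) / ((fi - fw) + eps)         if fi == fg  (K ~ U(-1,1))

All positions are clipped to the unit box after every update.  Random
scalar scoping: the safety threshold ``ST ~ U(0.5, 1)`` is drawn once per
run, the alarm ``R2 ~ U(0, 1)`` once per iteration, ``alpha``/``Q`` per
sparrow per iteration, ``beta``/``K`` per scout per iteration.  ``K`` is
drawn from U(-1, 1) — it encodes a movement direction — with a config
switch to restrict it to (0, 1).

The driver keeps an elite record (best-ever position and fitness), so the
reported best-fitness history is non-increasing even when the population
moves away from the optimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = [
    "SSAConfig",
    "SparrowPopulation",
    "OptimizeResult",
    "SSAEvaluationError",
    "init_population",
    "assign_roles",
    "update_producers",
    "update_scroungers",
    "update_scouts",
    "optimize",
    "random_search",
    "sphere",
]

EPS = 1e-10


@dataclass(frozen=True)
class SSAConfig:
    n: int = 10
    itermax: int = 20
    producer_ratio: float = 0.7
    scout_ratio: float = 0.2
    st_range: tuple = (0.5, 1.0)
    scout_k_positive: bool = False  # True restricts K to (0, 1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("population size n must be >= 2")
        if not (0 < self.producer_ratio <= 1):
            raise ValueError("producer_ratio must be in (0, 1]")
        if not (0 <= self.scout_ratio <= 1):
            raise ValueError("scout_ratio must be in [0, 1]")

    @property
    def n_producers(self) -> int:
        return min(math.ceil(self.producer_ratio * self.n), self.n)

    @property
    def n_scouts(self) -> int:
        return int(round(self.scout_ratio * self.n))


@dataclass
class SparrowPopulation:
    """Population state; rows of ``X`` are sorted by fitness after role assignment."""

    X: np.ndarray
    F: np.ndarray
    ST: float
    roles: Optional[np.ndarray] = None  # "producer" / "scrounger" per row
    scout_idx: Optional[np.ndarray] = None
    Xbest: Optional[np.ndarray] = None  # current-iteration best position
    Xworst: Optional[np.ndarray] = None
    fg: float = math.nan  # current-iteration best fitness
    fw: float = math.nan
    t: int = 0

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]


class SSAEvaluationError(RuntimeError):
    """Fitness function failure, annotated with iteration and sparrow index."""

    def __init__(self, iteration: int, index: int, cause: BaseException):
        self.iteration = iteration
        self.index = index
        super().__init__(f"fitness evaluation failed at iteration {iteration}, sparrow {index}: {cause!r}")
        self.__cause__ = cause


def init_population(config: SSAConfig, d: int, rng: Optional[np.random.Generator] = None) -> SparrowPopulation:
    """Uniform positions on [0,1]^d; fitness unset; ST drawn once for the run."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    X = rng.uniform(0.0, 1.0, size=(config.n, d))
    st_lo, st_hi = config.st_range
    ST = float(rng.uniform(st_lo, st_hi))
    F = np.full(config.n, np.nan)
    return SparrowPopulation(X=X, F=F, ST=ST)


def assign_roles(pop: SparrowPopulation, config: SSAConfig, rng: np.random.Generator) -> SparrowPopulation:
    """Stable-sort by fitness; best ceil(ratio*n) become producers; draw scouts.

    Scouts are a random subset of the whole population, independent of role,
    redrawn every iteration.  Also refreshes the current-iteration best/worst
    trackers.  Requires evaluated fitness.
    """
    if np.any(np.isnan(pop.F)):
        raise ValueError("fitness must be evaluated before role assignment")
    order = np.argsort(pop.F, kind="stable")  # ties keep index order
    pop.X = pop.X[order]
    pop.F = pop.F[order]
    n1 = config.n_producers
    roles = np.array(["scrounger"] * pop.n, dtype=object)
    roles[:n1] = "producer"
    pop.roles = roles
    pop.scout_idx = np.sort(rng.choice(pop.n, size=config.n_scouts, replace=False))
    pop.Xbest = pop.X[0].copy()
    pop.Xworst = pop.X[-1].copy()
    pop.fg = float(pop.F[0])
    pop.fw = float(pop.F[-1])
    return pop


def update_producers(pop: SparrowPopulation, config: SSAConfig, rng: np.random.Generator) -> np.ndarray:
    """Producer update; draws R2 once, then alpha or Q per producer in rank order."""
    n1 = config.n_producers
    R2 = float(rng.uniform(0.0, 1.0))
    for rank in range(1, n1 + 1):
        row = rank - 1
        if R2 < pop.ST:
            alpha = 1.0 - float(rng.uniform(0.0, 1.0))  # U(0, 1]
            pop.X[row] = pop.X[row] * math.exp(-rank / (alpha * config.itermax))
        else:
            Q = float(rng.standard_normal())
            pop.X[row] = pop.X[row] + Q  # Q times the all-ones vector
    np.clip(pop.X[:n1], 0.0, 1.0, out=pop.X[:n1])
    return pop.X


def update_scroungers(pop: SparrowPopulation, config: SSAConfig, rng: np.random.Generator) -> np.ndarray:
    """Scrounger update; follows the best producer position after its update."""
    n1 = config.n_producers
    n2 = pop.n - n1
    if n2 == 0:
        return pop.X
    x_best_producer = pop.X[0]  # rank-1 producer, already updated
    for rank in range(1, n2 + 1):
        row = n1 + rank - 1
        if rank > n2 / 2.0:
            Q = float(rng.standard_normal())
            pop.X[row] = Q * np.exp((pop.Xworst - pop.X[row]) / rank**2)
        else:
            r = rng.uniform(-1.0, 1.0, size=pop.d)
            offset = float(np.mean(r * np.abs(pop.X[row] - x_best_producer)))
            pop.X[row] = x_best_producer + offset
    np.clip(pop.X[n1:], 0.0, 1.0, out=pop.X[n1:])
    return pop.X


def update_scouts(pop: SparrowPopulation, config: SSAConfig, rng: np.random.Generator) -> np.ndarray:
    """Scout update for the drawn subset, in ascending row order."""
    if pop.scout_idx is None:
        raise ValueError("scout subset not drawn; call assign_roles first")
    k_lo = 0.0 if config.scout_k_positive else -1.0
    for row in pop.scout_idx:
        fi = float(pop.F[row])
        if fi != pop.fg:
            beta = float(rng.standard_normal())
            pop.X[row] = pop.Xbest + beta * (pop.X[row] - pop.Xbest)
        else:
            K = float(rng.uniform(k_lo, 1.0))
            pop.X[row] = pop.X[row] + K * (pop.X[row] - pop.Xworst) / ((fi - pop.fw) + EPS)
        np.clip(pop.X[row], 0.0, 1.0, out=pop.X[row])
    return pop.X


@dataclass
class OptimizeResult:
    best_position: np.ndarray
    best_fitness: float
    history: np.ndarray  # best-so-far fitness after each evaluation round
    n_evaluations: int
    population: SparrowPopulation = field(repr=False, default=None)


def _evaluate(pop: SparrowPopulation, fitness_fn: Callable, iteration: int) -> None:
    for i in range(pop.n):
        try:
            pop.F[i] = float(fitness_fn(pop.X[i].copy()))
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise SSAEvaluationError(iteration, i, exc) from exc


def optimize(fitness_fn: Callable, config: SSAConfig, d: int = 4) -> OptimizeResult:
    """Run SSA; returns the elite (best-ever) position and fitness.

    Exactly ``n * (itermax + 1)`` fitness evaluations are performed: one
    round at initialization and one per iteration.
    """
    rng = np.random.default_rng(config.seed)
    pop = init_population(config, d, rng)
    _evaluate(pop, fitness_fn, iteration=0)
    n_evals = pop.n

    best_row = int(np.argmin(pop.F))
    elite_x = pop.X[best_row].copy()
    elite_f = float(pop.F[best_row])
    history = [elite_f]

    for t in range(1, config.itermax + 1):
        pop.t = t
        assign_roles(pop, config, rng)
        update_producers(pop, config, rng)
        update_scroungers(pop, config, rng)
        update_scouts(pop, config, rng)
        _evaluate(pop, fitness_fn, iteration=t)
        n_evals += pop.n
        best_row = int(np.argmin(pop.F))
        if pop.F[best_row] < elite_f:
            elite_f = float(pop.F[best_row])
            elite_x = pop.X[best_row].copy()
        history.append(elite_f)

    return OptimizeResult(
        best_position=elite_x,
        best_fitness=elite_f,
        history=np.asarray(history),
        n_evaluations=n_evals,
        population=pop,
    )


def random_search(fitness_fn: Callable, n_evals: int, d: int, seed: int = 0) -> OptimizeResult:
    """Uniform random-search baseline over the unit box."""
    rng = np.random.default_rng(seed)
    X = rng.uniform(0.0, 1.0, size=(n_evals, d))
    F = np.array([float(fitness_fn(x)) for x in X])
    best = int(np.argmin(F))
    return OptimizeResult(
        best_position=X[best].copy(),
        best_fitness=float(F[best]),
        history=np.minimum.accumulate(F),
        n_evaluations=n_evals,
    )


def sphere(x: np.ndarray, center: float = 0.3) -> float:
    """Benchmark objective: sum of squared distances to an off-origin center."""
    x = np.asarray(x, dtype=float)
    return float(np.sum((x - center) ** 2))
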