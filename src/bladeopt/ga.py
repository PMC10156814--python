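"""Genetic algorithm for constrained blade-design optimisation.

Minimises an objective (typically the negated surrogate-predicted
efficiency) over the five blade parameters subject to per-parameter box
bounds and the linear ordering constraint beta2 > beta1.

Mechanics: rank-scaled stochastic-universal-sampling selection (scaled
value 1/sqrt(rank)), elitism, intermediate crossover on a fraction of the
non-elite offspring, and per-coordinate Gaussian mutation whose standard
deviation starts at ``scale`` x (box width) and shrinks linearly over the
generation budget. Every candidate is repaired before evaluation: clipped
into the box, then beta2 lifted just above beta1 when the ordering is
violated - so the objective is only ever evaluated on feasible designs.

Convergence: the run stops when the relative change between the current
generation's best objective value and the best from ``stall_generations``
ago is at most ``convergence_tol`` (or at ``max_generations``). Elitism
makes the best-so-far history non-increasing.

Objectives are evaluated on whole populations: a callable receiving an
(n, 5) array and returning (n,) values. Use :func:`vectorize_objective`
to adapt a scalar function.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np

from .geometry import PARAM_NAMES, BladeDesign, ConstraintBox, FeasibilityReport, validate_design

__all__ = [
    "GAConfig",
    "GAResult",
    "RepeatabilityReport",
    "optimize",
    "repeatability_study",
    "vectorize_objective",
]

#: minimum margin by which a repaired beta2 exceeds beta1, degrees
_BETA_REPAIR_DELTA = 1e-3


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings.

    Mutation ``scale`` and ``shrink`` are relative to the box width per
    coordinate: sigma(gen) = scale * width * (1 - shrink * gen/max_generations).
    """

    population_size: int = 50
    crossover_fraction: float = 0.8
    mutation_scale: float = 1.0
    mutation_shrink: float = 1.0
    elite_count: int = 3
    convergence_tol: float = 1e-6
    stall_generations: int = 50
    max_generations: int = 500
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.crossover_fraction <= 1.0):
            raise ValueError("crossover fraction must be in [0, 1]")
        if not (0 <= self.elite_count < self.population_size):
            raise ValueError("elite count must be smaller than the population")
        if self.convergence_tol <= 0:
            raise ValueError("convergence tolerance must be positive")
        if self.stall_generations < 1 or self.max_generations < 1:
            raise ValueError("generation counts must be positive")


@dataclass(frozen=True)
class GAResult:
    best_design: BladeDesign
    best_x: np.ndarray
    best_fitness: float
    generations_run: int
    history: np.ndarray  # best fitness per generation (non-increasing)
    feasibility: FeasibilityReport
    seed: int

    def history_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"generation": np.arange(len(self.history)), "best_fitness": self.history}
        )


def vectorize_objective(f: Callable[[Sequence[float]], float]):
    """Adapt a scalar objective f(x) -> real to the population interface."""

    def batched(x: np.ndarray) -> np.ndarray:
        return np.array([float(f(row)) for row in np.atleast_2d(x)])

    return batched


def _repair(pop: np.ndarray, lower: np.ndarray, upper: np.ndarray) -> np.ndarray:
    """Project candidates into the feasible set (box and beta2 > beta1)."""
    pop = np.clip(pop, lower, upper)
    bad = pop[:, 1] <= pop[:, 0]
    if np.any(bad):
        pop[bad, 1] = np.minimum(upper[1], pop[bad, 0] + _BETA_REPAIR_DELTA)
    return pop


def _sus_select(rng: np.random.Generator, order: np.ndarray, n_draws: int) -> np.ndarray:
    """Stochastic universal sampling with 1/sqrt(rank) scaling.

    ``order`` is the index array sorting the population by fitness
    (best first); returns population indices of the selected parents.
    """
    n = len(order)
    scaled = 1.0 / np.sqrt(np.arange(1, n + 1))
    cum = np.cumsum(scaled)
    total = cum[-1]
    pointers = (rng.random() + np.arange(n_draws)) * total / n_draws
    picks = np.searchsorted(cum, pointers)
    parents = order[picks]
    rng.shuffle(parents)
    return parents


def optimize(
    objective: Callable[[np.ndarray], np.ndarray],
    box: ConstraintBox,
    config: GAConfig = GAConfig(),
) -> GAResult:
    """Run the GA and return the feasible incumbent."""
    lower, upper = box.lower(), box.upper()
    if upper[1] <= lower[0]:
        raise ValueError("infeasible box: no point can satisfy beta2 > beta1")
    rng = np.random.default_rng(config.seed)
    n = config.population_size
    width = upper - lower

    pop = _repair(lower + rng.random((n, 5)) * width, lower, upper)
    history: List[float] = []
    best_x: Optional[np.ndarray] = None
    best_f = np.inf

    gen = 0
    for gen in range(1, config.max_generations + 1):
        fitness = np.asarray(objective(pop), dtype=float)
        order = np.argsort(fitness, kind="stable")
        if fitness[order[0]] < best_f:
            best_f = float(fitness[order[0]])
            best_x = pop[order[0]].copy()
        history.append(best_f)

        # convergence: relative best-fitness change over the stall window
        if gen > config.stall_generations:
            f_then = history[-1 - config.stall_generations]
            rel = abs(best_f - f_then) / max(abs(best_f), 1e-12)
            if rel <= config.convergence_tol:
                break
        if gen == config.max_generations:
            break

        elites = pop[order[: config.elite_count]].copy()
        n_children = n - config.elite_count
        n_xover = int(round(config.crossover_fraction * n_children))
        n_mut = n_children - n_xover

        parents = pop[_sus_select(rng, order, 2 * n_xover + n_mut)]
        children = np.empty((n_children, 5))
        if n_xover > 0:
            p1 = parents[:n_xover]
            p2 = parents[n_xover : 2 * n_xover]
            u = rng.random((n_xover, 5))
            children[:n_xover] = p1 + u * (p2 - p1)
        if n_mut > 0:
            frac = 1.0 - config.mutation_shrink * gen / config.max_generations
            sigma = config.mutation_scale * width * max(frac, 0.0)
            base = parents[2 * n_xover :]
            children[n_xover:] = base + rng.normal(0.0, 1.0, (n_mut, 5)) * sigma
        pop = np.vstack([elites, _repair(children, lower, upper)])

    best_design = BladeDesign.from_vector(best_x, design_id="ga_optimum")
    return GAResult(
        best_design=best_design,
        best_x=best_x,
        best_fitness=best_f,
        generations_run=gen,
        history=np.array(history),
        feasibility=validate_design(best_design, box),
        seed=config.seed,
    )


@dataclass(frozen=True)
class RepeatabilityReport:
    """Spread of GA solutions over independently seeded repeats."""

    per_param_spread_pct: Dict[str, float]
    max_spread_pct: float
    threshold_pct: float
    passed: bool
    fitness_values: np.ndarray
    solutions: np.ndarray  # (n_repeats, 5)
    generations: np.ndarray
    seeds: Sequence[int]
    note: str = ""

    @property
    def best_index(self) -> int:
        return int(np.argmin(self.fitness_values))


def repeatability_study(
    objective: Callable[[np.ndarray], np.ndarray],
    box: ConstraintBox,
    config: GAConfig = GAConfig(),
    n_repeats: int = 5,
    seeds: Optional[Sequence[int]] = None,
    threshold_pct: float = 1.0,
) -> RepeatabilityReport:
    """Run the GA ``n_repeats`` times with distinct seeds and report spread.

    The per-parameter spread is 100 * (max - min) / max over the repeated
    solutions; the report passes when the largest spread is at or below
    ``threshold_pct``. A large parameter spread combined with essentially
    identical objective values is flagged as non-identifiability (a flat
    objective) rather than treated as an optimiser failure alone.
    """
    if n_repeats < 2:
        raise ValueError("need at least two repeats")
    if seeds is None:
        seeds = [config.seed + i for i in range(n_repeats)]
    if len(seeds) != n_repeats:
        raise ValueError("one seed per repeat required")
    sols, fits, gens = [], [], []
    for s in seeds:
        cfg = GAConfig(**{**config.__dict__, "seed": int(s)})
        res = optimize(objective, box, cfg)
        sols.append(res.best_x)
        fits.append(res.best_fitness)
        gens.append(res.generations_run)
    sols = np.array(sols)
    fits = np.array(fits)
    spread = 100.0 * (sols.max(axis=0) - sols.min(axis=0)) / sols.max(axis=0)
    per_param = dict(zip(PARAM_NAMES, (float(s) for s in spread)))
    max_spread = float(spread.max())
    note = ""
    if max_spread > threshold_pct:
        f_rel = (fits.max() - fits.min()) / max(abs(fits.mean()), 1e-12)
        if f_rel < 1e-6:
            note = (
                "non-identifiable: objective values agree across repeats but "
                "solutions differ (flat objective)"
            )
    return RepeatabilityReport(
        per_param_spread_pct=per_param,
        max_spread_pct=max_spread,
        threshold_pct=threshold_pct,
        passed=max_spread <= threshold_pct,
        fitness_values=fits,
        solutions=sols,
        generations=np.array(gens),
        seeds=list(seeds),
        note=note,
    )
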