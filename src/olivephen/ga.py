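"""Seeded real-valued genetic algorithm for bounded minimisation.

A deliberately small, dependency-free GA: tournament selection, blend (BLX)
crossover, Gaussian mutation with a geometric scale decay, elitism, bound
clipping, and early stopping on a stagnant best fitness.  Given the same
seed it is bit-for-bit reproducible.  The calibration objectives in this
package (day-scale RMSE surfaces) are piecewise constant with broad
plateaus, which is exactly the regime where a population method with
elitism is a safe default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import BoundsError, OptimizerError

__all__ = ["GAConfig", "GAResult", "ga_minimize"]


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings.

    population_size : individuals per generation (>= 4).
    max_generations : hard iteration cap.
    crossover_prob, mutation_prob : per-pair / per-gene probabilities in [0, 1].
    n_elites : best individuals copied unchanged into the next generation.
    patience : stop after this many generations without improvement.
    mutation_scale : initial mutation s.d. as a fraction of each bound width.
    mutation_decay : geometric per-generation decay of the mutation s.d.
                     (floored at 1e-4 of the bound width) so late generations
                     refine rather than jump.
    seed : mandatory RNG seed (reproducibility is part of the contract).
    """

    population_size: int = 50
    max_generations: int = 1000
    crossover_prob: float = 0.8
    mutation_prob: float = 0.1
    n_elites: int = 2
    patience: int = 100
    tournament_size: int = 3
    blend_alpha: float = 0.5
    mutation_scale: float = 0.1
    mutation_decay: float = 0.99
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 4:
            raise BoundsError("population_size must be >= 4")
        for name in ("crossover_prob", "mutation_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise BoundsError(f"{name} must lie in [0, 1], got {p}")
        if self.n_elites >= self.population_size:
            raise BoundsError("n_elites must be smaller than the population")


@dataclass
class GAResult:
    """Best point found, its objective value, and the per-generation trace."""

    x: np.ndarray
    fun: float
    trace: np.ndarray = field(repr=False)  # running best objective per generation
    n_generations: int = 0
    seed: int = 0


def _evaluate(
    objective: Callable[[np.ndarray], float], pop: np.ndarray
) -> np.ndarray:
    values = np.empty(len(pop))
    for i, x in enumerate(pop):
        v = float(objective(x))
        if not np.isfinite(v):
            raise OptimizerError(f"objective returned {v} at x={x.tolist()}")
        values[i] = v
    return values


def ga_minimize(
    objective: Callable[[np.ndarray], float],
    bounds: Sequence[tuple[float, float]],
    config: GAConfig | None = None,
) -> GAResult:
    """Minimise a bounded real objective with a seeded genetic algorithm.

    Equivalent to maximising -objective.  The returned best point always
    respects the bounds, and the fitness trace is non-worsening by
    construction (elitism).
    """
    config = config or GAConfig()
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    if np.any(lo >= hi):
        bad = int(np.argmax(lo >= hi))
        raise BoundsError(f"bounds[{bad}] must satisfy lower < upper: ({lo[bad]}, {hi[bad]})")
    width = hi - lo
    rng = np.random.default_rng(config.seed)
    n, d = config.population_size, len(bounds)

    pop = lo + rng.random((n, d)) * width
    values = _evaluate(objective, pop)
    order = np.argsort(values, kind="stable")
    best_x, best_f = pop[order[0]].copy(), float(values[order[0]])
    trace = [best_f]
    stagnant = 0
    sd = config.mutation_scale * width
    sd_floor = 1e-4 * width
    gen = 0

    for gen in range(1, config.max_generations + 1):
        elites = pop[order[: config.n_elites]].copy()
        children = np.empty_like(pop)
        children[: config.n_elites] = elites

        # Tournament selection for the remaining slots.
        n_rest = n - config.n_elites
        draws = rng.integers(0, n, size=(n_rest, config.tournament_size))
        winners = draws[np.arange(n_rest), np.argmin(values[draws], axis=1)]
        parents = pop[winners]

        # BLX-alpha crossover between consecutive parent pairs.
        partners = parents[rng.permutation(n_rest)]
        do_cx = rng.random(n_rest) < config.crossover_prob
        span = np.abs(parents - partners)
        low = np.minimum(parents, partners) - config.blend_alpha * span
        high = np.maximum(parents, partners) + config.blend_alpha * span
        blended = low + rng.random((n_rest, d)) * (high - low)
        offspring = np.where(do_cx[:, None], blended, parents)

        # Per-gene Gaussian mutation with decaying scale.
        mutate = rng.random((n_rest, d)) < config.mutation_prob
        noise = rng.normal(0.0, 1.0, size=(n_rest, d)) * sd
        offspring = np.where(mutate, offspring + noise, offspring)
        children[config.n_elites:] = np.clip(offspring, lo, hi)

        pop = children
        values = _evaluate(objective, pop)
        order = np.argsort(values, kind="stable")
        if values[order[0]] < best_f:
            best_x, best_f = pop[order[0]].copy(), float(values[order[0]])
            stagnant = 0
        else:
            stagnant += 1
        trace.append(best_f)
        sd = np.maximum(sd * config.mutation_decay, sd_floor)
        if stagnant >= config.patience:
            break

    return GAResult(
        x=best_x, fun=best_f, trace=np.array(trace), n_generations=gen,
        seed=config.seed,
    )
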