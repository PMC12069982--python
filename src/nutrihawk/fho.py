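"""Fire Hawk Optimizer: a population metaheuristic over box constraints.

The metaphor: a few elite candidates ("fire hawks") spread fire to herd the
remaining candidates ("prey"). Each iteration the population is split into
hawks (the best few, count drawn via a Gaussian-modulated fraction) and
prey; each hawk claims a territory of nearby prey. Hawks move towards the
global best while repelling from a peer:

    Fh_new = Fh + r1 * GB - r2 * Fh_near

and each prey moves either relative to its own hawk and the territory's
"safe place" (the mean prey position inside the territory) or relative to a
foreign hawk and the global safe place (the mean over all prey):

    Pr_new = Pr + r3 * Fh_own   - r4 * Sa_territory
    Pr_new = Pr + r5 * Fh_other - r6 * Sa_global

with a fair coin deciding which. Moves are clamped to the box; the best
position ever evaluated is archived (elitism), so the convergence history
is monotone non-increasing. All randomness flows from one seeded generator,
making runs bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = ["SearchSpace", "FHOConfig", "FHOResult", "FireHawkOptimizer", "minimize"]


@dataclass(frozen=True)
class SearchSpace:
    """Axis-aligned box of feasible positions."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        if lo.shape != hi.shape or lo.ndim != 1:
            raise ValueError("bounds must be 1-D vectors of equal length")
        if not np.all(hi > lo):
            raise ValueError("upper bounds must exceed lower bounds element-wise")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)

    @property
    def dimension(self) -> int:
        return self.lower.shape[0]

    def clamp(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)


@dataclass(frozen=True)
class FHOConfig:
    pop_size: int = 50
    max_iters: int = 300
    hawk_count_cap: float = 0.05  # max hawk fraction; few elite hawks exploit best
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 4:
            raise ValueError("pop_size must be >= 4")
        if self.max_iters < 1:
            raise ValueError("max_iters must be positive")
        if not 0.0 < self.hawk_count_cap <= 0.5:
            raise ValueError("hawk_count_cap must lie in (0, 0.5]")


@dataclass
class FHOResult:
    best_position: np.ndarray
    best_fitness: float
    history: np.ndarray  # best fitness after each iteration, monotone


def initialize_population(space: SearchSpace, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform positions inside the box, one row per candidate."""
    if n < 4:
        raise ValueError("population size must be >= 4")
    r = rng.random((n, space.dimension))
    return space.lower + r * (space.upper - space.lower)


def select_hawks(fitness: np.ndarray, cap: float, rng: np.random.Generator):
    """Split the population into hawk and prey index sets.

    The hawk count follows a Gaussian-modulated fraction of the population:
    s = clamp(round(|g| * n * cap), 1, n // 2) with g ~ N(0, 1); the s
    lowest-fitness candidates become hawks.
    """
    if np.any(~np.isfinite(fitness)):
        raise ValueError("all fitness values must be evaluated and finite")
    n = fitness.shape[0]
    g = rng.standard_normal()
    s = int(np.clip(round(abs(g) * n * cap), 1, n // 2))
    order = np.argsort(fitness, kind="stable")
    return order[:s], order[s:]


def assign_territories(
    hawk_idx: np.ndarray,
    prey_idx: np.ndarray,
    positions: np.ndarray,
    fitness: np.ndarray,
) -> dict[int, list[int]]:
    """Give each hawk a balanced territory of its nearest unclaimed prey.

    Hawks claim in ascending fitness order (the best hawk picks first); each
    takes its ceil(q/s) nearest remaining prey by Euclidean distance, ties
    broken by lower prey index.
    """
    territories: dict[int, list[int]] = {int(h): [] for h in hawk_idx}
    if prey_idx.size == 0:
        return territories
    quota = math.ceil(prey_idx.size / hawk_idx.size)
    unclaimed = list(prey_idx)
    for h in sorted(hawk_idx, key=lambda i: (fitness[i], i)):
        if not unclaimed:
            break
        d = np.linalg.norm(positions[unclaimed] - positions[h], axis=1)
        take = np.argsort(d, kind="stable")[:quota]
        claimed = [unclaimed[t] for t in sorted(take)]
        territories[int(h)] = claimed
        unclaimed = [u for u in unclaimed if u not in set(map(int, claimed))]
    return territories


def update_hawk(
    hawk: np.ndarray,
    global_best: np.ndarray,
    other_hawk: np.ndarray,
    rng: np.random.Generator,
    space: SearchSpace,
) -> np.ndarray:
    """Move a hawk towards the global best, away from a peer (clamped)."""
    rand1, rand2 = rng.random(2)
    return space.clamp(hawk + rand1 * global_best - rand2 * other_hawk)


def safe_place_within(prey_positions: np.ndarray, hawk_position: np.ndarray) -> np.ndarray:
    """Mean prey position of one territory; the hawk itself if empty."""
    if prey_positions.shape[0] == 0:
        return hawk_position.copy()
    return prey_positions.mean(axis=0)


def safe_place_global(all_prey_positions: np.ndarray, fallback: np.ndarray) -> np.ndarray:
    """Mean over all prey; the archived best position if there is no prey."""
    if all_prey_positions.shape[0] == 0:
        return fallback.copy()
    return all_prey_positions.mean(axis=0)


def update_prey(
    prey: np.ndarray,
    owner_hawk: np.ndarray,
    other_hawk: np.ndarray,
    safe_within: np.ndarray,
    safe_global: np.ndarray,
    rng: np.random.Generator,
    space: SearchSpace,
) -> np.ndarray:
    """One prey move: within-territory or outside, on a fair coin (clamped)."""
    if rng.random() < 0.5:
        rand3, rand4 = rng.random(2)
        new = prey + rand3 * owner_hawk - rand4 * safe_within
    else:
        rand5, rand6 = rng.random(2)
        new = prey + rand5 * other_hawk - rand6 * safe_global
    return space.clamp(new)


class FireHawkOptimizer:
    """Seeded minimizer of a scalar objective over a box."""

    def __init__(self, space: SearchSpace, config: FHOConfig | None = None):
        self.space = space
        self.config = config or FHOConfig()

    def _evaluate(self, objective, positions: np.ndarray) -> np.ndarray:
        fit = np.array([float(objective(p)) for p in positions])
        if np.any(~np.isfinite(fit)):
            bad = positions[np.flatnonzero(~np.isfinite(fit))[0]]
            raise FloatingPointError(f"objective returned non-finite value at {bad}")
        return fit

    def minimize(self, objective: Callable[[np.ndarray], float]) -> FHOResult:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        positions = initialize_population(self.space, cfg.pop_size, rng)
        fitness = self._evaluate(objective, positions)

        best_i = int(np.argmin(fitness))
        gb_pos = positions[best_i].copy()
        gb_fit = float(fitness[best_i])
        history = np.empty(cfg.max_iters)

        for it in range(cfg.max_iters):
            hawk_idx, prey_idx = select_hawks(fitness, cfg.hawk_count_cap, rng)
            territories = assign_territories(hawk_idx, prey_idx, positions, fitness)
            new_positions = positions.copy()

            hawk_list = list(hawk_idx)
            for h in hawk_list:
                if len(hawk_list) > 1:
                    other = hawk_list[int(rng.integers(len(hawk_list) - 1))]
                    if other == h:
                        other = hawk_list[-1]
                else:
                    other = h
                new_positions[h] = update_hawk(
                    positions[h], gb_pos, positions[other], rng, self.space
                )

            sa_glob = safe_place_global(positions[prey_idx], gb_pos)
            for h in hawk_list:
                members = territories[int(h)]
                sa_within = safe_place_within(positions[members], positions[h])
                for p in members:
                    if len(hawk_list) > 1:
                        other = hawk_list[int(rng.integers(len(hawk_list) - 1))]
                        if other == h:
                            other = hawk_list[-1]
                    else:
                        other = h
                    new_positions[p] = update_prey(
                        positions[p], new_positions[h], positions[other],
                        sa_within, sa_glob, rng, self.space,
                    )

            positions = new_positions
            fitness = self._evaluate(objective, positions)
            i = int(np.argmin(fitness))
            if fitness[i] < gb_fit:
                gb_fit = float(fitness[i])
                gb_pos = positions[i].copy()
            history[it] = gb_fit

        return FHOResult(gb_pos, gb_fit, history)


def minimize(
    objective: Callable[[np.ndarray], float],
    space: SearchSpace,
    config: FHOConfig | None = None,
) -> FHOResult:
    """Functional front door: minimize ``objective`` over ``space``."""
    return FireHawkOptimizer(space, config).minimize(objective)
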