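"""Marine Predators Algorithm: a bound-constrained population minimizer.

MPA evolves an n-by-d matrix of prey positions toward low objective values,
guided by an elite (the best-so-far "top predator").  The run is split into
three velocity-ratio phases over the iteration budget:

* phase 1 (first third, exploration): prey move by Brownian (standard normal)
  steps relative to the elite;
* phase 2 (middle third): the first half of the population takes Levy-flight
  steps (exploration) while the second half contracts toward the elite by
  Brownian steps scaled by the adaptive coefficient CF;
* phase 3 (final third, exploitation): all prey take Levy steps around the
  elite, scaled by CF.

After every phase update a FADs (fish-aggregating-devices) perturbation either
makes a rare long jump inside the bounds or recombines pairs of prey, which
prevents stagnation.  CF = (1 - it/T)^(2 it/T) decays from 1 to 0 over the run.
Positions are clamped to the box bounds after every step, and a greedy
"marine memory" rule keeps a prey's previous position when the new one is
worse (configurable, default on, matching the algorithm's published form).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable

import numpy as np

Objective = Callable[[np.ndarray], float]


@dataclass
class MPAConfig:
    """Run settings for the optimizer.

    ``P`` (step constant) and ``fads`` (perturbation probability) are the
    algorithm's published constants; ``levy_alpha`` is the stability exponent
    of the Levy-flight sampler and ``levy_scale`` the conventional 0.05 factor
    applied to Levy steps inside the phase updates.
    """

    d: int
    x_min: np.ndarray | float
    x_max: np.ndarray | float
    n: int = 100
    max_iter: int = 200
    P: float = 0.5
    fads: float = 0.2
    levy_alpha: float = 1.5
    levy_scale: float = 0.05
    memory_saving: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        self.x_min = np.broadcast_to(np.asarray(self.x_min, dtype=float), (self.d,)).copy()
        self.x_max = np.broadcast_to(np.asarray(self.x_max, dtype=float), (self.d,)).copy()
        if self.d < 1:
            raise ValueError("dimension must be >= 1")
        if not np.all(self.x_min < self.x_max):
            raise ValueError("require x_min < x_max componentwise")
        if self.n < 2:
            raise ValueError("population size must be >= 2")
        if self.max_iter < 3:
            raise ValueError("max_iter must be >= 3 so every phase is non-empty")
        if not 0.0 <= self.fads <= 1.0:
            raise ValueError("fads probability must lie in [0, 1]")
        if not 0.0 < self.levy_alpha <= 2.0:
            raise ValueError("levy_alpha must lie in (0, 2]")


@dataclass
class PreyPopulation:
    """Candidate positions with their objective values."""

    positions: np.ndarray  # (n, d)
    costs: np.ndarray      # (n,)
    iteration: int = 0


@dataclass
class EliteMatrix:
    """Best-so-far predator; conceptually replicated n times to guide every prey."""

    top_predator: np.ndarray
    top_cost: float


@dataclass
class OptimizeResult:
    best_position: np.ndarray
    best_cost: float
    history: list[float]


# ---------------------------------------------------------------------------
# primitive draws
# ---------------------------------------------------------------------------

def brownian_step(shape: tuple[int, ...], rng: np.random.Generator) -> np.ndarray:
    """i.i.d. standard-normal increments (Brownian motion steps)."""
    return rng.standard_normal(shape)


def levy_step(shape: tuple[int, ...], alpha: float, rng: np.random.Generator) -> np.ndarray:
    """Heavy-tailed stable-law samples via Mantegna's construction.

    Draws u ~ N(0, sigma_u^2) and v ~ N(0, 1) and returns u / |v|^(1/alpha),
    whose tail exceedance P(|X| > t) decays like t^(-alpha).  At alpha = 2 the
    law degenerates to the Gaussian family.
    """
    if not 0.0 < alpha <= 2.0:
        raise ValueError(f"alpha must lie in (0, 2], got {alpha}")
    sigma_u = (
        math.gamma(1 + alpha) * math.sin(math.pi * alpha / 2)
        / (math.gamma((1 + alpha) / 2) * alpha * 2 ** ((alpha - 1) / 2))
    ) ** (1 / alpha)
    u = rng.standard_normal(shape) * sigma_u
    v = rng.standard_normal(shape)
    return u / np.abs(v) ** (1 / alpha)


def compute_cf(iteration: int, max_iter: int) -> float:
    """Adaptive step coefficient (1 - it/T)^(2 it/T); 1 at it=0, 0 at it=T."""
    if not 0 <= iteration <= max_iter:
        raise ValueError(f"iteration {iteration} outside [0, {max_iter}]")
    frac = iteration / max_iter
    if frac == 1.0:
        return 0.0
    return float((1.0 - frac) ** (2.0 * frac))


# ---------------------------------------------------------------------------
# population mechanics
# ---------------------------------------------------------------------------

def _evaluate(objective: Objective, positions: np.ndarray) -> np.ndarray:
    costs = np.empty(positions.shape[0])
    for i, x in enumerate(positions):
        c = float(objective(x))
        if not np.isfinite(c):
            raise ValueError(f"objective returned non-finite value {c} at position {x}")
        costs[i] = c
    return costs


def _clamp(positions: np.ndarray, cfg: MPAConfig) -> np.ndarray:
    return np.clip(positions, cfg.x_min, cfg.x_max)


def init_population(cfg: MPAConfig, objective: Objective,
                    rng: np.random.Generator) -> PreyPopulation:
    """Uniform positions X = X_min + rand(0,1) * (X_max - X_min), costs evaluated."""
    positions = cfg.x_min + rng.random((cfg.n, cfg.d)) * (cfg.x_max - cfg.x_min)
    return PreyPopulation(positions=positions, costs=_evaluate(objective, positions))


def _split_point(n: int) -> int:
    # first ceil(n/2) prey explore in phase 2, the rest exploit
    return (n + 1) // 2


def phase1_update(pop: PreyPopulation, elite: EliteMatrix, cfg: MPAConfig,
                  rng: np.random.Generator) -> PreyPopulation:
    """High-velocity phase: Step = R_B*(Elite - R_B*Prey); Prey += P*R*Step.

    RNG draw order: R_B as one (n, d) standard-normal block, then R as one
    (n, d) uniform block.  The same R_B entry multiplies both occurrences in
    the step expression.
    """
    n, d = pop.positions.shape
    rb = brownian_step((n, d), rng)
    r = rng.random((n, d))
    step = rb * (elite.top_predator - rb * pop.positions)
    positions = _clamp(pop.positions + cfg.P * r * step, cfg)
    return replace(pop, positions=positions)


def phase2_update(pop: PreyPopulation, elite: EliteMatrix, cfg: MPAConfig,
                  rng: np.random.Generator, cf: float) -> PreyPopulation:
    """Unit-velocity phase: Levy exploration for the first half of the prey,
    CF-scaled Brownian contraction onto the elite for the second half.

    RNG draw order: R_L (n1, d) Levy block, R (n1, d) uniform block, then
    R_B (n-n1, d) normal block.
    """
    n, d = pop.positions.shape
    n1 = _split_point(n)
    rl = cfg.levy_scale * levy_step((n1, d), cfg.levy_alpha, rng)
    r = rng.random((n1, d))
    rb = brownian_step((n - n1, d), rng)
    positions = pop.positions.copy()
    step1 = rl * (elite.top_predator - rl * positions[:n1])
    positions[:n1] = positions[:n1] + cfg.P * r * step1
    step2 = rb * (rb * elite.top_predator - positions[n1:])
    positions[n1:] = elite.top_predator + cfg.P * cf * step2
    return replace(pop, positions=_clamp(positions, cfg))


def phase3_update(pop: PreyPopulation, elite: EliteMatrix, cfg: MPAConfig,
                  rng: np.random.Generator, cf: float) -> PreyPopulation:
    """Low-velocity phase: Step = R_L*(R_L*Elite - Prey); Prey = Elite + P*CF*Step."""
    n, d = pop.positions.shape
    rl = cfg.levy_scale * levy_step((n, d), cfg.levy_alpha, rng)
    step = rl * (rl * elite.top_predator - pop.positions)
    positions = _clamp(elite.top_predator + cfg.P * cf * step, cfg)
    return replace(pop, positions=positions)


def fads_effect(pop: PreyPopulation, cfg: MPAConfig, cf: float,
                rng: np.random.Generator) -> PreyPopulation:
    """FADs perturbation applied after each phase update.

    With probability ``fads`` every prey takes a CF-scaled jump toward a random
    point in the box, gated per-entry by a binary mask U; otherwise prey are
    recombined along random pairwise differences.  RNG draw order: scalar r;
    branch one draws U (n, d) then R (n, d); branch two draws two index
    permutations.
    """
    n, d = pop.positions.shape
    if n < 3:
        raise ValueError("FADs recombination needs a population of size >= 3")
    r = rng.random()
    positions = pop.positions.copy()
    if r <= cfg.fads:
        u = rng.random((n, d)) < cfg.fads
        rand_box = cfg.x_min + rng.random((n, d)) * (cfg.x_max - cfg.x_min)
        positions = positions + cf * rand_box * u
    else:
        r1 = rng.permutation(n)
        r2 = rng.permutation(n)
        positions = positions + (cfg.fads * (1 - r) + r) * (positions[r1] - positions[r2])
    return replace(pop, positions=_clamp(positions, cfg))


def _update_elite(elite: EliteMatrix | None, pop: PreyPopulation) -> EliteMatrix:
    i = int(np.argmin(pop.costs))  # lowest index wins ties
    if elite is None or pop.costs[i] < elite.top_cost:
        return EliteMatrix(top_predator=pop.positions[i].copy(),
                           top_cost=float(pop.costs[i]))
    return elite


def phase_for_iteration(iteration: int, max_iter: int) -> int:
    """Phase dispatch: 1 below T/3, 2 below 2T/3, 3 otherwise (floor bounds)."""
    if iteration < max_iter // 3:
        return 1
    if iteration < (2 * max_iter) // 3:
        return 2
    return 3


def optimize(objective: Objective, cfg: MPAConfig,
             rng: np.random.Generator | None = None) -> OptimizeResult:
    """Full MPA loop: init, then per iteration phase update -> FADs ->
    re-evaluate -> (greedy memory) -> elite update.

    ``history`` records the best-so-far cost after each iteration and is
    monotone non-increasing; ``best_cost`` equals the objective at
    ``best_position`` exactly.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    pop = init_population(cfg, objective, rng)
    elite = _update_elite(None, pop)
    history: list[float] = []
    for it in range(cfg.max_iter):
        cf = compute_cf(it, cfg.max_iter)
        prev_pos = pop.positions.copy()
        prev_costs = pop.costs.copy()
        phase = phase_for_iteration(it, cfg.max_iter)
        if phase == 1:
            pop = phase1_update(pop, elite, cfg, rng)
        elif phase == 2:
            pop = phase2_update(pop, elite, cfg, rng, cf)
        else:
            pop = phase3_update(pop, elite, cfg, rng, cf)
        pop = fads_effect(pop, cfg, cf, rng)
        pop.costs = _evaluate(objective, pop.positions)
        if cfg.memory_saving:
            worse = pop.costs > prev_costs
            pop.positions[worse] = prev_pos[worse]
            pop.costs[worse] = prev_costs[worse]
        elite = _update_elite(elite, pop)
        pop.iteration = it + 1
        history.append(elite.top_cost)
    return OptimizeResult(best_position=elite.top_predator.copy(),
                          best_cost=elite.top_cost, history=history)


# ---------------------------------------------------------------------------
# benchmark objectives
# ---------------------------------------------------------------------------

def sphere(x: np.ndarray) -> float:
    """f(x) = sum(x^2); global minimum 0 at the origin."""
    return float(np.sum(np.asarray(x) ** 2))


def rastrigin(x: np.ndarray) -> float:
    """Multimodal benchmark; global minimum 0 at the origin."""
    x = np.asarray(x, dtype=float)
    return float(10 * x.size + np.sum(x ** 2 - 10 * np.cos(2 * np.pi * x)))


def abs1d(x: np.ndarray) -> float:
    """|x - 0.3| on the unit interval; unique minimum at 0.3."""
    return float(np.abs(np.asarray(x)[0] - 0.3))


BENCHMARKS: dict[str, Objective] = {"sphere": sphere, "rastrigin": rastrigin, "abs1d": abs1d}
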