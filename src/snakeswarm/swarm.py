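"""Bound-constrained minimization by the Snake Optimizer (SO), Particle Swarm
Optimization (PSO), and the hybrid Particle Snake Swarm Optimizer (PSSO).

The snake optimizer maintains a population split into male and female
subgroups whose movement mode is gated by two environment signals computed
from the iteration counter: food quantity ``Q = K1*exp((C-T)/T)`` and
temperature ``Temp = exp(-C/T)``.  When food is scarce (``Q`` below a
threshold) snakes explore around random same-sex peers; when food is
plentiful and the environment hot they converge on the best-ever position
(the "food"); otherwise they fight or mate, with occasional replacement of
the worst individuals by fresh random positions ("egg hatching").

PSO moves each particle by an inertial velocity plus cognitive (personal
best) and social (global best) attraction.  The hybrid PSSO adds a
snake-derived environmental displacement ``dSO`` to the PSO velocity:
the food-attraction form ``K3*Temp*R*(L_food - X)`` when food is plentiful,
and a fight-style attraction toward the best individual of the opposite sex
otherwise.

All three algorithms are elitist (the best-ever solution is never lost),
strictly box-feasible after every iteration, and bit-reproducible for a
fixed seed: each stochastic component (initialization, signs, mode gates,
snake moves, particle moves) draws from its own named substream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from ._rng import substream

__all__ = [
    "BoundsSpec",
    "OptimizerConfig",
    "Candidate",
    "SwarmState",
    "OptimizationResult",
    "environment",
    "behavior_coefficient",
    "init_population",
    "so_move",
    "pso_update",
    "psso_update",
    "optimize",
    "ALGORITHMS",
]

Objective = Callable[[np.ndarray], float]

ALGORITHMS = ("so", "pso", "psso")


@dataclass(frozen=True)
class BoundsSpec:
    """Axis-aligned box constraining every candidate position."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lo = np.atleast_1d(np.asarray(self.lower, dtype=float))
        hi = np.atleast_1d(np.asarray(self.upper, dtype=float))
        if lo.shape != hi.shape or lo.ndim != 1:
            raise ValueError("lower and upper must be 1-D arrays of equal length")
        if lo.size < 1:
            raise ValueError("dim must be >= 1")
        if not np.all(lo < hi):
            raise ValueError("lower[j] < upper[j] required for every dimension")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)

    @property
    def dim(self) -> int:
        return self.lower.size

    @property
    def span(self) -> np.ndarray:
        return self.upper - self.lower

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)

    @classmethod
    def cube(cls, lower: float, upper: float, dim: int) -> "BoundsSpec":
        return cls(np.full(dim, float(lower)), np.full(dim, float(upper)))


@dataclass(frozen=True)
class OptimizerConfig:
    """Swarm constants and thresholds.

    Defaults: population 10, 50 iterations, box [1, 100] used elsewhere;
    snake constants K1=0.5, K2=0.05, K3=2 with food threshold 0.25 and
    temperature threshold 0.6; PSO inertia 0.5, cognitive 0.8, social 0.9.

    ``so_weight`` scales the hybrid's snake displacement term; at 0 the
    hybrid update reduces exactly to plain PSO.
    """

    n_pop: int = 10
    n_iter: int = 50
    k1: float = 0.5
    k2: float = 0.05
    k3: float = 2.0
    q_threshold: float = 0.25
    temp_threshold: float = 0.6
    inertia: float = 0.5
    cognitive: float = 0.8
    social: float = 0.9
    v_max_fraction: float = 0.1
    sign_prob: float = 0.5
    hatch_prob: float = 0.5
    mode_split: float = 0.6
    so_weight: float = 1.0
    eps_fitness: float = 1e-9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pop < 4:
            raise ValueError("population must have at least 4 members")
        if self.n_iter < 1:
            raise ValueError("invalid-config: need at least one iteration")
        if not (0.0 < self.q_threshold < 1.0 and 0.0 < self.temp_threshold < 1.0):
            raise ValueError("thresholds must lie strictly inside (0, 1)")
        if not (0.0 <= self.sign_prob <= 1.0):
            raise ValueError("sign_prob must lie in [0, 1]")


@dataclass
class Candidate:
    position: np.ndarray
    velocity: np.ndarray
    fitness: float
    personal_best_position: np.ndarray
    personal_best_fitness: float
    role: str  # "male" | "female"


@dataclass
class SwarmState:
    iteration: int
    candidates: list[Candidate]
    food_position: np.ndarray
    food_fitness: float
    best_male_position: np.ndarray
    best_male_fitness: float
    best_female_position: np.ndarray
    best_female_fitness: float
    q: float
    temp: float
    trace: list[float] = field(default_factory=list)
    evaluations: int = 0

    def males(self) -> list[Candidate]:
        return [c for c in self.candidates if c.role == "male"]

    def females(self) -> list[Candidate]:
        return [c for c in self.candidates if c.role == "female"]


@dataclass(frozen=True)
class OptimizationResult:
    best_position: np.ndarray
    best_fitness: float
    trace: np.ndarray
    evaluations: int
    seed: int
    algorithm: str

    def trace_csv(self) -> str:
        lines = ["iteration,best_fitness"]
        lines += [f"{i},{v!r}" for i, v in enumerate(self.trace, start=1)]
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps(
            {
                "algorithm": self.algorithm,
                "seed": self.seed,
                "best_position": [float(v) for v in self.best_position],
                "best_fitness": float(self.best_fitness),
                "evaluations": int(self.evaluations),
                "trace": [float(v) for v in self.trace],
            }
        )


def environment(c: int, t: int, config: OptimizerConfig) -> tuple[float, float]:
    """Food quantity Q and temperature Temp at iteration ``c`` of ``t``."""
    if t < 1:
        raise ValueError("invalid-config: total iterations must be >= 1")
    if not 0 <= c <= t:
        raise ValueError("iteration counter outside [0, T]")
    q = config.k1 * np.exp((c - t) / t)
    temp = np.exp(-c / t)
    return float(q), float(temp)


def behavior_coefficient(
    kind: str, f_ref: float, f_self: float, config: OptimizerConfig
) -> float:
    """Shared snake-behavior coefficient ``exp(-f_ref / f_self)``.

    ``kind`` is one of {"forage", "fight", "mate"}; all three use the same
    functional form with different fitness arguments.  Inputs must already
    be shifted to be strictly positive; the denominator is floored at
    ``eps_fitness``.
    """
    if kind not in ("forage", "fight", "mate"):
        raise ValueError(f"unknown behavior kind: {kind!r}")
    if not (np.isfinite(f_ref) and np.isfinite(f_self)):
        raise ValueError("invalid-fitness: non-finite input to behavior coefficient")
    return float(np.exp(-f_ref / max(f_self, config.eps_fitness)))


def _evaluate(objective: Objective, x: np.ndarray) -> float:
    value = float(objective(x))
    if not np.isfinite(value):
        raise ValueError(f"invalid-objective: non-finite value at position {x!r}")
    return value


def _shifted(fitness: float, state: SwarmState, config: OptimizerConfig) -> float:
    # coefficients need positive fitnesses; shift by the best-ever (minimum) value
    return fitness - state.food_fitness + config.eps_fitness


def init_population(
    bounds: BoundsSpec, config: OptimizerConfig, objective: Objective
) -> SwarmState:
    """Seeded uniform initialization inside the box.

    Positions are drawn as ``lower + rand*(upper - lower)`` and velocities as
    ``rand*0.1*(upper - lower)``; the first floor(N/2) candidates are male,
    the remainder female.  Bests and the food position start at the
    population minimum.
    """
    rng = substream(config.seed, "init")
    n, d = config.n_pop, bounds.dim
    positions = bounds.lower + rng.random((n, d)) * bounds.span
    velocities = rng.random((n, d)) * 0.1 * bounds.span
    n_male = n // 2
    candidates = []
    for i in range(n):
        fit = _evaluate(objective, positions[i])
        candidates.append(
            Candidate(
                position=positions[i].copy(),
                velocity=velocities[i].copy(),
                fitness=fit,
                personal_best_position=positions[i].copy(),
                personal_best_fitness=fit,
                role="male" if i < n_male else "female",
            )
        )
    best = min(candidates, key=lambda c: c.fitness)
    best_male = min(candidates[:n_male], key=lambda c: c.fitness)
    best_female = min(candidates[n_male:], key=lambda c: c.fitness)
    q, temp = environment(0, config.n_iter, config)
    return SwarmState(
        iteration=0,
        candidates=candidates,
        food_position=best.position.copy(),
        food_fitness=best.fitness,
        best_male_position=best_male.position.copy(),
        best_male_fitness=best_male.fitness,
        best_female_position=best_female.position.copy(),
        best_female_fitness=best_female.fitness,
        q=q,
        temp=temp,
        evaluations=n,
    )


def _signs(rng: np.random.Generator, config: OptimizerConfig, n: int) -> np.ndarray:
    return np.where(rng.random(n) < config.sign_prob, 1.0, -1.0)


def _update_bests(state: SwarmState) -> None:
    """Refresh sex-group and food bests under elitism (they never worsen)."""
    for c in state.candidates:
        if c.fitness < c.personal_best_fitness:
            c.personal_best_fitness = c.fitness
            c.personal_best_position = c.position.copy()
        if c.role == "male" and c.fitness < state.best_male_fitness:
            state.best_male_fitness = c.fitness
            state.best_male_position = c.position.copy()
        elif c.role == "female" and c.fitness < state.best_female_fitness:
            state.best_female_fitness = c.fitness
            state.best_female_position = c.position.copy()
        if c.fitness < state.food_fitness:
            state.food_fitness = c.fitness
            state.food_position = c.position.copy()


def so_move(
    state: SwarmState,
    bounds: BoundsSpec,
    config: OptimizerConfig,
    objective: Objective,
) -> SwarmState:
    """One full snake-optimizer iteration (advances the iteration counter)."""
    c_iter = state.iteration + 1
    q, temp = environment(c_iter, config.n_iter, config)
    move_rng = substream(config.seed, f"so_moves/{c_iter}")
    sign_rng = substream(config.seed, f"signs/{c_iter}")
    mode_rng = substream(config.seed, f"mode/{c_iter}")

    males = state.males()
    females = state.females()
    signs = _signs(sign_rng, config, len(state.candidates))
    d = bounds.dim

    new_positions: list[np.ndarray] = []
    if q < config.q_threshold:
        # exploration: move around a random same-sex reference scaled by its
        # foraging ability
        for i, cand in enumerate(state.candidates):
            group = males if cand.role == "male" else females
            ref = group[move_rng.integers(len(group))]
            ab = behavior_coefficient(
                "forage",
                _shifted(ref.fitness, state, config),
                _shifted(cand.fitness, state, config),
                config,
            )
            r = move_rng.random(d)
            step = config.k2 * ab * (bounds.span * r + bounds.lower)
            new_positions.append(ref.position + signs[i] * step)
    elif temp > config.temp_threshold:
        # hot with plentiful food: everyone migrates toward the food
        for i, cand in enumerate(state.candidates):
            r = move_rng.random(d)
            step = config.k3 * temp * r * (state.food_position - cand.position)
            new_positions.append(state.food_position + signs[i] * step)
    else:
        if not males or not females:
            raise ValueError("degenerate-population: fight/mate needs both sexes")
        fight = mode_rng.random() > config.mode_split
        if fight:
            for i, cand in enumerate(state.candidates):
                if cand.role == "male":
                    target, f_ref = state.best_female_position, state.best_female_fitness
                else:
                    target, f_ref = state.best_male_position, state.best_male_fitness
                fa = behavior_coefficient(
                    "fight",
                    _shifted(f_ref, state, config),
                    _shifted(cand.fitness, state, config),
                    config,
                )
                r = move_rng.random(d)
                new_positions.append(
                    cand.position
                    + signs[i] * config.k3 * fa * r * (target - cand.position)
                )
        else:
            for i, cand in enumerate(state.candidates):
                if cand.role == "male":
                    mate = females[
                        [j for j, m in enumerate(males) if m is cand][0] % len(females)
                    ]
                else:
                    mate = males[
                        [j for j, f in enumerate(females) if f is cand][0] % len(males)
                    ]
                ma = behavior_coefficient(
                    "mate",
                    _shifted(mate.fitness, state, config),
                    _shifted(cand.fitness, state, config),
                    config,
                )
                r = move_rng.random(d)
                new_positions.append(
                    cand.position
                    + signs[i] * config.k3 * ma * r * (q * mate.position - cand.position)
                )
        hatched = (not fight) and (mode_rng.random() < config.hatch_prob)
        if hatched:
            # egg hatches: worst male and worst female restart at random points
            worst_m = max(range(len(males)), key=lambda j: males[j].fitness)
            worst_f = max(range(len(females)), key=lambda j: females[j].fitness)
            for cand in (males[worst_m], females[worst_f]):
                idx = next(i for i, c in enumerate(state.candidates) if c is cand)
                new_positions[idx] = bounds.lower + move_rng.random(d) * bounds.span

    evals = 0
    for cand, pos in zip(state.candidates, new_positions):
        cand.position = bounds.clip(pos)
        cand.fitness = _evaluate(objective, cand.position)
        evals += 1
    state.iteration = c_iter
    state.q, state.temp = q, temp
    state.evaluations += evals
    _update_bests(state)
    state.trace.append(state.food_fitness)
    return state


def pso_update(
    candidate: Candidate,
    global_best: np.ndarray,
    bounds: BoundsSpec,
    config: OptimizerConfig,
    rng: np.random.Generator,
    objective: Objective,
    delta_so: np.ndarray | None = None,
) -> Candidate:
    """One PSO velocity/position step for a single particle.

    ``delta_so``, when given, is the hybrid's snake displacement added to the
    velocity before clamping.
    """
    d = bounds.dim
    rand1 = rng.random(d)
    rand2 = rng.random(d)
    velocity = (
        config.inertia * candidate.velocity
        + config.cognitive * rand1 * (candidate.personal_best_position - candidate.position)
        + config.social * rand2 * (global_best - candidate.position)
    )
    if delta_so is not None:
        velocity = velocity + delta_so
    v_max = config.v_max_fraction * bounds.span
    velocity = np.clip(velocity, -v_max, v_max)
    position = bounds.clip(candidate.position + velocity)
    fitness = _evaluate(objective, position)
    out = replace(
        candidate,
        position=position,
        velocity=velocity,
        fitness=fitness,
        personal_best_position=candidate.personal_best_position.copy(),
    )
    if fitness < out.personal_best_fitness:
        out.personal_best_fitness = fitness
        out.personal_best_position = position.copy()
    return out


def _velocity_iteration(
    state: SwarmState,
    bounds: BoundsSpec,
    config: OptimizerConfig,
    objective: Objective,
    hybrid: bool,
) -> SwarmState:
    """Shared PSO / PSSO iteration; ``hybrid`` enables the snake term."""
    c_iter = state.iteration + 1
    q, temp = environment(c_iter, config.n_iter, config)
    pso_rng = substream(config.seed, f"pso_moves/{c_iter}")
    so_rng = substream(config.seed, f"so_moves/{c_iter}") if hybrid else None
    sign_rng = substream(config.seed, f"signs/{c_iter}") if hybrid else None
    mode_rng = substream(config.seed, f"mode/{c_iter}") if hybrid else None

    global_best = state.food_position.copy()
    new_candidates: list[Candidate] = []
    if hybrid:
        signs = _signs(sign_rng, config, len(state.candidates))
        fight = mode_rng.random() > config.mode_split
        males, females = state.males(), state.females()
    for i, cand in enumerate(state.candidates):
        delta = None
        if hybrid:
            r3 = so_rng.random(bounds.dim)
            if q > config.q_threshold:
                # food-attraction form of the snake displacement
                delta = config.k3 * temp * r3 * (state.food_position - cand.position)
            elif fight:
                # fight: attraction to the best of the opposite sex
                if cand.role == "male":
                    target, f_ref = state.best_female_position, state.best_female_fitness
                else:
                    target, f_ref = state.best_male_position, state.best_male_fitness
                fa = behavior_coefficient(
                    "fight",
                    _shifted(f_ref, state, config),
                    _shifted(cand.fitness, state, config),
                    config,
                )
                delta = config.k3 * fa * r3 * (target - cand.position)
            else:
                # mating: attraction to the food-scaled position of a paired
                # partner (the Q factor keeps early-phase mating dispersive)
                if cand.role == "male":
                    mate = females[[j for j, m in enumerate(males) if m is cand][0] % len(females)]
                else:
                    mate = males[[j for j, f in enumerate(females) if f is cand][0] % len(males)]
                ma = behavior_coefficient(
                    "mate",
                    _shifted(mate.fitness, state, config),
                    _shifted(cand.fitness, state, config),
                    config,
                )
                delta = config.k3 * ma * r3 * (q * mate.position - cand.position)
            # the +/- diversity factor of the snake moves, per candidate
            delta = config.so_weight * signs[i] * delta
        new_candidates.append(
            pso_update(cand, global_best, bounds, config, pso_rng, objective, delta)
        )

    state.candidates = new_candidates
    state.iteration = c_iter
    state.q, state.temp = q, temp
    state.evaluations += len(new_candidates)
    _update_bests(state)
    state.trace.append(state.food_fitness)
    return state


def psso_update(
    state: SwarmState, bounds: BoundsSpec, config: OptimizerConfig, objective: Objective
) -> SwarmState:
    """One hybrid PSSO iteration: PSO velocity update plus the snake term."""
    return _velocity_iteration(state, bounds, config, objective, hybrid=True)


def optimize(
    objective: Objective,
    bounds: BoundsSpec,
    config: OptimizerConfig,
    algorithm: str = "psso",
) -> OptimizationResult:
    """Run ``n_iter`` iterations of the chosen algorithm from a seeded start.

    Returns the elitist best with a non-increasing convergence trace of
    length ``n_iter``.  Identical seed and config give bit-identical results.
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"invalid-algorithm: {algorithm!r} (choose from {ALGORITHMS})")
    state = init_population(bounds, config, objective)
    for _ in range(config.n_iter):
        if algorithm == "so":
            so_move(state, bounds, config, objective)
        else:
            _velocity_iteration(
                state, bounds, config, objective, hybrid=(algorithm == "psso")
            )
    return OptimizationResult(
        best_position=state.food_position.copy(),
        best_fitness=state.food_fitness,
        trace=np.asarray(state.trace),
        evaluations=state.evaluations,
        seed=config.seed,
        algorithm=algorithm,
    )
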