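"""The main multiobjective spider-wasp optimization loop.

Each generation, every wasp either hunts (searching, following/escaping or
nesting, chosen stochastically with the exploration behaviours favoured
early and the exploitative ones late) or mates (uniform crossover with a
random partner).  Survivors of each generation are the best of parents and
offspring by (non-domination rank, crowding distance), with the
worst-per-objective feasible members protected as diversity anchors.  An
external bounded archive of non-dominated solutions is maintained
throughout and supplies the leaders that guide the chase and nesting
moves; the population shrinks on a linear schedule so the late evaluation
budget concentrates on refinement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import operators as ops
from .benchmarks import Problem
from .metrics import hypervolume
from .operators import Bounds, OperatorParams
from .pareto import (
    Archive,
    Individual,
    constrained_dominates,
    crowding_of,
    sort_fronts,
    update_archive,
)

__all__ = ["MOSWOConfig", "RunResult", "select_leader", "run"]


@dataclass
class MOSWOConfig:
    """All run parameters of the optimizer.

    pop_size          initial population size N
    n_min             floor of the population-reduction schedule
    budget            maximum number of objective evaluations
    archive_capacity  bound on the external archive (nothing in the
                      method fixes it; default mirrors the population size)
    reduction_period  apply the shrink schedule every k-th iteration
    params            operator-level factors (trade-off, crossover, ...)
    seed              seed of the single generator threaded everywhere
    hv_window         optional early stop: halt when archive hypervolume
                      has not improved for this many iterations (0 = off)
    """

    pop_size: int = 100
    n_min: int = 20
    budget: int = 10_000
    archive_capacity: int = 100
    reduction_period: int = 10
    params: OperatorParams = field(default_factory=OperatorParams)
    seed: int = 0
    hv_window: int = 0

    def __post_init__(self) -> None:
        if self.n_min < 2:
            raise ValueError("n_min must be at least 2")
        if self.pop_size < self.n_min:
            raise ValueError("pop_size must be at least n_min")
        if self.budget <= 0:
            raise ValueError("budget must be positive")
        if self.budget < 2 * self.pop_size:
            raise ValueError("budget must cover initialization plus one generation")


@dataclass
class RunResult:
    """Outcome of one optimizer run."""

    archive: Archive
    history: list[dict]
    seed: int
    config: MOSWOConfig
    evaluations: int

    def config_dict(self) -> dict:
        return asdict(self.config)


def select_leader(
    archive: Archive, rng: np.random.Generator, population: list[Individual] | None = None
) -> Individual:
    """Binary tournament on crowding distance among archive members.

    Higher crowding wins (pressure toward sparse regions of the front);
    ties break uniformly at random.  An empty archive falls back to the
    best-ranked population member.
    """
    members = archive.members
    if not members:
        if not population:
            raise ValueError("cannot select a leader from empty archive and population")
        return min(
            population,
            key=lambda ind: (ind.rank if ind.rank is not None else 1, -ind.crowding),
        )
    if len(members) == 1:
        return members[0]
    i, j = rng.integers(len(members)), rng.integers(len(members))
    a, b = members[i], members[j]
    if a.crowding > b.crowding:
        return a
    if b.crowding > a.crowding:
        return b
    return a if rng.uniform() < 0.5 else b


def _evaluate(problem: Problem, x: np.ndarray) -> tuple[np.ndarray, float]:
    f = np.asarray(problem.evaluate(x), dtype=float)
    if np.any(~np.isfinite(f)):
        raise FloatingPointError(
            f"objective evaluation returned a non-finite value at x={x!r}"
        )
    return f, problem.violation(x)


def _offspring_position(
    ind: Individual,
    population: list[Individual],
    archive: Archive,
    bounds: Bounds,
    p: OperatorParams,
    t: int,
    t_max: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, bool]:
    """One stochastic behaviour branch: hunt (search / follow-escape /
    nest) with probability ``tr``, otherwise mate.  Returns the clipped
    offspring position and whether it came from the mating operator."""
    x = ind.position
    mated = False
    if rng.uniform() < p.tr:  # hunting
        k = max(0.0, 1.0 - t / t_max)  # exploration weight, fades over time
        leader = select_leader(archive, rng, population)
        if (
            np.linalg.norm(x - leader.position)
            > ops.escape_threshold(bounds, t, t_max, p.escape_scale)
        ):
            # prey escaped out of reach: fall back to a random relocation
            new = ops.explore_jump(x, bounds, rng)
        else:
            # stochastic behaviour mixture: the long-range jump and the
            # leader chase fade with the speed schedule; the local
            # difference move, the contraction escape and nesting stay
            # active throughout.  The escape carries the largest weight:
            # its per-dimension rescaling both supplies fresh coordinate
            # values on multimodal landscapes (which mating then
            # assembles) and refines solutions late in the run.
            weights = np.array([k, 1.0, k, 2.0, 1.0])
            u = rng.uniform() * weights.sum()
            edges = np.cumsum(weights)
            if u < edges[0]:  # long-range search jump
                new = ops.explore_jump(x, bounds, rng)
            elif u < edges[1]:  # local web-search move along a difference
                picks = rng.integers(len(population), size=2)
                new = ops.explore_move(
                    x, population[picks[0]].position, population[picks[1]].position, rng
                )
            elif u < edges[2]:  # chase toward the leader
                new = ops.follow_move(x, leader.position, t, t_max, rng, c0=p.c0)
            elif u < edges[3]:  # contraction escape
                new = ops.escape_move(x, rng, p.k_vc_low, p.k_vc_high)
            else:  # nesting around the leader
                new = ops.nest_move(leader.position, x, rng)
    else:  # mating: uniform crossover with a random population member
        partner = population[rng.integers(len(population))]
        new = ops.mate(x, partner.position, p.cr, rng)
        mated = True
    return ops.clip_to_bounds(new, bounds), mated


def _truncate_population(
    population: list[Individual], new_size: int
) -> list[Individual]:
    """Keep the best ``new_size`` members by (rank, crowding) lexicographic
    order — elitist truncation mirroring the archive rule.

    One feasible member per objective — the one with the largest value of
    that objective — is always retained as a diversity anchor.  Without
    this, a single early near-optimal corner solution can dominate the
    whole population, extinguish all positional diversity, and freeze the
    run in a one-point degenerate front.
    """
    objs = np.array([ind.objectives for ind in population])
    viol = np.array([ind.violation for ind in population])
    fronts, ranks = sort_fronts(objs, viol)
    for ind, r in zip(population, ranks):
        ind.rank = int(r)
    for f in fronts:
        cd = crowding_of(objs[f])
        for idx, c in zip(f, cd):
            population[idx].crowding = float(c)
    anchors: set[int] = set()
    feasible = np.flatnonzero(viol == 0)
    if feasible.size:
        for m in range(objs.shape[1]):
            anchors.add(int(feasible[np.argmax(objs[feasible, m])]))
    order = sorted(
        range(len(population)),
        key=lambda i: (i not in anchors, population[i].rank, -population[i].crowding, i),
    )
    return [population[i] for i in order[:new_size]]


def run(problem: Problem, config: MOSWOConfig) -> RunResult:
    """Run the optimizer on a problem; the returned archive is the
    Pareto-front estimate.

    The budget counts objective evaluations; the iteration horizon used by
    the time-dependent schedules accounts for the population-reduction
    schedule (approximately ``2 * budget / (pop_size + n_min)``).  NaN or
    inf from the objective aborts the run with a diagnostic.
    """
    rng = np.random.default_rng(config.seed)
    bounds = problem.bounds
    p = config.params
    n0 = config.pop_size
    # iteration horizon consistent with the linear population-reduction
    # schedule, so evals(t_max) ~= budget: sum of N(t) ~= t_max*(N0+Nmin)/2
    if config.reduction_period > 0 and config.n_min < n0:
        t_max = max(1, int(2 * config.budget / (n0 + config.n_min)))
    else:
        t_max = max(1, config.budget // n0)

    positions = rng.uniform(bounds.low, bounds.high, size=(n0, bounds.dim))
    population: list[Individual] = []
    evals = 0
    for x in positions:
        f, v = _evaluate(problem, x)
        evals += 1
        population.append(Individual(position=x, objectives=f, violation=v))

    archive = Archive(capacity=config.archive_capacity)
    update_archive(archive, population)

    history: list[dict] = []

    def _log(t: int) -> None:
        objs = archive.objectives()
        history.append(
            {
                "iteration": t,
                "evaluations": evals,
                "archive_size": len(archive),
                "best_objectives": objs.min(axis=0).tolist(),
            }
        )

    _log(0)
    stall = 0
    last_hv = -np.inf
    t = 0
    target_size = len(population)
    while evals + len(population) <= config.budget:
        t += 1
        offspring: list[Individual] = []
        for ind in population:
            x_new, mated = _offspring_position(
                ind, population, archive, bounds, p, t, t_max, rng
            )
            f, v = _evaluate(problem, x_new)
            evals += 1
            child = Individual(position=x_new, objectives=f, violation=v)
            # a mating offspring enters only if its parent does not
            # dominate it; hunting offspring always compete
            if mated and constrained_dominates(ind, child):
                continue
            offspring.append(child)

        # elitist survival: rank the union of parents and offspring by
        # non-domination and crowding, keep the best candidates
        if config.reduction_period > 0 and t % config.reduction_period == 0:
            target_size = ops.reduce_population(n0, config.n_min, t, t_max)
        pool = population + offspring
        population = _truncate_population(pool, min(target_size, len(pool)))

        update_archive(archive, offspring)
        _log(t)

        if config.hv_window > 0 and len(archive) and problem.n_obj in (2, 3):
            objs = archive.objectives()
            ref = objs.max(axis=0) + 1.0
            hv = hypervolume(objs, ref)
            if hv <= last_hv + 1e-12:
                stall += 1
                if stall >= config.hv_window:
                    break
            else:
                stall = 0
                last_hv = hv

    return RunResult(
        archive=archive, history=history, seed=config.seed,
        config=config, evaluations=evals,
    )
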