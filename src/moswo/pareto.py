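"""Pareto dominance, non-dominated sorting, crowding distance, and the
external archive.

All objectives are minimized internally.  Constraint handling follows the
feasibility-first rule: a feasible solution dominates any infeasible one;
among two infeasible solutions the one with the smaller aggregate violation
wins; ordinary Pareto dominance applies only between feasible solutions.

Two API levels coexist: array-level functions (``dominance_matrix``,
``sort_fronts``, ``crowding_of``) that the optimizer loop uses, and
:class:`Individual`-level wrappers that mirror them one-to-one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Individual",
    "Archive",
    "dominates",
    "constrained_dominates",
    "dominance_matrix",
    "sort_fronts",
    "crowding_of",
    "non_dominated_sort",
    "crowding_distance",
    "update_archive",
    "write_archive",
    "read_archive",
]


@dataclass
class Individual:
    """One candidate solution: a decision vector with its evaluation."""

    position: np.ndarray
    objectives: np.ndarray
    rank: int | None = None
    crowding: float = 0.0
    violation: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.objectives = np.asarray(self.objectives, dtype=float)
        if self.violation < 0:
            raise ValueError("violation must be non-negative")


# ---------------------------------------------------------------------------
# array-level core
# ---------------------------------------------------------------------------

def dominates(a: np.ndarray, b: np.ndarray) -> bool:
    """True iff ``a`` Pareto-dominates ``b`` (minimization).

    ``a`` dominates ``b`` when it is no worse in every objective and
    strictly better in at least one.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"objective length mismatch: {a.shape} vs {b.shape}")
    return bool(np.all(a <= b) and np.any(a < b))


def constrained_dominates(a: Individual, b: Individual) -> bool:
    """Feasibility-first dominance between two evaluated individuals."""
    if a.violation == 0.0 and b.violation == 0.0:
        return dominates(a.objectives, b.objectives)
    if a.violation == 0.0:
        return True
    if b.violation == 0.0:
        return False
    return a.violation < b.violation


def dominance_matrix(
    objs: np.ndarray, violations: np.ndarray | None = None
) -> np.ndarray:
    """Pairwise dominance: D[i, j] is True iff solution i dominates j.

    Vectorized over the whole population; applies the feasibility-first
    rule when a violation vector is given.
    """
    objs = np.atleast_2d(np.asarray(objs, dtype=float))
    le = np.all(objs[:, None, :] <= objs[None, :, :], axis=-1)
    lt = np.any(objs[:, None, :] < objs[None, :, :], axis=-1)
    dom = le & lt
    if violations is None:
        return dom
    viol = np.asarray(violations, dtype=float)
    feas = viol == 0.0
    both_feas = feas[:, None] & feas[None, :]
    feas_beats_infeas = feas[:, None] & ~feas[None, :]
    less_violating = (
        ~feas[:, None] & ~feas[None, :] & (viol[:, None] < viol[None, :])
    )
    return (dom & both_feas) | feas_beats_infeas | less_violating


def sort_fronts(
    objs: np.ndarray, violations: np.ndarray | None = None
) -> tuple[list[np.ndarray], np.ndarray]:
    """Non-dominated sorting on an objective matrix.

    Returns ``(fronts, ranks)`` where fronts is an ordered list of index
    arrays F_1, F_2, ... and ranks is 1-based.  Classic counting scheme:
    n_i dominators per solution, iterative peeling of the zero-count set.
    """
    objs = np.atleast_2d(np.asarray(objs, dtype=float))
    n = objs.shape[0]
    if n == 0:
        raise ValueError("population must be non-empty")
    dom = dominance_matrix(objs, violations)
    n_dominators = dom.sum(axis=0).astype(int)
    ranks = np.zeros(n, dtype=int)
    fronts: list[np.ndarray] = []
    remaining = np.ones(n, dtype=bool)
    rank = 1
    while remaining.any():
        current = np.flatnonzero(remaining & (n_dominators == 0))
        if current.size == 0:  # cycle cannot happen with a strict order
            raise RuntimeError("non-dominated sort failed to make progress")
        ranks[current] = rank
        fronts.append(current)
        remaining[current] = False
        n_dominators = n_dominators - dom[current].sum(axis=0)
        rank += 1
    return fronts, ranks


def crowding_of(objs: np.ndarray) -> np.ndarray:
    """Crowding distance of every member of one front.

    Boundary solutions per objective get infinity; interior solutions
    accumulate (f_m(i+1) - f_m(i-1)) / (f_m max - f_m min) over objectives
    starting from 0.  Fronts of size <= 2 are all-infinite; a degenerate
    objective (max == min) contributes nothing.  Sorting is stable with
    the index as tie-break, so the result is order-deterministic.
    """
    objs = np.atleast_2d(np.asarray(objs, dtype=float))
    n, m = objs.shape
    if n <= 2:
        return np.full(n, np.inf)
    cd = np.zeros(n)
    for k in range(m):
        order = np.argsort(objs[:, k], kind="stable")
        col = objs[order, k]
        span = col[-1] - col[0]
        cd[order[0]] = np.inf
        cd[order[-1]] = np.inf
        if span == 0:
            continue
        interior = order[1:-1]
        gaps = (col[2:] - col[:-2]) / span
        finite = ~np.isinf(cd[interior])
        cd[interior[finite]] += gaps[finite]
    return cd


# ---------------------------------------------------------------------------
# Individual-level wrappers
# ---------------------------------------------------------------------------

def _pop_arrays(pop: list[Individual]) -> tuple[np.ndarray, np.ndarray]:
    objs = np.array([ind.objectives for ind in pop])
    viol = np.array([ind.violation for ind in pop])
    return objs, viol


def non_dominated_sort(pop: list[Individual]) -> list[list[int]]:
    """Partition a population into successive non-dominated fronts.

    Assigns 1-based ``rank`` on every individual and returns the fronts as
    ordered lists of population indices.
    """
    if not pop:
        raise ValueError("population must be non-empty")
    objs, viol = _pop_arrays(pop)
    fronts, ranks = sort_fronts(objs, viol)
    for ind, r in zip(pop, ranks):
        ind.rank = int(r)
    return [list(map(int, f)) for f in fronts]


def crowding_distance(front: list[Individual]) -> None:
    """Assign crowding distances to one front of individuals, in place.

    Members are expected to be mutually non-dominated (documented, not
    enforced).
    """
    if not front:
        return
    cd = crowding_of(np.array([ind.objectives for ind in front]))
    for ind, v in zip(front, cd):
        ind.crowding = float(v)


# ---------------------------------------------------------------------------
# external archive
# ---------------------------------------------------------------------------

@dataclass
class Archive:
    """Bounded store of mutually non-dominated solutions.

    The archive is the evolving Pareto-front estimate.  After every update
    no member dominates another and the size never exceeds ``capacity``;
    truncation removes the most crowded (lowest crowding distance) member
    one at a time, recomputing crowding after each removal so adjacent
    points are never dropped together.
    """

    capacity: int = 100
    members: list[Individual] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.capacity < 1:
            raise ValueError("archive capacity must be positive")

    def __len__(self) -> int:
        return len(self.members)

    def objectives(self) -> np.ndarray:
        return np.array([m.objectives for m in self.members])

    def positions(self) -> np.ndarray:
        return np.array([m.position for m in self.members])

    def update(self, candidates: list[Individual]) -> "Archive":
        return update_archive(self, candidates)


def update_archive(archive: Archive, candidates: list[Individual]) -> Archive:
    """Merge candidates into the archive, keeping the non-dominated set.

    Exact duplicates of an already-pooled objective vector are dropped
    (first-inserted wins) so clones cannot flood the archive.  If the
    non-dominated union exceeds capacity, the lowest-crowding member is
    removed repeatedly, with crowding recomputed after each removal.
    """
    pool: list[Individual] = []
    seen: set[bytes] = set()
    for ind in list(archive.members) + list(candidates):
        key = np.ascontiguousarray(ind.objectives).tobytes()
        if key in seen:
            continue
        seen.add(key)
        pool.append(ind)
    if not pool:
        return archive

    objs, viol = _pop_arrays(pool)
    dom = dominance_matrix(objs, viol)
    nd_mask = ~dom.any(axis=0)
    keep = [pool[i] for i in np.flatnonzero(nd_mask)]

    while len(keep) > archive.capacity:
        cd = crowding_of(np.array([ind.objectives for ind in keep]))
        keep.pop(int(np.lexsort((np.arange(len(cd)), cd))[0]))

    crowding_distance(keep)
    for ind in keep:
        ind.rank = 1
    archive.members = keep
    return archive


def write_archive(archive: Archive, path, run_id: str = "run0") -> None:
    """Serialize an archive: one row per member with position, objectives,
    rank and crowding.  Header row is mandatory."""
    rows = []
    for k, ind in enumerate(archive.members):
        row = {"run_id": run_id, "member_id": k}
        row.update({f"x{d}": v for d, v in enumerate(ind.position)})
        row.update({f"f{m}": v for m, v in enumerate(ind.objectives)})
        row["rank"] = ind.rank if ind.rank is not None else 1
        row["crowding"] = ind.crowding
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_archive(path) -> Archive:
    """Read an archive written by :func:`write_archive`."""
    df = pd.read_csv(path)
    xcols = sorted((c for c in df.columns if c.startswith("x")), key=lambda c: int(c[1:]))
    fcols = sorted((c for c in df.columns if c.startswith("f")), key=lambda c: int(c[1:]))
    members = [
        Individual(
            position=row[xcols].to_numpy(dtype=float),
            objectives=row[fcols].to_numpy(dtype=float),
            rank=int(row["rank"]),
            crowding=float(row["crowding"]),
        )
        for _, row in df.iterrows()
    ]
    arc = Archive(capacity=max(len(members), 1))
    arc.members = members
    return arc
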