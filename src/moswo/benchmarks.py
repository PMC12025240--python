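"""Analytic multiobjective test problems: ZDT1-4, ZDT6 and DTLZ1-7.

The canonical formulations and dimensions from the benchmark literature are
used: ZDT problems are bi-objective (D = 30 for ZDT1-3, D = 10 for
ZDT4/ZDT6); DTLZ problems are built with M = 3 objectives and
D = M - 1 + k with the standard k (5 for DTLZ1, 10 for DTLZ2-6, 20 for
DTLZ7).  Every problem carries a sampler of its analytic Pareto front so
quality indicators can be computed against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .operators import Bounds
from .pareto import Individual, non_dominated_sort

__all__ = ["Problem", "make_zdt", "make_dtlz", "get_problem", "sample_true_front"]


@dataclass
class Problem:
    """A multiobjective minimization problem over a box."""

    name: str
    dim: int
    n_obj: int
    bounds: Bounds
    evaluate: Callable[[np.ndarray], np.ndarray]
    true_front: Callable[[int], np.ndarray] | None = None
    constraints: Callable[[np.ndarray], float] | None = field(default=None)
    # constraints(x) returns an aggregate violation >= 0 (0 == feasible)

    def violation(self, x: np.ndarray) -> float:
        return 0.0 if self.constraints is None else float(self.constraints(x))


# ---------------------------------------------------------------------------
# ZDT family (bi-objective)
# ---------------------------------------------------------------------------

def _zdt6_f1_min() -> float:
    # f1(x1) = 1 - exp(-4 x1) sin^6(6 pi x1); locate its minimum once
    x = np.linspace(0.0, 1.0, 200_001)
    f1 = 1.0 - np.exp(-4.0 * x) * np.sin(6.0 * np.pi * x) ** 6
    return float(f1.min())


_ZDT6_F1_MIN = _zdt6_f1_min()  # ~= 0.280775


def _zdt1_eval(x: np.ndarray) -> np.ndarray:
    g = 1.0 + 9.0 * np.mean(x[1:])
    f1 = x[0]
    return np.array([f1, g * (1.0 - np.sqrt(f1 / g))])


def _zdt2_eval(x: np.ndarray) -> np.ndarray:
    g = 1.0 + 9.0 * np.mean(x[1:])
    f1 = x[0]
    return np.array([f1, g * (1.0 - (f1 / g) ** 2)])


def _zdt3_eval(x: np.ndarray) -> np.ndarray:
    g = 1.0 + 9.0 * np.mean(x[1:])
    f1 = x[0]
    h = 1.0 - np.sqrt(f1 / g) - (f1 / g) * np.sin(10.0 * np.pi * f1)
    return np.array([f1, g * h])


def _zdt4_eval(x: np.ndarray) -> np.ndarray:
    xi = x[1:]
    g = 1.0 + 10.0 * xi.size + np.sum(xi**2 - 10.0 * np.cos(4.0 * np.pi * xi))
    f1 = x[0]
    return np.array([f1, g * (1.0 - np.sqrt(f1 / g))])


def _zdt6_eval(x: np.ndarray) -> np.ndarray:
    f1 = 1.0 - np.exp(-4.0 * x[0]) * np.sin(6.0 * np.pi * x[0]) ** 6
    g = 1.0 + 9.0 * np.mean(x[1:]) ** 0.25
    return np.array([f1, g * (1.0 - (f1 / g) ** 2)])


def _grid(n: int) -> np.ndarray:
    return np.linspace(0.0, 1.0, n)


def _zdt1_front(n: int) -> np.ndarray:
    # uniform in t = sqrt(f1): even spacing along f2, e.g. n=3 gives
    # (0,1), (0.25,0.5), (1,0)
    t = _grid(n)
    return np.column_stack([t**2, 1.0 - t])


def _zdt2_front(n: int) -> np.ndarray:
    f1 = _grid(n)
    return np.column_stack([f1, 1.0 - f1**2])


def _zdt3_front(n: int) -> np.ndarray:
    # sample densely in f1, keep the non-dominated (disconnected) segments
    f1 = np.linspace(0.0, 1.0, max(4 * n, 2000))
    f2 = 1.0 - np.sqrt(f1) - f1 * np.sin(10.0 * np.pi * f1)
    pts = np.column_stack([f1, f2])
    pts = _filter_non_dominated(pts)
    idx = np.linspace(0, len(pts) - 1, min(n, len(pts))).astype(int)
    return pts[idx]


def _zdt6_front(n: int) -> np.ndarray:
    f1 = np.linspace(_ZDT6_F1_MIN, 1.0, n)
    return np.column_stack([f1, 1.0 - f1**2])


def _filter_non_dominated(pts: np.ndarray) -> np.ndarray:
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    pts = pts[order]
    keep = []
    best_f2 = np.inf
    for p in pts:
        if p[1] < best_f2 - 1e-12:
            keep.append(p)
            best_f2 = p[1]
    return np.array(keep)


_ZDT = {
    1: (_zdt1_eval, _zdt1_front, 30, (0.0, 1.0)),
    2: (_zdt2_eval, _zdt2_front, 30, (0.0, 1.0)),
    3: (_zdt3_eval, _zdt3_front, 30, (0.0, 1.0)),
    4: (_zdt4_eval, _zdt1_front, 10, None),  # same front shape as ZDT1
    6: (_zdt6_eval, _zdt6_front, 10, (0.0, 1.0)),
}


def make_zdt(which: int, dim: int | None = None) -> Problem:
    """Build a ZDT problem (1, 2, 3, 4 or 6) at its standard dimension."""
    if which not in _ZDT:
        raise ValueError(f"unknown ZDT index: {which}")
    evaluate, front, default_dim, box = _ZDT[which]
    d = default_dim if dim is None else int(dim)
    if d < 2:
        raise ValueError("ZDT problems need at least 2 decision variables")
    if which == 4:
        low = np.concatenate([[0.0], np.full(d - 1, -5.0)])
        high = np.concatenate([[1.0], np.full(d - 1, 5.0)])
    else:
        low = np.full(d, box[0])
        high = np.full(d, box[1])
    return Problem(
        name=f"zdt{which}",
        dim=d,
        n_obj=2,
        bounds=Bounds(low, high),
        evaluate=evaluate,
        true_front=front,
    )


# ---------------------------------------------------------------------------
# DTLZ family (three objectives)
# ---------------------------------------------------------------------------

_DTLZ_K = {1: 5, 2: 10, 3: 10, 4: 10, 5: 10, 6: 10, 7: 20}


def _dtlz_g1(xm: np.ndarray) -> float:
    return 100.0 * (
        xm.size + np.sum((xm - 0.5) ** 2 - np.cos(20.0 * np.pi * (xm - 0.5)))
    )


def _dtlz1_eval(x: np.ndarray, m: int = 3) -> np.ndarray:
    xm = x[m - 1 :]
    g = _dtlz_g1(xm)
    f = np.empty(m)
    for i in range(m):
        val = 0.5 * (1.0 + g)
        val *= np.prod(x[: m - 1 - i])
        if i > 0:
            val *= 1.0 - x[m - 1 - i]
        f[i] = val
    return f


def _dtlz_sphere(x: np.ndarray, m: int, g: float, alpha: float = 1.0) -> np.ndarray:
    theta = (x[: m - 1] ** alpha) * np.pi / 2.0
    f = np.empty(m)
    for i in range(m):
        val = 1.0 + g
        val *= np.prod(np.cos(theta[: m - 1 - i]))
        if i > 0:
            val *= np.sin(theta[m - 1 - i])
        f[i] = val
    return f


def _dtlz2_eval(x: np.ndarray, m: int = 3) -> np.ndarray:
    g = float(np.sum((x[m - 1 :] - 0.5) ** 2))
    return _dtlz_sphere(x, m, g)


def _dtlz3_eval(x: np.ndarray, m: int = 3) -> np.ndarray:
    g = _dtlz_g1(x[m - 1 :])
    return _dtlz_sphere(x, m, g)


def _dtlz4_eval(x: np.ndarray, m: int = 3, alpha: float = 100.0) -> np.ndarray:
    g = float(np.sum((x[m - 1 :] - 0.5) ** 2))
    return _dtlz_sphere(x, m, g, alpha=alpha)


def _dtlz5_theta(x: np.ndarray, m: int, g: float) -> np.ndarray:
    theta = np.empty(m - 1)
    theta[0] = x[0] * np.pi / 2.0
    for i in range(1, m - 1):
        theta[i] = np.pi / (4.0 * (1.0 + g)) * (1.0 + 2.0 * g * x[i])
    return theta


def _dtlz5_eval(x: np.ndarray, m: int = 3) -> np.ndarray:
    g = float(np.sum((x[m - 1 :] - 0.5) ** 2))
    theta = _dtlz5_theta(x, m, g)
    f = np.empty(m)
    for i in range(m):
        val = 1.0 + g
        val *= np.prod(np.cos(theta[: m - 1 - i]))
        if i > 0:
            val *= np.sin(theta[m - 1 - i])
        f[i] = val
    return f


def _dtlz6_eval(x: np.ndarray, m: int = 3) -> np.ndarray:
    g = float(np.sum(x[m - 1 :] ** 0.1))
    theta = _dtlz5_theta(x, m, g)
    f = np.empty(m)
    for i in range(m):
        val = 1.0 + g
        val *= np.prod(np.cos(theta[: m - 1 - i]))
        if i > 0:
            val *= np.sin(theta[m - 1 - i])
        f[i] = val
    return f


def _dtlz7_eval(x: np.ndarray, m: int = 3) -> np.ndarray:
    xm = x[m - 1 :]
    g = 1.0 + 9.0 * np.mean(xm)
    f = np.empty(m)
    f[: m - 1] = x[: m - 1]
    h = m - np.sum(f[: m - 1] / (1.0 + g) * (1.0 + np.sin(3.0 * np.pi * f[: m - 1])))
    f[m - 1] = (1.0 + g) * h
    return f


def _square_grid(n: int) -> tuple[np.ndarray, np.ndarray]:
    side = max(2, int(np.ceil(np.sqrt(n))))
    u, v = np.meshgrid(np.linspace(0.0, 1.0, side), np.linspace(0.0, 1.0, side))
    return u.ravel(), v.ravel()


def _dedupe_subsample(pts: np.ndarray, n: int) -> np.ndarray:
    pts = np.unique(pts, axis=0)
    if len(pts) <= n:
        return pts
    idx = np.linspace(0, len(pts) - 1, n).astype(int)
    return pts[idx]


def _dtlz1_front(n: int) -> np.ndarray:
    u, v = _square_grid(n)
    f1 = 0.5 * u * v
    f2 = 0.5 * u * (1.0 - v)
    f3 = 0.5 * (1.0 - u)
    return _dedupe_subsample(np.column_stack([f1, f2, f3]), n)


def _dtlz2_front(n: int) -> np.ndarray:
    u, v = _square_grid(n)
    t1, t2 = u * np.pi / 2.0, v * np.pi / 2.0
    pts = np.column_stack(
        [np.cos(t1) * np.cos(t2), np.cos(t1) * np.sin(t2), np.sin(t1)]
    )
    return _dedupe_subsample(pts, n)


def _dtlz5_front(n: int) -> np.ndarray:
    t1 = np.linspace(0.0, np.pi / 2.0, n)
    c = np.cos(np.pi / 4.0)
    return np.column_stack([np.cos(t1) * c, np.cos(t1) * c, np.sin(t1)])


def _dtlz7_front(n: int) -> np.ndarray:
    u, v = _square_grid(max(n, 64) * 4)
    f3 = 2.0 * (
        3.0
        - u / 2.0 * (1.0 + np.sin(3.0 * np.pi * u))
        - v / 2.0 * (1.0 + np.sin(3.0 * np.pi * v))
    )
    pts = np.column_stack([u, v, f3])
    pop = [Individual(position=np.zeros(1), objectives=p) for p in pts]
    fronts = non_dominated_sort(pop)
    nd = pts[fronts[0]]
    idx = np.linspace(0, len(nd) - 1, min(n, len(nd))).astype(int)
    return nd[idx]


_DTLZ_EVAL = {
    1: (_dtlz1_eval, _dtlz1_front),
    2: (_dtlz2_eval, _dtlz2_front),
    3: (_dtlz3_eval, _dtlz2_front),
    4: (_dtlz4_eval, _dtlz2_front),
    5: (_dtlz5_eval, _dtlz5_front),
    6: (_dtlz6_eval, _dtlz5_front),
    7: (_dtlz7_eval, _dtlz7_front),
}


def make_dtlz(which: int, n_obj: int = 3, dim: int | None = None) -> Problem:
    """Build a DTLZ problem (1..7) with three objectives."""
    if which not in _DTLZ_EVAL:
        raise ValueError(f"unknown DTLZ index: {which}")
    if n_obj != 3:
        raise ValueError("only the three-objective DTLZ instances are supported")
    evaluate, front = _DTLZ_EVAL[which]
    d = (n_obj - 1 + _DTLZ_K[which]) if dim is None else int(dim)
    return Problem(
        name=f"dtlz{which}",
        dim=d,
        n_obj=n_obj,
        bounds=Bounds(np.zeros(d), np.ones(d)),
        evaluate=evaluate,
        true_front=front,
    )


_REGISTRY: dict[str, Callable[[], Problem]] = {
    **{f"zdt{i}": (lambda i=i: make_zdt(i)) for i in (1, 2, 3, 4, 6)},
    **{f"dtlz{i}": (lambda i=i: make_dtlz(i)) for i in range(1, 8)},
}


def get_problem(name: str) -> Problem:
    """Resolve a benchmark problem by name, e.g. ``'zdt1'`` or ``'dtlz5'``."""
    key = name.lower()
    if key not in _REGISTRY:
        raise ValueError(
            f"unknown problem {name!r}; choose from {sorted(_REGISTRY)}"
        )
    return _REGISTRY[key]()


def sample_true_front(problem: Problem, n: int) -> np.ndarray:
    """Sample ``n`` mutually non-dominated points on the analytic front."""
    if problem.true_front is None:
        raise ValueError(f"problem {problem.name!r} has no analytic front")
    if n < 2:
        raise ValueError("need at least 2 front points")
    return problem.true_front(n)
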