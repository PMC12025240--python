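"""Spider-wasp variation operators.

The optimizer mimics four behaviours of spider wasps: searching for prey
(two exploration moves), following / escaping prey (a guided chase and a
contraction retreat), nesting (exploitation around the best solution found)
and mating (uniform crossover).  Every operator takes and returns plain
position vectors and draws its random factors from a caller-supplied
``numpy.random.Generator`` so whole runs are reproducible from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Bounds",
    "OperatorParams",
    "explore_move",
    "explore_jump",
    "follow_move",
    "escape_move",
    "nest_move",
    "mate",
    "reduce_population",
    "clip_to_bounds",
    "escape_threshold",
]


@dataclass
class Bounds:
    """Box bounds of the decision space, lower < upper component-wise."""

    low: np.ndarray
    high: np.ndarray

    def __post_init__(self) -> None:
        self.low = np.atleast_1d(np.asarray(self.low, dtype=float))
        self.high = np.atleast_1d(np.asarray(self.high, dtype=float))
        if self.low.shape != self.high.shape:
            raise ValueError("bound vectors must have equal length")
        if not np.all(self.low < self.high):
            raise ValueError("lower bounds must be strictly below upper bounds")

    @property
    def dim(self) -> int:
        return self.low.size

    @property
    def span(self) -> np.ndarray:
        return self.high - self.low


@dataclass
class OperatorParams:
    """Tunable factors shared by the variation operators.

    tr            probability of hunting (vs mating) per individual
    cr            crossover rate of the mating operator
    c0            initial value of the speed factor C, which decays
                  linearly to 0 over the iteration budget
    k_vc_low/high support of the per-dimension contraction factor vc used
                  by the escape move
    escape_scale  fraction of the decision-space diagonal that defines the
                  prey-too-far threshold (tightens linearly over time)
    """

    tr: float = 0.3
    cr: float = 0.2
    c0: float = 2.0
    k_vc_low: float = -1.0
    k_vc_high: float = 1.0
    escape_scale: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.tr <= 1.0:
            raise ValueError("tr must lie in [0, 1]")
        if not 0.0 <= self.cr <= 1.0:
            raise ValueError("cr must lie in [0, 1]")
        if self.c0 <= 0:
            raise ValueError("c0 must be positive")
        if self.k_vc_low > self.k_vc_high:
            raise ValueError("k_vc_low must not exceed k_vc_high")


def _check_dims(*vectors: np.ndarray) -> None:
    dims = {np.asarray(v).shape for v in vectors}
    if len(dims) > 1:
        raise ValueError(f"position dimension mismatch: {sorted(dims)}")


def explore_move(
    sw_i: np.ndarray,
    sw_a: np.ndarray,
    sw_b: np.ndarray,
    rng: np.random.Generator,
    mu1: float | None = None,
) -> np.ndarray:
    """Web-search step: move along the difference of two population members.

    Returns ``sw_i + mu1 * (sw_a - sw_b)`` with ``mu1 = rn * r1``,
    rn ~ Normal(0, 1) and r1 ~ Uniform(0, 1).  ``mu1`` can be pinned for
    testing.  The caller clips the result to bounds.
    """
    sw_i, sw_a, sw_b = (np.asarray(v, dtype=float) for v in (sw_i, sw_a, sw_b))
    _check_dims(sw_i, sw_a, sw_b)
    if mu1 is None:
        mu1 = rng.standard_normal() * rng.uniform()
    return sw_i + mu1 * (sw_a - sw_b)


def explore_jump(
    sw_c: np.ndarray,
    bounds: Bounds,
    rng: np.random.Generator,
    mu2: float | None = None,
) -> np.ndarray:
    """Long-range relocation toward a random point of the box.

    Returns ``sw_c + mu2 * (L + r2 * (H - L))`` with
    ``mu2 = B * cos(2*pi*l)``, ``B = 1 / (1 + e^l)`` and l ~ Uniform[-2, -1];
    r2 ~ Uniform(0, 1) is drawn fresh per call.
    """
    sw_c = np.asarray(sw_c, dtype=float)
    if mu2 is None:
        l = rng.uniform(-2.0, -1.0)
        mu2 = np.cos(2.0 * np.pi * l) / (1.0 + np.exp(l))
    r2 = rng.uniform()
    return sw_c + mu2 * (bounds.low + r2 * bounds.span)


def speed_factor(t: int, t_max: int, c0: float = 2.0) -> float:
    """Speed-controlling factor C, decaying linearly from c0 to 0."""
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    return c0 * max(0.0, 1.0 - t / t_max)


def follow_move(
    sw_i: np.ndarray,
    sw_a: np.ndarray,
    t: int,
    t_max: int,
    rng: np.random.Generator,
    c0: float = 2.0,
    c: float | None = None,
) -> np.ndarray:
    """Chase step toward a leader: ``sw_i + C * 2 * r5 ∘ (sw_a - sw_i)``.

    ``r5`` is a per-dimension Uniform(0, 1) vector; C decays linearly over
    iterations and can be pinned for testing.
    """
    sw_i, sw_a = np.asarray(sw_i, dtype=float), np.asarray(sw_a, dtype=float)
    _check_dims(sw_i, sw_a)
    if c is None:
        c = speed_factor(t, t_max, c0)
    r5 = rng.uniform(size=sw_i.shape)
    return sw_i + c * 2.0 * r5 * (sw_a - sw_i)


def escape_move(
    sw_i: np.ndarray,
    rng: np.random.Generator,
    k_vc_low: float = -1.0,
    k_vc_high: float = 1.0,
    vc: np.ndarray | None = None,
) -> np.ndarray:
    """Retreat by a per-dimension random contraction: ``sw_i ∘ vc``,
    vc ~ Uniform(k_vc_low, k_vc_high) element-wise."""
    sw_i = np.asarray(sw_i, dtype=float)
    if vc is None:
        vc = rng.uniform(k_vc_low, k_vc_high, size=sw_i.shape)
    return sw_i * np.asarray(vc, dtype=float)


def nest_move(
    sw_star: np.ndarray,
    sw_i: np.ndarray,
    rng: np.random.Generator,
    l: float | None = None,
) -> np.ndarray:
    """Nesting step around the best solution:
    ``sw_star + cos(2*pi*l) * (sw_star - sw_i)`` with l ~ Uniform[-2, -1].

    The output is always collinear with ``sw_i`` and ``sw_star``.
    """
    sw_star, sw_i = np.asarray(sw_star, dtype=float), np.asarray(sw_i, dtype=float)
    _check_dims(sw_star, sw_i)
    if l is None:
        l = rng.uniform(-2.0, -1.0)
    return sw_star + np.cos(2.0 * np.pi * l) * (sw_star - sw_i)


def mate(
    sw_i: np.ndarray,
    sw_m: np.ndarray,
    cr: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Uniform crossover: each dimension is taken from the partner ``sw_m``
    with probability ``cr``, otherwise kept from ``sw_i``."""
    sw_i, sw_m = np.asarray(sw_i, dtype=float), np.asarray(sw_m, dtype=float)
    _check_dims(sw_i, sw_m)
    if not 0.0 <= cr <= 1.0:
        raise ValueError("cr must lie in [0, 1]")
    take = rng.uniform(size=sw_i.shape) < cr
    return np.where(take, sw_m, sw_i)


def reduce_population(n_initial: int, n_min: int, t: int, t_max: int) -> int:
    """Population-size schedule: interpolate from the initial size down to
    ``n_min`` as iterations advance.

    Returns ``round(n_min + (n_initial - n_min) * k)`` with
    ``k = (t_max - t) / t_max`` (round half away from zero), clamped to be
    at least ``n_min``.  Monotone non-increasing in t.
    """
    if n_min > n_initial:
        raise ValueError("n_min must not exceed the initial population size")
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    k = max(0.0, (t_max - t) / t_max)
    raw = n_min + (n_initial - n_min) * k
    rounded = int(np.floor(raw + 0.5))  # half away from zero (values are >= 0)
    return max(n_min, rounded)


def clip_to_bounds(position: np.ndarray, bounds: Bounds) -> np.ndarray:
    """Project each component onto the box [low, high]."""
    return np.clip(np.asarray(position, dtype=float), bounds.low, bounds.high)


def escape_threshold(bounds: Bounds, t: int, t_max: int, scale: float = 0.5) -> float:
    """Distance beyond which the prey counts as escaped:
    ``scale * ||H - L|| * (1 - t / t_max)`` — scale-aware and tightening
    over time."""
    return scale * float(np.linalg.norm(bounds.span)) * max(0.0, 1.0 - t / t_max)
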