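"""Quality indicators for Pareto-front approximations.

- IGD: mean distance from reference-front points to their nearest
  approximation point (lower is better).
- Hypervolume: exact Lebesgue measure of the region dominated by the
  approximation set and bounded by a reference point, for 2 or 3
  objectives (higher is better).
- Spread (Delta): diversity of the approximation along the front, 0 for a
  perfectly uniform set spanning the extremes (lower is better).

Benchmark reporting normalizes objectives by the analytic front's ideal
and nadir points and uses the reference point 1.1 per objective, so a
dense sample of the ZDT1 front scores HV = 0.1 + 2/3 + 0.11 ~= 0.8767.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "igd",
    "hypervolume",
    "spread",
    "normalize_objectives",
    "MetricReport",
    "summarize_runs",
]


def igd(approx: np.ndarray, reference: np.ndarray) -> float:
    """Inverted generational distance of ``approx`` w.r.t. ``reference``."""
    approx = np.atleast_2d(np.asarray(approx, dtype=float))
    reference = np.atleast_2d(np.asarray(reference, dtype=float))
    if approx.size == 0 or reference.size == 0:
        raise ValueError("IGD needs non-empty point sets")
    if approx.shape[1] != reference.shape[1]:
        raise ValueError("objective dimensionality mismatch")
    dists, _ = cKDTree(approx).query(reference)
    return float(np.mean(dists))


def _hv2d(points: np.ndarray, ref: np.ndarray) -> float:
    mask = np.all(points < ref, axis=1)
    pts = points[mask]
    if len(pts) == 0:
        return 0.0
    # sort by f1 ascending; staircase sweep keeping the running best f2
    pts = pts[np.lexsort((pts[:, 1], pts[:, 0]))]
    hv = 0.0
    prev_f2 = ref[1]
    for f1, f2 in pts:
        if f2 < prev_f2:
            hv += (ref[0] - f1) * (prev_f2 - f2)
            prev_f2 = f2
    return hv


def _hv3d(points: np.ndarray, ref: np.ndarray) -> float:
    mask = np.all(points < ref, axis=1)
    pts = points[mask]
    if len(pts) == 0:
        return 0.0
    # slice along f3: between consecutive f3 levels the dominated 2-D
    # region is fixed, so integrate 2-D hypervolume over the slabs
    order = np.argsort(pts[:, 2], kind="stable")
    pts = pts[order]
    levels = np.append(pts[:, 2], ref[2])
    hv = 0.0
    for i in range(len(pts)):
        depth = levels[i + 1] - levels[i]
        if depth <= 0:
            continue
        active = pts[: i + 1, :2]
        hv += depth * _hv2d(active, ref[:2])
    return hv


def hypervolume(approx: np.ndarray, ref_point: np.ndarray) -> float:
    """Exact hypervolume for 2- or 3-objective point sets.

    Points not strictly dominating the reference point are ignored; an
    empty contributing set scores 0.
    """
    approx = np.atleast_2d(np.asarray(approx, dtype=float))
    ref = np.asarray(ref_point, dtype=float)
    m = approx.shape[1]
    if m != ref.size:
        raise ValueError("reference point dimensionality mismatch")
    if m == 2:
        return _hv2d(approx, ref)
    if m == 3:
        return _hv3d(approx, ref)
    raise ValueError("exact hypervolume implemented for 2 or 3 objectives only")


def spread(approx: np.ndarray, extremes: np.ndarray) -> float:
    """Delta diversity metric of a front approximation.

    For two objectives: sort along the front, take consecutive Euclidean
    gaps d_i, the distances d_f/d_l from the supplied extreme points to
    the boundary solutions, and return
    (d_f + d_l + sum|d_i - dbar|) / (d_f + d_l + (n-1) dbar).
    For three objectives the generalized form uses each point's
    nearest-neighbour distance and the distances from the M extreme
    points to the approximation.  Fewer than 3 points is undefined and
    returns infinity with a warning.
    """
    approx = np.atleast_2d(np.asarray(approx, dtype=float))
    extremes = np.atleast_2d(np.asarray(extremes, dtype=float))
    n = len(approx)
    if n < 3:
        warnings.warn("spread undefined for fewer than 3 points", stacklevel=2)
        return float("inf")
    m = approx.shape[1]
    if m == 2:
        order = np.lexsort((approx[:, 1], approx[:, 0]))
        pts = approx[order]
        gaps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        dbar = gaps.mean()
        ext_sorted = extremes[np.lexsort((extremes[:, 1], extremes[:, 0]))]
        d_f = float(np.linalg.norm(ext_sorted[0] - pts[0]))
        d_l = float(np.linalg.norm(ext_sorted[-1] - pts[-1]))
        num = d_f + d_l + float(np.sum(np.abs(gaps - dbar)))
        den = d_f + d_l + (n - 1) * dbar
        return num / den if den > 0 else 0.0
    # generalized Delta: nearest-neighbour distances within the set
    dists, _ = cKDTree(approx).query(approx, k=2)
    nn = dists[:, 1]
    dbar = nn.mean()
    d_ext = cKDTree(approx).query(extremes)[0]
    num = float(np.sum(d_ext)) + float(np.sum(np.abs(nn - dbar)))
    den = float(np.sum(d_ext)) + n * dbar
    return num / den if den > 0 else 0.0


def normalize_objectives(
    points: np.ndarray, ideal: np.ndarray, nadir: np.ndarray
) -> np.ndarray:
    """Affine-map objectives so the front spans [0, 1] per objective."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    span = np.asarray(nadir, dtype=float) - np.asarray(ideal, dtype=float)
    span = np.where(span <= 0, 1.0, span)
    return (points - np.asarray(ideal, dtype=float)) / span


@dataclass
class MetricReport:
    """Per-run indicator values with summary statistics over the runs."""

    values: dict[str, list[float]]
    seeds: list[int] = field(default_factory=list)

    @property
    def n_runs(self) -> int:
        return len(next(iter(self.values.values())))

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, vals in self.values.items():
            arr = np.asarray(vals, dtype=float)
            rows.append(
                {
                    "metric": name,
                    "mean": float(arr.mean()),
                    "std": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
                    "min": float(arr.min()),
                    "max": float(arr.max()),
                    "runs": arr.size,
                }
            )
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values)
        if self.seeds:
            df.insert(0, "seed", self.seeds)
        return df


def summarize_runs(
    per_run: dict[str, list[float]], seeds: list[int] | None = None
) -> MetricReport:
    """Bundle per-run metric values into a report with mean/std/min/max."""
    lengths = {len(v) for v in per_run.values()}
    if not per_run or lengths == {0}:
        raise ValueError("need at least one run")
    if len(lengths) != 1:
        raise ValueError("all metrics must cover the same runs")
    return MetricReport(values={k: list(v) for k, v in per_run.items()},
                        seeds=list(seeds) if seeds else [])
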