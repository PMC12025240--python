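"""Benchmark campaigns: repeated seeded runs per problem with indicator
summaries in comparison-ready tables.

The standard protocol is population 100 with 10,000 evaluations on the
bi-objective ZDT problems and 20,000 on the three-objective DTLZ problems,
25 independent runs each; per-run IGD, hypervolume and spread are computed
against the analytic front, with hypervolume taken on ideal/nadir
normalized objectives against the reference point 1.1 per objective.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .benchmarks import get_problem, sample_true_front
from .engine import MOSWOConfig, run
from .metrics import hypervolume, igd, normalize_objectives, spread, summarize_runs
from .operators import OperatorParams
from .pareto import write_archive

__all__ = ["CampaignSpec", "run_campaign", "evaluate_archive", "DEFAULT_BUDGETS"]

DEFAULT_BUDGETS = {"zdt": 10_000, "dtlz": 20_000}
_REF_POINT = 1.1
_IGD_REF_SIZE = {2: 1_000, 3: 5_000}


@dataclass
class CampaignSpec:
    """What to run: problems, repetitions, budgets, seeds, output dir."""

    problems: list[str]
    runs: int = 25
    pop_size: int = 100
    budgets: dict = field(default_factory=lambda: dict(DEFAULT_BUDGETS))
    base_seed: int = 0
    out_dir: str | Path | None = None
    params: OperatorParams = field(default_factory=OperatorParams)

    def __post_init__(self) -> None:
        if self.runs < 1:
            raise ValueError("need at least one run")
        if any(b <= 0 for b in self.budgets.values()):
            raise ValueError("budgets must be positive")

    def budget_for(self, problem_name: str) -> int:
        family = "dtlz" if problem_name.lower().startswith("dtlz") else "zdt"
        return int(self.budgets.get(problem_name, self.budgets[family]))

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def evaluate_archive(objectives: np.ndarray, problem_name: str) -> dict[str, float]:
    """IGD, normalized hypervolume and spread of one archive against the
    problem's analytic front."""
    problem = get_problem(problem_name)
    front = sample_true_front(problem, _IGD_REF_SIZE[problem.n_obj])
    ideal, nadir = front.min(axis=0), front.max(axis=0)
    norm = normalize_objectives(objectives, ideal, nadir)
    ref = np.full(problem.n_obj, _REF_POINT)
    if problem.n_obj == 2:
        extremes = np.array([front[0], front[-1]])
        extremes_n = normalize_objectives(extremes, ideal, nadir)
    else:
        extremes = front[np.argmax(front, axis=0)]
        extremes_n = normalize_objectives(extremes, ideal, nadir)
    return {
        "igd": igd(objectives, front),
        "hv": hypervolume(norm, ref),
        "spread": spread(norm, extremes_n),
        "archive_size": float(len(objectives)),
    }


def run_campaign(spec: CampaignSpec) -> dict[str, pd.DataFrame]:
    """Execute the campaign; returns one per-run metric table per problem
    plus a summary table under the key ``"summary"``.

    When ``spec.out_dir`` is set, per-run archives and metric rows are
    written as they complete (atomically, one file per run), so an
    interrupted campaign resumes from the finished runs on re-invocation.
    The summary embeds the seed list and a hash of the spec.
    """
    out = Path(spec.out_dir) if spec.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    tables: dict[str, pd.DataFrame] = {}
    summary_rows = []
    for name in spec.problems:
        problem = get_problem(name)
        budget = spec.budget_for(name)
        rows = []
        for r in range(spec.runs):
            seed = spec.base_seed + r
            run_file = out / f"{name}_run{r:03d}.json" if out else None
            if run_file and run_file.exists():
                rows.append(json.loads(run_file.read_text()))
                continue
            cfg = MOSWOConfig(
                pop_size=spec.pop_size, budget=budget, seed=seed, params=spec.params
            )
            result = run(problem, cfg)
            metrics = evaluate_archive(result.archive.objectives(), name)
            row = {"problem": name, "run": r, "seed": seed,
                   "evaluations": result.evaluations, **metrics}
            rows.append(row)
            if out:
                write_archive(result.archive, out / f"{name}_run{r:03d}_archive.csv",
                              run_id=f"{name}-{seed}")
                tmp = run_file.with_suffix(".tmp")
                tmp.write_text(json.dumps(row))
                tmp.replace(run_file)  # atomic per-run completion marker
        df = pd.DataFrame(rows)
        tables[name] = df
        report = summarize_runs(
            {k: df[k].tolist() for k in ("igd", "hv", "spread", "archive_size")},
            seeds=df["seed"].tolist(),
        )
        for _, srow in report.summary().iterrows():
            summary_rows.append({"problem": name, **srow.to_dict()})
        if out:
            df.to_csv(out / f"{name}_runs.csv", index=False)
    summary = pd.DataFrame(summary_rows)
    tables["summary"] = summary
    if out:
        summary.to_csv(out / "summary.csv", index=False)
        digest = {
            "config_hash": spec.config_hash(),
            "base_seed": spec.base_seed,
            "runs": spec.runs,
            "problems": spec.problems,
            "seeds": list(range(spec.base_seed, spec.base_seed + spec.runs)),
            "mean": {
                name: tables[name][["igd", "hv", "spread"]].mean().to_dict()
                for name in spec.problems
            },
        }
        (out / "digest.json").write_text(json.dumps(digest, indent=2))
    return tables
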