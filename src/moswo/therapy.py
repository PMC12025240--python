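"""Drug-regimen design: efficacy/safety/cost objectives over a dose-schedule
decision vector, scored against a pharmacokinetic/pharmacodynamic cohort.

A candidate therapy is a four-slot regimen — primary drug dose (mg), dosing
interval (h), companion drug dose (mg), treatment duration (weeks).  The
cohort is a table of per-patient dose -> exposure (Cmax, Tmax, AUC) ->
response (therapeutic effect %, toxicity grade, therapeutic index) rows;
a synthetic generator emulates that schema with one-compartment kinetics
and a saturating Emax exposure-response curve.

The three objectives follow the deduction form
    E(SW) = E_max - w1 * AE(SW)      (efficacy minus adverse effect)
    S(SW) = S_max - w2 * AR(SW)      (safety minus adverse-reaction burden)
    C(SW) = C_max - w3 * Cost(SW)    (budget minus regimen cost)
with AE the cohort-model predicted response shortfall (100 - effect %), AR
the expected toxicity grade, and Cost the drug-acquisition plus care cost.
Internally the optimizer minimizes (w1*AE, w2*AR, w3*Cost); reports carry
both conventions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .benchmarks import Problem
from .operators import Bounds

__all__ = [
    "RegimenVector",
    "ObjectiveWeights",
    "PKPDRecord",
    "Cohort",
    "CohortGeneratorParams",
    "CohortModel",
    "generate_cohort",
    "read_cohort",
    "write_cohort",
    "efficacy",
    "safety",
    "cost",
    "regimen_problem",
    "RegimenEncoder",
    "REGIMEN_BOUNDS",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class RegimenVector:
    """One therapy regimen: the four decision slots of the optimizer."""

    dose_a: float  # primary drug dose per administration, mg
    interval: float  # dosing interval, hours
    dose_b: float  # companion drug dose per administration, mg
    duration: float  # treatment duration, weeks

    def __post_init__(self) -> None:
        if self.interval <= 0:
            raise ValueError("dosing interval must be positive")
        if self.duration < 1:
            raise ValueError("duration must be at least one week")

    def to_array(self) -> np.ndarray:
        return np.array([self.dose_a, self.interval, self.dose_b, self.duration])

    @classmethod
    def from_array(cls, x: np.ndarray) -> "RegimenVector":
        return cls(dose_a=float(x[0]), interval=float(x[1]),
                   dose_b=float(x[2]), duration=float(x[3]))


#: default decision-space box: dose_a 50-300 mg, interval 4-24 h,
#: dose_b 0-200 mg, duration 1-12 weeks
REGIMEN_BOUNDS = Bounds(
    low=np.array([50.0, 4.0, 0.0, 1.0]),
    high=np.array([300.0, 24.0, 200.0, 12.0]),
)


@dataclass
class ObjectiveWeights:
    """Scale constants and weights of the three regimen objectives.

    e_max is on the percent-effect scale, s_max on the toxicity-grade
    scale, c_max in cost units (arbitrary currency).  Weights inside a
    Pareto method do not change the Pareto set for positive weights; they
    are kept because the objective form is written with them and they let
    a user re-scale single objectives in reports.
    """

    e_max: float = 100.0
    s_max: float = 3.0
    c_max: float = 5000.0
    w1: float = 1.0
    w2: float = 1.0
    w3: float = 1.0
    price_a: float = 0.08  # currency per mg of drug A
    price_b: float = 0.05  # currency per mg of drug B
    weekly_care_cost: float = 40.0

    def __post_init__(self) -> None:
        if min(self.w1, self.w2, self.w3) < 0:
            raise ValueError("weights must be non-negative")
        if min(self.e_max, self.s_max, self.c_max) <= 0:
            raise ValueError("scale constants must be positive")
        if min(self.price_a, self.price_b) < 0 or self.weekly_care_cost < 0:
            raise ValueError("prices must be non-negative")


@dataclass
class PKPDRecord:
    """One patient's dose -> exposure -> response row."""

    patient_id: str
    dose_a: float
    dose_b: float
    c_max: float
    t_max: float
    auc: float
    effect: float
    toxicity: int
    therapeutic_index: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.effect <= 100.0:
            raise ValueError(f"effect must be in [0, 100], got {self.effect}")
        if self.toxicity not in (1, 2, 3):
            raise ValueError(f"toxicity grade must be 1, 2 or 3, got {self.toxicity}")
        if min(self.c_max, self.auc, self.dose_a, self.dose_b) < 0:
            raise ValueError("doses and concentrations must be non-negative")
        if self.therapeutic_index <= 0:
            raise ValueError("therapeutic index must be positive")


@dataclass
class Cohort:
    """A set of PK/PD records plus the provenance of how it was made."""

    records: list[PKPDRecord]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("cohort must contain at least one record")
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("patient ids must be unique")

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.records])


# ---------------------------------------------------------------------------
# synthetic cohort generator
# ---------------------------------------------------------------------------

@dataclass
class CohortGeneratorParams:
    """Ground-truth parameters of the synthetic PK/PD cohort.

    Exposure follows one-compartment kinetics: Cmax and AUC are
    proportional to the synergy-weighted dose with lognormal
    inter-patient variability.  Response follows a saturating Emax curve
    of AUC with additive observation noise; toxicity grade thresholds the
    (noisy) exposure.  Defaults are calibrated so generated rows match
    the magnitudes of a typical dose-finding table (doses 100-200 /
    50-150 mg, AUC ~1200-1800 ng.h/mL, effects 80-95%).
    """

    dose_a_levels: tuple = (100.0, 150.0, 200.0)
    dose_b_levels: tuple = (50.0, 75.0, 100.0, 125.0, 150.0)
    synergy: float = 0.5  # mg of drug B equivalent to 1 mg of drug A
    auc_per_mg: float = 8.0  # ng.h/mL per effective mg
    cmax_per_mg: float = 1.1  # ng/mL per effective mg
    t_max_mean: float = 2.0  # h
    pk_cv: float = 0.12  # lognormal sigma of inter-patient PK variability
    emax: float = 100.0  # ceiling of the exposure-response curve, %
    ec50: float = 220.0  # AUC at half-maximal effect, ng.h/mL
    effect_noise_sd: float = 2.0  # additive observation noise, %
    tox_threshold_1: float = 1375.0  # AUC above which grade >= 2
    tox_threshold_2: float = 1550.0  # AUC above which grade == 3
    tox_noise_sd: float = 75.0  # latent exposure noise in the grading


def generate_cohort(
    n: int,
    params: CohortGeneratorParams | None = None,
    seed: int | None = None,
) -> Cohort:
    """Generate a synthetic cohort of ``n`` patients.

    Dose pairs are sampled on the level grid; exposure, response and
    toxicity follow the generator model above.  The therapeutic index is
    the patient's toxic-dose estimate over their effective-dose estimate,
    both derived from the patient's own exposure coefficient.
    """
    if n < 1:
        raise ValueError("need at least one patient")
    p = params or CohortGeneratorParams()
    rng = np.random.default_rng(seed)
    records: list[PKPDRecord] = []
    for i in range(n):
        dose_a = float(rng.choice(p.dose_a_levels))
        dose_b = float(rng.choice(p.dose_b_levels))
        eff_dose = dose_a + p.synergy * dose_b
        pk_factor = float(np.exp(rng.normal(0.0, p.pk_cv)))
        auc = p.auc_per_mg * eff_dose * pk_factor
        c_max = p.cmax_per_mg * eff_dose * float(np.exp(rng.normal(0.0, p.pk_cv)))
        t_max = p.t_max_mean * float(np.exp(rng.normal(0.0, 0.1)))
        effect = p.emax * auc / (p.ec50 + auc) + rng.normal(0.0, p.effect_noise_sd)
        effect = float(np.clip(effect, 0.0, 100.0))
        latent = auc + rng.normal(0.0, p.tox_noise_sd)
        toxicity = 1 + int(latent > p.tox_threshold_1) + int(latent > p.tox_threshold_2)
        # safety margin: dose reaching the severe-toxicity exposure over
        # the dose reaching half-maximal effect.  Under linear kinetics
        # the ratio is a drug property (threshold/EC50); per-patient
        # variation comes from the two dose estimates being measured
        # under independent PK noise
        toxic_dose = p.tox_threshold_2 / (p.auc_per_mg * np.exp(rng.normal(0.0, p.pk_cv)))
        effective_dose = p.ec50 / (p.auc_per_mg * np.exp(rng.normal(0.0, p.pk_cv)))
        ti = toxic_dose / effective_dose
        records.append(
            PKPDRecord(
                patient_id=f"{i + 1:03d}",
                dose_a=dose_a,
                dose_b=dose_b,
                c_max=round(c_max, 1),
                t_max=round(t_max, 2),
                auc=round(auc, 1),
                effect=round(effect, 1),
                toxicity=toxicity,
                therapeutic_index=round(ti, 1),
            )
        )
    return Cohort(records=records, provenance={"generator": asdict(p), "seed": seed, "n": n})


# ---------------------------------------------------------------------------
# cohort file I/O (standard PK/PD sample-table schema)
# ---------------------------------------------------------------------------

_COLUMNS = {
    "patientid": "patient_id",
    "drugadosemg": "dose_a",
    "drugbdosemg": "dose_b",
    "cmaxngml": "c_max",
    "tmaxh": "t_max",
    "aucnghml": "auc",
    "therapeuticeffect": "effect",
    "toxicitylevelgrade": "toxicity",
    "therapeuticindexti": "therapeutic_index",
}

_HEADERS = {
    "patient_id": "Patient ID",
    "dose_a": "Drug A Dose (mg)",
    "dose_b": "Drug B Dose (mg)",
    "c_max": "Cmax (ng/mL)",
    "t_max": "Tmax (h)",
    "auc": "AUC (ng·h/mL)",
    "effect": "Therapeutic Effect (%)",
    "toxicity": "Toxicity Level (Grade)",
    "therapeutic_index": "Therapeutic Index (TI)",
}


def _canon(header: str) -> str:
    return re.sub(r"[^a-z0-9]", "", header.lower())


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort as a CSV with the standard PK/PD header names."""
    df = cohort.to_frame().rename(columns=_HEADERS)
    df.to_csv(path, index=False)


def read_cohort(path) -> Cohort:
    """Read a PK/PD cohort file (header-driven, order- and case-insensitive).

    Missing columns raise a schema error; malformed cells raise an error
    naming the offending row.
    """
    df = pd.read_csv(path, dtype=str)
    mapping = {}
    for col in df.columns:
        key = _canon(col)
        for pattern, target in _COLUMNS.items():
            if key.startswith(pattern) or pattern.startswith(key):
                mapping[col] = target
                break
    missing = set(_COLUMNS.values()) - set(mapping.values())
    if missing:
        raise ValueError(f"cohort file is missing columns: {sorted(missing)}")
    df = df.rename(columns=mapping)
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                PKPDRecord(
                    patient_id=str(row["patient_id"]),
                    dose_a=float(row["dose_a"]),
                    dose_b=float(row["dose_b"]),
                    c_max=float(row["c_max"]),
                    t_max=float(row["t_max"]),
                    auc=float(row["auc"]),
                    effect=float(row["effect"]),
                    toxicity=int(float(row["toxicity"])),
                    therapeutic_index=float(row["therapeutic_index"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed cohort row {i + 2} (1-based, incl. header): {exc}") from exc
    return Cohort(records=records, provenance={"source": str(path)})


# ---------------------------------------------------------------------------
# fitted cohort model: regimen -> predicted exposure/response
# ---------------------------------------------------------------------------

@dataclass
class CohortModel:
    """Exposure and response predictors fitted to a cohort.

    Exposure is linear in the two doses (least squares); the response is
    a saturating Emax curve of AUC; the toxicity expectation interpolates
    smoothly between the fitted grade thresholds.  All predictions are
    pure functions of the fitted coefficients.
    """

    auc_coef: np.ndarray  # per-mg AUC contribution of (dose_a, dose_b)
    cmax_coef: np.ndarray
    emax: float
    ec50: float
    tox_thresholds: tuple[float, float]
    tox_scale: float = 60.0
    reference_interval: float = 12.0  # h; the cohort's implied schedule

    @classmethod
    def fit(cls, cohort: Cohort) -> "CohortModel":
        df = cohort.to_frame()
        doses = df[["dose_a", "dose_b"]].to_numpy(dtype=float)
        auc_coef, *_ = np.linalg.lstsq(doses, df["auc"].to_numpy(dtype=float), rcond=None)
        cmax_coef, *_ = np.linalg.lstsq(doses, df["c_max"].to_numpy(dtype=float), rcond=None)

        auc = df["auc"].to_numpy(dtype=float)
        effect = df["effect"].to_numpy(dtype=float)
        try:
            (emax, ec50), _ = curve_fit(
                lambda a, emax, ec50: emax * a / (ec50 + a),
                auc, effect, p0=(100.0, np.median(auc) / 4),
                bounds=([1.0, 1.0], [100.0, 1e6]), maxfev=10_000,
            )
        except RuntimeError:  # tiny or degenerate cohorts
            emax, ec50 = float(effect.max()), float(np.median(auc))

        grades = df["toxicity"].to_numpy(dtype=int)
        thresholds = []
        for lo, hi in ((1, 2), (2, 3)):
            a_lo = auc[grades == lo]
            a_hi = auc[grades == hi]
            if a_lo.size and a_hi.size:
                thresholds.append(0.5 * (a_lo.mean() + a_hi.mean()))
            else:  # grade absent from the cohort: threshold beyond the data
                thresholds.append(float(auc.max()) * (1.5 if hi == 3 else 1.2))
        return cls(
            auc_coef=np.asarray(auc_coef),
            cmax_coef=np.asarray(cmax_coef),
            emax=float(emax),
            ec50=float(ec50),
            tox_thresholds=(float(thresholds[0]), float(thresholds[1])),
        )

    # -- per-regimen predictions ------------------------------------------

    def predicted_auc(self, regimen: RegimenVector) -> float:
        """Daily exposure relative to the cohort's reference schedule."""
        per_dose = float(
            self.auc_coef[0] * regimen.dose_a + self.auc_coef[1] * regimen.dose_b
        )
        return per_dose * self.reference_interval / regimen.interval

    def predicted_cmax(self, regimen: RegimenVector) -> float:
        return float(
            self.cmax_coef[0] * regimen.dose_a + self.cmax_coef[1] * regimen.dose_b
        )

    def predicted_effect(self, regimen: RegimenVector) -> float:
        a = self.predicted_auc(regimen)
        return float(np.clip(self.emax * a / (self.ec50 + a), 0.0, 100.0))

    def adverse_effect(self, regimen: RegimenVector) -> float:
        """AE: response shortfall, 100 minus the predicted effect %."""
        return 100.0 - self.predicted_effect(regimen)

    def adverse_reaction(self, regimen: RegimenVector) -> float:
        """AR: expected toxicity grade (1..3) at the predicted exposure."""
        a = self.predicted_auc(regimen)
        t1, t2 = self.tox_thresholds
        s = self.tox_scale
        sig = lambda z: 1.0 / (1.0 + np.exp(-z))  # noqa: E731
        return float(1.0 + sig((a - t1) / s) + sig((a - t2) / s))

    def therapeutic_index(self, regimen: RegimenVector | None = None) -> float:
        """Toxic-dose / effective-dose ratio implied by the fitted model.

        With exposure linear in dose the per-mg coefficient cancels, so
        the ratio reduces to severe-toxicity threshold over EC50 — a
        safety margin of the drug combination itself, independent of the
        particular schedule (the optional regimen argument is accepted
        for interface symmetry with the other predictors).
        """
        return self.tox_thresholds[1] / self.ec50


# ---------------------------------------------------------------------------
# objectives
# ---------------------------------------------------------------------------

def _model_for(cohort: Cohort, model: CohortModel | None) -> CohortModel:
    return model if model is not None else CohortModel.fit(cohort)


def efficacy(
    regimen: RegimenVector,
    cohort: Cohort,
    weights: ObjectiveWeights,
    model: CohortModel | None = None,
) -> float:
    """E(SW) = E_max - w1 * AE(SW); higher is better."""
    m = _model_for(cohort, model)
    return weights.e_max - weights.w1 * m.adverse_effect(regimen)


def safety(
    regimen: RegimenVector,
    cohort: Cohort,
    weights: ObjectiveWeights,
    model: CohortModel | None = None,
) -> float:
    """S(SW) = S_max - w2 * AR(SW); higher is better."""
    m = _model_for(cohort, model)
    return weights.s_max - weights.w2 * m.adverse_reaction(regimen)


def regimen_cost(regimen: RegimenVector, weights: ObjectiveWeights) -> float:
    """Raw cost of the regimen: drug acquisition plus weekly care."""
    doses_per_course = regimen.duration * 7.0 * 24.0 / regimen.interval
    return (
        regimen.dose_a * weights.price_a * doses_per_course
        + regimen.dose_b * weights.price_b * doses_per_course
        + weights.weekly_care_cost * regimen.duration
    )


def cost(regimen: RegimenVector, weights: ObjectiveWeights) -> float:
    """C(SW) = C_max - w3 * Cost(SW); higher is better (cheaper)."""
    return weights.c_max - weights.w3 * regimen_cost(regimen, weights)


# ---------------------------------------------------------------------------
# encoding and the optimization problem
# ---------------------------------------------------------------------------

@dataclass
class RegimenEncoder:
    """Affine map between regimens and normalized [0, 1]^4 positions."""

    bounds: Bounds = field(default_factory=lambda: REGIMEN_BOUNDS)

    def encode(self, regimen: RegimenVector) -> np.ndarray:
        x = regimen.to_array()
        clipped = np.clip(x, self.bounds.low, self.bounds.high)
        if not np.allclose(clipped, x):
            import warnings

            warnings.warn("regimen outside bounds was clipped before encoding",
                          stacklevel=2)
        return (clipped - self.bounds.low) / self.bounds.span

    def decode(self, z: np.ndarray) -> RegimenVector:
        z = np.clip(np.asarray(z, dtype=float), 0.0, 1.0)
        return RegimenVector.from_array(self.bounds.low + z * self.bounds.span)


def regimen_problem(
    cohort: Cohort,
    weights: ObjectiveWeights | None = None,
    bounds: Bounds | None = None,
    cmax_ceiling: float | None = None,
) -> Problem:
    """Wrap the three therapy objectives as a minimization problem.

    Internal objectives are (w1*AE, w2*AR, w3*Cost) — smaller is better,
    equivalent to maximizing (E, S, C).  The exposure constraint
    ``predicted Cmax <= ceiling`` maps to an aggregate violation measure
    consumed by the feasibility-first dominance rule; the default ceiling
    is 1.5x the cohort's highest observed Cmax.
    """
    w = weights or ObjectiveWeights()
    box = bounds or REGIMEN_BOUNDS
    if not np.all(box.low < box.high):
        raise ValueError("infeasible regimen bounds")
    model = CohortModel.fit(cohort)
    ceiling = cmax_ceiling
    if ceiling is None:
        ceiling = 1.5 * max(r.c_max for r in cohort.records)

    def evaluate(x: np.ndarray) -> np.ndarray:
        r = RegimenVector.from_array(x)
        return np.array(
            [
                w.w1 * model.adverse_effect(r),
                w.w2 * model.adverse_reaction(r),
                w.w3 * regimen_cost(r, w),
            ]
        )

    def violation(x: np.ndarray) -> float:
        r = RegimenVector.from_array(x)
        excess = model.predicted_cmax(r) - ceiling
        return max(0.0, excess / ceiling)

    return Problem(
        name="drug_regimen",
        dim=4,
        n_obj=3,
        bounds=box,
        evaluate=evaluate,
        true_front=None,
        constraints=violation,
    )
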