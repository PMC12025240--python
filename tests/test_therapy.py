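"""Drug-regimen layer: objectives, synthetic cohort generator, cohort file
I/O, encoding, and the wrapped optimization problem."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from moswo.engine import MOSWOConfig, run
from moswo.operators import Bounds
from moswo.therapy import (
    REGIMEN_BOUNDS,
    Cohort,
    CohortGeneratorParams,
    CohortModel,
    ObjectiveWeights,
    PKPDRecord,
    RegimenEncoder,
    RegimenVector,
    cost,
    efficacy,
    generate_cohort,
    read_cohort,
    regimen_cost,
    regimen_problem,
    safety,
    write_cohort,
)


class FixedModel(CohortModel):
    """Predictor stub with pinned AE/AR values for arithmetic checks."""

    def __init__(self, ae, ar):
        self._ae, self._ar = ae, ar

    def adverse_effect(self, regimen):
        return self._ae

    def adverse_reaction(self, regimen):
        return self._ar


@pytest.fixture
def regimen():
    return RegimenVector(dose_a=100.0, interval=12.0, dose_b=50.0, duration=4.0)


class TestObjectiveArithmetic:
    def test_zero_adverse_effect_gives_full_efficacy(self, small_cohort, regimen):
        w = ObjectiveWeights(e_max=100.0, w1=1.0)
        assert efficacy(regimen, small_cohort, w, model=FixedModel(0.0, 1.0)) == 100.0

    def test_efficacy_deduction(self, small_cohort, regimen):
        w = ObjectiveWeights(e_max=100.0, w1=1.0)
        assert efficacy(regimen, small_cohort, w, model=FixedModel(15.0, 1.0)) == 85.0

    def test_safety_deduction(self, small_cohort, regimen):
        w = ObjectiveWeights(s_max=10.0, w2=2.0)
        assert safety(regimen, small_cohort, w, model=FixedModel(0.0, 1.5)) == 7.0

    def test_doubling_weight_doubles_deduction(self, small_cohort, regimen):
        w1 = ObjectiveWeights(s_max=10.0, w2=1.0)
        w2 = ObjectiveWeights(s_max=10.0, w2=2.0)
        m = FixedModel(0.0, 1.2)
        d1 = 10.0 - safety(regimen, small_cohort, w1, model=m)
        d2 = 10.0 - safety(regimen, small_cohort, w2, model=m)
        assert d2 == pytest.approx(2 * d1)

    def test_cost_single_dose_arithmetic(self):
        # one dose total: duration such that duration*7*24/interval == 1
        reg = RegimenVector(dose_a=100.0, interval=168.0, dose_b=50.0, duration=1.0)
        w = ObjectiveWeights(c_max=1000.0, w3=1.0, price_a=1.0, price_b=1.0,
                             weekly_care_cost=0.0)
        assert regimen_cost(reg, w) == pytest.approx(150.0)
        assert cost(reg, w) == pytest.approx(850.0)

    def test_cost_increases_with_duration(self):
        w = ObjectiveWeights()
        costs = [
            regimen_cost(RegimenVector(100, 12, 50, d), w) for d in (1, 4, 8, 12)
        ]
        assert all(a < b for a, b in zip(costs, costs[1:]))


class TestGenerator:
    def test_fixed_seed_reproducible(self):
        a = generate_cohort(25, seed=3)
        b = generate_cohort(25, seed=3)
        assert a.to_frame().equals(b.to_frame())

    def test_records_satisfy_invariants(self):
        cohort = generate_cohort(300, seed=11)
        df = cohort.to_frame()
        assert df["effect"].between(0, 100).all()
        assert df["toxicity"].isin([1, 2, 3]).all()
        assert (df[["c_max", "auc", "dose_a", "dose_b"]] >= 0).all().all()
        assert df["patient_id"].is_unique

    def test_effect_increases_with_exposure(self):
        cohort = generate_cohort(500, seed=19)
        df = cohort.to_frame()
        rho, _ = spearmanr(df["auc"], df["effect"])
        assert rho > 0.5

    def test_toxicity_increases_with_exposure(self):
        df = generate_cohort(500, seed=23).to_frame()
        assert df.groupby("toxicity")["auc"].mean().is_monotonic_increasing

    def test_dose_grid_matches_schema(self):
        df = generate_cohort(200, seed=2).to_frame()
        assert set(df["dose_a"].unique()) <= {100.0, 150.0, 200.0}
        assert set(df["dose_b"].unique()) <= {50.0, 75.0, 100.0, 125.0, 150.0}


class TestCohortIO:
    def test_reference_sample_row_parses(self, tmp_path):
        path = tmp_path / "sample.csv"
        path.write_text(
            "Patient ID,Drug A Dose (mg),Drug B Dose (mg),Cmax (ng/mL),Tmax (h),"
            "AUC (ng·h/mL),Therapeutic Effect (%),Toxicity Level (Grade),"
            "Therapeutic Index (TI)\n"
            "001,100,50,150,2,1200,85,1,1200\n"
        )
        cohort = read_cohort(path)
        rec = cohort.records[0]
        assert rec.patient_id == "001"
        assert rec.dose_a == 100 and rec.dose_b == 50
        assert rec.c_max == 150 and rec.t_max == 2 and rec.auc == 1200
        assert rec.effect == 85 and rec.toxicity == 1
        assert rec.therapeutic_index == 1200

    def test_write_then_read_round_trip(self, tmp_path, small_cohort):
        path = tmp_path / "cohort.csv"
        write_cohort(small_cohort, path)
        loaded = read_cohort(path)
        a = small_cohort.to_frame().reset_index(drop=True)
        b = loaded.to_frame().reset_index(drop=True)
        for col in ("dose_a", "dose_b", "c_max", "t_max", "auc", "effect"):
            np.testing.assert_allclose(a[col], b[col])
        assert a["toxicity"].tolist() == b["toxicity"].tolist()

    def test_shuffled_columns_parse_identically(self, tmp_path, small_cohort):
        path = tmp_path / "cohort.csv"
        write_cohort(small_cohort, path)
        import pandas as pd

        df = pd.read_csv(path, dtype=str)  # preserve id formatting
        shuffled = tmp_path / "shuffled.csv"
        df[list(df.columns[::-1])].to_csv(shuffled, index=False)
        a = read_cohort(path).to_frame()
        b = read_cohort(shuffled).to_frame()
        assert a.equals(b)

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "broken.csv"
        path.write_text("Patient ID,Drug A Dose (mg)\n001,100\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_cohort(path)

    def test_malformed_row_names_row_number(self, tmp_path, small_cohort):
        path = tmp_path / "cohort.csv"
        write_cohort(small_cohort, path)
        lines = path.read_text().splitlines()
        parts = lines[3].split(",")
        parts[3] = "not-a-number"
        lines[3] = ",".join(parts)
        path.write_text("\n".join(lines))
        with pytest.raises(ValueError, match="row 4"):
            read_cohort(path)


class TestEncoder:
    def test_bounds_map_to_unit_corners(self):
        enc = RegimenEncoder()
        lo = RegimenVector.from_array(REGIMEN_BOUNDS.low)
        hi = RegimenVector.from_array(REGIMEN_BOUNDS.high)
        np.testing.assert_allclose(enc.encode(lo), 0.0)
        np.testing.assert_allclose(enc.encode(hi), 1.0)

    def test_midpoint(self):
        enc = RegimenEncoder()
        mid = RegimenVector.from_array((REGIMEN_BOUNDS.low + REGIMEN_BOUNDS.high) / 2)
        np.testing.assert_allclose(enc.encode(mid), 0.5)

    def test_random_round_trips(self, rng):
        enc = RegimenEncoder()
        for _ in range(100):
            x = rng.uniform(REGIMEN_BOUNDS.low, REGIMEN_BOUNDS.high)
            reg = RegimenVector.from_array(x)
            back = enc.decode(enc.encode(reg)).to_array()
            assert np.abs(back - x).max() < 1e-12

    def test_out_of_bounds_clipped_with_warning(self):
        enc = RegimenEncoder()
        with pytest.warns(UserWarning):
            z = enc.encode(RegimenVector(dose_a=1000.0, interval=12, dose_b=50, duration=4))
        assert z[0] == 1.0


class TestRegimenProblem:
    def test_evaluation_deterministic(self, small_cohort, rng):
        problem = regimen_problem(small_cohort)
        x = rng.uniform(problem.bounds.low, problem.bounds.high)
        np.testing.assert_array_equal(problem.evaluate(x), problem.evaluate(x))

    def test_exposure_ceiling_violation_positive(self, small_cohort):
        problem = regimen_problem(small_cohort, cmax_ceiling=100.0)
        heavy = np.array([300.0, 4.0, 200.0, 12.0])
        assert problem.violation(heavy) > 0

    def test_degenerate_weights_collapse_efficacy_objective(self, small_cohort):
        w = ObjectiveWeights(w1=0.0, w2=0.0)
        problem = regimen_problem(small_cohort, weights=w)
        rng = np.random.default_rng(0)
        f = np.array([
            problem.evaluate(rng.uniform(problem.bounds.low, problem.bounds.high))
            for _ in range(50)
        ])
        assert np.ptp(f[:, 0]) == 0.0 and np.ptp(f[:, 1]) == 0.0
        assert np.ptp(f[:, 2]) > 0.0

    def test_invalid_bounds_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            Bounds(np.array([10.0, 4, 0, 1]), np.array([5.0, 24, 200, 12]))

    def test_archive_best_efficacy_matches_grid_search(self, small_cohort):
        """Parameter recovery: the optimizer's best-efficacy regimen must
        reach the grid-search optimum of the fitted response surface."""
        problem = regimen_problem(small_cohort)
        result = run(problem, MOSWOConfig(pop_size=50, budget=5000, n_min=20, seed=4))
        best_ae = result.archive.objectives()[:, 0].min()

        model = CohortModel.fit(small_cohort)
        grid_ae = np.inf
        for da in np.linspace(50, 300, 26):
            for iv in np.linspace(4, 24, 21):
                for db in np.linspace(0, 200, 21):
                    r = RegimenVector(da, iv, db, 1.0)
                    if model.predicted_cmax(r) <= 1.5 * max(
                        rec.c_max for rec in small_cohort.records
                    ):
                        grid_ae = min(grid_ae, model.adverse_effect(r))
        best_eff = 100.0 - best_ae
        grid_eff = 100.0 - grid_ae
        assert abs(best_eff - grid_eff) / grid_eff < 0.05

    def test_archive_spans_cost_range(self, small_cohort):
        problem = regimen_problem(small_cohort)
        result = run(problem, MOSWOConfig(pop_size=50, budget=5000, n_min=20, seed=8))
        costs = result.archive.objectives()[:, 2]
        w = ObjectiveWeights()
        model = CohortModel.fit(small_cohort)
        ceiling = 1.5 * max(r.c_max for r in small_cohort.records)
        cheapest = regimen_cost(RegimenVector.from_array(REGIMEN_BOUNDS.low), w)
        # most effective feasible corner: the cheapest grid regimen whose
        # predicted effect is within 1% of the feasible grid maximum
        best_eff, dearest = -np.inf, np.inf
        grid = [
            RegimenVector(da, iv, db, 1.0)
            for da in np.linspace(50, 300, 16)
            for iv in np.linspace(4, 24, 16)
            for db in np.linspace(0, 200, 16)
        ]
        feasible = [r for r in grid if model.predicted_cmax(r) <= ceiling]
        best_eff = max(model.predicted_effect(r) for r in feasible)
        dearest = min(
            regimen_cost(r, w) for r in feasible
            if model.predicted_effect(r) >= 0.99 * best_eff
        )
        coverage = (costs.max() - costs.min()) / (dearest - cheapest)
        assert coverage >= 0.8


class TestRecordValidation:
    def test_bad_grade_rejected(self):
        with pytest.raises(ValueError):
            PKPDRecord("x", 100, 50, 150, 2, 1200, 85, 4, 1200)

    def test_bad_effect_rejected(self):
        with pytest.raises(ValueError):
            PKPDRecord("x", 100, 50, 150, 2, 1200, 150, 1, 1200)

    def test_duplicate_patient_ids_rejected(self):
        rec = PKPDRecord("x", 100, 50, 150, 2, 1200, 85, 1, 1200)
        rec2 = PKPDRecord("x", 150, 75, 200, 2, 1500, 90, 2, 750)
        with pytest.raises(ValueError):
            Cohort(records=[rec, rec2])
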