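"""Variation operators: pinned-factor arithmetic, identities, distributions
and the population-reduction schedule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from moswo.operators import (
    Bounds,
    OperatorParams,
    clip_to_bounds,
    escape_move,
    escape_threshold,
    explore_jump,
    explore_move,
    follow_move,
    mate,
    nest_move,
    reduce_population,
    speed_factor,
)


@pytest.fixture
def unit_bounds():
    return Bounds(np.zeros(3), np.ones(3))


class TestExploreMove:
    def test_zero_step_is_identity(self, rng):
        x = np.array([0.2, 0.8])
        out = explore_move(x, np.array([1.0, 0.0]), np.array([0.0, 1.0]), rng, mu1=0.0)
        np.testing.assert_array_equal(out, x)

    def test_pinned_factor_arithmetic(self, rng):
        out = explore_move(np.array([0.5]), np.array([0.8]), np.array([0.2]), rng, mu1=0.5)
        assert out == pytest.approx([0.8])

    def test_equal_anchors_cancel(self, rng):
        x = np.array([0.3, 0.4])
        a = np.array([0.9, 0.1])
        for _ in range(5):
            np.testing.assert_array_equal(explore_move(x, a, a, rng), x)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            explore_move(np.zeros(2), np.zeros(3), np.zeros(3), rng)

    def test_mu1_is_mean_zero(self):
        rng = np.random.default_rng(0)
        x = np.zeros(1)
        steps = [
            explore_move(x, np.ones(1), np.zeros(1), rng)[0] for _ in range(4000)
        ]
        # mu1 = rn * r1 has mean 0 and Var = E[r1^2] = 1/3
        assert abs(np.mean(steps)) < 3 * np.sqrt(1 / 3 / 4000)


class TestExploreJump:
    def test_zero_factor_is_identity(self, rng, unit_bounds):
        x = np.array([0.1, 0.5, 0.9])
        np.testing.assert_array_equal(explore_jump(x, unit_bounds, rng, mu2=0.0), x)

    def test_closed_form_factor_at_l_minus_one(self):
        # B = 1/(1+e^-1), cos(2 pi * -1) = 1
        expected = 1.0 / (1.0 + np.exp(-1.0))
        assert expected == pytest.approx(0.7311, abs=1e-4)

    def test_factor_support(self):
        rng = np.random.default_rng(1)
        bound = 1.0 / (1.0 + np.exp(-2.0))  # |cos| <= 1, B increasing in -l
        x = np.zeros(1)
        b = Bounds(np.ones(1), 2 * np.ones(1))  # L + r2 span in [1, 2]
        for _ in range(2000):
            out = explore_jump(x, b, rng)
            mu2 = out[0] / np.clip(np.abs(out[0]), 1e-12, None) * np.abs(out[0])
            assert np.abs(mu2) <= bound * 2.0 + 1e-12


class TestFollowMove:
    def test_exhausted_schedule_is_identity(self, rng):
        x = np.array([0.4, 0.6])
        out = follow_move(x, np.array([1.0, 1.0]), t=100, t_max=100, rng=rng)
        np.testing.assert_array_equal(out, x)

    def test_stationary_at_target(self, rng):
        x = np.array([0.4, 0.6])
        np.testing.assert_array_equal(follow_move(x, x, 0, 10, rng), x)

    def test_pinned_arithmetic(self):
        rng = np.random.default_rng(3)
        # c pinned to 1, r5 forced through a generator stub
        class Stub:
            def uniform(self, size=None):
                return np.full(size, 0.5) if size else 0.5

        out = follow_move(np.array([0.0]), np.array([1.0]), 0, 10, Stub(), c=1.0)
        assert out == pytest.approx([1.0])

    def test_speed_factor_decays_linearly(self):
        assert speed_factor(0, 100) == pytest.approx(2.0)
        assert speed_factor(50, 100) == pytest.approx(1.0)
        assert speed_factor(100, 100) == 0.0


class TestEscapeMove:
    def test_unit_contraction_is_identity(self, rng):
        x = np.array([2.0, -2.0])
        np.testing.assert_array_equal(escape_move(x, rng, vc=np.ones(2)), x)

    def test_pinned_contraction(self, rng):
        out = escape_move(np.array([2.0, -2.0]), rng, vc=np.array([0.5, 0.5]))
        np.testing.assert_allclose(out, [1.0, -1.0])

    def test_degenerate_interval_is_exact_scaling(self, rng):
        x = np.array([1.5, -3.0, 0.25])
        out = escape_move(x, rng, k_vc_low=0.3, k_vc_high=0.3)
        np.testing.assert_allclose(out, 0.3 * x)


class TestNestMove:
    def test_fixed_point_at_best(self, rng):
        star = np.array([0.7, 0.2])
        np.testing.assert_array_equal(nest_move(star, star, rng), star)

    def test_reflection_at_unit_cosine(self, rng):
        star, x = np.array([1.0, 1.0]), np.array([0.0, 0.5])
        out = nest_move(star, x, rng, l=-1.0)
        np.testing.assert_allclose(out, 2 * star - x)

    def test_output_collinear(self, rng):
        star, x = np.array([1.0, 2.0]), np.array([3.0, 5.0])
        for _ in range(10):
            out = nest_move(star, x, rng)
            d1 = star - x
            d2 = out - star
            assert abs(d1[0] * d2[1] - d1[1] * d2[0]) < 1e-12


class TestMate:
    def test_cr_zero_keeps_parent(self, rng):
        x, m = np.array([1.0, 2.0, 3.0]), np.array([9.0, 9.0, 9.0])
        np.testing.assert_array_equal(mate(x, m, 0.0, rng), x)

    def test_cr_one_takes_partner(self, rng):
        x, m = np.array([1.0, 2.0, 3.0]), np.array([9.0, 9.0, 9.0])
        np.testing.assert_array_equal(mate(x, m, 1.0, rng), m)

    def test_per_dimension_rate_matches_cr(self):
        rng = np.random.default_rng(7)
        x, m = np.zeros(10), np.ones(10)
        cr, trials = 0.3, 10_000
        taken = sum(mate(x, m, cr, rng).sum() for _ in range(trials))
        n = trials * 10
        sigma = np.sqrt(n * cr * (1 - cr))
        assert abs(taken - n * cr) < 3 * sigma


class TestReducePopulation:
    @pytest.mark.parametrize(
        "t, t_max, expected",
        [(0, 100, 100), (100, 100, 20), (50, 100, 60)],
    )
    def test_schedule_endpoints_and_midpoint(self, t, t_max, expected):
        assert reduce_population(100, 20, t, t_max) == expected

    def test_monotone_non_increasing_and_bounded(self):
        sizes = [reduce_population(100, 20, t, 200) for t in range(201)]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))
        assert min(sizes) == 20 and max(sizes) == 100

    def test_invalid_floor_rejected(self):
        with pytest.raises(ValueError):
            reduce_population(10, 20, 0, 100)

    @given(st.integers(2, 50), st.integers(0, 100))
    @settings(derandomize=True, max_examples=100)
    def test_never_below_floor(self, n_min, t):
        assert reduce_population(100, n_min, t, 100) >= n_min


class TestClipAndBounds:
    def test_in_bounds_unchanged(self, unit_bounds):
        x = np.array([0.1, 0.5, 0.9])
        np.testing.assert_array_equal(clip_to_bounds(x, unit_bounds), x)

    @pytest.mark.parametrize(
        "x, expected",
        [([-5.0, 0.5, 0.5], [0.0, 0.5, 0.5]), ([0.3, 7.0, 0.1], [0.3, 1.0, 0.1])],
    )
    def test_projection(self, x, expected, unit_bounds):
        np.testing.assert_array_equal(
            clip_to_bounds(np.array(x), unit_bounds), expected
        )

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            Bounds(np.ones(2), np.ones(2))

    def test_every_operator_clipped_stays_inside(self, rng, unit_bounds):
        x = rng.random(3)
        a, b = rng.random(3), rng.random(3)
        candidates = [
            explore_move(x * 10, a, b, rng),
            explore_jump(x * 10, unit_bounds, rng),
            follow_move(x, a * 5, 1, 10, rng),
            escape_move(x * 8, rng),
            nest_move(a * 3, x, rng),
        ]
        for c in candidates:
            clipped = clip_to_bounds(c, unit_bounds)
            assert np.all(clipped >= unit_bounds.low - 1e-15)
            assert np.all(clipped <= unit_bounds.high + 1e-15)

    def test_escape_threshold_tightens(self, unit_bounds):
        early = escape_threshold(unit_bounds, 0, 100)
        late = escape_threshold(unit_bounds, 90, 100)
        assert early == pytest.approx(0.5 * np.sqrt(3))
        assert late < early


class TestOperatorParams:
    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            OperatorParams(tr=1.5)
        with pytest.raises(ValueError):
            OperatorParams(cr=-0.1)
        with pytest.raises(ValueError):
            OperatorParams(k_vc_low=1.0, k_vc_high=-1.0)
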