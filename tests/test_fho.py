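"""Fire Hawk Optimizer mechanics and convergence behaviour."""

import numpy as np
import pytest

from nutrihawk.fho import (
    FHOConfig,
    FireHawkOptimizer,
    SearchSpace,
    assign_territories,
    initialize_population,
    minimize,
    safe_place_global,
    safe_place_within,
    select_hawks,
    update_hawk,
    update_prey,
)


class ScriptedRNG:
    """Replays fixed uniform and normal draws for the update-rule identities."""

    def __init__(self, uniforms=(), normals=()):
        self._u = list(uniforms)
        self._n = list(normals)

    def random(self, size=None):
        if size is None:
            return self._u.pop(0)
        return np.array([self._u.pop(0) for _ in range(size)])

    def standard_normal(self):
        return self._n.pop(0)


UNIT_SQUARE = SearchSpace(np.zeros(2), np.ones(2))
WIDE = SearchSpace(np.full(2, -100.0), np.full(2, 100.0))


class TestInit:
    def test_points_inside_box(self, rng):
        pop = initialize_population(UNIT_SQUARE, 10, rng)
        assert pop.shape == (10, 2)
        assert np.all((pop >= 0) & (pop <= 1))

    def test_degenerate_narrow_bounds(self, rng):
        space = SearchSpace(np.array([1.0]), np.array([1.0 + 1e-9]))
        pop = initialize_population(space, 5, rng)
        assert np.all((pop >= 1.0) & (pop <= 1.0 + 1e-9))

    def test_seeded_reproducibility(self):
        a = initialize_population(UNIT_SQUARE, 8, np.random.default_rng(3))
        b = initialize_population(UNIT_SQUARE, 8, np.random.default_rng(3))
        np.testing.assert_array_equal(a, b)

    def test_small_population_rejected(self, rng):
        with pytest.raises(ValueError):
            initialize_population(UNIT_SQUARE, 3, rng)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            SearchSpace(np.array([1.0]), np.array([1.0]))


class TestSelectHawks:
    def test_gaussian_scaled_count(self):
        fitness = np.arange(10.0)
        hawks, prey = select_hawks(fitness, 0.2, ScriptedRNG(normals=[1.0]))
        assert len(hawks) == 2  # round(|1| * 10 * 0.2)
        np.testing.assert_array_equal(np.sort(hawks), [0, 1])
        assert len(prey) == 8

    def test_floor_of_one_hawk(self):
        hawks, _ = select_hawks(np.arange(10.0), 0.2, ScriptedRNG(normals=[0.0]))
        assert len(hawks) == 1

    def test_best_fitness_becomes_hawk(self):
        hawks, _ = select_hawks(np.array([3.0, 1.0, 2.0, 5.0]), 0.1,
                                ScriptedRNG(normals=[0.5]))
        assert list(hawks) == [1]

    def test_unevaluated_fitness_rejected(self):
        with pytest.raises(ValueError):
            select_hawks(np.array([1.0, np.nan]), 0.2, ScriptedRNG(normals=[1.0]))


class TestTerritories:
    def test_three_four_five_distance(self):
        pos = np.array([[0.0, 0.0], [3.0, 4.0]])
        terr = assign_territories(np.array([0]), np.array([1]), pos, np.array([0.0, 1.0]))
        assert terr == {0: [1]}

    def test_balanced_quota(self):
        pos = np.array([[0.0, 0], [10.0, 0], [1.0, 0], [2.0, 0], [9.0, 0], [8.0, 0]])
        fit = np.array([0.0, 0.5, 1, 1, 1, 1])
        terr = assign_territories(np.array([0, 1]), np.array([2, 3, 4, 5]), pos, fit)
        assert sorted(map(len, terr.values())) == [2, 2]
        assert set(terr[0]) == {2, 3}      # nearest to the best hawk
        assert set(terr[1]) == {4, 5}

    def test_single_hawk_takes_all(self):
        pos = np.random.default_rng(0).random((5, 2))
        terr = assign_territories(np.array([0]), np.arange(1, 5), pos,
                                  np.arange(5.0))
        assert sorted(terr[0]) == [1, 2, 3, 4]

    def test_empty_prey(self):
        terr = assign_territories(np.array([0]), np.array([], dtype=int),
                                  np.zeros((1, 2)), np.zeros(1))
        assert terr == {0: []}


class TestUpdateRules:
    def test_hawk_zero_randomness_fixed_point(self):
        new = update_hawk(np.array([0.3, 0.4]), np.ones(2), np.ones(2),
                          ScriptedRNG([0.0, 0.0]), UNIT_SQUARE)
        np.testing.assert_array_equal(new, [0.3, 0.4])

    def test_hawk_symmetric_cancellation(self):
        new = update_hawk(np.ones(2), np.ones(2), np.ones(2),
                          ScriptedRNG([0.5, 0.5]), WIDE)
        np.testing.assert_allclose(new, [1.0, 1.0])

    def test_hawk_direct_evaluation(self):
        new = update_hawk(np.zeros(2), np.array([2.0, 0.0]), np.zeros(2),
                          ScriptedRNG([0.5, 0.3]), WIDE)
        np.testing.assert_allclose(new, [1.0, 0.0])

    def test_safe_places(self):
        np.testing.assert_allclose(
            safe_place_within(np.array([[0.0, 0], [2.0, 2]]), np.zeros(2)), [1, 1])
        np.testing.assert_allclose(
            safe_place_within(np.array([[0.7, 0.1]]), np.zeros(2)), [0.7, 0.1])
        np.testing.assert_allclose(  # empty territory -> owner hawk
            safe_place_within(np.zeros((0, 2)), np.array([0.5, 0.5])), [0.5, 0.5])
        np.testing.assert_allclose(  # no prey at all -> archived best
            safe_place_global(np.zeros((0, 2)), np.array([0.9, 0.9])), [0.9, 0.9])

    def test_prey_zero_randomness_fixed_point(self):
        new = update_prey(np.array([0.2, 0.2]), np.ones(2), np.ones(2),
                          np.ones(2), np.ones(2),
                          ScriptedRNG([0.0, 0.0, 0.0]), UNIT_SQUARE)
        np.testing.assert_array_equal(new, [0.2, 0.2])

    def test_prey_within_territory_cancellation(self):
        # coin 0.0 -> within-territory move with equal pulls cancelling
        new = update_prey(np.zeros(2), np.ones(2), np.full(2, 9.0),
                          np.ones(2), np.full(2, 9.0),
                          ScriptedRNG([0.0, 0.7, 0.7]), WIDE)
        np.testing.assert_allclose(new, [0.0, 0.0])

    def test_prey_outside_territory_move(self):
        # coin 0.9 -> outside move: Kp + r5*Fh_vary - r6*Sa_global
        new = update_prey(np.array([1.0, 0.0]), np.zeros(2), np.array([3.0, 0.0]),
                          np.zeros(2), np.array([1.0, 0.0]),
                          ScriptedRNG([0.9, 0.5, 0.5]), WIDE)
        np.testing.assert_allclose(new, [2.0, 0.0])


class TestMinimize:
    def test_1d_quadratic_optimum(self):
        space = SearchSpace(np.array([0.0]), np.array([4.0]))
        res = minimize(lambda x: float((x[0] - 2) ** 2), space,
                       FHOConfig(pop_size=20, max_iters=100, seed=0))
        assert abs(res.best_position[0] - 2.0) < 0.05

    def test_constant_objective(self):
        res = minimize(lambda x: 7.0, UNIT_SQUARE,
                       FHOConfig(pop_size=6, max_iters=10, seed=1))
        assert np.all(res.history == 7.0)
        assert res.best_fitness == 7.0

    def test_elitist_history_monotone_and_bounded(self):
        space = SearchSpace(np.full(3, -2.0), np.full(3, 2.0))
        res = minimize(lambda x: float(np.sum(np.abs(x))), space,
                       FHOConfig(pop_size=12, max_iters=50, seed=5))
        assert len(res.history) == 50
        assert np.all(np.diff(res.history) <= 0)
        assert np.all((res.best_position >= -2) & (res.best_position <= 2))

    def test_fixed_seed_bit_identical_history(self):
        space = SearchSpace(np.full(2, -1.0), np.full(2, 1.0))
        f = lambda x: float((x ** 2).sum())
        cfg = FHOConfig(pop_size=10, max_iters=30, seed=9)
        a = minimize(f, space, cfg)
        b = minimize(f, space, cfg)
        np.testing.assert_array_equal(a.history, b.history)
        np.testing.assert_array_equal(a.best_position, b.best_position)

    def test_non_finite_objective_reported(self):
        opt = FireHawkOptimizer(UNIT_SQUARE, FHOConfig(pop_size=5, max_iters=5, seed=0))
        with pytest.raises(FloatingPointError):
            opt.minimize(lambda x: np.nan)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            FHOConfig(pop_size=3)
        with pytest.raises(ValueError):
            FHOConfig(hawk_count_cap=0.9)
        with pytest.raises(ValueError):
            FHOConfig(max_iters=0)
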