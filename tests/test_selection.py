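import itertools

import numpy as np
import pytest
from sklearn.neighbors import NearestCentroid

from harpipe.selection import (
    FitnessSpec,
    GeoSchedule,
    Eagle,
    attack_vector,
    binomial_random_vector,
    cruise_vector,
    geo_minimize,
    mask_fitness,
    nearest_centroid_cv_accuracy,
    _stratified_folds,
    propensity_schedule,
    select_features,
    step_and_move,
)
from harpipe.synthetic import generate_informative_feature_table


class TestAttackVector:
    def test_points_from_eagle_to_prey(self):
        np.testing.assert_array_equal(
            attack_vector(np.ones(2), np.zeros(2)), np.ones(2)
        )

    def test_zero_at_prey(self):
        x = np.array([0.3, 0.7])
        assert not attack_vector(x, x).any()

    def test_euclidean_norm(self):
        assert np.linalg.norm(attack_vector(np.ones(2), np.zeros(2))) == pytest.approx(
            np.sqrt(2)
        )


class TestCruiseVector:
    def test_destination_satisfies_hyperplane_identity(self, rng):
        for _ in range(200):
            dim = rng.integers(2, 12)
            alpha = rng.standard_normal(dim)
            prey = rng.uniform(0, 1, dim)
            res = cruise_vector(alpha, prey, rng)
            assert abs(alpha @ res.destination - res.s) <= 1e-9

    def test_worked_two_dim_example(self):
        # beta=(1,1), prey=(1,1): s=2, and any free draw a gives A=(a, 2-a)
        rng = np.random.default_rng(0)
        res = cruise_vector(np.array([1.0, 1.0]), np.array([1.0, 1.0]), rng)
        a1, a2 = res.destination
        assert a1 + a2 == pytest.approx(2.0, abs=1e-12)

    def test_one_dimensional_problem_falls_back_to_unit_vector(self, rng):
        res = cruise_vector(np.array([0.5]), np.array([0.3]), rng)
        assert np.linalg.norm(res.cruise) == pytest.approx(1.0)

    def test_zero_attack_falls_back(self, rng):
        res = cruise_vector(np.zeros(3), np.full(3, 0.5), rng)
        assert np.linalg.norm(res.cruise) == pytest.approx(1.0)


class TestBinomialRandomVector:
    def test_degenerate_probabilities(self, rng):
        assert not binomial_random_vector(5, 10, 0.0, rng).any()
        assert (binomial_random_vector(5, 10, 1.0, rng) == 1.0).all()

    def test_moments_match_binomial_over_n(self, rng):
        u = binomial_random_vector(100_000, 10, 0.5, rng)
        assert u.mean() == pytest.approx(0.5, abs=0.005)
        assert u.var() == pytest.approx(0.025, abs=0.003)

    def test_values_confined_to_unit_interval(self, rng):
        u = binomial_random_vector(1000, 7, 0.3, rng)
        assert ((u >= 0) & (u <= 1)).all()


class TestPropensitySchedule:
    def test_endpoints(self):
        s = GeoSchedule(iter_max=100)
        assert propensity_schedule(s, 0) == (0.5, 1.0)
        assert propensity_schedule(s, 100) == (2.0, 0.5)

    def test_linear_midpoint(self):
        s = GeoSchedule(iter_max=100)
        ka, kc = propensity_schedule(s, 50)
        assert ka == pytest.approx(1.25)
        assert kc == pytest.approx(0.75)

    def test_zero_iter_max_returns_initials(self):
        s = GeoSchedule(iter_max=0)
        assert propensity_schedule(s, 0) == (0.5, 1.0)


class TestStepAndMove:
    def test_step_norm_bounded_by_propensities(self, rng):
        # triangle inequality: |R1 ka a^| + |R2 kc g^| <= ka + kc
        worst = 0.0
        for _ in range(10_000):
            e = Eagle(rng.uniform(0, 1, 4), np.zeros(4), 0.0)
            prey = rng.uniform(0, 1, 4)
            moved = step_and_move(e, prey, 1.5, 0.8, rng, bounds=(-10, 10))
            worst = max(worst, np.linalg.norm(moved.position - e.position))
        assert worst <= 1.5 + 0.8 + 1e-9

    def test_positions_stay_clamped_in_unit_box(self, rng):
        e = Eagle(np.array([0.99, 0.01]), np.zeros(2), 0.0)
        for _ in range(100):
            e = step_and_move(e, rng.uniform(0, 1, 2), 2.0, 0.5, rng)
            assert ((e.position >= 0) & (e.position <= 1)).all()


class TestGeoMinimize:
    def test_sphere_convergence_and_monotone_trace(self):
        f = lambda x: float(((x - 0.3) ** 2).sum())
        hits = 0
        for seed in range(5):
            _, best, trace = geo_minimize(f, 2, pop_size=20, n_iter=200, seed=seed)
            assert (np.diff(trace) <= 1e-12).all()
            hits += best < 1e-3
        assert hits >= 4


class TestWrapperFitness:
    def test_cv_folds_are_stratified_and_deterministic(self):
        y = np.repeat([0, 1, 2], 30)
        f1 = _stratified_folds(y, 3, seed=5)
        f2 = _stratified_folds(y, 3, seed=5)
        for a, b in zip(f1, f2):
            np.testing.assert_array_equal(a, b)
        for fold in f1:
            _, counts = np.unique(y[fold], return_counts=True)
            assert (counts == 10).all()

    def test_accuracy_scorer_agrees_with_sklearn_nearest_centroid(self, rng):
        X, y, _ = generate_informative_feature_table(90, 6, 3, 1.5, 2, seed=3)
        folds = _stratified_folds(y, 3, seed=0)
        expected_correct = 0
        for test_idx in folds:
            train = np.setdiff1d(np.arange(len(y)), test_idx)
            clf = NearestCentroid().fit(X[train], y[train])
            expected_correct += (clf.predict(X[test_idx]) == y[test_idx]).sum()
        acc = nearest_centroid_cv_accuracy(X, y, 3, 0)
        assert acc == pytest.approx(expected_correct / len(y))

    def test_empty_mask_is_never_viable(self):
        X = np.random.default_rng(0).normal(size=(20, 4))
        y = np.array([0, 1] * 10)
        assert mask_fitness(X, y, np.zeros(4, bool), FitnessSpec()) == -np.inf


class TestSelectFeatures:
    def test_single_planted_feature_is_recovered(self):
        hits = 0
        for seed in range(10):
            X, y, info = generate_informative_feature_table(
                200, 5, 1, effect_size=3.0, seed=seed
            )
            Xz = (X - X.mean(0)) / X.std(0)
            res = select_features(Xz, y, pop_size=10, iter_max=50, seed=seed)
            # exhaustive oracle: the informative feature is in the argmax subset
            spec = FitnessSpec()
            best = max(
                (m for m in itertools.product([0, 1], repeat=5) if any(m)),
                key=lambda m: mask_fitness(Xz, y, np.array(m, bool), spec),
            )
            assert best[info[0]] == 1
            hits += bool(res.mask[info[0]])
        assert hits >= 9

    def test_elitist_trace_is_nondecreasing(self):
        X, y, _ = generate_informative_feature_table(100, 8, 4, 2.0, seed=2)
        res = select_features(X, y, pop_size=8, iter_max=30, seed=2)
        assert (np.diff(res.trace) >= -1e-12).all()
        assert res.best_fitness >= res.trace[0]

    def test_identical_seed_reproduces_result(self):
        X, y, _ = generate_informative_feature_table(100, 8, 4, 2.0, seed=4)
        r1 = select_features(X, y, pop_size=8, iter_max=20, seed=9)
        r2 = select_features(X, y, pop_size=8, iter_max=20, seed=9)
        np.testing.assert_array_equal(r1.mask, r2.mask)
        np.testing.assert_array_equal(r1.trace, r2.trace)

    def test_single_class_labels_rejected(self):
        X = np.zeros((10, 3))
        with pytest.raises(ValueError, match="two classes"):
            select_features(X, np.zeros(10, dtype=int))
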