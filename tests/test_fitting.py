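import numpy as np
import pytest
from shapely.geometry import Point

from tactilepop.fitting import (
    CandidateModel,
    FitDataset,
    GAConfig,
    estimate_max_rate,
    fit_neuron,
    fitness_over_orientations,
    ga_optimize_box,
    make_null_model,
    nearest_edge_prediction,
    r2_score,
    sample_in_region,
    select_model,
)
from tactilepop.neuron_model import NeuronModel, ResponsivityParams, SpikeTrain


class TestR2Score:
    def test_perfect_fit(self):
        o = np.array([0.0, 10.0, 20.0, 10.0])
        assert r2_score(o, o) == pytest.approx(1.0)

    def test_mean_predictor_scores_zero(self):
        o = np.array([0.0, 10.0, 20.0, 10.0])
        assert r2_score(np.full_like(o, o.mean()), o) == pytest.approx(0.0)

    def test_hand_computed_example(self):
        # residual mse 25, total variance 50 -> R^2 = 0.5
        o = np.array([0.0, 10.0, 20.0, 10.0])
        m = np.array([0.0, 10.0, 10.0, 10.0])
        assert r2_score(m, o) == pytest.approx(1.0 - 25.0 / 50.0)

    def test_constant_observed_rejected(self):
        with pytest.raises(ValueError):
            r2_score(np.ones(4), np.ones(4))

    def test_can_be_negative(self):
        o = np.array([0.0, 1.0, 0.0, 1.0])
        assert r2_score(10 * o, o) < 0.0


class TestEstimateMaxRate:
    def test_regular_train(self):
        train = SpikeTrain(times=np.arange(0, 100, 5.0), duration=100.0)
        assert estimate_max_rate([train]) == pytest.approx(200.0)

    def test_needs_isis(self):
        with pytest.raises(ValueError):
            estimate_max_rate([SpikeTrain(times=np.array([3.0]), duration=10.0)])


class TestGaOptimize:
    def test_recovers_known_point(self):
        target = np.array([0.3, -0.7])

        def evaluate(pop):
            return -np.linalg.norm(pop - target, axis=1)

        bounds = (np.full(2, -1.0), np.full(2, 1.0))
        res = ga_optimize_box(evaluate, bounds, GAConfig(iterations=200, seed=3))
        assert np.allclose(res.best_genome, target, atol=0.02)  # 1% of range

    def test_population_of_one_rejected(self):
        with pytest.raises(ValueError):
            GAConfig(population_size=1)

    def test_same_seed_same_trace(self):
        def evaluate(pop):
            return -np.abs(pop[:, 0])

        bounds = (np.array([-1.0]), np.array([1.0]))
        cfg = GAConfig(population_size=10, iterations=30, seed=11)
        a = ga_optimize_box(evaluate, bounds, cfg)
        b = ga_optimize_box(evaluate, bounds, cfg)
        assert np.array_equal(a.trace, b.trace)
        assert np.array_equal(a.best_genome, b.best_genome)

    def test_trace_running_max_is_nondecreasing(self):
        rng_target = np.array([0.1, 0.2, 0.3])

        def evaluate(pop):
            return -((pop - rng_target) ** 2).sum(axis=1)

        bounds = (np.full(3, -1.0), np.full(3, 1.0))
        res = ga_optimize_box(evaluate, bounds, GAConfig(population_size=8, iterations=50, seed=0))
        assert np.all(np.diff(res.trace) >= 0.0)

    def test_pure_selection_still_improves(self):
        def evaluate(pop):
            return -np.abs(pop).sum(axis=1)

        bounds = (np.full(2, -1.0), np.full(2, 1.0))
        cfg = GAConfig(population_size=20, iterations=10, mutation_p=0.0, crossover_p=0.0, seed=2)
        res = ga_optimize_box(evaluate, bounds, cfg)
        assert np.all(np.diff(res.trace) >= 0.0)


def _candidate(n_mr, train, cv):
    model = NeuronModel(np.zeros((1, 2)), ResponsivityParams(0.3, 0.5, 100.0), 50.0)
    fitness = {o: train for o in (-45.0, -22.5, 22.5, 45.0)}
    return CandidateModel(model=model, n_mr=n_mr, train_fitness=fitness,
                          crossval_fitness=cv, test_fitness=0.0)


class TestSelectModel:
    def test_single_candidate(self):
        c = _candidate(10, 0.9, 0.8)
        assert select_model([c]) is c

    def test_prefers_fewer_mechanoreceptors(self):
        few = _candidate(10, 0.9, 0.80)
        many = _candidate(40, 0.9, 0.81)
        assert select_model([few, many]) is few

    def test_orientation_filter_excludes_weak_fit(self):
        weak = _candidate(10, 0.5, 0.99)  # best cross-val but poor train fit
        strong = _candidate(20, 0.9, 0.7)
        assert select_model([weak, strong]) is strong

    def test_within_window_best_crossval_wins(self):
        a = _candidate(10, 0.90, 0.80)
        b = _candidate(12, 0.91, 0.82)
        assert select_model([a, b]) is b

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            select_model([])

    def test_order_independent(self):
        cands = [_candidate(10, 0.9, 0.8), _candidate(20, 0.92, 0.83), _candidate(30, 0.9, 0.82)]
        assert select_model(cands).n_mr == select_model(cands[::-1]).n_mr


class TestSampleInRegion:
    def test_points_inside(self):
        region = Point(3.0, 4.0).buffer(2.0)
        pts = sample_in_region(region, 200, np.random.default_rng(0))
        assert np.all(np.linalg.norm(pts - [3, 4], axis=1) <= 2.0)


class TestNullModel:
    def test_preserves_everything_but_locations(self, truth_neuron, clean_dataset):
        null = make_null_model(truth_neuron, clean_dataset.boundary, seed=4)
        assert null.n_mr == truth_neuron.n_mr
        assert null.responsivity == truth_neuron.responsivity
        assert null.max_rate == truth_neuron.max_rate
        assert not np.allclose(null.mr_locations, truth_neuron.mr_locations)

    def test_locations_inside_boundary(self, truth_neuron, clean_dataset):
        from shapely import contains_xy

        null = make_null_model(truth_neuron, clean_dataset.boundary, seed=5)
        assert contains_xy(
            clean_dataset.boundary, null.mr_locations[:, 0], null.mr_locations[:, 1]
        ).all()


class TestFitnessAndBaselines:
    def test_ground_truth_fits_perfectly_without_jitter(self, truth_neuron, clean_dataset):
        assert fitness_over_orientations(truth_neuron, clean_dataset) == pytest.approx(1.0)

    def test_two_orientation_mean(self, truth_neuron, clean_dataset):
        a = fitness_over_orientations(truth_neuron, clean_dataset, orientations=[22.5])
        b = fitness_over_orientations(truth_neuron, clean_dataset, orientations=[-45.0])
        ab = fitness_over_orientations(truth_neuron, clean_dataset, orientations=[22.5, -45.0])
        assert ab == pytest.approx((a + b) / 2.0)

    def test_nearest_edge_prediction_below_perfect(self, clean_dataset):
        score = nearest_edge_prediction(clean_dataset)
        assert score < 1.0

    def test_nearest_edge_requires_orientations(self, clean_dataset):
        crippled = FitDataset(
            trains={k: v for k, v in clean_dataset.trains.items() if k != 30.0},
            boundary=clean_dataset.boundary,
            patch=clean_dataset.patch,
            clock=clean_dataset.clock,
            max_rate=clean_dataset.max_rate,
        )
        with pytest.raises(ValueError):
            nearest_edge_prediction(crippled)


@pytest.mark.slow
class TestSmallRecovery:
    def test_fit_beats_nulls_on_tiny_budget(self, clean_dataset):
        cand = fit_neuron(clean_dataset, 10, GAConfig(population_size=20, iterations=60, seed=9))
        assert cand.mean_train_fitness > 0.5
        nulls = [
            fitness_over_orientations(
                make_null_model(cand.model, clean_dataset.boundary, seed=s),
                clean_dataset,
                orientations=[30.0],
            )
            for s in range(5)
        ]
        assert cand.test_fitness > np.mean(nulls)
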