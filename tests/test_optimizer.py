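"""DSS objective, GP/EI surrogate, episodes, and the brute-force oracle."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from reliamol import (
    DesignRun,
    ExplorationHistory,
    ScalerConfig,
    SearchSpace,
    brute_force_landscape,
    dss,
    evaluate_levels,
    expected_improvement,
    make_benchmark,
    reliability_scaler,
    run_episode,
    suggest_next,
    top_fraction_mean,
)
from reliamol.generator import DesignRecord
from reliamol.optimizer import (
    DSSConfig,
    CombinatorialExplosionError,
    EmptyRewardsError,
    ExhaustedSpaceError,
    ExplorationRecord,
    fit_surrogate,
)


class TestReliabilityScaler:
    def test_peak_at_center(self):
        assert reliability_scaler(1.0, ScalerConfig(sigma=0.25)) == 1.0
        assert reliability_scaler(0.9, ScalerConfig(sigma=0.25, center=0.8)) == 1.0

    def test_closed_form_one_sigma(self):
        value = reliability_scaler(0.75, ScalerConfig(sigma=0.25, center=1.0))
        assert value == pytest.approx(math.exp(-0.5), abs=1e-12)

    def test_smaller_sigma_is_stricter(self):
        for rho in [0.2, 0.5, 0.8]:
            tight = reliability_scaler(rho, ScalerConfig(sigma=0.15))
            loose = reliability_scaler(rho, ScalerConfig(sigma=0.35))
            assert tight < loose

    def test_strictly_increasing_below_center(self):
        cfg = ScalerConfig(sigma=0.25)
        values = [reliability_scaler(r, cfg) for r in np.linspace(0, 1, 21)]
        below = values[:-1]  # strictly increasing until the center at 1.0
        assert all(a < b for a, b in zip(below, below[1:]))


class TestTopFractionMean:
    def test_top_one_is_max(self):
        rewards = [0.1, 0.9, 0.3, 0.5, 0.2, 0.4, 0.6, 0.0, 0.8, 0.7]
        assert top_fraction_mean(rewards, 0.10) == 0.9

    def test_constant_rewards(self):
        assert top_fraction_mean([0.4] * 7, 0.25) == pytest.approx(0.4)

    def test_matches_sort_oracle(self, rng):
        rewards = rng.random(25)
        expected = float(np.mean(sorted(rewards)[-3:]))  # ceil(2.5) = 3
        assert top_fraction_mean(rewards, 0.10) == pytest.approx(expected, abs=1e-12)

    def test_empty_raises(self):
        with pytest.raises(EmptyRewardsError):
            top_fraction_mean([], 0.1)


def _run_with_rewards(rewards):
    records = [DesignRecord(smiles=f"m{i}", valid=True, reward=r) for i, r in enumerate(rewards)]
    return DesignRun(records=records, budget=len(records), seed=0)


class TestDss:
    def test_saturated_scalers_give_top_reward(self):
        run = _run_with_rewards([0.2, 0.8, 0.5, 0.1])
        cfg = DSSConfig(scalers=[ScalerConfig(sigma=0.25, center=0.5)], top_fraction=0.25)
        assert dss([0.9, 0.9], run, cfg) == pytest.approx(0.8)

    def test_closed_form_composition(self):
        run = _run_with_rewards([0.5, 0.1])
        cfg = DSSConfig(scalers=[ScalerConfig(sigma=0.25), ScalerConfig(sigma=0.35)], top_fraction=0.5)
        rho = [0.6, 0.7]
        expected = math.sqrt(
            reliability_scaler(0.6, cfg.scalers[0]) * reliability_scaler(0.7, cfg.scalers[1])
        ) * 0.5
        assert dss(rho, run, cfg) == pytest.approx(expected, abs=1e-12)

    def test_all_zero_rewards_give_zero(self):
        run = _run_with_rewards([0.0, 0.0, 0.0])
        cfg = DSSConfig(scalers=[ScalerConfig(sigma=0.25)])
        assert dss([0.5, 0.5], run, cfg) == 0.0

    def test_bounded_unit_interval(self, rng):
        cfg = DSSConfig(scalers=[ScalerConfig(sigma=0.2)], top_fraction=0.3)
        for _ in range(20):
            run = _run_with_rewards(rng.random(8))
            value = dss(rng.random(3), run, cfg)
            assert 0.0 <= value <= 1.0


@pytest.fixture(scope="module")
def small_benchmark_context():
    bm = make_benchmark(k=3, separation=0.7, seed=11)
    return bm.context(seed=11)


class TestEvaluateLevels:
    def test_deterministic(self, small_benchmark_context):
        a, _ = evaluate_levels([0.3, 0.3, 0.3], small_benchmark_context)
        b, _ = evaluate_levels([0.3, 0.3, 0.3], small_benchmark_context)
        assert a == b

    def test_fully_gated_levels_give_zero(self, small_benchmark_context):
        score, run = evaluate_levels([0.99, 0.99, 0.99], small_benchmark_context)
        assert score == 0.0 and run.n_in_ad == 0

    def test_delegates_to_dss_composition(self, small_benchmark_context):
        ctx = small_benchmark_context
        rho = [0.3, 0.3, 0.3]
        score, run = evaluate_levels(rho, ctx)
        assert score == pytest.approx(dss(rho, run, ctx.dss_config), abs=1e-12)


class TestSuggestNext:
    def _toy_history(self, space, n=6, seed=0):
        rng = np.random.default_rng(seed)
        history = ExplorationHistory(seed=seed)
        flat = rng.choice(space.n_points, size=n, replace=False)
        for step, f in enumerate(flat):
            rho = space.point(int(f))
            value = float(np.exp(-np.sum((rho - 0.5) ** 2)))
            history.records.append(
                ExplorationRecord(step, "random", tuple(rho), value, value, 1, 10)
            )
        return history

    def test_feasible_and_unevaluated(self):
        space = SearchSpace(grids=[np.linspace(0.1, 0.9, 9)] * 2)
        history = self._toy_history(space)
        rho = suggest_next(history, space, seed=1)
        assert tuple(rho) not in history.evaluated_points()
        assert all(any(np.isclose(v, g).any() for g in [space.grids[i]]) for i, v in enumerate(rho))

    def test_deterministic_given_seed(self):
        space = SearchSpace(grids=[np.linspace(0.1, 0.9, 9)] * 2)
        history = self._toy_history(space)
        assert np.array_equal(suggest_next(history, space, seed=5), suggest_next(history, space, seed=5))

    def test_exhausted_space_raises(self):
        space = SearchSpace(grids=[np.array([0.2, 0.8])])
        history = ExplorationHistory()
        for step, rho in enumerate(space.enumerate()):
            history.records.append(ExplorationRecord(step, "random", tuple(rho), 0.1, 0.1, 1, 5))
        with pytest.raises(ExhaustedSpaceError):
            suggest_next(history, space, seed=0)

    def test_ei_closed_form_matches_monte_carlo(self):
        # GP fitted on a 10-point 1-D history; EI at held-out inputs must
        # agree with a Monte-Carlo estimate from the posterior Gaussian.
        rng = np.random.default_rng(3)
        X = np.linspace(0, 1, 10).reshape(-1, 1)
        y = np.sin(3 * X[:, 0]) * 0.4 + 0.5
        gp = fit_surrogate(X, y, seed=0)
        best = float(y.max())
        Xq = np.array([[0.05], [0.33], [0.71], [0.97]])
        mu, sigma = gp.predict(Xq, return_std=True)
        ei = expected_improvement(mu, sigma, best)
        n_draws = 100_000
        for j in range(len(Xq)):
            draws = rng.normal(mu[j], sigma[j], size=n_draws)
            improvements = np.maximum(draws - best, 0.0)
            mc = improvements.mean()
            se = improvements.std(ddof=1) / math.sqrt(n_draws)
            assert abs(ei[j] - mc) <= 3 * se + 1e-12


class TestRunEpisode:
    def test_pure_random_episode(self, small_benchmark_context):
        space = SearchSpace(grids=[np.array([0.2, 0.4, 0.6])] * 3)
        history = run_episode(space, small_benchmark_context, n_random=8, n_bo=0, seed=1)
        assert len(history) == 8
        assert all(r.step_type == "random" for r in history.records)
        # random phase samples without replacement
        assert len(history.evaluated_points()) == 8

    def test_best_so_far_nondecreasing(self, small_benchmark_context):
        space = SearchSpace(grids=[np.array([0.2, 0.35, 0.5])] * 3)
        history = run_episode(space, small_benchmark_context, n_random=6, n_bo=6, seed=3)
        trace = history.best_so_far()
        assert np.all(np.diff(trace) >= 0)
        assert trace[-1] == history.best().dss

    def test_exhaustive_episode_finds_landscape_maximum(self, small_benchmark_context):
        space = SearchSpace(grids=[np.array([0.2, 0.35, 0.5])] * 3)
        history = run_episode(space, small_benchmark_context, n_random=10, n_bo=17, seed=0)
        landscape = brute_force_landscape(space, small_benchmark_context)
        assert history.best().dss == pytest.approx(max(landscape.values()), abs=1e-12)

    def test_history_csv_roundtrip(self, small_benchmark_context, tmp_path):
        space = SearchSpace(grids=[np.array([0.2, 0.4])] * 3)
        history = run_episode(space, small_benchmark_context, n_random=4, n_bo=2, seed=2)
        path = tmp_path / "episode.csv"
        history.to_csv(path)
        loaded = ExplorationHistory.from_csv(path, seed=2)
        assert len(loaded) == len(history)
        for a, b in zip(loaded.records, history.records):
            assert a.rho == pytest.approx(b.rho)
            assert a.dss == pytest.approx(b.dss)
            assert a.step_type == b.step_type


class TestBruteForce:
    def test_two_by_two_grid(self, small_benchmark_context):
        space = SearchSpace(grids=[np.array([0.2, 0.5])] * 2 + [np.array([0.3])])
        landscape = brute_force_landscape(space, small_benchmark_context)
        assert len(landscape) == 4

    def test_entries_match_evaluate_levels(self, small_benchmark_context):
        space = SearchSpace(grids=[np.array([0.2, 0.5])] * 3)
        landscape = brute_force_landscape(space, small_benchmark_context)
        for rho, value in landscape.items():
            assert value == evaluate_levels(np.asarray(rho), small_benchmark_context)[0]

    def test_explosion_guard(self, small_benchmark_context):
        space = SearchSpace(grids=[np.linspace(0.01, 0.99, 60)] * 3)
        with pytest.raises(CombinatorialExplosionError):
            brute_force_landscape(space, small_benchmark_context)


class TestSearchSpace:
    def test_literal_default_grid_enumeration(self):
        space = SearchSpace.from_range(3)
        assert space.grids[0][0] == pytest.approx(0.1)
        assert space.grids[0][-1] == pytest.approx(0.9)
        assert space.grids[0].size == 81

    def test_validation(self):
        with pytest.raises(ValueError):
            SearchSpace(grids=[np.array([0.5, 0.2])])
        with pytest.raises(ValueError):
            SearchSpace(grids=[np.array([])])

    def test_point_indexing_consistent_with_enumeration(self):
        space = SearchSpace(grids=[np.array([0.1, 0.5]), np.array([0.2, 0.4, 0.6])])
        enumerated = list(space.enumerate())
        for flat in range(space.n_points):
            assert np.array_equal(space.point(flat), enumerated[flat])
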