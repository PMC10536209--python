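import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import olivephen as op
from olivephen.errors import BoundsError, DataError, OptimizerError, StatisticsError, ValidationError
from olivephen.ga import GAConfig, ga_minimize

from conftest import segmented_season


class TestRMSE:
    def test_values(self):
        assert op.rmse([10, 20], [10, 20]) == 0.0
        assert op.rmse([10], [13]) == 3.0
        assert op.rmse([0, 0], [3, 4]) == pytest.approx(np.sqrt(12.5))

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            op.rmse([1, 2], [1])


class TestObjectives:
    def seasons_and_truth(self):
        seasons = [
            segmented_season(1997, [(n, 2, 8), (365 - n, 12, 18)])
            for n in (10, 12, 15, 20)
        ]
        params = op.CACParams(tc=10, cr=-30)
        truth = np.array([op.predict_sprouting(s, params).jday for s in seasons])
        assert all(t is not None for t in truth)
        return seasons, params, truth.astype(int)

    def test_self_consistency_gives_zero(self):
        seasons, params, truth = self.seasons_and_truth()
        assert op.cac_objective(params, seasons, truth) == 0.0

    def test_shifted_observations_give_shift(self):
        seasons, params, truth = self.seasons_and_truth()
        assert op.cac_objective(params, seasons, truth + 1) == 1.0

    def test_infeasible_params_hit_finite_penalty(self):
        seasons, _, truth = self.seasons_and_truth()
        hopeless = op.CACParams(tc=10, cr=-5000.0)
        value = op.cac_objective(hopeless, seasons, truth)
        assert np.isfinite(value)
        # penalty substitutes 31 October, far beyond any spring date
        assert value > 200

    def test_mismatched_lengths_are_data_error(self):
        seasons, params, truth = self.seasons_and_truth()
        with pytest.raises(DataError):
            op.cac_objective(params, seasons[:-1], truth)

    def test_gdd_objective_self_consistency_and_shift(self):
        seasons, _, truth = self.seasons_and_truth()
        gdd = op.GDDParams(tb=5, tx_base=30, hr=60)
        pred = np.array([
            op.predict_phase_date(s, int(t), gdd, "blooming").jday
            for s, t in zip(seasons, truth)
        ])
        assert op.gdd_objective(gdd, seasons, pred, truth) == 0.0
        assert op.gdd_objective(gdd, seasons, pred + 2, truth) == 2.0
        impossible = op.GDDParams(tb=5, tx_base=30, hr=1e6)
        assert op.gdd_objective(impossible, seasons, pred, truth) > 100


class TestGeneticAlgorithm:
    def test_convex_toy_reaches_optimum(self):
        result = ga_minimize(
            lambda x: (x[0] - 3.0) ** 2, [(0.0, 10.0)],
            GAConfig(seed=0, max_generations=400),
        )
        assert abs(result.x[0] - 3.0) < 1e-2

    def test_same_seed_is_bit_identical(self):
        cfg = GAConfig(seed=42, max_generations=50, patience=50)
        f = lambda x: (x[0] - 1.0) ** 2 + (x[1] + 2.0) ** 2
        a = ga_minimize(f, [(-5, 5), (-5, 5)], cfg)
        b = ga_minimize(f, [(-5, 5), (-5, 5)], cfg)
        assert np.array_equal(a.x, b.x) and a.fun == b.fun
        assert np.array_equal(a.trace, b.trace)

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(BoundsError):
            ga_minimize(lambda x: x[0], [(1.0, 1.0)], GAConfig(seed=0))

    def test_trace_monotone_and_solution_in_bounds(self):
        rng_obj = lambda x: np.sin(5 * x[0]) + 0.1 * x[0] ** 2
        result = ga_minimize(rng_obj, [(-4.0, 4.0)],
                             GAConfig(seed=3, max_generations=120))
        assert np.all(np.diff(result.trace) <= 0)
        assert -4.0 <= result.x[0] <= 4.0

    def test_non_finite_objective_is_reported(self):
        with pytest.raises(OptimizerError, match="nan"):
            ga_minimize(lambda x: float("nan"), [(0, 1)], GAConfig(seed=0))

    def test_config_validation(self):
        with pytest.raises(BoundsError):
            GAConfig(population_size=2)
        with pytest.raises(BoundsError):
            GAConfig(crossover_prob=1.5)


class TestLOOCV:
    def test_fold_count_and_zero_noise_errors(self):
        # six seasons whose cold spell varies in length, so sprouting dates
        # differ season to season
        seasons = [
            segmented_season(1997, [(n, 2, 8), (365 - n, 12, 18)])
            for n in (35, 40, 45, 50, 55, 60)
        ]
        params = op.CACParams(tc=10, cr=-30)
        truth = np.array([op.predict_sprouting(s, params).jday for s in seasons])
        assert len(np.unique(truth)) > 3
        result = op.loocv(
            seasons, truth, kind="cac",
            bounds=op.ParameterBounds({"tc": (7.0, 14.0), "cr": (-60.0, -10.0)}),
            config=dict(population_size=30, max_generations=100, patience=50,
                        random_state=0),
        )
        assert result.n_samples == len(seasons)
        assert len(result.fold_errors) == len(seasons)
        assert result.mean <= 1.0
        if np.all(result.fold_errors == result.fold_errors[0]):
            assert result.stdev == 0.0

    def test_too_few_observations(self):
        seasons = [segmented_season(1997, [(10, 2, 8), (355, 12, 18)])] * 2
        with pytest.raises(DataError):
            op.loocv(seasons, [100, 101], kind="cac")

    def test_statistics_recomputed_from_folds(self):
        result = op.LOOCVResult.from_errors([2.0, 2.0, 2.0])
        assert result.mean == 2.0 and result.stdev == 0.0 and result.n_samples == 3


class TestTaylorStats:
    def test_perfect_prediction(self):
        stats = op.taylor_stats([1, 2, 3, 4], [1, 2, 3, 4])
        assert stats.pearson_r == pytest.approx(1.0)
        assert stats.sd_ratio == pytest.approx(1.0)
        assert stats.centered_rmse_norm == pytest.approx(0.0)

    def test_constant_shift_is_invisible_to_centered_stats(self):
        obs = np.array([10.0, 20.0, 30.0, 40.0])
        stats = op.taylor_stats(obs + 7.0, obs)
        assert stats.pearson_r == pytest.approx(1.0)
        assert stats.sd_ratio == pytest.approx(1.0)
        assert stats.centered_rmse_norm == pytest.approx(0.0)
        assert stats.rmse == pytest.approx(7.0)

    def test_linear_scaling_doubles_sd_ratio(self):
        obs = np.array([10.0, 20.0, 30.0, 40.0])
        pred = 2.0 * (obs - obs.mean()) + obs.mean()
        stats = op.taylor_stats(pred, obs)
        assert stats.sd_ratio == pytest.approx(2.0)
        assert stats.pearson_r == pytest.approx(1.0)

    def test_zero_observed_variance_rejected(self):
        with pytest.raises(StatisticsError):
            op.taylor_stats([1, 2, 3], [5, 5, 5])

    @given(st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_taylor_identity(self, seed):
        rng = np.random.default_rng(seed)
        obs = rng.normal(size=20)
        pred = obs + rng.normal(scale=rng.uniform(0.1, 3.0), size=20)
        stats = op.taylor_stats(pred, obs)
        lhs = stats.centered_rmse_norm**2
        rhs = stats.sd_ratio**2 + 1 - 2 * stats.sd_ratio * stats.pearson_r
        assert lhs == pytest.approx(rhs, abs=1e-9)


class TestSummaries:
    def test_packaged_parameter_class_means(self):
        tables = op.summarize_phenology(op.cultivar_parameter_table())
        by_class = tables["by_class"]
        assert by_class.loc["mid-late", "cr"] == pytest.approx(-135.0)
        assert by_class.loc["mid-late", "hr_bloom"] == pytest.approx(379.0)
        assert by_class.loc["mid-late", "hr_pit"] == pytest.approx(1295.0)

    def test_packaged_date_class_gap(self):
        tables = op.summarize_phenology(op.mean_phase_dates())
        diff = tables["class_difference"]
        assert diff.loc["pit_hardening", "jday"] == pytest.approx(28.0)
        assert diff.loc["blooming", "jday"] == pytest.approx(10.5)

    def test_single_row_is_its_own_mean(self):
        table = op.mean_phase_dates().iloc[:1]
        tables = op.summarize_phenology(table)
        assert tables["by_cultivar"].iloc[0]["jday"] == 96

    def test_unknown_class_rejected(self):
        table = op.mean_phase_dates().copy()
        table.loc[0, "maturity_class"] = "mystery"
        with pytest.raises(DataError):
            op.summarize_phenology(table)
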