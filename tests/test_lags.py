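"""Lag alignment, calculator fitting, and the exhaustive grid scan."""

import dataclasses
import itertools

import numpy as np
import pytest

from dietlag import (
    FULL_SPAN,
    AnalysisConfig,
    CollinearityError,
    InsufficientDataError,
    LifePeriod,
    NutrientSeries,
    RSeries,
    count_lag_combinations,
    evaluate_lag_vectors,
    fit_calculator,
    global_optimize,
    shift_alignment,
    synth_dataset,
    synth_validation_dataset,
)
from dietlag.synthetic import SyntheticTruth, VALIDATION_TRENDS, VALIDATION_NOISE_SD

YOUTH = LifePeriod("youth", 1929, 1949)


def _naive_optimize(series, r, period, config):
    """Materialize-everything oracle: one explicit fit per lag vector."""
    L = config.max_lag + 1
    best = None
    grids = {}
    for lags in itertools.product(range(L), repeat=5):
        try:
            X, y, _ = shift_alignment(series, r, lags, period, config.min_rows)
            r_fit = fit_calculator(X, y, min_rows=config.min_rows).r_fit
        except InsufficientDataError:
            grids[lags] = np.nan
            continue
        grids[lags] = r_fit
        if best is None or r_fit > best[1]:
            best = (lags, r_fit)
    return best, grids


class TestCountCombinations:
    def test_full_study_grid(self):
        assert count_lag_combinations(20, 5) == 4_084_101

    @pytest.mark.parametrize("max_lag, n, expected", [(0, 5, 1), (5, 5, 7776), (2, 3, 27)])
    def test_small_grids(self, max_lag, n, expected):
        assert count_lag_combinations(max_lag, n) == expected

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            count_lag_combinations(-1, 5)


class TestShiftAlignment:
    @pytest.fixture()
    def series(self, rng):
        years = np.arange(1927, 1951)
        return NutrientSeries(years=years, values=rng.uniform(10, 400, (years.size, 5)))

    @pytest.fixture()
    def response(self, rng):
        years = np.arange(1929, 1950)
        return RSeries(years=years, r=rng.uniform(-0.5, 0.5, years.size))

    def test_zero_lags_pair_directly(self, series, response):
        X, y, years = shift_alignment(series, response, (0,) * 5, YOUTH)
        np.testing.assert_array_equal(years, np.arange(1929, 1950))
        np.testing.assert_array_equal(y, response.r)
        np.testing.assert_array_equal(X, series.values[2:-1])

    def test_lagged_row_uses_earlier_availability(self, series, response):
        X, _, years = shift_alignment(series, response, (2, 0, 0, 0, 0), YOUTH)
        assert years[0] == 1929
        # carbohydrate column of the 1929 row comes from 1927
        assert X[0, 0] == series.values[0, 0]
        assert X[0, 1] == series.values[2, 1]

    def test_uncovered_years_dropped_until_insufficient(self, rng):
        years = np.arange(1929, 1951)  # no back-history at all
        series = NutrientSeries(years=years, values=rng.uniform(10, 400, (years.size, 5)))
        r = RSeries(years=years, r=rng.uniform(-0.5, 0.5, years.size))
        # lag 10 leaves 1939-1949 = 11 rows
        _, _, kept = shift_alignment(series, r, (10, 0, 0, 0, 0), YOUTH)
        assert kept[0] == 1939 and kept[-1] == 1949
        # lag 20 leaves a single row -> too few
        with pytest.raises(InsufficientDataError):
            shift_alignment(series, r, (20, 0, 0, 0, 0), YOUTH)


class TestFitCalculator:
    def test_exact_recovery_of_noiseless_linear_response(self, rng):
        X = rng.uniform(0, 400, (15, 5))
        alpha, betas = 0.3, np.array([0.001, -0.002, 0.0015, 0.0, -0.0005])
        y = alpha + X @ betas
        fit = fit_calculator(X, y)
        assert fit.alpha == pytest.approx(alpha, abs=1e-10)
        np.testing.assert_allclose(fit.betas, betas, atol=1e-10)
        assert fit.r_fit == pytest.approx(1.0, abs=1e-12)

    def test_constant_response_defines_zero_fit(self, rng):
        X = rng.uniform(0, 400, (12, 5))
        fit = fit_calculator(X, np.full(12, 0.4))
        assert fit.r_fit == 0.0
        np.testing.assert_array_equal(fit.betas, np.zeros(5))
        assert fit.alpha == pytest.approx(0.4)

    def test_matches_statsmodels_ols(self, rng):
        import statsmodels.api as sm

        for _ in range(20):
            X = rng.uniform(0, 400, (12, 5))
            y = rng.normal(0, 0.3, 12)
            fit = fit_calculator(X, y)
            res = sm.OLS(y, sm.add_constant(X)).fit()
            assert fit.alpha == pytest.approx(res.params[0], abs=1e-8)
            np.testing.assert_allclose(fit.betas, res.params[1:], atol=1e-8)
            assert fit.r_fit == pytest.approx(np.sqrt(res.rsquared), abs=1e-8)

    def test_collinear_design_names_columns(self, rng):
        X = rng.uniform(0, 400, (12, 5))
        X[:, 2] = 2.0 * X[:, 1]  # sat_fat duplicates protein
        with pytest.raises(CollinearityError, match="protein"):
            fit_calculator(X, rng.normal(size=12))

    def test_too_few_rows(self, rng):
        with pytest.raises(InsufficientDataError):
            fit_calculator(rng.uniform(0, 1, (6, 5)), rng.normal(size=6))

    def test_r_fit_invariant_under_affine_predictor_rescaling(self, rng):
        X = rng.uniform(0, 400, (15, 5))
        y = rng.normal(0, 0.3, 15)
        base = fit_calculator(X, y).r_fit
        scales = rng.uniform(0.1, 10, 5)
        shifts = rng.uniform(-50, 50, 5)
        rescaled = fit_calculator(X * scales + shifts, y).r_fit
        assert rescaled == pytest.approx(base, abs=1e-10)


class TestGlobalOptimize:
    def test_zero_max_lag_equals_single_fit(self, noiseless_dataset):
        series, r, _ = noiseless_dataset
        cfg = AnalysisConfig(max_lag=0, periods=(FULL_SPAN,))
        res = global_optimize(series, r, FULL_SPAN, cfg)
        X, y, _ = shift_alignment(series, r, (0,) * 5, FULL_SPAN)
        direct = fit_calculator(X, y)
        assert res.optimal_lags == (0,) * 5
        assert res.r_optimal == pytest.approx(direct.r_fit, abs=1e-12)
        assert res.usable_count == 1 and res.unusable_count == 0

    def test_noiseless_truth_recovered_exactly(self):
        rng = np.random.default_rng(77)
        from dietlag import random_truth

        base = random_truth(
            rng, max_lag=5, trends=VALIDATION_TRENDS,
            availability_noise_sd=VALIDATION_NOISE_SD, center_range=(-0.1, 0.1),
        )
        truth = dataclasses.replace(base, true_lags=(3, 0, 1, 2, 4))
        series, r = synth_dataset(
            truth, trends=VALIDATION_TRENDS, availability_noise_sd=VALIDATION_NOISE_SD
        )
        res = global_optimize(series, r, FULL_SPAN, AnalysisConfig(max_lag=5, periods=(FULL_SPAN,)))
        assert res.optimal_lags == (3, 0, 1, 2, 4)
        assert res.r_optimal == pytest.approx(1.0, abs=1e-10)

    def test_matches_naive_oracle_with_varying_windows(self, rng):
        # series with no back-history: usable windows shrink with max(lags)
        years = np.arange(1929, 1951)
        series = NutrientSeries(years=years, values=rng.uniform(10, 400, (years.size, 5)))
        r = RSeries(years=years, r=rng.uniform(-0.5, 0.5, years.size))
        cfg = AnalysisConfig(max_lag=2, periods=(YOUTH,))
        res = global_optimize(series, r, YOUTH, cfg)
        (naive_lags, naive_r), naive_grid = _naive_optimize(series, r, YOUTH, cfg)
        assert res.optimal_lags == naive_lags
        assert res.r_optimal == pytest.approx(naive_r, abs=1e-12)
        for lags, val in naive_grid.items():
            got = res.r_grid[lags]
            if np.isnan(val):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(val, abs=1e-12)

    def test_usable_and_unusable_counts_conserve_grid(self, rng):
        years = np.arange(1929, 1951)
        series = NutrientSeries(years=years, values=rng.uniform(10, 400, (years.size, 5)))
        r = RSeries(years=years, r=rng.uniform(-0.5, 0.5, years.size))
        cfg = AnalysisConfig(max_lag=16, periods=(YOUTH,))
        res = global_optimize(series, r, YOUTH, cfg)
        assert res.usable_count + res.unusable_count == count_lag_combinations(16, 5)
        assert res.unusable_count > 0  # large lags leave < 7 rows

    def test_r_optimal_dominates_grid(self, noiseless_scan):
        grid = noiseless_scan.r_grid
        assert noiseless_scan.r_optimal == np.nanmax(grid)
        assert grid[noiseless_scan.optimal_lags] == noiseless_scan.r_optimal

    def test_tie_break_is_lexicographic(self):
        # constant response: every combination fits r_fit = 0 exactly
        years = np.arange(1929, 2006)
        rng = np.random.default_rng(5)
        series = NutrientSeries(years=years, values=rng.uniform(10, 400, (years.size, 5)))
        r = RSeries(years=years, r=np.full(years.size, 0.3))
        cfg = AnalysisConfig(max_lag=2, periods=(FULL_SPAN,))
        res = global_optimize(series, r, FULL_SPAN, cfg)
        assert res.optimal_lags == (0, 0, 0, 0, 0)
        assert res.r_optimal == 0.0

    def test_common_window_mode_uses_max_lag_window_everywhere(self, rng):
        years = np.arange(1929, 1951)
        series = NutrientSeries(years=years, values=rng.uniform(10, 400, (years.size, 5)))
        r = RSeries(years=years, r=rng.uniform(-0.5, 0.5, years.size))
        cfg = AnalysisConfig(max_lag=2, periods=(YOUTH,), coverage="common_window")
        res = global_optimize(series, r, YOUTH, cfg)
        # every combination fitted on the 1931-1949 window, including (0,...,0)
        X, y, years_used = shift_alignment(
            series, r, (0,) * 5, LifePeriod("clip", 1931, 1949)
        )
        direct = fit_calculator(X, y)
        assert res.r_grid[(0, 0, 0, 0, 0)] == pytest.approx(direct.r_fit, abs=1e-12)

    def test_scan_agrees_with_direct_evaluation(self, noiseless_dataset, noiseless_scan):
        series, r, _ = noiseless_dataset
        rng = np.random.default_rng(3)
        vecs = rng.integers(0, 6, size=(100, 5))
        cfg = AnalysisConfig(max_lag=5, periods=(FULL_SPAN,))
        direct = evaluate_lag_vectors(series, r, FULL_SPAN, vecs, cfg)
        grid = np.array([noiseless_scan.r_grid[tuple(v)] for v in vecs])
        np.testing.assert_allclose(direct, grid, atol=1e-12)

    def test_no_usable_combination_raises(self, rng):
        years = np.arange(1929, 1937)
        series = NutrientSeries(years=years, values=rng.uniform(10, 400, (years.size, 5)))
        r = RSeries(years=years, r=rng.uniform(-0.5, 0.5, years.size))
        period = LifePeriod("tiny", 1933, 1936)
        with pytest.raises(InsufficientDataError):
            global_optimize(series, r, period, AnalysisConfig(max_lag=1, periods=(period,)))
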