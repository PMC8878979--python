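"""Threshold rules, outlier filtering, and the empirical grid search."""

import numpy as np
import pytest

from rssistep import (
    ChannelModel,
    ThresholdPair,
    distance_from_path_loss,
    filter_path_loss,
    grid_search_thresholds,
    lower_threshold_rule,
    survival_function,
    upper_threshold_rule,
)
from rssistep.errors import ConfigError, EmptyFilterError, GridError

from conftest import make_series


class TestUpperThresholdRule:
    @pytest.mark.parametrize(
        "mu, sigma, env, expected",
        [
            (48.0900, 4.2419, "indoor", 52.3319),  # indoor walking
            (52.3400, 4.7991, "indoor", 57.1391),  # indoor jogging
            (49.6100, 3.4882, "outdoor", 51.3541),  # outdoor walking
            (52.3900, 3.8615, "outdoor", 54.3208),  # outdoor jogging
        ],
    )
    def test_reference_values(self, mu, sigma, env, expected):
        assert upper_threshold_rule(mu, sigma, env) == pytest.approx(expected, abs=1e-4)

    def test_zero_sigma_returns_mu(self):
        assert upper_threshold_rule(50.0, 0.0, "indoor") == 50.0

    def test_k_override(self):
        assert upper_threshold_rule(50.0, 2.0, "indoor", k=1.5) == 53.0

    def test_unknown_environment(self):
        with pytest.raises(ConfigError):
            upper_threshold_rule(50.0, 2.0, "underwater")

    def test_negative_sigma_rejected(self):
        with pytest.raises(ConfigError):
            upper_threshold_rule(50.0, -1.0, "indoor")


class TestLowerThresholdRule:
    def test_nearest_survival_wins(self, series_factory):
        curve = survival_function(
            series_factory([36, 38, 40, 40, 42, 44, 46, 48, 50, 52])
        )
        lower, s = lower_threshold_rule(curve, 0.68)
        assert lower == 42.0  # |0.6 - 0.68| beats |0.8 - 0.68|
        assert s == pytest.approx(0.6)

    def test_constant_series(self, series_factory):
        curve = survival_function(series_factory([50.0] * 5))
        lower, s = lower_threshold_rule(curve, 0.68)
        assert (lower, s) == (50.0, 1.0)

    def test_target_one_gives_minimum(self, series_factory):
        curve = survival_function(series_factory([41, 44, 47, 52]))
        lower, s = lower_threshold_rule(curve, 1.0)
        assert lower == 41.0 and s == 1.0

    def test_tie_breaks_toward_smaller_value(self, series_factory):
        # S = [1.0, 0.5] over {40, 45}: both are 0.25 from target 0.75
        curve = survival_function(series_factory([40, 40, 45, 45]))
        lower, _ = lower_threshold_rule(curve, 0.75)
        assert lower == 40.0

    def test_result_in_support(self, series_factory):
        rng = np.random.default_rng(3)
        values = rng.integers(30, 60, 200).astype(float)
        curve = survival_function(series_factory(values))
        lower, _ = lower_threshold_rule(curve)
        assert lower in values


class TestFilterPathLoss:
    def test_inclusive_window(self, series_factory):
        pair = ThresholdPair(lower_db=40.0, upper_db=52.0)
        filtered = filter_path_loss(series_factory([30, 40, 41, 52, 53]), pair)
        assert filtered.values_db.tolist() == [40.0, 41.0, 52.0]
        assert filtered.n_dropped_below == 1
        assert filtered.n_dropped_above == 1
        assert filtered.n_total == 5

    def test_unbounded_proxy_is_identity(self, series_factory):
        pair = ThresholdPair(lower_db=-1e9, upper_db=1e9)
        series = series_factory([30, 45, 60])
        assert filter_path_loss(series, pair).values_db.tolist() == [30, 45, 60]

    def test_empty_after_filter(self, series_factory):
        pair = ThresholdPair(lower_db=60.0, upper_db=70.0)
        with pytest.raises(EmptyFilterError, match="60"):
            filter_path_loss(series_factory([40, 45, 50]), pair)

    def test_idempotent(self, series_factory):
        rng = np.random.default_rng(5)
        series = series_factory(rng.integers(30, 60, 500).astype(float))
        pair = ThresholdPair(lower_db=40.0, upper_db=52.0)
        once = filter_path_loss(series, pair)
        twice = filter_path_loss(once, pair)
        np.testing.assert_array_equal(once.values_db, twice.values_db)

    def test_widening_never_shrinks_retention(self, series_factory):
        rng = np.random.default_rng(6)
        series = series_factory(rng.integers(30, 60, 500).astype(float))
        last = 0
        for widen in range(0, 10):
            pair = ThresholdPair(lower_db=44.0 - widen, upper_db=46.0 + widen)
            kept = len(filter_path_loss(series, pair))
            assert kept >= last
            last = kept

    def test_invalid_pair_rejected(self):
        with pytest.raises(ConfigError):
            ThresholdPair(lower_db=50.0, upper_db=50.0)


class TestGridSearch:
    def test_single_cell(self, series_factory, model):
        series = series_factory([44, 46, 48])
        result = grid_search_thresholds(series, 0.7, model, [43.0], [49.0])
        assert (result.best_pair.lower_db, result.best_pair.upper_db) == (43.0, 49.0)
        assert result.best_pair.method == "grid"

    def test_hand_computed_cells(self, series_factory, model):
        # d0 chosen as the distance at 48 dB; every cell mean is a closed-form
        # average of the retained distances
        series = series_factory([46, 47, 48, 49, 50])
        d0 = distance_from_path_loss(48.0, model)
        result = grid_search_thresholds(series, d0, model, [46.0, 47.0], [49.0, 50.0])
        for (lo, up), (d_bar, abs_mm, rel_pct) in result.error_table.items():
            vals = [v for v in [46, 47, 48, 49, 50] if lo <= v <= up]
            expected = np.mean([distance_from_path_loss(v, model) for v in vals])
            assert d_bar == pytest.approx(expected, rel=1e-12)
            assert abs_mm == pytest.approx(1000 * abs(expected - d0), rel=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_best_cell_matches_exhaustive_recheck(self, seed, series_factory, model):
        rng = np.random.default_rng(seed)
        series = series_factory(rng.integers(35, 58, 2000).astype(float))
        lows = np.arange(36.0, 46.0)
        ups = np.arange(46.0, 56.0)
        d0 = 0.714
        result = grid_search_thresholds(series, d0, model, lows, ups)
        # brute-force oracle: recompute every cell's error independently
        best = None
        for lo in lows:
            for up in ups:
                vals = series.values_db[(series.values_db >= lo) & (series.values_db <= up)]
                if vals.size == 0 or not lo < up:
                    continue
                rel = abs(np.mean(distance_from_path_loss(vals, model)) - d0) / d0
                if best is None or rel < best[0] - 1e-15:
                    best = (rel, lo, up)
        best_rel = result.error_table[(result.best_pair.lower_db, result.best_pair.upper_db)][2]
        assert best_rel == pytest.approx(100 * best[0], rel=1e-9)
        for cell in result.error_table.values():
            assert cell[2] >= best_rel - 1e-9

    def test_all_cells_empty(self, series_factory, model):
        with pytest.raises(GridError):
            grid_search_thresholds(series_factory([45.0]), 0.7, model, [50.0], [55.0])

    def test_matrix_export_shape(self, series_factory, model):
        series = series_factory([44, 46, 48, 50])
        result = grid_search_thresholds(
            series, 0.7, model, [43.0, 45.0], [49.0, 51.0]
        )
        frame = result.to_frame()
        assert list(frame.index) == [49.0, 51.0]  # rows = upper
        assert list(frame.columns) == [43.0, 45.0]  # columns = lower
        assert frame.notna().all().all()
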