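"""End-to-end step-length estimation from a raw RSSI trace.

Stages: clean the trace to a path-loss series; build the probability
histogram and fit the two-term Gaussian; derive the (lower, upper) threshold
pair (closed-form rules, or grid search when ground truth is supplied);
filter outliers; convert the retained losses to distances and average them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .channel import ChannelModel, ErrorMetrics, distance_from_path_loss, error_metrics
from .errors import ConfigError, EmptyFilterError
from .histogram import (
    TwoTermGaussianFit,
    build_histogram,
    fit_two_term_gaussian,
    second_hump_stats,
    survival_function,
)
from .io import PathLossSeries, RSSITrace, to_path_loss_series
from .thresholds import (
    DEFAULT_SURVIVAL_TARGET,
    GridSearchResult,
    ThresholdPair,
    filter_path_loss,
    grid_search_thresholds,
    lower_threshold_rule,
    upper_threshold_rule,
)

__all__ = ["StepLengthEstimate", "estimate_from_filtered", "run_pipeline"]


@dataclass(frozen=True)
class StepLengthEstimate:
    """Average estimated step length with full provenance."""

    d_bar_m: float
    n_retained: int
    pair: ThresholdPair
    fit: TwoTermGaussianFit | None = None
    metrics: ErrorMetrics | None = None
    series_counts: dict | None = None
    environment: str | None = None
    grid: GridSearchResult | None = None

    def to_dict(self) -> dict:
        out = {
            "d_bar_m": self.d_bar_m,
            "n_retained": self.n_retained,
            "pair": self.pair.to_dict(),
            "environment": self.environment,
            "series_counts": self.series_counts,
        }
        if self.fit is not None:
            out["fit"] = self.fit.to_dict()
        if self.metrics is not None:
            out["metrics"] = self.metrics.to_dict()
        return out


def estimate_from_filtered(
    filtered: PathLossSeries,
    model: ChannelModel = ChannelModel(),
    mean_domain: str = "distance",
) -> float:
    """Average step length of a threshold-filtered path-loss series.

    Default behaviour converts every retained path loss to a distance and
    takes the arithmetic mean in the distance domain (the estimate is "the
    average estimated distance between two ankles"). ``mean_domain="db"``
    instead converts the mean path loss — exposed for sensitivity analysis;
    the two differ because distance is convex in dB.
    """
    if len(filtered) == 0:
        raise EmptyFilterError("cannot estimate from an empty filtered series")
    if mean_domain == "distance":
        return float(np.mean(distance_from_path_loss(filtered.values_db, model)))
    if mean_domain == "db":
        return float(distance_from_path_loss(float(np.mean(filtered.values_db)), model))
    raise ConfigError(f"unknown mean_domain {mean_domain!r}; expected 'distance' or 'db'")


def run_pipeline(
    trace: RSSITrace,
    environment: str,
    model: ChannelModel = ChannelModel(),
    d0: float | None = None,
    threshold_mode: str = "rule",
    bin_width_db: float = 1.0,
    survival_target: float = DEFAULT_SURVIVAL_TARGET,
    k: float | None = None,
    grid_lower: np.ndarray | None = None,
    grid_upper: np.ndarray | None = None,
    mean_domain: str = "distance",
) -> StepLengthEstimate:
    """Run the full estimation pipeline on a raw trace.

    Rule mode: two-term Gaussian fit gives the upper threshold mu + k*sigma
    (k by ``environment`` unless overridden); the empirical survival curve
    gives the lower threshold at ``survival_target``. Grid mode requires
    ``d0`` and searches threshold pairs exhaustively; default candidate grids
    span mu - 3 sigma .. mu (lower) and mu .. mu + 3 sigma (upper) in 1 dB
    steps around the fitted second hump.

    The whole recording is processed as one batch; the same trace and
    configuration always produce the identical estimate.
    """
    if threshold_mode not in ("rule", "grid"):
        raise ConfigError(f"unknown threshold_mode {threshold_mode!r}")
    series = to_path_loss_series(trace)
    hist = build_histogram(series, bin_width=bin_width_db)
    fit = fit_two_term_gaussian(hist)
    mu, sigma = second_hump_stats(fit)

    grid = None
    if threshold_mode == "rule":
        upper = upper_threshold_rule(mu, sigma, environment, k=k)
        curve = survival_function(series)
        lower, s_at_lower = lower_threshold_rule(curve, survival_target)
        if not lower < upper:
            raise ConfigError(
                f"degenerate threshold pair: lower {lower} dB >= upper {upper:.4f} dB"
            )
        k_used = k if k is not None else {"indoor": 1.0, "outdoor": 0.5}[environment]
        pair = ThresholdPair(
            lower_db=lower,
            upper_db=upper,
            method="rule",
            k_used=k_used,
            survival_at_lower=s_at_lower,
        )
    else:
        if d0 is None:
            raise ConfigError("grid threshold mode requires the true step length d0")
        if grid_lower is None:
            grid_lower = np.arange(round(mu - 3 * sigma), round(mu) + 1.0)
        if grid_upper is None:
            grid_upper = np.arange(round(mu), round(mu + 3 * sigma) + 1.0)
        grid = grid_search_thresholds(series, d0, model, grid_lower, grid_upper)
        pair = grid.best_pair

    filtered = filter_path_loss(series, pair)
    d_bar = estimate_from_filtered(filtered, model, mean_domain=mean_domain)
    metrics = error_metrics(d_bar, d0) if d0 is not None else None
    return StepLengthEstimate(
        d_bar_m=d_bar,
        n_retained=len(filtered),
        pair=pair,
        fit=fit,
        metrics=metrics,
        series_counts=series.counts(),
        environment=environment,
        grid=grid,
    )
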