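"""Outlier threshold pair for on-ankle path loss, and window filtering.

The step length corresponds to path losses around the second histogram hump,
so samples outside a (lower, upper) window are outliers:

* upper threshold: mu + k*sigma of the second fitted hump, with k = 1 in an
  indoor environment and k = 0.5 outdoors (indoor multipath widens the spread
  of losses around the full-separation events, warranting a larger margin);
* lower threshold: the observed path-loss value where the empirical survival
  rate S(x) = P(PL >= x) is closest to 0.68.

Alternatively, when the true step length is known, the pair can be found by
exhaustive grid search minimizing the relative estimation error.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .channel import ChannelModel, distance_from_path_loss, error_metrics
from .errors import ConfigError, EmptyFilterError, EmptyInputError, GridError
from .histogram import SurvivalCurve
from .io import PathLossSeries

__all__ = [
    "UPPER_K_BY_ENVIRONMENT",
    "DEFAULT_SURVIVAL_TARGET",
    "ThresholdPair",
    "GridSearchResult",
    "upper_threshold_rule",
    "lower_threshold_rule",
    "filter_path_loss",
    "grid_search_thresholds",
]

UPPER_K_BY_ENVIRONMENT = {"indoor": 1.0, "outdoor": 0.5}
DEFAULT_SURVIVAL_TARGET = 0.68


@dataclass(frozen=True)
class ThresholdPair:
    """Lower/upper path-loss bounds in dB with provenance."""

    lower_db: float
    upper_db: float
    method: str = "rule"  # "rule" | "grid"
    k_used: float | None = None
    survival_at_lower: float | None = None

    def __post_init__(self) -> None:
        if not self.lower_db < self.upper_db:
            raise ConfigError(
                f"lower threshold must be below upper, got "
                f"({self.lower_db}, {self.upper_db})"
            )
        if self.method not in ("rule", "grid"):
            raise ConfigError(f"unknown threshold method {self.method!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class GridSearchResult:
    """Exhaustive (lower, upper) threshold search minimizing relative error.

    ``error_table`` maps (lower, upper) to (d_bar m, abs error mm,
    rel error %); cells left empty by the filter are absent.
    """

    best_pair: ThresholdPair
    error_table: dict
    grid_lower_db: tuple
    grid_upper_db: tuple

    def to_frame(self) -> pd.DataFrame:
        """Matrix view: rows = upper threshold, columns = lower threshold,
        cell = "d_bar (abs_mm, rel_pct)"."""
        frame = pd.DataFrame(
            index=pd.Index(self.grid_upper_db, name="upper_db"),
            columns=pd.Index(self.grid_lower_db, name="lower_db"),
            dtype=object,
        )
        for (lo, up), (d_bar, abs_mm, rel_pct) in self.error_table.items():
            frame.loc[up, lo] = f"{d_bar:.4f} ({abs_mm:.2f}, {rel_pct:.2f})"
        return frame


def upper_threshold_rule(
    mu: float, sigma: float, environment: str, k: float | None = None
) -> float:
    """Upper threshold mu + k*sigma; k = 1 indoor, 0.5 outdoor unless given."""
    if sigma < 0:
        raise ConfigError(f"sigma must be >= 0, got {sigma}")
    if k is None:
        try:
            k = UPPER_K_BY_ENVIRONMENT[environment]
        except KeyError:
            raise ConfigError(
                f"unknown environment {environment!r}; expected "
                f"{sorted(UPPER_K_BY_ENVIRONMENT)}"
            ) from None
    return mu + k * sigma


def lower_threshold_rule(
    curve: SurvivalCurve, target_survival: float = DEFAULT_SURVIVAL_TARGET
) -> tuple[float, float]:
    """Lower threshold: observed value whose survival is nearest the target.

    Returns ``(threshold_db, survival_at_threshold)``. Ties in
    |S(x) - target| break toward the smaller path loss. The result always
    lies in the observed support (no interpolation; RSSI is quantized).
    """
    if curve.support_db.size == 0:
        raise EmptyInputError("survival curve is empty")
    if not 0.0 < target_survival <= 1.0:
        raise ConfigError(f"target survival must be in (0, 1], got {target_survival}")
    gap = np.abs(curve.survival - target_survival)
    idx = int(np.argmin(gap))  # argmin takes the first (= smallest x) on ties
    return float(curve.support_db[idx]), float(curve.survival[idx])


def filter_path_loss(series: PathLossSeries, pair: ThresholdPair) -> PathLossSeries:
    """Retain values with lower <= v <= upper (inclusive at both ends).

    Values strictly outside the window are outliers; counts of removed
    values are recorded on the returned series.
    """
    values = series.values_db
    below = values < pair.lower_db
    above = values > pair.upper_db
    retained = values[~below & ~above]
    if retained.size == 0:
        raise EmptyFilterError(
            f"threshold pair ({pair.lower_db}, {pair.upper_db}) dB retained no "
            f"samples out of {values.size}"
        )
    return PathLossSeries(
        values_db=retained,
        n_total=values.size,
        n_dropped_below=int(below.sum()),
        n_dropped_above=int(above.sum()),
    )


def grid_search_thresholds(
    series: PathLossSeries,
    d0: float,
    model: ChannelModel,
    grid_lower: np.ndarray,
    grid_upper: np.ndarray,
) -> GridSearchResult:
    """Evaluate every (lower, upper) pair with lower < upper and pick the best.

    Each cell filters the series, converts retained losses to distances,
    averages them and scores against the true step length ``d0``. The best
    pair minimizes the relative error; ties break toward the narrower window,
    then the lower upper threshold.
    """
    grid_lower = np.asarray(grid_lower, dtype=float)
    grid_upper = np.asarray(grid_upper, dtype=float)
    if grid_lower.size == 0 or grid_upper.size == 0:
        raise ConfigError("threshold grids must be non-empty")
    if d0 <= 0:
        raise ConfigError(f"true step length must be > 0, got {d0}")

    table = {}
    for lo in grid_lower:
        for up in grid_upper:
            if not lo < up:
                continue
            mask = (series.values_db >= lo) & (series.values_db <= up)
            if not mask.any():
                continue
            d_bar = float(np.mean(distance_from_path_loss(series.values_db[mask], model)))
            metrics = error_metrics(d_bar, d0)
            table[(float(lo), float(up))] = (
                d_bar,
                metrics.abs_error_mm,
                metrics.rel_error_pct,
            )
    if not table:
        raise GridError("every grid cell was empty after filtering")

    def rank(item):
        (lo, up), (_, _, rel) = item
        return (rel, up - lo, up)

    (best_lo, best_up), _ = min(table.items(), key=rank)
    best_pair = ThresholdPair(lower_db=best_lo, upper_db=best_up, method="grid")
    return GridSearchResult(
        best_pair=best_pair,
        error_table=table,
        grid_lower_db=tuple(float(x) for x in grid_lower),
        grid_upper_db=tuple(float(x) for x in grid_upper),
    )
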