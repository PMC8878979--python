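"""Probability histogram of on-ankle path loss and its two-term Gaussian model.

During steady gait the path-loss histogram is bimodal: a first, smaller hump
where the feet pass each other (half-finished step, small separation) and a
second, bigger hump where the feet are most apart. The histogram is modelled
as a sum of two Gaussian-shaped terms

    f(x) = a1 exp(-((x - b1)/c1)^2) + a2 exp(-((x - b2)/c2)^2)

fitted by nonlinear least squares against per-bin probability mass. The
second term summarizes the full-separation events; its centroid and spread

    mu = b2,    sigma = c2 / sqrt(2)

drive the upper outlier threshold. The empirical survival function
S(x) = P(PL >= x) of the same samples drives the lower threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import EmptyInputError, FitError, InsufficientDataError, InvalidFitError
from .io import PathLossSeries

__all__ = [
    "ProbabilityHistogram",
    "TwoTermGaussianFit",
    "SurvivalCurve",
    "build_histogram",
    "two_term_gaussian",
    "fit_two_term_gaussian",
    "second_hump_stats",
    "survival_function",
]


@dataclass(frozen=True)
class ProbabilityHistogram:
    """Per-bin probability mass of a path-loss sample set."""

    bin_centers_db: np.ndarray
    probabilities: np.ndarray
    bin_width_db: float
    n_samples: int

    def __post_init__(self) -> None:
        centers = np.asarray(self.bin_centers_db, dtype=float)
        probs = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "bin_centers_db", centers)
        object.__setattr__(self, "probabilities", probs)
        if centers.shape != probs.shape:
            raise ValueError("bin_centers_db and probabilities must match in length")
        if np.any(probs < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1, got {probs.sum()!r}")
        if centers.size > 1:
            spacing = np.diff(centers)
            if np.any(spacing <= 0) or not np.allclose(
                spacing, self.bin_width_db, rtol=0, atol=1e-9
            ):
                raise ValueError("bin centers must increase in constant bin_width steps")


@dataclass(frozen=True)
class TwoTermGaussianFit:
    """Coefficients of the fitted two-term Gaussian, normalized so b1 < b2."""

    a1: float
    b1: float
    c1: float
    a2: float
    b2: float
    c2: float
    rmse: float
    converged: bool

    @property
    def mu_db(self) -> float:
        """Centroid of the second hump."""
        return self.b2

    @property
    def sigma_db(self) -> float:
        """Standard deviation of the second hump, c2 / sqrt(2)."""
        return self.c2 / math.sqrt(2.0)

    def to_dict(self) -> dict:
        return {
            "a1": self.a1, "b1": self.b1, "c1": self.c1,
            "a2": self.a2, "b2": self.b2, "c2": self.c2,
            "mu_db": self.mu_db, "sigma_db": self.sigma_db,
            "rmse": self.rmse, "converged": self.converged,
        }


@dataclass(frozen=True)
class SurvivalCurve:
    """Empirical survival function over the observed path-loss support.

    ``survival[i]`` is S(x_i) = P(PL >= x_i); ``cdf[i]`` is P(PL <= x_i),
    so S(x) + P(PL < x) = 1 at every support point.
    """

    support_db: np.ndarray
    survival: np.ndarray
    cdf: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.survival, dtype=float)
        if np.any(np.diff(s) > 0):
            raise ValueError("survival must be non-increasing")
        if s.size and not np.isclose(s[0], 1.0):
            raise ValueError("survival at the minimum support value must be 1")


def build_histogram(series: PathLossSeries, bin_width: float = 1.0) -> ProbabilityHistogram:
    """Bin a path-loss series into a probability histogram.

    Bins are centred on the grid floor(min), floor(min)+w, ... and cover
    [floor(min) - w/2, ceil(max) + w/2]; with integer-dB data and the default
    1 dB width every distinct value gets its own bin. Empty interior bins are
    kept (they constrain the fitted tails).
    """
    if len(series) == 0:
        raise EmptyInputError("cannot build a histogram of an empty series")
    if bin_width <= 0:
        raise ValueError(f"bin_width must be > 0, got {bin_width}")
    values = series.values_db
    lo = math.floor(values.min())
    hi = math.ceil(values.max())
    n_bins = max(1, math.ceil((hi - lo) / bin_width + 0.5))
    centers = lo + bin_width * np.arange(n_bins)
    edges = np.concatenate([centers - bin_width / 2, [centers[-1] + bin_width / 2]])
    counts, _ = np.histogram(values, bins=edges)
    return ProbabilityHistogram(
        bin_centers_db=centers,
        probabilities=counts / values.size,
        bin_width_db=float(bin_width),
        n_samples=values.size,
    )


def two_term_gaussian(x, a1, b1, c1, a2, b2, c2):
    """f(x) = a1 exp(-((x-b1)/c1)^2) + a2 exp(-((x-b2)/c2)^2)."""
    x = np.asarray(x, dtype=float)
    return a1 * np.exp(-(((x - b1) / c1) ** 2)) + a2 * np.exp(-(((x - b2) / c2) ** 2))


def _initial_guess(centers: np.ndarray, probs: np.ndarray) -> list[float]:
    """b-guesses at the two most prominent local maxima of the smoothed
    histogram, falling back to the 25th/75th percentile positions."""
    if centers.size >= 3:
        smooth = np.convolve(probs, np.ones(3) / 3.0, mode="same")
    else:
        smooth = probs
    peaks = [
        i
        for i in range(1, centers.size - 1)
        if smooth[i] >= smooth[i - 1] and smooth[i] >= smooth[i + 1]
    ]
    peaks = sorted(sorted(peaks, key=lambda i: -smooth[i])[:2])
    if len(peaks) < 2:
        cum = np.cumsum(probs)
        peaks = [int(np.searchsorted(cum, q)) for q in (0.25, 0.75)]
        peaks = [min(p, centers.size - 1) for p in peaks]
        if peaks[0] == peaks[1]:
            peaks = [0, centers.size - 1]
    a_guess = [max(probs[p], 1e-6) for p in peaks]
    return [a_guess[0], centers[peaks[0]], 5.0, a_guess[1], centers[peaks[1]], 5.0]


def fit_two_term_gaussian(
    hist: ProbabilityHistogram,
    p0: list[float] | None = None,
    max_evaluations: int = 10_000,
) -> TwoTermGaussianFit:
    """Least-squares fit of the two-term Gaussian to (bin centre, mass) pairs.

    Amplitudes and widths are constrained positive; the two terms are
    relabelled afterwards so that b1 < b2. Raises
    :class:`InsufficientDataError` with fewer nonzero bins than the six free
    parameters and :class:`FitError` (carrying the last iterate) on
    non-convergence.
    """
    centers = hist.bin_centers_db
    probs = hist.probabilities
    if np.count_nonzero(probs) < 6:
        raise InsufficientDataError(
            f"two-term Gaussian fit needs >= 6 nonzero bins, "
            f"got {np.count_nonzero(probs)}"
        )
    if p0 is None:
        p0 = _initial_guess(centers, probs)
    p0 = np.asarray(p0, dtype=float)
    lower = np.array([1e-12, -np.inf, 1e-12, 1e-12, -np.inf, 1e-12])
    p0 = np.maximum(p0, lower)

    def residuals(params):
        return two_term_gaussian(centers, *params) - probs

    result = least_squares(
        residuals,
        p0,
        bounds=(lower, np.full(6, np.inf)),
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
        max_nfev=max_evaluations,
    )
    params = result.x
    if not result.success:
        raise FitError(
            f"two-term Gaussian fit did not converge: {result.message}",
            last_params=params,
        )
    if params[1] > params[4]:  # normalize term order so b1 < b2
        params = np.concatenate([params[3:6], params[0:3]])
    rmse = float(np.sqrt(np.mean(residuals_of(params, centers, probs) ** 2)))
    return TwoTermGaussianFit(
        a1=float(params[0]), b1=float(params[1]), c1=float(params[2]),
        a2=float(params[3]), b2=float(params[4]), c2=float(params[5]),
        rmse=rmse, converged=True,
    )


def residuals_of(params, centers, probs):
    return two_term_gaussian(centers, *params) - probs


def second_hump_stats(fit: TwoTermGaussianFit) -> tuple[float, float]:
    """(mu, sigma) of the second fitted hump: mu = b2, sigma = c2 / sqrt(2)."""
    if not fit.converged:
        raise InvalidFitError("cannot take second-hump statistics of an unconverged fit")
    return fit.mu_db, fit.sigma_db


def survival_function(series: PathLossSeries) -> SurvivalCurve:
    """Empirical survival S(x) = (# samples >= x) / n over the observed support.

    Strict per-sample counting on distinct observed values; no smoothing or
    interpolation (RSSI is integer-quantized, so the support is discrete).
    """
    if len(series) == 0:
        raise EmptyInputError("cannot build a survival curve of an empty series")
    values = np.sort(series.values_db)
    n = values.size
    support, first_index, counts = np.unique(
        values, return_index=True, return_counts=True
    )
    survival = (n - first_index) / n
    cdf = np.cumsum(counts) / n
    return SurvivalCurve(support_db=support, survival=survival, cdf=cdf)
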