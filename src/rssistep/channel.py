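"""Closed-form radio-channel model between two on-ankle transceivers.

The separation between the ankles maps to path loss through the free-space
model plus a fixed hardware correction:

    PL_OA(d) = 20 log10(4 pi d / lambda) + dPL

with wavelength ``lambda`` of the 2.4 GHz carrier and an empirical
correction ``dPL`` = 10 dB covering hardware non-linearity, insertion and
mismatch losses, and average multipath for the specific transceiver pair.
Inverting gives the distance estimate used throughout the package:

    d(PL) = (lambda / 4 pi) * 10^((PL - dPL) / 20)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError

SPEED_OF_LIGHT_M_S = 299_792_458.0

__all__ = [
    "SPEED_OF_LIGHT_M_S",
    "ChannelModel",
    "ErrorMetrics",
    "free_space_path_loss",
    "on_ankle_path_loss",
    "distance_from_path_loss",
    "error_metrics",
]


@dataclass(frozen=True)
class ChannelModel:
    """Carrier wavelength and correction factor of the on-ankle channel.

    Parameters
    ----------
    carrier_hz
        Carrier frequency used to derive the wavelength when ``wavelength_m``
        is not given. Default 2.4 GHz (IEEE 802.15.4 ISM band).
    wavelength_m
        Signal wavelength in metres. Derived as c / carrier_hz when None.
    correction_db
        Fixed correction dPL added on top of free-space loss, in dB.
    """

    carrier_hz: float = 2.4e9
    wavelength_m: float = field(default=None)  # type: ignore[assignment]
    correction_db: float = 10.0

    def __post_init__(self) -> None:
        if self.wavelength_m is None:
            if self.carrier_hz <= 0:
                raise DomainError(f"carrier_hz must be > 0, got {self.carrier_hz}")
            object.__setattr__(
                self, "wavelength_m", SPEED_OF_LIGHT_M_S / self.carrier_hz
            )
        if self.wavelength_m <= 0:
            raise DomainError(f"wavelength_m must be > 0, got {self.wavelength_m}")
        if not np.isfinite(self.correction_db):
            raise DomainError("correction_db must be finite")


@dataclass(frozen=True)
class ErrorMetrics:
    """Absolute and relative step-length estimation error vs. ground truth."""

    d_bar_m: float
    d0_m: float
    abs_error_mm: float
    rel_error_pct: float

    def to_dict(self) -> dict:
        return {
            "d_bar_m": self.d_bar_m,
            "d0_m": self.d0_m,
            "abs_error_mm": self.abs_error_mm,
            "rel_error_pct": self.rel_error_pct,
        }


def free_space_path_loss(d, model: ChannelModel = ChannelModel()):
    """Free-space path loss 20*log10(4*pi*d / lambda) in dB.

    ``d`` may be a scalar or array of distances in metres; all must be > 0.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise DomainError("distance must be > 0 m")
    out = 20.0 * np.log10(4.0 * np.pi * d / model.wavelength_m)
    return float(out) if out.ndim == 0 else out


def on_ankle_path_loss(d, model: ChannelModel = ChannelModel()):
    """On-ankle path loss: free-space loss plus the correction factor (dB)."""
    return free_space_path_loss(d, model) + model.correction_db


def distance_from_path_loss(pl, model: ChannelModel = ChannelModel()):
    """Invert the on-ankle model: distance in metres for a path loss in dB.

    Exact inverse of :func:`on_ankle_path_loss` for any finite path loss.
    """
    pl = np.asarray(pl, dtype=float)
    if not np.all(np.isfinite(pl)):
        raise DomainError("path loss must be finite")
    out = model.wavelength_m / (4.0 * np.pi) * 10.0 ** ((pl - model.correction_db) / 20.0)
    return float(out) if out.ndim == 0 else out


def error_metrics(d_bar: float, d0: float) -> ErrorMetrics:
    """Absolute (mm) and relative (%) error of an estimate vs. ground truth.

    The relative error is |d_bar - d0| / d0 * 100%.
    """
    if d0 <= 0:
        raise DomainError(f"ground-truth step length must be > 0, got {d0}")
    abs_err_m = abs(d_bar - d0)
    return ErrorMetrics(
        d_bar_m=float(d_bar),
        d0_m=float(d0),
        abs_error_mm=1000.0 * abs_err_m,
        rel_error_pct=100.0 * abs_err_m / d0,
    )
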