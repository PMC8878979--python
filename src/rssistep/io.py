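"""Reading, writing and cleaning of on-ankle RSSI logs.

A recording session is a CSV file with header ``time_s,rssi_db``: one row per
received packet, timestamps in seconds since recording start, RSSI in dB as
logged by the receiver. The logger writes a sentinel path-loss value
(120 dB by default) for packets that were lost, and the first fraction of a
second of a recording is a transmitter/receiver synchronization phase whose
samples are discarded before analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyInputError, EmptySeriesError, FormatError, ParseError

__all__ = [
    "SIGN_CONVENTIONS",
    "RSSITrace",
    "PathLossSeries",
    "read_rssi_log",
    "write_rssi_log",
    "to_path_loss_series",
]

#: Supported interpretations of the logged RSSI column.
#: "positive-attenuation": the radio logs |RSSI| as a positive attenuation
#: magnitude, so PL = Pt + rssi. This is the convention of the XBee-class
#: hardware the package models, and the default.
#: "signed-dbm": the log stores signed received power offsets, PL = Pt - rssi.
SIGN_CONVENTIONS = ("positive-attenuation", "signed-dbm")

REQUIRED_COLUMNS = ("time_s", "rssi_db")


@dataclass(frozen=True)
class RSSITrace:
    """Time-stamped raw RSSI samples of one recording session.

    ``warnings`` records non-fatal anomalies found while reading (currently:
    non-monotonic timestamps).
    """

    timestamps: np.ndarray
    rssi_values: np.ndarray
    tx_power_dbm: float = 0.0
    sentinel_db: float = 120.0
    sample_interval_s: float = 0.02
    sync_skip_s: float = 0.64
    sign_convention: str = "positive-attenuation"
    warnings: tuple = ()

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=float)
        rs = np.asarray(self.rssi_values, dtype=float)
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "rssi_values", rs)
        if ts.shape != rs.shape or ts.ndim != 1:
            raise FormatError(
                f"timestamps and rssi_values must be 1-D and equal length, "
                f"got {ts.shape} and {rs.shape}"
            )
        if ts.size and ts.min() < 0:
            raise FormatError("timestamps must be non-negative")
        # A sentinel at or below plausible on-ankle losses could silently
        # swallow real data, so it must sit clearly above them.
        if self.sentinel_db <= 80:
            raise FormatError(
                f"sentinel_db must exceed 80 dB (plausible on-ankle path loss), "
                f"got {self.sentinel_db}"
            )
        if self.sign_convention not in SIGN_CONVENTIONS:
            raise FormatError(
                f"unknown sign convention {self.sign_convention!r}; "
                f"expected one of {SIGN_CONVENTIONS}"
            )

    def __len__(self) -> int:
        return self.timestamps.size


@dataclass(frozen=True)
class PathLossSeries:
    """Valid on-ankle path-loss samples (dB) with removal bookkeeping.

    Invariant: ``n_total`` equals the retained length plus every drop counter.
    ``n_dropped_below``/``n_dropped_above`` are populated by threshold
    filtering; they are zero for a freshly converted series.
    """

    values_db: np.ndarray
    n_total: int
    n_dropped_sentinel: int = 0
    n_dropped_sync: int = 0
    n_dropped_below: int = 0
    n_dropped_above: int = 0

    def __post_init__(self) -> None:
        vals = np.asarray(self.values_db, dtype=float)
        object.__setattr__(self, "values_db", vals)
        if not np.all(np.isfinite(vals)):
            raise FormatError("path-loss values must be finite")
        dropped = (
            self.n_dropped_sentinel
            + self.n_dropped_sync
            + self.n_dropped_below
            + self.n_dropped_above
        )
        if self.n_total != vals.size + dropped:
            raise FormatError(
                f"bookkeeping violated: n_total={self.n_total} != "
                f"{vals.size} retained + {dropped} dropped"
            )

    def __len__(self) -> int:
        return self.values_db.size

    def counts(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_retained": len(self),
            "n_dropped_sentinel": self.n_dropped_sentinel,
            "n_dropped_sync": self.n_dropped_sync,
            "n_dropped_below": self.n_dropped_below,
            "n_dropped_above": self.n_dropped_above,
        }


def read_rssi_log(path, **trace_kwargs) -> RSSITrace:
    """Read a ``time_s,rssi_db`` CSV log into an :class:`RSSITrace`.

    Keyword arguments (``tx_power_dbm``, ``sentinel_db``, ``sync_skip_s``,
    ``sign_convention``, ...) are attached to the returned trace. Row order
    is preserved; out-of-order timestamps are accepted but recorded in
    ``trace.warnings``.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path} is empty") from None
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path} is missing required column(s) {missing}")
    if len(frame) == 0:
        raise EmptyInputError(f"{path} contains a header but no samples")

    numeric = {}
    for col in REQUIRED_COLUMNS:
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.isna() & frame[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path}: non-numeric value {frame[col].iloc[row]!r} in column "
                f"{col!r} at data row {row}"
            )
        if converted.isna().any():
            row = int(np.flatnonzero(converted.isna().to_numpy())[0])
            raise ParseError(f"{path}: missing value in column {col!r} at data row {row}")
        numeric[col] = converted.to_numpy(dtype=float)

    warnings = []
    t = numeric["time_s"]
    if np.any(np.diff(t) < 0):
        first = int(np.flatnonzero(np.diff(t) < 0)[0])
        warnings.append(
            f"timestamps are not monotonic non-decreasing (first decrease after "
            f"data row {first})"
        )
    return RSSITrace(
        timestamps=t,
        rssi_values=numeric["rssi_db"],
        warnings=tuple(warnings),
        **trace_kwargs,
    )


def write_rssi_log(trace: RSSITrace, path) -> None:
    """Write a trace back to the CSV dialect accepted by :func:`read_rssi_log`."""
    frame = pd.DataFrame({"time_s": trace.timestamps, "rssi_db": trace.rssi_values})
    frame.to_csv(path, index=False, float_format="%.6g")


def to_path_loss_series(trace: RSSITrace) -> PathLossSeries:
    """Convert a raw trace to a clean on-ankle path-loss series.

    Per sample, PL = Pt + rssi under the positive-attenuation convention
    (PL = Pt - rssi under "signed-dbm"). Samples inside the initial
    synchronization window (timestamp < ``sync_skip_s``) are dropped first,
    then samples whose path loss reaches the sentinel (>= ``sentinel_db``,
    so clipped or overflowed values are dropped too). Remaining values are
    returned in time order.
    """
    if len(trace) == 0:
        raise EmptyInputError("trace holds no samples")
    if trace.sign_convention == "positive-attenuation":
        pl = trace.tx_power_dbm + trace.rssi_values
    else:
        pl = trace.tx_power_dbm - trace.rssi_values

    in_sync = trace.timestamps < trace.sync_skip_s
    n_sync = int(in_sync.sum())
    pl = pl[~in_sync]
    is_sentinel = pl >= trace.sentinel_db
    n_sentinel = int(is_sentinel.sum())
    retained = pl[~is_sentinel]
    if retained.size == 0:
        raise EmptySeriesError(
            f"no valid samples left: {n_sync} dropped in the {trace.sync_skip_s} s "
            f"synchronization window, {n_sentinel} dropped as sentinel-flagged "
            f"out of {len(trace)} total"
        )
    return PathLossSeries(
        values_db=retained,
        n_total=len(trace),
        n_dropped_sentinel=n_sentinel,
        n_dropped_sync=n_sync,
    )
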