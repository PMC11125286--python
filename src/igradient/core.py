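"""Core data containers for epoch-based accelerometry.

The shared time model: an epoch series is a regularly spaced vector of
per-epoch summaries (activity counts, or ENMO in mg) indexed by the *start*
time of each epoch.  Wear intervals are half-open ``[on, off)`` and an epoch
belongs to wear iff its start time falls inside an interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["EpochSeries", "RawSignal", "WearLog", "apply_wear_log", "wear_minutes"]


@dataclass
class EpochSeries:
    """A per-participant, per-device vector of epoch-level intensity values.

    Parameters
    ----------
    participant_id, device_id
        Opaque identifiers.
    start_time
        Timestamp of the first epoch's start.
    epoch_length
        Epoch duration in seconds (15 s for the devices this package targets).
    values
        Non-negative epoch values; integer activity counts or ENMO in mg.
    wear
        Boolean mask, one entry per epoch; only wear-true epochs enter any
        downstream analysis.  Defaults to all-true.
    units
        ``"counts"`` or ``"mg"``.
    """

    participant_id: str
    device_id: str
    start_time: pd.Timestamp
    values: np.ndarray
    epoch_length: float = 15.0
    wear: np.ndarray | None = None
    units: str = "counts"

    def __post_init__(self) -> None:
        self.start_time = pd.Timestamp(self.start_time)
        self.values = np.asarray(self.values)
        if self.wear is None:
            self.wear = np.ones(len(self.values), dtype=bool)
        self.wear = np.asarray(self.wear, dtype=bool)
        if self.epoch_length <= 0:
            raise ValueError("epoch_length must be positive")
        if len(self.values) != len(self.wear):
            raise ValueError("values and wear must have equal length")
        if np.any(~np.isfinite(self.values.astype(float))):
            raise ValueError("epoch values must be finite")
        if np.any(self.values < 0):
            i = int(np.argmax(self.values < 0))
            raise ValueError(f"negative epoch value at row {i}")
        if self.units == "counts" and len(self.values):
            if not np.allclose(self.values, np.round(self.values.astype(float))):
                raise ValueError("count-typed series must hold integer values")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def epoch_times(self) -> pd.DatetimeIndex:
        """Start time of every epoch."""
        step = pd.to_timedelta(self.epoch_length, unit="s")
        return pd.DatetimeIndex(self.start_time + step * np.arange(len(self)))

    def copy(self, **changes) -> "EpochSeries":
        out = replace(self, **changes)
        if "values" not in changes:
            out.values = self.values.copy()
        if "wear" not in changes:
            out.wear = self.wear.copy()
        return out


@dataclass
class RawSignal:
    """Triaxial raw acceleration in g at a fixed sampling rate."""

    participant_id: str
    device_id: str
    start_time: pd.Timestamp
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    sample_rate: float = 30.0

    def __post_init__(self) -> None:
        self.start_time = pd.Timestamp(self.start_time)
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not (len(self.ax) == len(self.ay) == len(self.az)):
            raise ValueError("axis vectors must have equal length")

    def __len__(self) -> int:
        return len(self.ax)


@dataclass
class WearLog:
    """Participant-reported on/off intervals, half-open ``[on, off)``."""

    participant_id: str
    intervals: list[tuple[pd.Timestamp, pd.Timestamp]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ivs = [(pd.Timestamp(a), pd.Timestamp(b)) for a, b in self.intervals]
        for on, off in ivs:
            if not on < off:
                raise ValueError(f"wear interval must satisfy on < off: {on} .. {off}")
        self.intervals = self._normalise(ivs)

    @staticmethod
    def _normalise(ivs: Sequence[tuple[pd.Timestamp, pd.Timestamp]]):
        """Sort and merge overlapping/abutting intervals."""
        merged: list[tuple[pd.Timestamp, pd.Timestamp]] = []
        for on, off in sorted(ivs):
            if merged and on <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], off))
            else:
                merged.append((on, off))
        return merged

    def covers(self, times: Iterable[pd.Timestamp]) -> np.ndarray:
        """Boolean mask: which of ``times`` fall inside a wear interval."""
        times = pd.DatetimeIndex(times)
        mask = np.zeros(len(times), dtype=bool)
        for on, off in self.intervals:
            mask |= (times >= on) & (times < off)
        return mask

    def total_minutes(self) -> float:
        return sum((off - on).total_seconds() for on, off in self.intervals) / 60.0


def apply_wear_log(series: EpochSeries, log: WearLog) -> EpochSeries:
    """Return a copy of ``series`` with the wear mask set from ``log``.

    An epoch is wear iff its start time lies in some ``[on, off)`` interval.
    Values are untouched, so the operation is idempotent.
    """
    if log.participant_id != series.participant_id:
        raise ValueError(
            f"wear log participant {log.participant_id!r} does not match "
            f"series participant {series.participant_id!r}"
        )
    return series.copy(wear=log.covers(series.epoch_times))


def wear_minutes(series: EpochSeries) -> float:
    """Total wear time in minutes: wear-true epochs x epoch length."""
    return float(np.count_nonzero(series.wear)) * series.epoch_length / 60.0
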