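"""ENMO (Euclidean norm minus one g) from raw triaxial acceleration.

ENMO removes the static gravity component from the acceleration magnitude:
``ENMO = max(0, ||a|| - 1) * 1000`` in mg, truncated at the sample level by
default and averaged over consecutive fixed-length epochs.  A simplified
stationary-period recalibration (per-axis offset and gain) is provided for
raw streams whose resting norm drifts from 1 g.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .core import EpochSeries, RawSignal

__all__ = ["EnmoParams", "enmo_per_sample", "enmo_epochs", "recalibrate", "CalibrationReport"]


@dataclass
class EnmoParams:
    epoch_length: float = 15.0          # s
    truncate_negative: bool = True      # truncate per sample before averaging
    truncate_after_average: bool = False
    calibrate: bool = False
    stationary_sd_threshold: float = 0.013  # g, per-axis SD defining "stationary"
    stationary_window: float = 10.0     # s
    min_orientation_angle_deg: float = 10.0

    def __post_init__(self) -> None:
        if self.epoch_length <= 0 or self.stationary_sd_threshold <= 0 or self.stationary_window <= 0:
            raise ValueError("epoch_length and stationarity thresholds must be positive")


def enmo_per_sample(ax, ay, az, truncate_negative: bool = True) -> np.ndarray:
    """Per-sample ENMO in mg from axis accelerations in g.

    Rotation-invariant by construction (depends only on the vector norm).
    """
    ax, ay, az = (np.asarray(v, dtype=float) for v in (ax, ay, az))
    if not (np.all(np.isfinite(ax)) and np.all(np.isfinite(ay)) and np.all(np.isfinite(az))):
        raise ValueError("acceleration samples must be finite")
    e = (np.sqrt(ax * ax + ay * ay + az * az) - 1.0) * 1000.0
    if truncate_negative:
        e = np.maximum(e, 0.0)
    return e


def enmo_epochs(signal: RawSignal, params: EnmoParams | None = None) -> EpochSeries:
    """Average per-sample ENMO over consecutive non-overlapping epochs.

    The trailing partial epoch is discarded, mirroring epoch-mode devices.
    """
    params = params or EnmoParams()
    n_per = params.epoch_length * signal.sample_rate
    if abs(n_per - round(n_per)) > 1e-9:
        raise ValueError("epoch_length must span an integer number of samples")
    n_per = int(round(n_per))
    if len(signal) < n_per:
        raise ValueError("signal shorter than one epoch")
    sig = signal
    if params.calibrate:
        sig, _ = recalibrate(signal, params)
    e = enmo_per_sample(sig.ax, sig.ay, sig.az,
                        truncate_negative=params.truncate_negative
                        and not params.truncate_after_average)
    n_ep = len(e) // n_per
    per_epoch = e[: n_ep * n_per].reshape(n_ep, n_per).mean(axis=1)
    if params.truncate_after_average:
        per_epoch = np.maximum(per_epoch, 0.0)
    return EpochSeries(
        participant_id=signal.participant_id,
        device_id=signal.device_id,
        start_time=signal.start_time,
        values=per_epoch,
        epoch_length=params.epoch_length,
        units="mg",
    )


@dataclass
class CalibrationReport:
    offsets: np.ndarray = field(default_factory=lambda: np.zeros(3))
    gains: np.ndarray = field(default_factory=lambda: np.ones(3))
    n_stationary_windows: int = 0
    residual_before: float = float("nan")
    residual_after: float = float("nan")
    calibrated: bool = False
    warning: str | None = None


def _stationary_means(signal: RawSignal, params: EnmoParams) -> np.ndarray:
    n_win = int(round(params.stationary_window * signal.sample_rate))
    n = len(signal) // n_win
    if n == 0:
        return np.empty((0, 3))
    axes = np.column_stack([signal.ax, signal.ay, signal.az])[: n * n_win]
    wins = axes.reshape(n, n_win, 3)
    sd = wins.std(axis=1)
    keep = np.all(sd < params.stationary_sd_threshold, axis=1)
    return wins.mean(axis=1)[keep]


def _orientation_spread_ok(means: np.ndarray, min_angle_deg: float) -> bool:
    if len(means) < 3:
        return False
    units = means / np.linalg.norm(means, axis=1, keepdims=True)
    cos = units @ units.T
    np.fill_diagonal(cos, 1.0)
    return float(np.min(cos)) < np.cos(np.deg2rad(min_angle_deg))


def recalibrate(signal: RawSignal, params: EnmoParams | None = None) -> tuple[RawSignal, CalibrationReport]:
    """Fit per-axis offset and gain so stationary windows have unit norm.

    Stationary windows are non-overlapping blocks whose per-axis SD is below
    ``stationary_sd_threshold``.  With fewer than 3 windows, or without
    distinct orientations among them, the signal is returned unchanged and a
    warning is set in the report.  The fit minimises
    ``sum((||gain * a + offset|| - 1)^2)`` over window means by nonlinear
    least squares; this is a deliberate simplification of full
    ellipsoid-style autocalibration.
    """
    params = params or EnmoParams()
    report = CalibrationReport()
    means = _stationary_means(signal, params)
    report.n_stationary_windows = len(means)
    if len(means):
        report.residual_before = float(np.sum((np.linalg.norm(means, axis=1) - 1.0) ** 2))
    if not _orientation_spread_ok(means, params.min_orientation_angle_deg):
        report.warning = (
            "fewer than 3 stationary windows with distinct orientations; "
            "calibration skipped"
        )
        report.residual_after = report.residual_before
        return signal, report

    def resid(theta):
        gain, off = theta[:3], theta[3:]
        return np.linalg.norm(means * gain + off, axis=1) - 1.0

    sol = least_squares(resid, x0=np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0]))
    gain, off = sol.x[:3], sol.x[3:]
    report.gains, report.offsets = gain, off
    report.residual_after = float(np.sum(resid(sol.x) ** 2))
    if report.residual_after > report.residual_before:
        # guard: never worsen the stationary residual
        report.warning = "calibration fit did not improve residual; skipped"
        report.residual_after = report.residual_before
        return signal, report
    report.calibrated = True
    out = RawSignal(
        participant_id=signal.participant_id,
        device_id=signal.device_id,
        start_time=signal.start_time,
        ax=signal.ax * gain[0] + off[0],
        ay=signal.ay * gain[1] + off[1],
        az=signal.az * gain[2] + off[2],
        sample_rate=signal.sample_rate,
    )
    return out, report
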