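"""Typed containers for raw trial data.

A trial is one task execution set (five monopodalic countermovement jumps,
mCMJ, or five single-leg squats, SLS) recorded by a shank-mounted IMU at
1000 Hz, optionally paired with a synchronized optical-gate contact signal
for the jump task.  Containers validate the acquisition contract at
construction: uniform sampling, monotone time and channel magnitudes within
the sensor full-scale ranges (accelerometer +/-16 g, gyroscope +/-2000 deg/s,
magnetometer +/-4800 uT).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

G = 9.80665
"""Standard gravity in m/s^2."""

ACCEL_FULL_SCALE = 16.0 * G
GYRO_FULL_SCALE = 2000.0
MAG_FULL_SCALE = 4800.0

#: sampling-uniformity tolerance on |dt - 1/fs|, seconds
DT_TOL = 1e-6

TASK_MCMJ = "mcmj"
TASK_SLS = "sls"


class TrialValidationError(ValueError):
    """Raised when a container violates the acquisition contract."""


def _as_2d(name: str, x, n_cols: int = 3) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != n_cols:
        raise TrialValidationError(f"{name} must be (N, {n_cols}), got {arr.shape}")
    return arr


def _check_uniform_time(t: np.ndarray, fs: float) -> None:
    if t.ndim != 1 or t.size < 2:
        raise TrialValidationError("time vector must be 1-D with at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        i = int(np.argmax(dt <= 0))
        raise TrialValidationError(f"time not strictly increasing at sample {i + 1}")
    err = np.abs(dt - 1.0 / fs)
    if err.max() > DT_TOL:
        i = int(np.argmax(err))
        raise TrialValidationError(
            f"non-uniform sampling at sample {i + 1}: dt={dt[i]:.9f}, expected {1.0 / fs:.9f}"
        )


@dataclass
class ImuTrial:
    """Synchronized shank-IMU record for one task repetition set.

    accel is linear acceleration in m/s^2, gyro is angular velocity in deg/s
    (converted to rad/s internally where needed); both are (N, 3) in the
    sensor frame.  ``mag`` is optional and unused by the fusion.
    """

    t: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    fs: float
    task: str
    leg: str = "dominant"
    subject_id: str = ""
    session_id: str = ""
    mag: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.accel = _as_2d("accel", self.accel)
        self.gyro = _as_2d("gyro", self.gyro)
        if self.fs <= 0:
            raise TrialValidationError("fs must be positive")
        if self.task not in (TASK_MCMJ, TASK_SLS):
            raise TrialValidationError(f"unknown task {self.task!r}")
        if self.leg not in ("dominant", "nondominant"):
            raise TrialValidationError(f"unknown leg {self.leg!r}")
        n = self.t.size
        if self.accel.shape[0] != n or self.gyro.shape[0] != n:
            raise TrialValidationError("t, accel and gyro lengths differ")
        _check_uniform_time(self.t, self.fs)
        for name, arr, fs_range in (
            ("accel", self.accel, ACCEL_FULL_SCALE),
            ("gyro", self.gyro, GYRO_FULL_SCALE),
        ):
            if not np.all(np.isfinite(arr)):
                i = int(np.argwhere(~np.isfinite(arr))[0, 0])
                raise TrialValidationError(f"non-finite {name} value at sample {i}")
            if np.abs(arr).max() > fs_range * (1 + 1e-9):
                raise TrialValidationError(
                    f"{name} exceeds full-scale range +/-{fs_range:g}"
                )
        if self.mag is not None:
            self.mag = _as_2d("mag", self.mag)
            if self.mag.shape[0] != n:
                raise TrialValidationError("mag length differs from t")
            if np.abs(self.mag).max() > MAG_FULL_SCALE * (1 + 1e-9):
                raise TrialValidationError("mag exceeds full-scale range")

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def gyro_rad(self) -> np.ndarray:
        """Angular velocity in rad/s."""
        return np.deg2rad(self.gyro)

    def slice_time(self, start: float, end: float) -> slice:
        """Index slice covering samples with start <= t <= end."""
        i0 = int(np.searchsorted(self.t, start, side="left"))
        i1 = int(np.searchsorted(self.t, end, side="right"))
        return slice(i0, i1)


@dataclass
class GateSignal:
    """Optical-gate ground-contact status on the IMU time base.

    ``contact`` is True while the foot occludes the gate LEDs (on ground)
    and False during flight.
    """

    t: np.ndarray
    contact: np.ndarray
    fs: float = 1000.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.contact = np.asarray(self.contact, dtype=bool)
        if self.t.shape != self.contact.shape:
            raise TrialValidationError("gate t and contact lengths differ")
        _check_uniform_time(self.t, self.fs)

    def check_same_base(self, trial: ImuTrial) -> None:
        if self.t.size != trial.t.size or np.abs(self.t - trial.t).max() > DT_TOL:
            raise TrialValidationError("gate and IMU trial do not share a time base")
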