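"""Sensor-to-world alignment and orientation estimation.

The world frame is Z vertical up, X antero-posterior, Y medio-lateral.
A static upright-stance window (10 s at the start of every acquisition)
defines the calibration: the window-mean accelerometer direction is mapped
to world +Z, and the horizontal projection of the sensor long axis fixes the
heading (+X).  Per-sample orientation is then estimated with an explicit
complementary (Mahony) filter that integrates the gyroscope and corrects
tilt with the accelerometer-measured gravity direction; the magnetometer is
deliberately excluded, so yaw is defined only up to the calibration heading.

Conventions
-----------
* Quaternions are scalar-first ``(w, x, y, z)`` and encode world <- sensor.
* At rest the accelerometer reads +g along world Z (reaction convention).
* Gyroscope input is deg/s (as acquired); internally rad/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .signals import G, ImuTrial

#: sensor-frame direction of the long side of the device (along the shank)
LONG_AXIS_SENSOR = np.array([0.0, 0.0, 1.0])


class CalibrationError(ValueError):
    """Raised when the static window does not permit calibration."""


@dataclass
class CalibrationTransform:
    """Rotation aligning the mean static sensor frame to the world frame."""

    R0: np.ndarray  # (3, 3), world <- sensor at calibration
    window: tuple[float, float]

    def as_quaternion(self) -> np.ndarray:
        q = Rotation.from_matrix(self.R0).as_quat()  # x, y, z, w
        return np.r_[q[3], q[:3]]


@dataclass
class OrientationSeries:
    """Unit-quaternion orientation (world <- sensor) per sample."""

    t: np.ndarray
    q: np.ndarray  # (N, 4) scalar-first, unit norm

    def as_rotation(self) -> Rotation:
        return Rotation.from_quat(np.c_[self.q[:, 1:], self.q[:, 0]])

    def euler_deg(self) -> np.ndarray:
        """Intrinsic x-y-z Euler angles in degrees, (N, 3).

        Column 1 (rotation about Y, the medio-lateral axis) tracks
        knee-flexion-like pitch of the shank during a squat.
        """
        return self.as_rotation().as_euler("xyz", degrees=True)

    def euler_relative_deg(self, cal: "CalibrationTransform") -> np.ndarray:
        """Euler angles (x-y-z, degrees) of the motion relative to the
        calibration pose.

        The arbitrary heading fixed at calibration cancels out, so quiet
        stance sits near zero on all three axes; the Y column is the
        knee-flexion-like pitch used for squat-phase detection.
        """
        rel = Rotation.from_matrix(cal.R0).inv() * self.as_rotation()
        return rel.as_euler("xyz", degrees=True)

    def long_axis_world(self, axis: np.ndarray = LONG_AXIS_SENSOR) -> np.ndarray:
        """World-frame direction of the sensor long axis, (N, 3)."""
        return self.as_rotation().apply(axis)

    def rotate_to_world(self, vec: np.ndarray) -> np.ndarray:
        """Rotate per-sample sensor-frame vectors into the world frame."""
        return self.as_rotation().apply(vec)


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix sending unit vector a onto unit vector b."""
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antipodal: rotate pi about any axis orthogonal to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return Rotation.from_rotvec(np.pi * axis).as_matrix()
    axis = v / np.linalg.norm(v)
    angle = math.atan2(float(np.linalg.norm(v)), c)
    return Rotation.from_rotvec(angle * axis).as_matrix()


def calibrate_static(
    trial: ImuTrial,
    window: tuple[float, float] = (0.0, 10.0),
    stillness_rms_dps: float = 10.0,
    long_axis: np.ndarray = LONG_AXIS_SENSOR,
) -> CalibrationTransform:
    """Derive the sensor->world re-alignment from an upright static window.

    The window-mean accelerometer direction is declared world +Z (gravity
    up); the heading is fixed by rotating the horizontal projection of the
    window-mean sensor long axis onto world +X.  When that projection is
    degenerate (long axis within ~0.006 deg of vertical) the heading is left
    at the tilt-only solution.

    Raises
    ------
    CalibrationError
        If the window is shorter than 1 s or the gyroscope RMS magnitude in
        the window exceeds ``stillness_rms_dps`` (motion during calibration).
    """
    start, end = window
    if end - start < 1.0:
        raise CalibrationError("calibration window must span at least 1 s")
    sl = trial.slice_time(start, end)
    if sl.stop - sl.start < 2:
        raise CalibrationError("calibration window outside trial time span")
    gyro_rms = float(np.sqrt(np.mean(np.linalg.norm(trial.gyro[sl], axis=1) ** 2)))
    if gyro_rms > stillness_rms_dps:
        raise CalibrationError(
            f"motion in calibration window: gyro RMS {gyro_rms:.1f} deg/s "
            f"> {stillness_rms_dps:g} deg/s"
        )
    a_mean = trial.accel[sl].mean(axis=0)
    a_norm = float(np.linalg.norm(a_mean))
    if a_norm < 0.1 * G:
        raise CalibrationError("static acceleration magnitude implausibly small")
    a_hat = a_mean / a_norm

    R_tilt = _rotation_between(a_hat, np.array([0.0, 0.0, 1.0]))
    u_world = R_tilt @ np.asarray(long_axis, dtype=float)
    horiz = np.array([u_world[0], u_world[1], 0.0])
    h = np.linalg.norm(horiz)
    if h > 1e-7:
        yaw = math.atan2(horiz[1], horiz[0])
        R_yaw = Rotation.from_euler("z", -yaw).as_matrix()
        R0 = R_yaw @ R_tilt
    else:
        R0 = R_tilt
    return CalibrationTransform(R0=R0, window=(start, end))


def _quat_mul(q: tuple, r: tuple) -> tuple:
    w1, x1, y1, z1 = q
    w2, x2, y2, z2 = r
    return (
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
    )


def estimate_orientation(
    trial: ImuTrial,
    cal: CalibrationTransform,
    kp: float = 1.0,
    ki: float = 0.1,
    accel_gate: float = 0.4,
) -> OrientationSeries:
    """Mahony explicit complementary filter over a calibrated trial.

    The gyroscope is integrated with a first-order quaternion exponential
    update at the sampling rate; the tilt error is the cross product of the
    accelerometer-measured gravity direction with the estimated one, fed
    back as ``kp * e + ki * integral(e)``.  Samples whose acceleration
    magnitude departs from g by more than ``accel_gate`` (fractional) carry
    no gravity information (free flight, impact) and receive no correction.

    The initial orientation is the calibration pose.
    """
    if kp <= 0 or ki < 0:
        raise ValueError("gains must satisfy kp > 0, ki >= 0")
    bad = ~np.isfinite(trial.accel).all(axis=1) | ~np.isfinite(trial.gyro).all(axis=1)
    if bad.any():
        raise ValueError(f"NaN/inf in input channels at sample {int(np.argmax(bad))}")

    n = trial.n_samples
    dt = 1.0 / trial.fs
    gyro = np.deg2rad(trial.gyro)
    acc = trial.accel
    acc_norm = np.linalg.norm(acc, axis=1)
    use_acc = np.abs(acc_norm - G) < accel_gate * G

    q0 = cal.as_quaternion()
    qw, qx, qy, qz = (float(v) for v in q0)
    ix = iy = iz = 0.0  # integral feedback state
    out = np.empty((n, 4))
    out[0] = (qw, qx, qy, qz)

    for i in range(1, n):
        gx, gy, gz = gyro[i]
        if use_acc[i]:
            an = acc_norm[i]
            axm, aym, azm = acc[i, 0] / an, acc[i, 1] / an, acc[i, 2] / an
            # estimated gravity direction in the sensor frame: R(q)^T e_z
            vx = 2.0 * (qx * qz - qw * qy)
            vy = 2.0 * (qw * qx + qy * qz)
            vz = qw * qw - qx * qx - qy * qy + qz * qz
            ex = aym * vz - azm * vy
            ey = azm * vx - axm * vz
            ez = axm * vy - aym * vx
            ix += ki * ex * dt
            iy += ki * ey * dt
            iz += ki * ez * dt
            gx += kp * ex + ix
            gy += kp * ey + iy
            gz += kp * ez + iz
        else:
            gx += ix
            gy += iy
            gz += iz
        # exact exponential of the body-rate increment
        theta = math.sqrt(gx * gx + gy * gy + gz * gz) * dt
        if theta > 1e-12:
            h = 0.5 * theta
            s = math.sin(h) / (theta / dt)
            dq = (math.cos(h), gx * s, gy * s, gz * s)
            qw, qx, qy, qz = _quat_mul((qw, qx, qy, qz), dq)
            inv = 1.0 / math.sqrt(qw * qw + qx * qx + qy * qy + qz * qz)
            qw *= inv
            qx *= inv
            qy *= inv
            qz *= inv
        out[i] = (qw, qx, qy, qz)

    return OrientationSeries(t=trial.t.copy(), q=out)
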