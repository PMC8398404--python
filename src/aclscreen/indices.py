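"""Leg-stability, load-absorption and leg-mobility indices.

Stability is quantified posturographically on the trajectory of the point
where the shank (sensor long) axis pierces a horizontal plane 1 cm from the
sensor: total and directional path lengths

    PL = sum_n sqrt((AP[n+1]-AP[n])^2 + (ML[n+1]-ML[n])^2)

and the area of the bivariate 95% confidence ellipse

    EA = 2 * pi * F_0.05[2, N-2] * sqrt(s_AP^2 * s_ML^2 - s_APML^2)

with s^2 the sample (co)variances of the path coordinates.  For jumps these
are normalized by the stabilization time Ts, for squats by the
descending-phase duration T_DP.  Load absorption is the RMS of the
world-frame vertical (RMS_z) and horizontal-plane (RMS_xy) linear
acceleration over the landing window, divided by the jump duration
(flight + contact).  Leg mobility is the maximal angle about the
medio-lateral axis during the squat descent (theta_ymax).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .events import JumpSegment, SquatSegment
from .orientation import LONG_AXIS_SENSOR, OrientationSeries
from .signals import G, ImuTrial

#: distance from the sensor to the intersection plane, cm
DEFAULT_PLANE_OFFSET_CM = 1.0


@dataclass
class SwayPath:
    """Planar trajectory of the leg-axis/floor intersection, in cm."""

    AP: np.ndarray
    ML: np.ndarray
    source_window: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.AP = np.asarray(self.AP, dtype=float)
        self.ML = np.asarray(self.ML, dtype=float)
        if self.AP.shape != self.ML.shape or self.AP.ndim != 1:
            raise ValueError("AP and ML must be 1-D arrays of equal length")
        if not (np.all(np.isfinite(self.AP)) and np.all(np.isfinite(self.ML))):
            raise ValueError("sway path contains non-finite coordinates")

    @property
    def N(self) -> int:
        return self.AP.size


@dataclass
class IndexSet:
    """Normalized indices for one repetition (units as printed in reports)."""

    task: str
    rep: int
    Ts: float | None = None          # s (jumps) -- stabilization time
    T_DP: float | None = None        # s (squats) -- descending-phase duration
    EA: float | None = None          # cm^2/s
    PL: float | None = None          # cm/s
    PL_AP: float | None = None       # cm/s
    PL_ML: float | None = None       # cm/s
    RMS_z: float | None = None       # m/s^3 (jumps only)
    RMS_xy: float | None = None      # m/s^3 (jumps only)
    theta_ymax: float | None = None  # degrees (squats only)
    flagged: bool = False


def project_leg_axis(
    orient: OrientationSeries,
    window: tuple[float, float],
    plane_offset_cm: float = DEFAULT_PLANE_OFFSET_CM,
    long_axis: np.ndarray = LONG_AXIS_SENSOR,
) -> SwayPath:
    """Intersect the world-frame leg axis with the horizontal plane.

    For each sample the line through the sensor origin along the long-axis
    direction u is intersected with the horizontal plane at signed distance
    ``plane_offset_cm`` below the origin: scale ``s = -offset / u_z``, point
    ``(s*u_x, s*u_y)`` in cm; AP is the world-X component, ML the world-Y.
    """
    i0 = int(np.searchsorted(orient.t, window[0], side="left"))
    i1 = int(np.searchsorted(orient.t, window[1], side="right"))
    if i1 - i0 < 1:
        raise ValueError("window outside orientation series span")
    u = OrientationSeries(orient.t[i0:i1], orient.q[i0:i1]).long_axis_world(long_axis)
    uz = u[:, 2]
    if np.any(np.abs(uz) < 1e-3):
        raise ValueError("leg axis (near-)parallel to the floor plane in window")
    s = -plane_offset_cm / uz
    return SwayPath(AP=s * u[:, 0], ML=s * u[:, 1], source_window=window)


def path_length(path: SwayPath) -> tuple[float, float, float]:
    """Raw total and directional path lengths (PL, PL_AP, PL_ML) in cm."""
    if path.N < 2:
        raise ValueError("path length undefined for fewer than 2 points")
    dap = np.diff(path.AP)
    dml = np.diff(path.ML)
    pl = float(np.sum(np.hypot(dap, dml)))
    return pl, float(np.sum(np.abs(dap))), float(np.sum(np.abs(dml)))


def ellipse_area(path: SwayPath, alpha: float = 0.05) -> float:
    """Raw bivariate confidence-ellipse area in cm^2.

    ``EA = 2*pi * F_alpha[2, N-2] * sqrt(det(cov))`` with the sample
    covariance of (AP, ML).  A singular covariance (collinear or constant
    path) yields 0 with a warning so that batch processing survives
    degenerate repetitions.
    """
    if path.N < 3:
        raise ValueError("ellipse area undefined for fewer than 3 points")
    cov = np.cov(path.AP, path.ML, ddof=1)
    det = float(cov[0, 0] * cov[1, 1] - cov[0, 1] ** 2)
    if det <= 0:
        warnings.warn("degenerate sway path: singular covariance, EA set to 0")
        return 0.0
    fcrit = float(stats.f.ppf(1.0 - alpha, 2, path.N - 2))
    return 2.0 * np.pi * fcrit * np.sqrt(det)


def _normalized_stability(path: SwayPath, divisor: float, alpha: float) -> dict:
    pl, pl_ap, pl_ml = path_length(path)
    ea = ellipse_area(path, alpha=alpha)
    return {
        "PL": pl / divisor,
        "PL_AP": pl_ap / divisor,
        "PL_ML": pl_ml / divisor,
        "EA": ea / divisor,
    }


def stability_indices_mcmj(path: SwayPath, seg: JumpSegment, alpha: float = 0.05) -> dict:
    """Jump stability indices normalized by the stabilization time Ts."""
    if seg.Ts is None:
        raise ValueError("segment has no stabilization time; repetition excluded")
    return _normalized_stability(path, seg.Ts, alpha)


def stability_indices_sls(path: SwayPath, seg: SquatSegment, alpha: float = 0.05) -> dict:
    """Squat stability indices normalized by the descending-phase time T_DP."""
    return _normalized_stability(path, seg.T_DP, alpha)


def load_absorption(
    trial: ImuTrial,
    orient: OrientationSeries,
    seg: JumpSegment,
    jump_duration: float | None = None,
) -> tuple[float, float]:
    """Landing-window acceleration RMS (RMS_z, RMS_xy), m/s^3.

    The measured acceleration is rotated to the world frame and gravity is
    subtracted from the vertical component; the RMS of the vertical and of
    the horizontal-plane magnitude over ``[CT_i, CT_i + Ts]`` is divided by
    the jump duration (``dFT + dCT`` unless given explicitly).
    """
    if seg.Ts is None:
        raise ValueError("segment has no stabilization time; repetition excluded")
    if jump_duration is None:
        jump_duration = seg.jump_duration
    sl = trial.slice_time(seg.CT_i, seg.CT_i + seg.Ts)
    if sl.stop - sl.start < 1:
        raise ValueError("empty landing window")
    a_world = OrientationSeries(orient.t[sl], orient.q[sl]).rotate_to_world(trial.accel[sl])
    a_z = a_world[:, 2] - G
    a_xy = np.hypot(a_world[:, 0], a_world[:, 1])
    rms = lambda x: float(np.sqrt(np.mean(np.square(x))))
    return rms(a_z) / jump_duration, rms(a_xy) / jump_duration


def mobility(seg: SquatSegment) -> float:
    """Leg-mobility index: maximal angle about the Y axis, degrees."""
    return seg.theta_ymax


def compute_mcmj_indices(
    trial: ImuTrial,
    orient: OrientationSeries,
    segments: list[JumpSegment],
    plane_offset_cm: float = DEFAULT_PLANE_OFFSET_CM,
    alpha: float = 0.05,
) -> list[IndexSet]:
    """Full per-repetition index sets for a jump trial.

    Repetitions without a well-defined stabilization time are flagged and
    carry no values (they are excluded from session averaging downstream).
    """
    out = []
    for r, seg in enumerate(segments):
        if seg.Ts is None or seg.flagged:
            out.append(IndexSet(task=trial.task, rep=r, flagged=True))
            continue
        path = project_leg_axis(orient, (seg.CT_i, seg.CT_i + seg.Ts), plane_offset_cm)
        stab = stability_indices_mcmj(path, seg, alpha)
        rms_z, rms_xy = load_absorption(trial, orient, seg)
        out.append(
            IndexSet(task=trial.task, rep=r, Ts=seg.Ts, RMS_z=rms_z, RMS_xy=rms_xy, **stab)
        )
    return out


def compute_sls_indices(
    trial: ImuTrial,
    orient: OrientationSeries,
    segments: list[SquatSegment],
    plane_offset_cm: float = DEFAULT_PLANE_OFFSET_CM,
    alpha: float = 0.05,
) -> list[IndexSet]:
    """Full per-repetition index sets for a squat trial."""
    out = []
    for r, seg in enumerate(segments):
        if seg.flagged:
            out.append(IndexSet(task=trial.task, rep=r, flagged=True))
            continue
        path = project_leg_axis(orient, (seg.DP_i, seg.DP_e), plane_offset_cm)
        stab = stability_indices_sls(path, seg, alpha)
        out.append(
            IndexSet(
                task=trial.task,
                rep=r,
                T_DP=seg.T_DP,
                theta_ymax=mobility(seg),
                **stab,
            )
        )
    return out
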