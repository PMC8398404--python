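"""Synthetic IMU and optical-gate trial generator with known ground truth.

Raw study data of this kind (shank IMU at 1000 Hz plus optical-gate contact
status during repeated single-leg jumps and squats) is rarely shared, so the
generator stands in for it: every produced trial carries exact ground-truth
events, sway paths and angle maxima, giving each downstream stage a testable
oracle.

Signal model (jumps)
--------------------
A 10 s quiet-stance calibration prefix is followed by ``n_reps``
flight/contact cycles.  After each landing the sensor spins about its long
axis with rate ``base + A * exp(-t/tau) * cos(w t)``; the frequency ``w`` is
solved so that the first minimum of the rate falls exactly at the blueprint
stabilization time.  Simultaneously the leg axis sways on a damped
quadrature (near-circular) planar orbit with independent AP/ML amplitudes,
which keeps the tilt-rate magnitude nearly constant so the angular-velocity
norm minimum stays at the spin minimum.  The accelerometer reads the
rotated specific force: +g upright, ~0 in flight, plus a half-sine impact
transient after touch-down.

Signal model (squats)
---------------------
The angle about the medio-lateral (Y) axis rises as a half-sine from the
descent onset to its maximum and returns symmetrically; onset slope is
nonzero so the onset is sharply detectable.  Other angles stay at baseline.

Only signal-level realism is attempted: no muscle/joint dynamics, no
center-of-mass ballistics consistency across phases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .events import JumpSegment, SquatSegment
from .signals import (
    ACCEL_FULL_SCALE,
    G,
    GYRO_FULL_SCALE,
    GateSignal,
    ImuTrial,
    TASK_MCMJ,
    TASK_SLS,
)


@dataclass
class SwayModel:
    """Planar leg-axis sway: damped quadrature (Lissajous-like) orbit.

    Amplitudes are expressed in cm at the 1 cm projection plane (i.e. the
    tangent of the tilt angle); AP/ML amplitudes and frequencies are
    independent, with a 90 degree phase offset between the components.
    """

    amp_ap_cm: float = 0.075
    amp_ml_cm: float = 0.068
    freq_ap_hz: float = 2.5
    freq_ml_hz: float = 2.5
    damping_s: float = 0.8
    #: high-frequency antero-posterior micro-instability: amplitude ratio
    #: relative to amp_ap_cm and its frequency.  Raises the AP path length
    #: while leaving the excursion amplitude (hence the ellipse area)
    #: essentially unchanged.
    ap_jitter_ratio: float = 0.0
    ap_jitter_hz: float = 12.0


@dataclass
class ChannelNoise:
    """Additive white Gaussian sensor noise, native units per channel."""

    gyro_dps: float = 0.5
    accel_ms2: float = 0.05


@dataclass
class TrialBlueprint:
    """Ground-truth recipe for one synthetic trial.

    Scalar per-rep parameters broadcast to ``n_reps``.  All durations are
    seconds; ``ts_truth`` must not exceed the contact duration of its rep.
    """

    task: str = TASK_MCMJ
    n_reps: int = 5
    fs: float = 1000.0
    flight_durations: float | np.ndarray = 0.40
    contact_durations: float | np.ndarray = 0.60
    ts_truth: float | np.ndarray = 0.24
    dp_bounds_truth: list[tuple[float, float]] | None = None
    theta_ymax_truth: float | np.ndarray = 28.5
    sway_model: SwayModel = field(default_factory=SwayModel)
    lean_deg: float = 3.0
    impact_accel_peak: float | np.ndarray = 80.0
    sway_rep_scale: float | np.ndarray = 1.0
    impact_duration: float = 0.08
    impact_xy_ratio: float = 0.85
    spin_base_dps: float = 400.0
    spin_amp_dps: float = 400.0
    spin_decay_s: float = 0.5
    noise_sd: ChannelNoise = field(default_factory=ChannelNoise)
    postural_sway_deg: float = 0.25
    calib_duration: float = 10.0
    baseline_quiet: float = 2.5
    inter_rep_quiet: float = 1.0
    descent_duration: float = 1.5
    total_duration: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in (TASK_MCMJ, TASK_SLS):
            raise ValueError(f"unknown task {self.task!r}")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.flight_durations = self._per_rep(self.flight_durations, "flight_durations")
        self.contact_durations = self._per_rep(self.contact_durations, "contact_durations")
        self.ts_truth = self._per_rep(self.ts_truth, "ts_truth")
        self.theta_ymax_truth = self._per_rep(self.theta_ymax_truth, "theta_ymax_truth")
        self.impact_accel_peak = self._per_rep(self.impact_accel_peak, "impact_accel_peak")
        self.sway_rep_scale = self._per_rep(self.sway_rep_scale, "sway_rep_scale")
        if self.task == TASK_MCMJ:
            if np.any(self.ts_truth > self.contact_durations):
                raise ValueError("ts_truth must not exceed the contact duration")
        if self.task == TASK_SLS:
            floor = detectable_angle_floor(self.noise_sd)
            if self.noise_sd.accel_ms2 > 0 and np.any(self.theta_ymax_truth <= floor):
                raise ValueError(
                    f"theta_ymax_truth at or below the baseline angle-noise level "
                    f"({floor:.2f} deg): undetectable by construction"
                )
            if self.dp_bounds_truth is None:
                self.dp_bounds_truth = self._default_dp_bounds()
            prev_end = self.calib_duration + self.baseline_quiet
            for r, (dpi, dpe) in enumerate(self.dp_bounds_truth):
                if not dpi < dpe:
                    raise ValueError(f"rep {r}: DP_i must precede DP_e")
                if dpi < prev_end:
                    raise ValueError(f"rep {r}: descending phases overlap or start too early")
                prev_end = dpe + (dpe - dpi)  # symmetric ascent
        if self.total_duration is not None and self.duration > self.total_duration:
            raise ValueError(
                f"phase durations require {self.duration:.2f} s "
                f"but total_duration is {self.total_duration:.2f} s"
            )

    def _per_rep(self, x, name: str) -> np.ndarray:
        arr = np.broadcast_to(np.asarray(x, dtype=float), (self.n_reps,)).copy()
        if np.any(arr <= 0):
            raise ValueError(f"{name} must be positive")
        return arr

    def _default_dp_bounds(self) -> list[tuple[float, float]]:
        bounds = []
        t = self.calib_duration + self.baseline_quiet
        for _ in range(self.n_reps):
            bounds.append((t, t + self.descent_duration))
            t += 2 * self.descent_duration + self.inter_rep_quiet
        return bounds

    @property
    def duration(self) -> float:
        """Total generated trial length, s."""
        if self.task == TASK_MCMJ:
            return float(
                self.calib_duration + np.sum(self.flight_durations + self.contact_durations)
            )
        last = self.dp_bounds_truth[-1]
        return last[1] + (last[1] - last[0]) + self.inter_rep_quiet


def _spin_frequency(ts: float, decay_s: float) -> float:
    """Angular frequency placing the first damped-cosine minimum at ts.

    Solves w*ts = pi - atan(lambda/w) by fixed-point iteration.
    """
    lam = 1.0 / decay_s
    w = math.pi / ts
    for _ in range(50):
        w = (math.pi - math.atan2(lam, w)) / ts
    return w


def _finite_diff_body_rates(rot: Rotation, fs: float) -> np.ndarray:
    """Body-frame angular velocity (deg/s) from an orientation sequence."""
    rel = rot[:-1].inv() * rot[1:]
    w = rel.as_rotvec() * fs
    w = np.vstack([w, w[-1]])
    return np.rad2deg(w)


def _sensor_accel(rot: Rotation, specific_force_world: np.ndarray) -> np.ndarray:
    return rot.inv().apply(specific_force_world)


def simulate_mcmj_trial(
    bp: TrialBlueprint,
) -> tuple[ImuTrial, GateSignal, list[JumpSegment]]:
    """Generate one monopodalic countermovement-jump trial.

    Returns the IMU record, the synchronized gate signal (off exactly during
    each flight interval) and the ground-truth segments with the true
    stabilization times.
    """
    if bp.task != TASK_MCMJ:
        raise ValueError("blueprint task must be mCMJ")
    fs, dt = bp.fs, 1.0 / bp.fs
    n = int(round(bp.duration * fs)) + 1
    t = np.arange(n) * dt

    # --- ground-truth timeline ---------------------------------------------
    segs: list[JumpSegment] = []
    cursor = bp.calib_duration
    for r in range(bp.n_reps):
        ft_i = cursor
        ct_i = ft_i + bp.flight_durations[r]
        segs.append(
            JumpSegment(
                FT_i=ft_i,
                CT_i=ct_i,
                dFT=bp.flight_durations[r],
                dCT=bp.contact_durations[r],
                Ts=float(bp.ts_truth[r]),
                omega_min_t=ct_i + float(bp.ts_truth[r]),
            )
        )
        cursor = ct_i + bp.contact_durations[r]

    contact = np.ones(n, dtype=bool)
    for seg in segs:
        contact[(t >= seg.FT_i) & (t < seg.CT_i)] = False

    # --- orientation: damped quadrature sway tilt + post-landing spin ------
    sm = bp.sway_model
    theta_ap = math.atan(sm.amp_ap_cm)  # rad, tilt giving the cm amplitude at 1 cm
    theta_ml = math.atan(sm.amp_ml_cm)
    tilt = np.zeros((n, 3))
    # constant forward shank lean: anchors the calibration heading (the
    # horizontal projection of the long axis defines antero-posterior +X)
    tilt[:, 1] = math.radians(bp.lean_deg)
    spin_rate = np.zeros(n)  # rad/s about the sensor long axis
    for r, seg in enumerate(segs):
        in_ct = (t >= seg.CT_i) & (t < seg.CT_i + seg.dCT)
        tau = t[in_ct] - seg.CT_i
        env = np.exp(-tau / sm.damping_s)
        onset = 1.0 - np.exp(-tau / 0.03)
        closing = np.clip((seg.dCT - tau) / 0.05, 0.0, 1.0)
        shape = env * onset * closing
        # rotation about Y tips the leg axis antero-posteriorly, about X medio-laterally
        ap_wave = np.cos(2 * np.pi * sm.freq_ap_hz * tau)
        if sm.ap_jitter_ratio > 0:
            ap_wave = ap_wave + sm.ap_jitter_ratio * np.cos(
                2 * np.pi * sm.ap_jitter_hz * tau + 2.399963 * r
            )
        rep_scale = float(bp.sway_rep_scale[r])
        tilt[in_ct, 1] += rep_scale * theta_ap * shape * ap_wave
        tilt[in_ct, 0] = rep_scale * theta_ml * shape * np.sin(2 * np.pi * sm.freq_ml_hz * tau)
        w_r = _spin_frequency(float(bp.ts_truth[r]), bp.spin_decay_s)
        rate = bp.spin_base_dps + bp.spin_amp_dps * np.exp(-tau / bp.spin_decay_s) * np.cos(
            w_r * tau
        )
        spin_rate[in_ct] = np.deg2rad(rate) * closing

    psi = np.cumsum(spin_rate) * dt
    spin_vec = np.zeros((n, 3))
    spin_vec[:, 2] = psi
    rot = Rotation.from_rotvec(tilt) * Rotation.from_rotvec(spin_vec)

    gyro = _finite_diff_body_rates(rot, fs)

    # --- specific force -----------------------------------------------------
    f_world = np.zeros((n, 3))
    f_world[:, 2] = G
    f_world[~contact, 2] = 0.0  # free flight: accelerometer reads ~0
    for r, seg in enumerate(segs):
        pulse = (t >= seg.CT_i) & (t < seg.CT_i + bp.impact_duration)
        tau = t[pulse] - seg.CT_i
        amp = np.sin(np.pi * tau / bp.impact_duration)
        phi = 2.399963 * r  # golden-angle spread of the horizontal impact direction
        peak = float(bp.impact_accel_peak[r])
        f_world[pulse, 2] += peak * amp
        f_world[pulse, 0] += bp.impact_xy_ratio * peak * amp * math.cos(phi)
        f_world[pulse, 1] += bp.impact_xy_ratio * peak * amp * math.sin(phi)
    accel = _sensor_accel(rot, f_world)

    # --- sensor noise -------------------------------------------------------
    rng = np.random.default_rng(bp.seed)
    if bp.noise_sd.gyro_dps > 0:
        gyro = gyro + rng.normal(0.0, bp.noise_sd.gyro_dps, gyro.shape)
    if bp.noise_sd.accel_ms2 > 0:
        accel = accel + rng.normal(0.0, bp.noise_sd.accel_ms2, accel.shape)
    gyro = np.clip(gyro, -GYRO_FULL_SCALE, GYRO_FULL_SCALE)
    accel = np.clip(accel, -ACCEL_FULL_SCALE, ACCEL_FULL_SCALE)

    trial = ImuTrial(t=t, accel=accel, gyro=gyro, fs=fs, task=TASK_MCMJ)
    gate = GateSignal(t=t, contact=contact, fs=fs)
    return trial, gate, segs


def simulate_sls_trial(bp: TrialBlueprint) -> tuple[ImuTrial, list[SquatSegment]]:
    """Generate one single-leg-squat trial with known descent ground truth."""
    if bp.task != TASK_SLS:
        raise ValueError("blueprint task must be SLS")
    fs, dt = bp.fs, 1.0 / bp.fs
    n = int(round(bp.duration * fs)) + 1
    t = np.arange(n) * dt
    rng = np.random.default_rng(bp.seed)

    # quiet-stance postural micro-sway: slow tilt wobble present throughout,
    # which is what sets the baseline SD that the onset detector thresholds on
    ph = rng.uniform(0, 2 * np.pi, 2)
    wobble_x = bp.postural_sway_deg * np.sin(2 * np.pi * 0.45 * t + ph[0])
    wobble_y = bp.postural_sway_deg * np.sin(2 * np.pi * 0.70 * t + ph[1])

    theta_y = np.zeros(n)
    truth: list[SquatSegment] = []
    for r, (dpi, dpe) in enumerate(bp.dp_bounds_truth):
        T = dpe - dpi
        span = (t >= dpi) & (t < dpi + 2 * T)
        tau = t[span] - dpi
        theta_y[span] = bp.theta_ymax_truth[r] * np.sin(np.pi * tau / (2 * T))
        truth.append(
            SquatSegment(
                DP_i=dpi,
                DP_e=dpe,
                theta_ymax=float(bp.theta_ymax_truth[r]),
                baseline_sd=0.0,
            )
        )

    rotvecs = np.zeros((n, 3))
    rotvecs[:, 0] = np.deg2rad(wobble_x)
    rotvecs[:, 1] = np.deg2rad(theta_y + wobble_y)
    rot = Rotation.from_rotvec(rotvecs)
    gyro = _finite_diff_body_rates(rot, fs)
    f_world = np.zeros((n, 3))
    f_world[:, 2] = G
    accel = _sensor_accel(rot, f_world)

    if bp.noise_sd.gyro_dps > 0:
        gyro = gyro + rng.normal(0.0, bp.noise_sd.gyro_dps, gyro.shape)
    if bp.noise_sd.accel_ms2 > 0:
        accel = accel + rng.normal(0.0, bp.noise_sd.accel_ms2, accel.shape)
    gyro = np.clip(gyro, -GYRO_FULL_SCALE, GYRO_FULL_SCALE)
    accel = np.clip(accel, -ACCEL_FULL_SCALE, ACCEL_FULL_SCALE)

    trial = ImuTrial(t=t, accel=accel, gyro=gyro, fs=fs, task=TASK_SLS)
    return trial, truth


def detectable_angle_floor(noise: ChannelNoise, factor: float = 5.0) -> float:
    """Smallest squat angle (deg) the generator accepts as detectable.

    ``factor`` times the tilt-angle equivalent of the accelerometer noise.
    """
    return factor * math.degrees(math.atan(noise.accel_ms2 / G))


# ---------------------------------------------------------------------------
# index-level cohort generator (hierarchical variance components)
# ---------------------------------------------------------------------------


@dataclass
class CohortBlueprint:
    """Hierarchical subject/session/error model for index values.

    value(subject s, session j) = mean + b_s + c_j + e_sj with independent
    zero-mean normal components of variance sigma2_subject, sigma2_session
    and sigma2_error.  The theoretical single-measure absolute-agreement ICC
    is sigma2_subject / (sigma2_subject + sigma2_session + sigma2_error).
    """

    index_means: dict[str, float]
    sigma2_subject: float | dict[str, float] = 1.0
    sigma2_session: float | dict[str, float] = 0.0
    sigma2_error: float | dict[str, float] = 0.1
    n_subjects: int = 12
    n_sessions: int = 3
    seed: int = 0

    def _comp(self, comp, name: str) -> dict[str, float]:
        if isinstance(comp, dict):
            out = {k: float(comp[k]) for k in self.index_means}
        else:
            out = {k: float(comp) for k in self.index_means}
        if any(v < 0 for v in out.values()):
            raise ValueError(f"{name} must be non-negative")
        return out

    def theoretical_icc(self, index: str) -> float:
        s = self._comp(self.sigma2_subject, "sigma2_subject")[index]
        c = self._comp(self.sigma2_session, "sigma2_session")[index]
        e = self._comp(self.sigma2_error, "sigma2_error")[index]
        total = s + c + e
        if total == 0:
            raise ValueError("all variance components are zero: ICC undefined")
        return s / total


def simulate_cohort(cb: CohortBlueprint) -> pd.DataFrame:
    """Session-indexed table of per-subject index values.

    Tidy frame with columns ``subject_id``, ``session_id`` and one column
    per index name; n_subjects x n_sessions rows.
    """
    s2s = cb._comp(cb.sigma2_subject, "sigma2_subject")
    s2c = cb._comp(cb.sigma2_session, "sigma2_session")
    s2e = cb._comp(cb.sigma2_error, "sigma2_error")
    rng = np.random.default_rng(cb.seed)
    subjects = [f"S{i + 1:02d}" for i in range(cb.n_subjects)]
    sessions = [f"sess{j + 1}" for j in range(cb.n_sessions)]
    rows = {"subject_id": np.repeat(subjects, cb.n_sessions),
            "session_id": np.tile(sessions, cb.n_subjects)}
    for name, mu in cb.index_means.items():
        b = rng.normal(0.0, math.sqrt(s2s[name]), cb.n_subjects)
        c = rng.normal(0.0, math.sqrt(s2c[name]), cb.n_sessions)
        e = rng.normal(0.0, math.sqrt(s2e[name]), (cb.n_subjects, cb.n_sessions))
        rows[name] = (mu + b[:, None] + c[None, :] + e).ravel()
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# study-level generator: blueprints for a control cohort and a case athlete
# ---------------------------------------------------------------------------


@dataclass
class PopulationModel:
    """Between-subject, between-session and rep-to-rep variation.

    Multiplicative log-normal coefficients of variation applied to the
    blueprint parameters; the squat angle varies additively (normal, deg).
    """

    subject_cv: float = 0.12
    session_cv: float = 0.05
    rep_cv: float = 0.13
    ts_subject_cv: float = 0.24
    theta_mean: float = 28.5
    theta_subject_sd: float = 2.5
    theta_rep_sd: float = 1.5


#: injured-profile alterations: high-frequency antero-posterior
#: micro-instability at slightly rebalanced amplitude (raises PL and PL_AP
#: while leaving the excursion variance, hence EA and PL_ML, unchanged),
#: harsher landings, reduced squat depth; stabilization time untouched.
INJURED_PROFILE = {
    "ap_jitter_ratio": 0.40,
    "ap_jitter_hz": 12.0,
    "amp_ap_factor": 0.92,
    "impact_factor": 1.5,
    "theta_mean": 21.8,
    "theta_subject_sd": 1.5,
}


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    if cv <= 0:
        return np.ones(size) if size else 1.0
    sigma = math.sqrt(math.log(1.0 + cv**2))
    return rng.lognormal(-0.5 * sigma**2, sigma, size)


def sample_subject_blueprints(
    rng: np.random.Generator,
    task: str,
    n_sessions: int = 1,
    pop: PopulationModel | None = None,
    injured: bool = False,
    typical: bool = False,
    n_reps: int = 5,
) -> list[TrialBlueprint]:
    """Blueprints for one subject's sessions, drawn from the population model.

    ``typical`` pins the subject-level factors at the population mean (the
    case-study athlete is modelled as a typical subject whose injury alters
    specific movement parameters); session and repetition variability remain.
    """
    pop = pop or PopulationModel()
    base_sway = SwayModel()
    subj = 1.0 if typical else None
    amp_ap = base_sway.amp_ap_cm * (subj or _lognormal_factor(rng, pop.subject_cv))
    amp_ml = base_sway.amp_ml_cm * (subj or _lognormal_factor(rng, pop.subject_cv))
    impact = 80.0 * (subj or _lognormal_factor(rng, pop.subject_cv))
    ts_mean = 0.24 * (subj or _lognormal_factor(rng, pop.ts_subject_cv))
    theta_mean = pop.theta_mean
    theta_sd = pop.theta_subject_sd
    jitter_ratio = 0.0
    if injured:
        amp_ap = amp_ap * INJURED_PROFILE["amp_ap_factor"]
        jitter_ratio = INJURED_PROFILE["ap_jitter_ratio"]
        impact *= INJURED_PROFILE["impact_factor"]
        theta_mean = INJURED_PROFILE["theta_mean"]
        theta_sd = INJURED_PROFILE["theta_subject_sd"]
    theta_subj = theta_mean if typical else rng.normal(theta_mean, theta_sd)

    blueprints = []
    for _ in range(n_sessions):
        sess = _lognormal_factor(rng, pop.session_cv)
        sway = SwayModel(
            amp_ap_cm=float(amp_ap * sess),
            amp_ml_cm=float(amp_ml * sess),
            freq_ap_hz=base_sway.freq_ap_hz,
            freq_ml_hz=base_sway.freq_ml_hz,
            ap_jitter_ratio=jitter_ratio,
            ap_jitter_hz=INJURED_PROFILE["ap_jitter_hz"],
        )
        ts_reps = np.clip(
            ts_mean * sess * _lognormal_factor(rng, pop.rep_cv, n_reps), 0.05, 0.55
        )
        theta_reps = np.clip(
            theta_subj + rng.normal(0.0, pop.theta_rep_sd, n_reps), 5.0, 60.0
        )
        bp = TrialBlueprint(
            task=task,
            n_reps=n_reps,
            sway_model=sway,
            sway_rep_scale=_lognormal_factor(rng, pop.rep_cv, n_reps),
            ts_truth=ts_reps if task == TASK_MCMJ else 0.24,
            theta_ymax_truth=theta_reps,
            impact_accel_peak=impact * sess * _lognormal_factor(rng, pop.rep_cv, n_reps),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        blueprints.append(bp)
    return blueprints


def simulate_case_study(
    seed: int,
    n_cg: int = 12,
    pop: PopulationModel | None = None,
):
    """Blueprints for the screening case study.

    Returns ``(cg, athlete)``: per-subject blueprint pairs (jump, squat) for
    ``n_cg`` control athletes (one session each) and the injured-profile
    athlete, modelled as a population-typical subject with the
    :data:`INJURED_PROFILE` alterations.
    """
    rng = np.random.default_rng(seed)
    cg = []
    for _ in range(n_cg):
        bj = sample_subject_blueprints(rng, TASK_MCMJ, 1, pop=pop)[0]
        bs = sample_subject_blueprints(rng, TASK_SLS, 1, pop=pop)[0]
        cg.append((bj, bs))
    aj = sample_subject_blueprints(rng, TASK_MCMJ, 1, pop=pop, injured=True, typical=True)[0]
    asq = sample_subject_blueprints(rng, TASK_SLS, 1, pop=pop, injured=True, typical=True)[0]
    return cg, (aj, asq)
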