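"""Movement-event detection.

Three detectors feed the index computations:

* jump contact/flight segmentation from the optical-gate contact signal,
  with debouncing of sub-physiological runs;
* stabilization time ``Ts`` as the delay from initial ground contact to the
  first local minimum of the (low-pass filtered) angular-velocity magnitude
  within the contact period;
* the squat descending phase: onset ``DP_i`` where the module of the three
  orientation angles leaves its quiet-baseline band for a sustained run,
  end ``DP_e`` at the maximum angle about the medio-lateral (Y) axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .signals import GateSignal, ImuTrial


@dataclass
class JumpSegment:
    """One jump repetition: flight then landing contact."""

    FT_i: float  #: initial flight time, s
    CT_i: float  #: initial contact time, s
    dFT: float   #: flight duration, s
    dCT: float   #: contact duration, s
    Ts: float | None = None        #: stabilization time (omega_min_t - CT_i), s
    omega_min_t: float | None = None
    flagged: bool = False          #: True when Ts fell back to the window end

    def __post_init__(self) -> None:
        if self.dFT <= 0 or self.dCT <= 0:
            raise ValueError("flight and contact durations must be positive")
        if abs(self.FT_i + self.dFT - self.CT_i) > 1e-9:
            raise ValueError("FT_i + dFT must equal CT_i")
        if self.Ts is not None and not 0 < self.Ts <= self.dCT + 1e-9:
            raise ValueError("Ts must lie in (0, dCT]")

    @property
    def jump_duration(self) -> float:
        """Flight plus contact duration of this repetition, s."""
        return self.dFT + self.dCT


@dataclass
class SquatSegment:
    """Descending phase of one single-leg squat repetition."""

    DP_i: float          #: onset of the descending phase, s
    DP_e: float          #: end of the descending phase (maximal Y angle), s
    theta_ymax: float    #: maximal angle about the Y axis, degrees
    baseline_sd: float   #: quiet-baseline SD statistic, degrees
    flagged: bool = False

    def __post_init__(self) -> None:
        if self.DP_e <= self.DP_i:
            raise ValueError("DP_e must follow DP_i")

    @property
    def T_DP(self) -> float:
        """Descending-phase duration, s."""
        return self.DP_e - self.DP_i


def _runs(x: np.ndarray) -> list[tuple[int, int, bool]]:
    """Maximal constant runs of a boolean series as (start, stop, value)."""
    edges = np.flatnonzero(np.diff(x.astype(np.int8))) + 1
    bounds = np.r_[0, edges, x.size]
    return [(int(a), int(b), bool(x[a])) for a, b in zip(bounds[:-1], bounds[1:])]


def _debounce(contact: np.ndarray, fs: float, min_flight: float, min_contact: float) -> np.ndarray:
    """Merge runs shorter than the physiological minima into their context.

    Interior glitches (a run shorter than its minimum bracketed by the
    opposite state) are flipped; the pass repeats until stable.
    """
    out = contact.copy()
    while True:
        runs = _runs(out)
        changed = False
        for k, (a, b, val) in enumerate(runs):
            if k == 0 or k == len(runs) - 1:
                continue  # never flip boundary runs
            min_len = (min_flight if not val else min_contact) * fs
            if b - a < min_len:
                out[a:b] = not val
                changed = True
                break
        if not changed:
            return out


def detect_contacts(
    gate: GateSignal,
    min_flight: float = 0.05,
    min_contact: float = 0.05,
) -> list[JumpSegment]:
    """Segment jump repetitions from the gate contact signal.

    Each flight run followed by a contact run yields one :class:`JumpSegment`
    (without ``Ts``): ``FT_i`` at the contact->flight transition, ``CT_i`` at
    the flight->contact transition, ``dCT`` extending to the next takeoff or
    the end of the record.
    """
    cleaned = _debounce(gate.contact, gate.fs, min_flight, min_contact)
    runs = _runs(cleaned)
    segs: list[JumpSegment] = []
    for k, (a, b, val) in enumerate(runs):
        if val or k + 1 >= len(runs):
            continue  # need a flight run with a following contact run
        ca, cb, _ = runs[k + 1]
        ft_i = float(gate.t[a])
        ct_i = float(gate.t[ca])
        dt = 1.0 / gate.fs
        dct = (cb - ca) * dt
        segs.append(JumpSegment(FT_i=ft_i, CT_i=ct_i, dFT=ct_i - ft_i, dCT=dct))
    if not segs:
        warnings.warn("no complete flight-contact cycle found in gate signal")
    return segs


def _lowpass(x: np.ndarray, fs: float, cutoff: float) -> np.ndarray:
    sos = sps.butter(4, cutoff, btype="low", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def stabilization_time(
    trial: ImuTrial,
    seg: JumpSegment,
    smooth_cutoff: float = 10.0,
) -> JumpSegment:
    """Locate the first minimum of |angular velocity| after landing.

    The Euclidean norm of the three gyroscope channels is zero-phase
    low-pass filtered (4th-order Butterworth, ``smooth_cutoff`` Hz) and the
    first strict local minimum inside ``(CT_i, CT_i + dCT]`` defines
    ``omega_min``; ``Ts`` is its delay from ``CT_i``.  If the filtered
    magnitude decreases monotonically over the whole contact the window end
    is used and the repetition is flagged.
    """
    omega = np.linalg.norm(trial.gyro, axis=1)
    smooth = _lowpass(omega, trial.fs, smooth_cutoff)
    sl = trial.slice_time(seg.CT_i, seg.CT_i + seg.dCT)
    w = smooth[sl]
    if w.size < 3:
        raise ValueError("contact window too short for minimum search")
    interior = np.flatnonzero((w[1:-1] < w[:-2]) & (w[1:-1] < w[2:])) + 1
    if interior.size:
        i_min = int(interior[0])
        t_min = float(trial.t[sl.start + i_min])
        return replace(seg, Ts=t_min - seg.CT_i, omega_min_t=t_min, flagged=False)
    return replace(seg, Ts=seg.dCT, omega_min_t=seg.CT_i + seg.dCT, flagged=True)


def detect_descending_phase(
    angles: np.ndarray,
    fs: float,
    baseline_window: float = 2.0,
    n_consecutive: int = 5,
    sd_multiplier: float = 1.0,
    t0: float = 0.0,
) -> SquatSegment:
    """Detect one squat descending phase from orientation angles.

    ``angles`` is (N, 3) in degrees (rotations about X, Y, Z).  The module
    ``m = ||(theta_x, theta_y, theta_z)||`` is compared against its quiet
    baseline: the threshold is ``sd_multiplier`` times the mean of the three
    per-axis SDs over the first ``baseline_window`` seconds.  ``DP_i`` is the
    first sample (after the baseline window) from which ``m`` exceeds its
    baseline mean by more than the threshold for ``n_consecutive``
    samples; ``DP_e`` is the argmax of the Y angle after ``DP_i``.

    Raises
    ------
    ValueError
        If the deviation never exceeds the threshold (no squat detected).
    """
    angles = np.asarray(angles, dtype=float)
    if angles.ndim != 2 or angles.shape[1] != 3:
        raise ValueError("angles must be (N, 3)")
    nb = int(round(baseline_window * fs))
    if angles.shape[0] <= nb + n_consecutive:
        raise ValueError("trial shorter than baseline window plus movement")
    m = np.linalg.norm(angles, axis=1)
    baseline_sd = float(np.mean(angles[:nb].std(axis=0, ddof=1)))
    m0 = float(m[:nb].mean())
    supra = (m - m0) > sd_multiplier * baseline_sd
    supra[:nb] = False
    onset = _first_sustained(supra, n_consecutive)
    if onset is None:
        raise ValueError("angle module never left the baseline band: no squat detected")
    theta_y = angles[:, 1]
    i_max = onset + int(np.argmax(theta_y[onset:]))
    return SquatSegment(
        DP_i=t0 + onset / fs,
        DP_e=t0 + i_max / fs,
        theta_ymax=float(theta_y[i_max]),
        baseline_sd=baseline_sd,
    )


def _first_sustained(mask: np.ndarray, n: int) -> int | None:
    """Start index of the first run of >= n consecutive True values."""
    if n <= 1:
        idx = np.flatnonzero(mask)
        return int(idx[0]) if idx.size else None
    kernel = np.ones(n, dtype=int)
    counts = np.convolve(mask.astype(int), kernel, mode="valid")
    hits = np.flatnonzero(counts == n)
    return int(hits[0]) if hits.size else None


def segment_squats(
    angles: np.ndarray,
    fs: float,
    baseline_window: float = 2.0,
    n_consecutive: int = 5,
    sd_multiplier: float = 1.0,
    min_prominence: float = 5.0,
    min_separation: float = 1.0,
    t0: float = 0.0,
) -> list[SquatSegment]:
    """Segment a multi-repetition squat trial into descending phases.

    Repetitions are localized as prominent peaks of the Y angle (knee
    flexion); each onset is then found with the sustained-threshold rule of
    :func:`detect_descending_phase`, anchored to its repetition: walking
    backwards from the peak, ``DP_i`` is the start of the supra-threshold
    run containing the peak (the run must last ``n_consecutive`` samples).
    Repetitions whose run is shorter are flagged and skipped.
    """
    angles = np.asarray(angles, dtype=float)
    nb = int(round(baseline_window * fs))
    if angles.shape[0] <= nb:
        raise ValueError("trial shorter than baseline window")
    m = np.linalg.norm(angles, axis=1)
    baseline_sd = float(np.mean(angles[:nb].std(axis=0, ddof=1)))
    m0 = float(m[:nb].mean())
    supra = (m - m0) > sd_multiplier * baseline_sd
    theta_y = angles[:, 1]
    peaks, _ = sps.find_peaks(
        theta_y, prominence=min_prominence, distance=max(1, int(min_separation * fs))
    )
    peaks = peaks[peaks >= nb]
    segs: list[SquatSegment] = []
    for p in peaks:
        i = int(p)
        while i > 0 and supra[i - 1]:
            i -= 1
        run_end = int(p)
        while run_end + 1 < supra.size and supra[run_end + 1]:
            run_end += 1
        if run_end - i + 1 < n_consecutive:
            continue  # too brief to satisfy the sustained-crossing rule
        # onset refinement: the threshold is crossed a few samples after the
        # movement starts, so back-extrapolate the local rise of the module
        # to its baseline mean (correction capped at 50 ms)
        dp_i = i / fs
        fit_end = min(i + int(0.03 * fs), int(p))
        if fit_end - i >= 5:
            tau = np.arange(i, fit_end) / fs
            slope = float(np.polyfit(tau, m[i:fit_end], 1)[0])
            if slope > 0:
                dp_i -= min((m[i] - m0) / slope, 0.05)
        # DP_e: maximal Y angle within this repetition's excursion
        i_max = i + int(np.argmax(theta_y[i : run_end + 1]))
        segs.append(
            SquatSegment(
                DP_i=t0 + dp_i,
                DP_e=t0 + i_max / fs,
                theta_ymax=float(theta_y[i_max]),
                baseline_sd=baseline_sd,
            )
        )
    return segs
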