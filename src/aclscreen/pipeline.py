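"""Trial-to-indices orchestration.

One call per task chains calibration, orientation estimation, event
detection and index computation, returning per-repetition index sets ready
for session averaging.
"""

from __future__ import annotations

from dataclasses import asdict

import pandas as pd

from .events import detect_contacts, segment_squats, stabilization_time
from .indices import IndexSet, compute_mcmj_indices, compute_sls_indices
from .orientation import calibrate_static, estimate_orientation
from .signals import GateSignal, ImuTrial

INDEX_COLUMNS = ["Ts", "T_DP", "EA", "PL", "PL_AP", "PL_ML", "RMS_z", "RMS_xy", "theta_ymax"]

MCMJ_INDICES = ["Ts", "EA", "PL", "PL_AP", "PL_ML", "RMS_z", "RMS_xy"]
SLS_INDICES = ["EA", "PL", "PL_AP", "PL_ML", "theta_ymax"]


def process_mcmj(
    trial: ImuTrial,
    gate: GateSignal,
    calib_window: tuple[float, float] = (0.0, 10.0),
    kp: float = 1.0,
    ki: float = 0.1,
    smooth_cutoff: float = 10.0,
    min_flight: float = 0.05,
    min_contact: float = 0.05,
    plane_offset_cm: float = 1.0,
) -> list[IndexSet]:
    """Jump trial -> per-repetition stability and load-absorption indices."""
    gate.check_same_base(trial)
    cal = calibrate_static(trial, calib_window)
    orient = estimate_orientation(trial, cal, kp=kp, ki=ki)
    segs = detect_contacts(gate, min_flight=min_flight, min_contact=min_contact)
    segs = [stabilization_time(trial, s, smooth_cutoff=smooth_cutoff) for s in segs]
    return compute_mcmj_indices(trial, orient, segs, plane_offset_cm=plane_offset_cm)


def process_sls(
    trial: ImuTrial,
    calib_window: tuple[float, float] = (0.0, 10.0),
    kp: float = 1.0,
    ki: float = 0.1,
    baseline_window: float = 2.0,
    n_consecutive: int = 5,
    sd_multiplier: float = 1.0,
    plane_offset_cm: float = 1.0,
) -> list[IndexSet]:
    """Squat trial -> per-repetition stability and mobility indices."""
    cal = calibrate_static(trial, calib_window)
    orient = estimate_orientation(trial, cal, kp=kp, ki=ki)
    angles = orient.euler_relative_deg(cal)
    segs = segment_squats(
        angles,
        trial.fs,
        baseline_window=baseline_window,
        n_consecutive=n_consecutive,
        sd_multiplier=sd_multiplier,
    )
    return compute_sls_indices(trial, orient, segs, plane_offset_cm=plane_offset_cm)


def indices_to_frame(
    index_sets: list[IndexSet],
    subject_id: str = "",
    session_id: str = "",
    leg: str = "dominant",
) -> pd.DataFrame:
    """Tidy per-repetition table: one row per rep, one column per index."""
    rows = []
    for s in index_sets:
        d = asdict(s)
        d.update(subject_id=subject_id, session_id=session_id, leg=leg)
        rows.append(d)
    cols = ["subject_id", "session_id", "task", "leg", "rep", *INDEX_COLUMNS, "flagged"]
    return pd.DataFrame(rows)[cols]
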