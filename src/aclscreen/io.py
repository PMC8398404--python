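"""CSV interchange, JSON reports and run configuration.

There is no community standard for raw IMU trial files, so a simple CSV
dialect is used throughout (UTF-8, dot decimal, header row):

* IMU: columns ``t, ax, ay, az, gx, gy, gz`` and optionally ``mx, my, mz``
  (seconds, m/s^2, deg/s, uT);
* gate: columns ``t, contact`` with contact in {0, 1};
* per-repetition index tables and reliability/comparison reports round-trip
  through CSV/JSON losslessly.

Readers reject malformed input (missing columns, non-monotone or gappy
time) with line diagnostics rather than coercing silently.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .signals import GateSignal, ImuTrial, TrialValidationError

IMU_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz"]
MAG_COLUMNS = ["mx", "my", "mz"]
GATE_COLUMNS = ["t", "contact"]


@dataclass
class RunConfig:
    """Validated parameters of one processing run."""

    fs: float = 1000.0
    calib_start: float = 0.0
    calib_end: float = 10.0
    kp: float = 1.0
    ki: float = 0.1
    smooth_cutoff: float = 10.0
    plane_offset_cm: float = 1.0
    n_consecutive: int = 5
    sd_multiplier: float = 1.0
    min_flight: float = 0.05
    min_contact: float = 0.05
    baseline_window: float = 2.0
    icc_threshold: float = 0.60
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            ("fs", self.fs > 0),
            ("calib window", self.calib_end > self.calib_start >= 0),
            ("kp", self.kp > 0),
            ("ki", self.ki >= 0),
            ("smooth_cutoff", 0 < self.smooth_cutoff < self.fs / 2),
            ("plane_offset_cm", self.plane_offset_cm > 0),
            ("n_consecutive", self.n_consecutive >= 1),
            ("sd_multiplier", self.sd_multiplier > 0),
            ("min_flight", self.min_flight >= 0),
            ("min_contact", self.min_contact >= 0),
            ("baseline_window", self.baseline_window > 0),
            ("icc_threshold", 0 <= self.icc_threshold <= 1),
            ("alpha", 0 < self.alpha < 1),
        ]
        bad = [name for name, ok in checks if not ok]
        if bad:
            raise ValueError(f"invalid configuration parameter(s): {', '.join(bad)}")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)


def _validate_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TrialValidationError(f"{path}: missing column(s) {missing}")


def read_imu_csv(
    path: str | Path,
    fs: float | None = None,
    task: str = "mcmj",
    leg: str = "dominant",
    subject_id: str = "",
    session_id: str = "",
) -> ImuTrial:
    """Load an IMU trial, inferring ``fs`` from the time column if not given."""
    df = pd.read_csv(path)
    _validate_columns(df, IMU_COLUMNS, path)
    t = df["t"].to_numpy(dtype=float)
    if t.size < 2:
        raise TrialValidationError(f"{path}: fewer than 2 samples")
    if fs is None:
        fs = 1.0 / float(np.median(np.diff(t)))
    mag = df[MAG_COLUMNS].to_numpy(float) if all(c in df.columns for c in MAG_COLUMNS) else None
    try:
        return ImuTrial(
            t=t,
            accel=df[["ax", "ay", "az"]].to_numpy(float),
            gyro=df[["gx", "gy", "gz"]].to_numpy(float),
            fs=fs,
            task=task,
            leg=leg,
            subject_id=subject_id,
            session_id=session_id,
            mag=mag,
        )
    except TrialValidationError as err:
        raise TrialValidationError(f"{path}: {err}") from err


def write_imu_csv(trial: ImuTrial, path: str | Path) -> None:
    df = pd.DataFrame(
        np.c_[trial.t, trial.accel, trial.gyro],
        columns=IMU_COLUMNS,
    )
    if trial.mag is not None:
        df[MAG_COLUMNS] = trial.mag
    df.to_csv(path, index=False, float_format="%.10g")


def read_gate_csv(path: str | Path, fs: float | None = None) -> GateSignal:
    df = pd.read_csv(path)
    _validate_columns(df, GATE_COLUMNS, path)
    t = df["t"].to_numpy(dtype=float)
    contact = df["contact"].to_numpy()
    if not np.isin(contact, [0, 1]).all():
        bad = int(np.argmax(~np.isin(contact, [0, 1])))
        raise TrialValidationError(f"{path}: contact must be 0/1 (row {bad + 2})")
    if fs is None:
        fs = 1.0 / float(np.median(np.diff(t)))
    try:
        return GateSignal(t=t, contact=contact.astype(bool), fs=fs)
    except TrialValidationError as err:
        raise TrialValidationError(f"{path}: {err}") from err


def write_gate_csv(gate: GateSignal, path: str | Path) -> None:
    pd.DataFrame({"t": gate.t, "contact": gate.contact.astype(int)}).to_csv(
        path, index=False, float_format="%.10g"
    )


def write_index_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_index_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json_report(obj, path: str | Path) -> None:
    """Serialize a report (dict / list / DataFrame) to pretty JSON."""
    if isinstance(obj, pd.DataFrame):
        obj = obj.to_dict(orient="records")
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.bool_):
        return bool(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def write_ground_truth_json(segments, path: str | Path) -> None:
    """Ground-truth sidecar for a simulated trial."""
    write_json_report([dataclasses.asdict(s) for s in segments], path)
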