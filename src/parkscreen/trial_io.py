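"""Reading, writing and quality control of kinematic trials and cohort tables.

A trial is stored as an open two-file format: a CSV with a time column and
the six sensor channels, plus a JSON sidecar carrying the trial metadata
(participant, hand, task, trial index, sample rate).  The vendor's native
motion-capture format is proprietary and out of scope.

Quality control follows the screening protocol: trials shorter than the
nominal 12 s are rejected, as are trials whose task-relevant gyroscope axis
flat-lines or saturates (operationalized thresholds; see ``qc_trial``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

HANDS = ("dominant", "non_dominant")
TASKS = ("finger_tapping", "hand_rotation", "action_tremor", "postural_tremor")

#: Bradykinesia tasks feed the prediction model; tremor tasks feed screening only.
BRADYKINESIA_TASKS = ("finger_tapping", "hand_rotation")

CHANNEL_COLUMNS = ("gyro_x", "gyro_y", "gyro_z", "accel_x", "accel_y", "accel_z")

#: Default gyroscope full-scale range, deg/s, used by the saturation rule.
DEFAULT_FULL_SCALE_DEG_S = 2000.0


@dataclass
class KinematicTrial:
    """One 12-s six-channel recording with task/hand/trial metadata.

    Gyroscope channels are angular velocity in deg/s; accelerometer channels
    are linear acceleration in g.  The time base is taken as uniform at
    ``sample_rate_hz``; any time column in the source file is informative
    only.
    """

    participant_id: str
    hand: str
    task: str
    trial_index: int
    sample_rate_hz: float
    gyro_x: np.ndarray
    gyro_y: np.ndarray
    gyro_z: np.ndarray
    accel_x: np.ndarray
    accel_y: np.ndarray
    accel_z: np.ndarray

    def __post_init__(self) -> None:
        if self.hand not in HANDS:
            raise ValidationError(f"hand must be one of {HANDS}, got {self.hand!r}")
        if self.task not in TASKS:
            raise ValidationError(f"task must be one of {TASKS}, got {self.task!r}")
        if self.trial_index not in (1, 2, 3):
            raise ValidationError(
                f"trial_index must be 1, 2 or 3, got {self.trial_index!r}"
            )
        if not self.sample_rate_hz > 0:
            raise ValidationError("sample_rate_hz must be positive")
        lengths = {len(getattr(self, c)) for c in CHANNEL_COLUMNS}
        if len(lengths) != 1:
            raise ValidationError(f"channel lengths differ: {sorted(lengths)}")
        if lengths == {0}:
            raise ValidationError("trial has no samples")
        for c in CHANNEL_COLUMNS:
            setattr(self, c, np.asarray(getattr(self, c), dtype=float))

    @property
    def n_samples(self) -> int:
        return len(self.gyro_x)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    @property
    def key(self) -> tuple[str, str, str, int]:
        return (self.participant_id, self.hand, self.task, self.trial_index)


@dataclass
class QcReport:
    """Classification of one trial: pass, too short, or sensor failure."""

    participant_id: str
    hand: str
    task: str
    trial_index: int
    status: str  # "pass" | "fail_short" | "fail_sensor"
    detail: str = ""

    @property
    def passed(self) -> bool:
        return self.status == "pass"


@dataclass
class ParticipantRecord:
    """Cohort-table row: demographics, pegboard results, optional UPDRS3."""

    participant_id: str
    age_years: float
    sex: str
    handedness: str
    community: str = ""
    pegboard_time_s: Optional[float] = None
    pegboard_pegs_placed: Optional[int] = None
    pegboard_pegs_dropped: Optional[int] = None
    updrs3_total: Optional[float] = None
    subscores: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.handedness not in ("right", "left"):
            raise ValidationError(
                "handedness must be 'right' or 'left' (ambidextrous participants "
                f"are excluded by the protocol); got {self.handedness!r}"
            )

    @property
    def has_updrs3(self) -> bool:
        return self.updrs3_total is not None


def read_trial(path: str | Path, sidecar: str | Path) -> KinematicTrial:
    """Read a trial CSV and its JSON sidecar into a validated trial.

    The CSV must contain columns ``t`` plus the six channel columns; ``t``
    must be non-decreasing.  Duration is computed from sample count and the
    sidecar's ``sample_rate_hz``, never from the time column.
    """
    df = pd.read_csv(path)
    required = ("t",) + CHANNEL_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    t = df["t"].to_numpy(dtype=float)
    if len(t) > 1 and np.any(np.diff(t) < 0):
        raise FormatError(f"{path}: time column is not monotone non-decreasing")
    with open(sidecar) as fh:
        meta = json.load(fh)
    for key in ("participant_id", "hand", "task", "trial_index", "sample_rate_hz"):
        if key not in meta:
            raise FormatError(f"{sidecar}: missing sidecar key {key!r}")
    return KinematicTrial(
        participant_id=str(meta["participant_id"]),
        hand=meta["hand"],
        task=meta["task"],
        trial_index=int(meta["trial_index"]),
        sample_rate_hz=float(meta["sample_rate_hz"]),
        **{c: df[c].to_numpy(dtype=float) for c in CHANNEL_COLUMNS},
    )


def write_trial(trial: KinematicTrial, path: str | Path, sidecar: str | Path) -> None:
    """Write a trial to the CSV + JSON sidecar dialect (see ``read_trial``)."""
    t = np.arange(trial.n_samples) / trial.sample_rate_hz
    df = pd.DataFrame({"t": t})
    for c in CHANNEL_COLUMNS:
        df[c] = getattr(trial, c)
    df.to_csv(path, index=False, float_format="%.6f")
    meta = {
        "participant_id": trial.participant_id,
        "hand": trial.hand,
        "task": trial.task,
        "trial_index": trial.trial_index,
        "sample_rate_hz": trial.sample_rate_hz,
    }
    with open(sidecar, "w") as fh:
        json.dump(meta, fh, indent=1)


def qc_trial(
    trial: KinematicTrial,
    min_duration_s: float = 12.0,
    flat_fraction: float = 0.5,
    saturation_fraction: float = 0.1,
    full_scale_deg_s: float = DEFAULT_FULL_SCALE_DEG_S,
) -> QcReport:
    """Classify a trial as pass / fail_short / fail_sensor.

    ``fail_short``: duration strictly below ``min_duration_s`` (a trial of
    exactly 12.0 s passes).  ``fail_sensor``: on the task's isolated
    gyroscope axis, either the series is constant over more than
    ``flat_fraction`` of consecutive sample pairs (flat-line) or more than
    ``saturation_fraction`` of samples sit at the sensor's full-scale limit
    (saturation).  QC never raises on content; it classifies.
    """
    from .kinematic_features import isolate_axis

    pid, hand, task, idx = trial.key
    if trial.duration_s < min_duration_s:
        return QcReport(
            pid, hand, task, idx, "fail_short",
            f"duration {trial.duration_s:.2f} s < {min_duration_s:g} s",
        )
    series = isolate_axis(trial)
    if len(series) > 1:
        const_frac = float(np.mean(np.diff(series) == 0.0))
    else:
        const_frac = 1.0
    if const_frac > flat_fraction:
        return QcReport(
            pid, hand, task, idx, "fail_sensor",
            f"flat-line: {100 * const_frac:.0f}% of consecutive samples constant",
        )
    sat_frac = float(np.mean(np.abs(series) >= full_scale_deg_s))
    if sat_frac > saturation_fraction:
        return QcReport(
            pid, hand, task, idx, "fail_sensor",
            f"saturation: {100 * sat_frac:.0f}% of samples at "
            f"|v| >= {full_scale_deg_s:g} deg/s",
        )
    return QcReport(pid, hand, task, idx, "pass")


def qc_batch(trials: Iterable[KinematicTrial], **kwargs) -> list[QcReport]:
    """QC every trial in a batch; one report per trial, input order kept."""
    return [qc_trial(t, **kwargs) for t in trials]


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

_COHORT_REQUIRED = ("participant_id", "age_years", "sex", "handedness")
_COHORT_OPTIONAL = (
    "community",
    "pegboard_time_s",
    "pegboard_pegs_placed",
    "pegboard_pegs_dropped",
    "updrs3_total",
)


def read_cohort(path: str | Path) -> list[ParticipantRecord]:
    """Read a cohort CSV into participant records.

    UPDRS3 columns are optional (records without them support prediction
    only).  Any column named ``updrs3_<subscore>`` other than
    ``updrs3_total`` is collected into the record's ``subscores`` dict.
    """
    df = pd.read_csv(path)
    missing = [c for c in _COHORT_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    sub_cols = [
        c for c in df.columns if c.startswith("updrs3_") and c != "updrs3_total"
    ]
    records = []
    for _, row in df.iterrows():
        def _opt(col, cast=float):
            if col not in df.columns or pd.isna(row[col]):
                return None
            return cast(row[col])

        records.append(
            ParticipantRecord(
                participant_id=str(row["participant_id"]),
                age_years=float(row["age_years"]),
                sex=str(row["sex"]),
                handedness=str(row["handedness"]),
                community=str(row["community"]) if "community" in df.columns else "",
                pegboard_time_s=_opt("pegboard_time_s"),
                pegboard_pegs_placed=_opt("pegboard_pegs_placed", int),
                pegboard_pegs_dropped=_opt("pegboard_pegs_dropped", int),
                updrs3_total=_opt("updrs3_total"),
                subscores={
                    c: float(row[c]) for c in sub_cols if not pd.isna(row[c])
                },
            )
        )
    return records


def write_cohort(records: Iterable[ParticipantRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        row = {
            "participant_id": r.participant_id,
            "age_years": r.age_years,
            "sex": r.sex,
            "handedness": r.handedness,
            "community": r.community,
            "pegboard_time_s": r.pegboard_time_s,
            "pegboard_pegs_placed": r.pegboard_pegs_placed,
            "pegboard_pegs_dropped": r.pegboard_pegs_dropped,
            "updrs3_total": r.updrs3_total,
        }
        row.update(r.subscores)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Model coefficient files
# ---------------------------------------------------------------------------

def read_model_json(path: str | Path):
    """Load model coefficients from the versioned JSON dialect."""
    from .screening_model import ModelCoefficients

    with open(path) as fh:
        payload = json.load(fh)
    return ModelCoefficients.from_dict(payload)


def write_model_json(model, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=1)
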