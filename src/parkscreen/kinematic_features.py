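"""The six per-trial kinematic summary measures and their aggregation.

The bradykinesia tasks are alternating movements whose angular velocity
oscillates around zero on one task-specific gyroscope axis: the x axis for
finger tapping and the y axis for hand rotation.  All six summary measures
are computed on that isolated axis:

* ``mean_velocity`` — mean absolute angular velocity over every sampled
  time point of the trial (deg/s);
* ``mean_peak_velocity`` — mean over cycles of the within-cycle maximum
  absolute velocity (deg/s);
* ``coefficient_of_variation`` — SD/mean of the per-cycle peaks;
* ``decrement_peak_velocity`` — OLS slope of per-cycle peaks against cycle
  index, divided by the mean peak (relative change per cycle);
* ``cycles_per_second`` — number of complete cycles divided by trial
  duration (Hz);
* ``decrement_cycles_per_second`` — OLS slope of the per-cycle
  instantaneous rate (reciprocal cycle duration) against cycle index,
  divided by the mean rate.

Cycles are the spans between consecutive upward zero crossings of the
low-pass-smoothed, mean-centered series; candidate cycles whose peak
velocity falls below a floor are discarded as non-movement.  The smoothing
cutoff (12 Hz) and peak floor (10 deg/s) are keyword arguments with these
defaults.

Tremor tasks have no single movement axis; they use the root-sum-square of
the three gyroscope axes.  They feed the screening stage only, never the
prediction model.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import InsufficientDataError, ValidationError
from .trial_io import KinematicTrial, QcReport, qc_trial

#: Task -> isolated gyroscope axis for the bradykinesia tasks.
TASK_AXIS = {"finger_tapping": "gyro_x", "hand_rotation": "gyro_y"}

MEASURES = (
    "mean_velocity",
    "mean_peak_velocity",
    "coefficient_of_variation",
    "decrement_peak_velocity",
    "cycles_per_second",
    "decrement_cycles_per_second",
)

AGGREGATIONS = ("first_trial", "mean_of_trials")


@dataclass
class TrialSummary:
    """The six kinematic summary measures for one trial on the isolated axis.

    Measures that need cycles are NaN when the trial yields no cycle;
    the two decrements and the coefficient of variation additionally need
    at least two cycles.
    """

    mean_velocity: float
    mean_peak_velocity: float
    coefficient_of_variation: float
    decrement_peak_velocity: float
    cycles_per_second: float
    decrement_cycles_per_second: float
    n_cycles: int

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


@dataclass
class HandTaskFeature:
    """Summary measures for one participant/hand/task under one aggregation."""

    participant_id: str
    hand: str
    task: str
    aggregation: str
    summary: TrialSummary
    n_trials_used: int = 1


def isolate_axis(trial: KinematicTrial) -> np.ndarray:
    """Return the task-relevant angular-velocity series in deg/s.

    Finger tapping isolates gyro x, hand rotation gyro y; the tremor tasks
    use the root-sum-square of all three gyroscope axes.
    """
    if trial.task in TASK_AXIS:
        return getattr(trial, TASK_AXIS[trial.task])
    if trial.task in ("action_tremor", "postural_tremor"):
        return np.sqrt(trial.gyro_x**2 + trial.gyro_y**2 + trial.gyro_z**2)
    raise ValidationError(f"unknown task {trial.task!r}")


def mean_velocity(series: Sequence[float]) -> float:
    """Mean absolute angular velocity across all sampled time points."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValidationError("mean_velocity of an empty series is undefined")
    return float(np.mean(np.abs(series)))


def _smooth(series: np.ndarray, sample_rate_hz: float, cutoff_hz: float) -> np.ndarray:
    nyquist = sample_rate_hz / 2.0
    if cutoff_hz >= nyquist:
        return series
    b, a = sps.butter(4, cutoff_hz / nyquist, btype="low")
    # filtfilt needs a minimum length for its edge padding
    if len(series) <= 3 * max(len(a), len(b)):
        return series
    return sps.filtfilt(b, a, series)


def segment_cycles(
    series: Sequence[float],
    sample_rate_hz: float,
    smoothing_cutoff_hz: float = 12.0,
    min_peak_deg_s: float = 10.0,
) -> list[tuple[int, int]]:
    """Segment an oscillatory series into movement cycles.

    A cycle is the half-open index span ``[start, end)`` between two
    consecutive upward zero crossings of the low-pass-smoothed,
    mean-centered series.  Candidate cycles whose raw peak ``max |v|``
    falls below ``min_peak_deg_s`` are dropped.  Zero cycles is a legal
    outcome (e.g. a flat or sub-threshold trial).
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValidationError("cannot segment an empty series")
    centered = _smooth(series, sample_rate_hz, smoothing_cutoff_hz)
    centered = centered - np.mean(centered)
    # upward crossing between i and i+1: s[i] <= eps < s[i+1]; the small
    # relative tolerance keeps boundary crossings that filter edge
    # transients would otherwise push marginally above zero
    eps = 1e-3 * np.max(np.abs(centered)) if np.any(centered) else 0.0
    ups = np.nonzero((centered[:-1] <= eps) & (centered[1:] > eps))[0] + 1
    cycles = []
    for start, end in zip(ups[:-1], ups[1:]):
        if np.max(np.abs(series[start:end])) >= min_peak_deg_s:
            cycles.append((int(start), int(end)))
    return cycles


def _relative_slope(values: np.ndarray) -> float:
    """OLS slope of values vs 0-based index, divided by the mean value."""
    idx = np.arange(len(values), dtype=float)
    slope = np.polyfit(idx, values, 1)[0]
    mean = np.mean(values)
    return float(slope / mean) if mean != 0 else float("nan")


def summarize_trial(
    trial: KinematicTrial,
    smoothing_cutoff_hz: float = 12.0,
    min_peak_deg_s: float = 10.0,
) -> TrialSummary:
    """Compute the six summary measures for one (QC-passing) trial."""
    series = isolate_axis(trial)
    mv = mean_velocity(series)
    cycles = segment_cycles(
        series, trial.sample_rate_hz, smoothing_cutoff_hz, min_peak_deg_s
    )
    n = len(cycles)
    nan = float("nan")
    if n == 0:
        return TrialSummary(mv, nan, nan, nan, nan, nan, 0)
    peaks = np.array([np.max(np.abs(series[s:e])) for s, e in cycles])
    durations = np.array([(e - s) / trial.sample_rate_hz for s, e in cycles])
    rates = 1.0 / durations
    mean_peak = float(np.mean(peaks))
    cps = n / trial.duration_s
    if n < 2:
        return TrialSummary(mv, mean_peak, nan, nan, cps, nan, n)
    cov = float(np.std(peaks, ddof=1) / mean_peak) if mean_peak != 0 else nan
    return TrialSummary(
        mean_velocity=mv,
        mean_peak_velocity=mean_peak,
        coefficient_of_variation=cov,
        decrement_peak_velocity=_relative_slope(peaks),
        cycles_per_second=cps,
        decrement_cycles_per_second=_relative_slope(rates),
        n_cycles=n,
    )


def directional_mean_velocity(
    series: Sequence[float],
    direction: str,
    sample_rate_hz: float = 64.0,
    smoothing_cutoff_hz: float = 12.0,
) -> float:
    """Mean |v| restricted to one movement direction.

    ``direction`` is ``"positive"`` or ``"negative"``, judged by the sign of
    the smoothed series (upward vs downward tap, clockwise vs
    counterclockwise rotation).  Kept as an optional research variant: in
    practice agreement with clinician ratings is not improved by isolating
    direction, so the standard measures use the whole signal.
    """
    if direction not in ("positive", "negative"):
        raise ValidationError("direction must be 'positive' or 'negative'")
    series = np.asarray(series, dtype=float)
    smoothed = _smooth(series, sample_rate_hz, smoothing_cutoff_hz)
    mask = smoothed > 0 if direction == "positive" else smoothed < 0
    if not np.any(mask):
        raise InsufficientDataError(f"no samples in the {direction} direction")
    return float(np.mean(np.abs(series[mask])))


def aggregate_hand_task(
    trials: Sequence[KinematicTrial],
    aggregation: str = "first_trial",
    qc_reports: Optional[Sequence[QcReport]] = None,
    **summary_kwargs,
) -> HandTaskFeature:
    """Aggregate one participant/hand/task's trials into a feature row.

    ``first_trial`` uses trial index 1 only (the screening protocol's
    minimal battery); ``mean_of_trials`` averages each measure over all
    QC-passing trials, ignoring missing values.
    """
    if aggregation not in AGGREGATIONS:
        raise ValidationError(f"aggregation must be one of {AGGREGATIONS}")
    if not trials:
        raise InsufficientDataError("no trials supplied")
    keys = {(t.participant_id, t.hand, t.task) for t in trials}
    if len(keys) != 1:
        raise ValidationError(f"trials mix participants/hands/tasks: {sorted(keys)}")
    pid, hand, task = keys.pop()
    if qc_reports is None:
        qc_reports = [qc_trial(t) for t in trials]
    passing = [t for t, r in zip(trials, qc_reports) if r.passed]
    if not passing:
        raise InsufficientDataError(
            f"no QC-passing trial for {pid}/{hand}/{task}"
        )
    if aggregation == "first_trial":
        first = [t for t in passing if t.trial_index == 1]
        if not first:
            raise InsufficientDataError(
                f"first trial missing or QC-failed for {pid}/{hand}/{task} "
                "(first_trial aggregation has no fallback)"
            )
        summary = summarize_trial(first[0], **summary_kwargs)
        return HandTaskFeature(pid, hand, task, aggregation, summary, 1)
    summaries = [summarize_trial(t, **summary_kwargs) for t in passing]
    pooled = {}
    for m in MEASURES:
        vals = np.array([getattr(s, m) for s in summaries], dtype=float)
        vals = vals[~np.isnan(vals)]
        pooled[m] = float(np.mean(vals)) if vals.size else float("nan")
    pooled["n_cycles"] = int(round(np.mean([s.n_cycles for s in summaries])))
    return HandTaskFeature(
        pid, hand, task, "mean_of_trials", TrialSummary(**pooled), len(passing)
    )


def feature_table(
    trials: Iterable[KinematicTrial],
    aggregations: Sequence[str] = AGGREGATIONS,
    **kwargs,
) -> pd.DataFrame:
    """Build the long feature table: one row per participant x hand x task
    x aggregation, columns = the six measures plus ``n_cycles``.

    Groups with no QC-passing trial (or a QC-failed first trial under
    ``first_trial``) are silently omitted; callers needing a hard error use
    :func:`aggregate_hand_task` directly.
    """
    groups: dict[tuple, list[KinematicTrial]] = {}
    for t in trials:
        groups.setdefault((t.participant_id, t.hand, t.task), []).append(t)
    rows = []
    for (pid, hand, task), ts in sorted(groups.items()):
        for agg in aggregations:
            try:
                feat = aggregate_hand_task(ts, agg, **kwargs)
            except InsufficientDataError:
                continue
            row = {
                "participant_id": pid,
                "hand": hand,
                "task": task,
                "aggregation": agg,
            }
            row.update(feat.summary.as_dict())
            rows.append(row)
    cols = ["participant_id", "hand", "task", "aggregation", *MEASURES, "n_cycles"]
    return pd.DataFrame(rows, columns=cols)


def pivot_model_inputs(
    features: pd.DataFrame,
    aggregation: str = "first_trial",
    hand: str = "non_dominant",
) -> pd.DataFrame:
    """Pivot the long feature table to the prediction model's wide inputs.

    Returns one row per participant with columns ``hand_rotation_mv`` and
    ``finger_tapping_mv`` (mean velocity of the requested hand and
    aggregation).
    """
    sub = features[
        (features["aggregation"] == aggregation) & (features["hand"] == hand)
    ]
    wide = sub.pivot_table(
        index="participant_id", columns="task", values="mean_velocity"
    )
    wide = wide.rename(
        columns={"hand_rotation": "hand_rotation_mv", "finger_tapping": "finger_tapping_mv"}
    )
    keep = [c for c in ("hand_rotation_mv", "finger_tapping_mv") if c in wide.columns]
    out = wide[keep].reset_index()
    out["participant_id"] = out["participant_id"].astype(str)
    out.columns.name = None
    return out
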