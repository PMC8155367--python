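"""Synthetic participants and synthetic sensor signals.

Every stage of the pipeline is exercisable without any field data:

* :func:`simulate_cohort` draws ages and the three motor predictors from
  configurable marginals (defaults: the training-community means/SDs) and
  generates the clinician motor score as the published prediction
  equation's linear predictor plus Gaussian residual noise — so refitting
  the equation on a simulated cohort is a parameter-recovery experiment
  with known truth.
* :func:`simulate_trial_signal` builds a raw six-channel gyroscope/
  accelerometer trial: an oscillation on the task's movement axis whose
  per-cycle amplitude decays by a configurable decrement fraction, with
  optional tremor overlay and sensor noise.  Lower oscillation amplitude
  and steeper decrement emulate greater parkinsonism severity.
* :func:`simulate_two_communities` pairs a higher-severity and a
  lower-severity cohort (target mean motor scores 9.1 and 3.9) for
  external-validation rehearsal: train on one, validate on the other.

With independent predictor draws the linear predictor's population mean
does not equal a real community's observed mean score (real predictors
co-vary).  A profile may therefore declare a target mean, implemented as
a closed-form intercept offset computed from the profile's marginals —
slope coefficients are never touched, so parameter recovery and all
rank-based validation are unaffected.  The default profile declares no
target and generates from the published equation exactly.

All randomness flows through one seeded :class:`numpy.random.Generator`;
identical seeds give identical artifacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .kinematic_features import MEASURES, TASK_AXIS
from .screening_model import ModelCoefficients, load_published_model
from .trial_io import KinematicTrial

#: amplitude of a sinusoid whose mean |v| equals a given mean velocity
MV_TO_AMPLITUDE = np.pi / 2.0


@dataclass
class CohortProfile:
    """Marginal distributions for one simulated community.

    Defaults are the training-community marginals: age normal (51.3, 8.2)
    truncated below at 41 years; pegboard time normal (116.2, 47.6) s
    capped at 300 s; hand-rotation mean velocity normal (614.2, 177.0)
    deg/s; finger-tapping mean velocity normal (352.0, 115.6) deg/s.  The
    motor score is the published with-age linear predictor plus
    N(0, residual_sd^2) noise; residual_sd defaults to 5.0 points, which
    yields score dispersion compatible with the observed community SDs.
    """

    n: int = 275
    community: str = "training"
    age_mean: float = 51.3
    age_sd: float = 8.2
    age_min: float = 41.0
    pegboard_mean: float = 116.2
    pegboard_sd: float = 47.6
    pegboard_cap: float = 300.0
    hand_rotation_mean: float = 614.2
    hand_rotation_sd: float = 177.0
    finger_tapping_mean: float = 352.0
    finger_tapping_sd: float = 115.6
    residual_sd: float = 5.0
    updrs3_target_mean: Optional[float] = None
    floor_at_zero: bool = False
    round_to_half: bool = False
    female_fraction: float = 0.556
    right_handed_fraction: float = 0.9

    def __post_init__(self) -> None:
        for name in ("age_sd", "pegboard_sd", "hand_rotation_sd",
                     "finger_tapping_sd", "residual_sd"):
            if not getattr(self, name) >= 0 or (
                name != "residual_sd" and getattr(self, name) == 0
            ):
                raise ValidationError(f"{name} must be positive")
        if self.updrs3_target_mean is not None and self.updrs3_target_mean < 0:
            raise ValidationError("updrs3_target_mean must be non-negative")


def training_profile(n: int = 275) -> CohortProfile:
    """Training-community marginals, no target mean (pure generator truth)."""
    return CohortProfile(n=n, community="training")


def exposed_profile(n: int = 275) -> CohortProfile:
    """Higher-severity community: training marginals, target mean score 9.1."""
    return CohortProfile(n=n, community="exposed", updrs3_target_mean=9.1)


def non_exposed_profile(n: int = 90) -> CohortProfile:
    """Lower-severity community: external-validation marginals, target 3.9."""
    return CohortProfile(
        n=n,
        community="non_exposed",
        age_mean=55.6,
        age_sd=8.6,
        pegboard_mean=121.7,
        pegboard_sd=45.5,
        hand_rotation_mean=583.5,
        hand_rotation_sd=163.7,
        finger_tapping_mean=408.2,
        finger_tapping_sd=124.5,
        updrs3_target_mean=3.9,
    )


def expected_linear_predictor_mean(
    profile: CohortProfile, model: Optional[ModelCoefficients] = None
) -> float:
    """Population mean of the linear predictor under the profile's marginals.

    Uses the truncated-normal mean for age, the censored-normal mean for
    capped pegboard time, and E[X^2] = mu^2 + sigma^2 for the quadratic
    hand-rotation term (predictors are independent draws).
    """
    if model is None:
        model = load_published_model("with_age")
    a = (profile.age_min - profile.age_mean) / profile.age_sd
    age_mean = stats.truncnorm.mean(
        a, np.inf, loc=profile.age_mean, scale=profile.age_sd
    )
    beta = (profile.pegboard_cap - profile.pegboard_mean) / profile.pegboard_sd
    # E[(X - c)^+] for X ~ N(mu, sd): sd*phi(beta) - (c - mu)*(1 - Phi(beta))
    excess = profile.pegboard_sd * stats.norm.pdf(beta) - (
        profile.pegboard_cap - profile.pegboard_mean
    ) * stats.norm.sf(beta)
    peg_mean = profile.pegboard_mean - excess
    hr_sq_mean = profile.hand_rotation_mean**2 + profile.hand_rotation_sd**2
    y = (
        model.intercept
        + model.hand_rotation_mv * profile.hand_rotation_mean
        + model.hand_rotation_mv_squared * hr_sq_mean
        + model.finger_tapping_mv * profile.finger_tapping_mean
        + model.pegboard_time * peg_mean
    )
    if model.variant == "with_age":
        y += model.age * age_mean
    return float(y)


def intercept_offset(
    profile: CohortProfile, model: Optional[ModelCoefficients] = None
) -> float:
    """Offset added to the generator intercept to hit the target mean score."""
    if profile.updrs3_target_mean is None:
        return 0.0
    return profile.updrs3_target_mean - expected_linear_predictor_mean(profile, model)


def simulate_cohort(
    profile: CohortProfile,
    seed: Optional[int] = None,
    model: Optional[ModelCoefficients] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one cohort; returns (cohort table, long feature table).

    The cohort table matches the cohort-CSV dialect (demographics,
    pegboard columns, ``updrs3_total``) plus a coarse synthetic
    upper-limb bradykinesia subscore ``updrs3_bradykinesia_nd`` so the
    Spearman screening stage is exercisable.  The feature table carries
    the two bradykinesia-task mean velocities (the model's kinematic
    inputs) under the first-trial aggregation; the remaining measures are
    left missing — full six-measure rows come from raw signals via
    :func:`simulate_trial_signal`.
    """
    if profile.n < 10:
        warnings.warn(f"cohort of n={profile.n} is very small", stacklevel=2)
    if model is None:
        model = load_published_model("with_age")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = profile.n
    a = (profile.age_min - profile.age_mean) / profile.age_sd
    age = stats.truncnorm.rvs(
        a, np.inf, loc=profile.age_mean, scale=profile.age_sd,
        size=n, random_state=rng,
    )
    peg_raw = rng.normal(profile.pegboard_mean, profile.pegboard_sd, n)
    peg = np.minimum(peg_raw, profile.pegboard_cap)
    hr = rng.normal(profile.hand_rotation_mean, profile.hand_rotation_sd, n)
    ft = rng.normal(profile.finger_tapping_mean, profile.finger_tapping_sd, n)
    lp = (
        model.intercept
        + model.hand_rotation_mv * hr
        + model.hand_rotation_mv_squared * hr**2
        + model.finger_tapping_mv * ft
        + model.pegboard_time * peg
    )
    if model.variant == "with_age":
        lp = lp + model.age * age
    lp = lp + intercept_offset(profile, model)
    updrs3 = lp + rng.normal(0.0, profile.residual_sd, n)
    if profile.round_to_half:
        updrs3 = np.round(updrs3 * 2.0) / 2.0
    if profile.floor_at_zero:
        updrs3 = np.maximum(updrs3, 0.0)
    # coarse clinician subscore correlated with the latent severity
    brady = np.maximum(0.25 * updrs3 + rng.normal(0.0, 1.0, n), 0.0)
    capped = peg >= profile.pegboard_cap
    pegs_placed = np.where(capped, rng.integers(12, 25, n), 25)
    ids = [f"{profile.community}-{i + 1:05d}" for i in range(n)]
    cohort = pd.DataFrame(
        {
            "participant_id": ids,
            "age_years": age,
            "sex": rng.choice(
                ["female", "male"], size=n,
                p=[profile.female_fraction, 1 - profile.female_fraction],
            ),
            "handedness": rng.choice(
                ["right", "left"], size=n,
                p=[profile.right_handed_fraction,
                   1 - profile.right_handed_fraction],
            ),
            "community": profile.community,
            "pegboard_time_s": peg,
            "pegboard_pegs_placed": pegs_placed,
            "pegboard_pegs_dropped": rng.poisson(0.2, n),
            "updrs3_total": updrs3,
            "updrs3_bradykinesia_nd": brady,
        }
    )
    rows = []
    for task, mv in (("hand_rotation", hr), ("finger_tapping", ft)):
        block = pd.DataFrame(
            {
                "participant_id": ids,
                "hand": "non_dominant",
                "task": task,
                "aggregation": "first_trial",
                "mean_velocity": mv,
            }
        )
        rows.append(block)
    features = pd.concat(rows, ignore_index=True)
    for m in MEASURES[1:]:
        features[m] = np.nan
    features["n_cycles"] = np.nan
    cols = ["participant_id", "hand", "task", "aggregation", *MEASURES, "n_cycles"]
    return cohort, features[cols]


@dataclass
class SignalProfile:
    """Parameters of one synthetic oscillatory trial.

    ``amplitude_deg_s`` is the first-cycle peak angular velocity;
    ``decrement_fraction`` is the per-cycle relative amplitude loss
    (0 = sustained movement, up to 0.1 = severe decrement).  A tremor
    overlay and white sensor noise are optional.  Defaults approximate a
    briskly performed task (amplitude pi/2 x the community-mean velocity,
    3 Hz tapping / 2 Hz rotation).
    """

    task: str = "finger_tapping"
    hand: str = "non_dominant"
    participant_id: str = "SYN-00001"
    trial_index: int = 1
    amplitude_deg_s: float = 553.0
    frequency_hz: float = 3.0
    decrement_fraction: float = 0.0
    tremor_amplitude_deg_s: float = 0.0
    tremor_frequency_hz: float = 6.0
    noise_sd_deg_s: float = 0.0
    off_axis_noise_sd_deg_s: float = 2.0
    phase_rad: float = 0.0

    def __post_init__(self) -> None:
        if not self.amplitude_deg_s > 0:
            raise ValidationError("amplitude_deg_s must be positive")
        if not self.frequency_hz > 0:
            raise ValidationError("frequency_hz must be positive")
        if not 0.0 <= self.decrement_fraction <= 0.1:
            raise ValidationError("decrement_fraction must be in [0, 0.1]")


def hand_rotation_signal_profile(**kwargs) -> SignalProfile:
    """Hand-rotation defaults: slower, larger-amplitude oscillation."""
    kwargs.setdefault("task", "hand_rotation")
    kwargs.setdefault("amplitude_deg_s", 965.0)
    kwargs.setdefault("frequency_hz", 2.0)
    return SignalProfile(**kwargs)


def profile_for_mean_velocity(
    task: str, mean_velocity: float, duration_s: float = 12.0, **kwargs
) -> SignalProfile:
    """Signal profile whose noiseless mean |v| equals ``mean_velocity``.

    For a pure sinusoid mean |v| = 2A/pi, so A = mean_velocity * pi/2; with
    a per-cycle decrement d over K cycles the time-averaged amplitude is
    A (1 - d (K-1)/2), which the first-cycle amplitude compensates for so
    the realized mean velocity still hits the target.  Lower target
    velocities give lower amplitudes: the knob through which latent
    severity degrades the simulated signal.
    """
    if task == "hand_rotation":
        base = hand_rotation_signal_profile(**kwargs)
    else:
        base = SignalProfile(task=task, **kwargs)
    n_cycles = max(round(base.frequency_hz * duration_s), 1)
    decay_factor = 1.0 - base.decrement_fraction * (n_cycles - 1) / 2.0
    base.amplitude_deg_s = mean_velocity * MV_TO_AMPLITUDE / decay_factor
    return base


def simulate_trial_signal(
    profile: SignalProfile,
    duration_s: float = 12.0,
    sample_rate_hz: float = 64.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> KinematicTrial:
    """Build one six-channel trial from a signal profile.

    The task's movement axis carries ``A_k sin(2 pi f t + phi)`` where the
    amplitude ``A_k = A0 (1 - d k)`` decays with the cycle index
    ``k = floor(f t)``, plus the tremor sinusoid and Gaussian noise.  The
    other channels carry low-amplitude noise.  Deterministic under a seed.
    """
    if duration_s < 1.0:
        raise ValidationError("duration_s must be at least 1 s")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    k = np.floor(profile.frequency_hz * t)
    amp = profile.amplitude_deg_s * np.maximum(
        1.0 - profile.decrement_fraction * k, 0.0
    )
    main = amp * np.sin(2 * np.pi * profile.frequency_hz * t + profile.phase_rad)
    if profile.tremor_amplitude_deg_s > 0:
        main = main + profile.tremor_amplitude_deg_s * np.sin(
            2 * np.pi * profile.tremor_frequency_hz * t
        )
    if profile.noise_sd_deg_s > 0:
        main = main + rng.normal(0.0, profile.noise_sd_deg_s, n)
    channels = {}
    main_axis = TASK_AXIS.get(profile.task, "gyro_x")
    for axis in ("gyro_x", "gyro_y", "gyro_z"):
        if axis == main_axis:
            channels[axis] = main
        else:
            channels[axis] = rng.normal(0.0, profile.off_axis_noise_sd_deg_s, n)
    for axis in ("accel_x", "accel_y", "accel_z"):
        channels[axis] = rng.normal(0.0, 0.02, n)
    return KinematicTrial(
        participant_id=profile.participant_id,
        hand=profile.hand,
        task=profile.task,
        trial_index=profile.trial_index,
        sample_rate_hz=sample_rate_hz,
        **channels,
    )


def simulate_participant_trials(
    participant_id: str,
    hand_rotation_mv: float,
    finger_tapping_mv: float,
    n_trials: int = 1,
    decrement_fraction: float = 0.01,
    noise_sd_deg_s: float = 5.0,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> list[KinematicTrial]:
    """Raw trials for one participant whose extracted mean velocities
    approximate the given targets (closure between cohort-level draws and
    signal-level feature extraction)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    trials = []
    for task, mv in (
        ("hand_rotation", hand_rotation_mv),
        ("finger_tapping", finger_tapping_mv),
    ):
        for idx in range(1, n_trials + 1):
            prof = profile_for_mean_velocity(
                task,
                mv,
                participant_id=participant_id,
                trial_index=idx,
                decrement_fraction=decrement_fraction,
                noise_sd_deg_s=noise_sd_deg_s,
                phase_rad=float(rng.uniform(0, 2 * np.pi)),
            )
            trials.append(simulate_trial_signal(prof, rng=rng))
    return trials


def simulate_two_communities(
    exposed: Optional[CohortProfile] = None,
    non_exposed: Optional[CohortProfile] = None,
    seed: Optional[int] = None,
    model: Optional[ModelCoefficients] = None,
) -> dict[str, tuple[pd.DataFrame, pd.DataFrame]]:
    """Paired higher- and lower-severity cohorts for validation rehearsal.

    Returns ``{"exposed": (cohort, features), "non_exposed": ...}``; the
    two cohorts get independent streams spawned from one seed.
    """
    if exposed is None:
        exposed = exposed_profile()
    if non_exposed is None:
        non_exposed = non_exposed_profile()
    ss = np.random.SeedSequence(seed)
    child_a, child_b = ss.spawn(2)
    return {
        "exposed": simulate_cohort(
            exposed, model=model, rng=np.random.default_rng(child_a)
        ),
        "non_exposed": simulate_cohort(
            non_exposed, model=model, rng=np.random.default_rng(child_b)
        ),
    }
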