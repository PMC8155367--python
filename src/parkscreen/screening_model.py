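"""The fixed-coefficient UPDRS3 prediction equation and screening classifier.

The predicted motor score is a linear function of four objective inputs
taken from the non-dominant hand's first kinematic trial plus age:

    UPDRS3^ = b0 + b1*HRmv + b2*HRmv^2 + b3*FTmv + b4*pegboard_time
              (+ b5*age, with-age variant)

where HRmv and FTmv are the hand-rotation and finger-tapping mean angular
velocities in deg/s and pegboard_time is the grooved-pegboard completion
time in seconds.  The published coefficients ship with the package as
versioned JSON, so a retrained model is a drop-in replacement.  The
quadratic hand-rotation term uses the raw (uncentered) velocity.

A participant screens positive when the predicted score reaches a chosen
cut point (>= convention, matching the dichotomized gold standards
UPDRS3 >= 10 and UPDRS3 >= 15).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional

import json

from .errors import ValidationError
from .kinematic_features import HandTaskFeature
from .pegboard import PegboardResult

VARIANTS = ("with_age", "age_free")

SCREEN_POSITIVE = "screen_positive"
SCREEN_NEGATIVE = "screen_negative"

#: Default screening cut point: with a cut of 9 the published model reached
#: 100% sensitivity for UPDRS3 >= 15 at 67.7% specificity.
DEFAULT_CUT_POINT = 9.0


@dataclass
class ModelCoefficients:
    """Named coefficients of a UPDRS3 prediction equation."""

    variant: str
    intercept: float
    hand_rotation_mv: float
    hand_rotation_mv_squared: float
    finger_tapping_mv: float
    pegboard_time: float
    age: Optional[float] = None
    version: str = ""

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValidationError(f"variant must be one of {VARIANTS}")
        if self.variant == "with_age" and self.age is None:
            raise ValidationError("with_age variant requires an age coefficient")
        if self.variant == "age_free" and self.age is not None:
            raise ValidationError("age_free variant must not carry an age coefficient")

    @classmethod
    def from_dict(cls, payload: dict) -> "ModelCoefficients":
        coef = payload.get("coefficients", {})
        required = (
            "hand_rotation_mv",
            "hand_rotation_mv_squared",
            "finger_tapping_mv",
            "pegboard_time",
        )
        missing = [k for k in required if k not in coef]
        if missing:
            raise ValidationError(f"model JSON missing coefficient(s) {missing}")
        return cls(
            variant=payload["variant"],
            intercept=float(payload["intercept"]),
            hand_rotation_mv=float(coef["hand_rotation_mv"]),
            hand_rotation_mv_squared=float(coef["hand_rotation_mv_squared"]),
            finger_tapping_mv=float(coef["finger_tapping_mv"]),
            pegboard_time=float(coef["pegboard_time"]),
            age=float(coef["age"]) if "age" in coef else None,
            version=str(payload.get("version", "")),
        )

    def to_dict(self) -> dict:
        coef = {
            "hand_rotation_mv": self.hand_rotation_mv,
            "hand_rotation_mv_squared": self.hand_rotation_mv_squared,
            "finger_tapping_mv": self.finger_tapping_mv,
            "pegboard_time": self.pegboard_time,
        }
        if self.age is not None:
            coef["age"] = self.age
        return {
            "variant": self.variant,
            "intercept": self.intercept,
            "coefficients": coef,
            "version": self.version,
        }


def load_published_model(variant: str = "with_age") -> ModelCoefficients:
    """Load the published coefficients shipped with the package."""
    if variant not in VARIANTS:
        raise ValidationError(f"variant must be one of {VARIANTS}")
    payload = json.loads(
        resources.files("parkscreen.data").joinpath(f"{variant}.json").read_text()
    )
    return ModelCoefficients.from_dict(payload)


@dataclass
class Prediction:
    participant_id: str
    predicted_updrs3: float
    hand_rotation_mv: float
    finger_tapping_mv: float
    pegboard_time_s: float
    age_years: Optional[float] = None


def evaluate(
    model: ModelCoefficients,
    hand_rotation_mv: float,
    finger_tapping_mv: float,
    pegboard_time_s: float,
    age_years: Optional[float] = None,
) -> float:
    """Evaluate the linear predictor; raw (unclipped) value."""
    for name, value in (
        ("hand_rotation_mv", hand_rotation_mv),
        ("finger_tapping_mv", finger_tapping_mv),
        ("pegboard_time_s", pegboard_time_s),
    ):
        if value is None or value != value:  # None or NaN
            raise ValidationError(f"missing required predictor: {name}")
    y = (
        model.intercept
        + model.hand_rotation_mv * hand_rotation_mv
        + model.hand_rotation_mv_squared * hand_rotation_mv**2
        + model.finger_tapping_mv * finger_tapping_mv
        + model.pegboard_time * pegboard_time_s
    )
    if model.variant == "with_age":
        if age_years is None or age_years != age_years:
            raise ValidationError("missing required predictor: age_years")
        y += model.age * age_years
    return float(y)


def predict_updrs3(
    hand_rotation: HandTaskFeature,
    finger_tapping: HandTaskFeature,
    pegboard: PegboardResult,
    age_years: Optional[float],
    model: ModelCoefficients,
    clip_at_zero: bool = False,
) -> Prediction:
    """Predict UPDRS3 from extracted features for one participant.

    The published equation is defined on the non-dominant hand's features;
    dominant-hand features are rejected.  The raw prediction may be
    negative for extreme inputs; ``clip_at_zero`` is a presentation option
    only — rank-based validation must use raw values.
    """
    for feat, task in ((hand_rotation, "hand_rotation"), (finger_tapping, "finger_tapping")):
        if feat.task != task:
            raise ValidationError(f"expected a {task} feature, got {feat.task}")
        if feat.hand != "non_dominant":
            raise ValidationError(
                "the prediction equation is defined on non-dominant-hand features; "
                f"got {feat.hand} for {task}"
            )
    if hand_rotation.participant_id != finger_tapping.participant_id:
        raise ValidationError("features belong to different participants")
    y = evaluate(
        model,
        hand_rotation.summary.mean_velocity,
        finger_tapping.summary.mean_velocity,
        pegboard.time_s,
        age_years,
    )
    if clip_at_zero:
        y = max(y, 0.0)
    return Prediction(
        participant_id=hand_rotation.participant_id,
        predicted_updrs3=y,
        hand_rotation_mv=hand_rotation.summary.mean_velocity,
        finger_tapping_mv=finger_tapping.summary.mean_velocity,
        pegboard_time_s=pegboard.time_s,
        age_years=age_years,
    )


def classify(predicted_updrs3: float, cut_point: float = DEFAULT_CUT_POINT) -> str:
    """Screen positive iff the predicted score reaches the cut point."""
    if not cut_point > 0:
        raise ValidationError("cut_point must be positive")
    return SCREEN_POSITIVE if predicted_updrs3 >= cut_point else SCREEN_NEGATIVE


def predict_cohort(cohort, model_inputs, model: ModelCoefficients):
    """Vectorized prediction over a cohort.

    ``cohort`` is a DataFrame with ``participant_id``, ``age_years`` and
    ``pegboard_time_s``; ``model_inputs`` the wide table from
    :func:`parkscreen.kinematic_features.pivot_model_inputs`.  Returns a
    DataFrame with the echoed inputs and ``predicted_updrs3``.
    """
    import pandas as pd

    cohort = cohort.copy()
    cohort["participant_id"] = cohort["participant_id"].astype(str)
    for col in ("pegboard_time_s", "age_years"):
        if col not in cohort.columns:
            raise ValidationError(f"cohort table missing column {col!r}")
    merged = cohort.merge(model_inputs, on="participant_id", how="inner")
    for col in ("hand_rotation_mv", "finger_tapping_mv"):
        if col not in merged.columns:
            raise ValidationError(f"feature table missing model input {col!r}")
    preds = [
        evaluate(
            model,
            row.hand_rotation_mv,
            row.finger_tapping_mv,
            row.pegboard_time_s,
            row.age_years if model.variant == "with_age" else None,
        )
        for row in merged.itertuples()
    ]
    out = merged[
        ["participant_id", "age_years", "pegboard_time_s",
         "hand_rotation_mv", "finger_tapping_mv"]
    ].copy()
    out["predicted_updrs3"] = preds
    return pd.DataFrame(out)
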