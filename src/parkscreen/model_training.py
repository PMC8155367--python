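"""Model-development pipeline: feature screening, nonlinearity diagnostics,
multicollinearity checks, and the final OLS fit.

The development sequence mirrors how the screening equation was built:

1. Spearman rank correlations between each candidate summary measure and
   its matched clinician subscore, kept only when at least weakly
   correlated (|rho| > 0.20 and/or p < 0.05) AND in the clinically
   expected direction (slower movement, longer pegboard time, greater
   decrement => higher motor score).
2. LOWESS smooths of outcome against each retained predictor to flag
   departures from linearity, followed by a formal quadratic-term test
   (keep x^2 iff its coefficient has p < 0.05); in the published model only
   hand rotation retains its square.
3. Variance-inflation-factor check (VIF < 2 for all predictors), with the
   hand-rotation linear/quadratic pair exempt because the two terms are
   inherently correlated.
4. OLS fit of the total motor score on the surviving predictors,
   conventional normal-theory CIs, emitting drop-in model JSON.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import InsufficientDataError, ValidationError
from .screening_model import ModelCoefficients

RHO_THRESHOLD = 0.20
P_THRESHOLD = 0.05
VIF_THRESHOLD = 2.0

#: Expected correlation direction with the motor score, by summary measure.
#: Higher scores mean more parkinsonism: movement gets slower (velocities,
#: cycles/second down), pegboard slower (time, drops up; pegs placed down),
#: decrement steeper (the relative slopes, measured as negative numbers,
#: go further negative) and more variable (coefficient of variation up).
EXPECTED_DIRECTIONS = {
    "pegboard_time": "positive",
    "pegboard_pegs_placed": "negative",
    "pegboard_pegs_dropped": "positive",
    "mean_velocity": "negative",
    "mean_peak_velocity": "negative",
    "cycles_per_second": "negative",
    "decrement_peak_velocity": "negative",
    "decrement_cycles_per_second": "negative",
    "coefficient_of_variation": "positive",
}

#: The model's predictor columns, by variant.
PREDICTORS = {
    "with_age": (
        "hand_rotation_mv", "hand_rotation_mv_squared",
        "finger_tapping_mv", "pegboard_time_s", "age_years",
    ),
    "age_free": (
        "hand_rotation_mv", "hand_rotation_mv_squared",
        "finger_tapping_mv", "pegboard_time_s",
    ),
}

_COEF_FIELD = {
    "hand_rotation_mv": "hand_rotation_mv",
    "hand_rotation_mv_squared": "hand_rotation_mv_squared",
    "finger_tapping_mv": "finger_tapping_mv",
    "pegboard_time_s": "pegboard_time",
    "age_years": "age",
}


def expected_direction(feature_name: str) -> str:
    """Expected sign of the feature's correlation with the motor score.

    Feature names may be prefixed by task/hand (e.g.
    ``hand_rotation_mean_velocity``); the longest matching catalogue entry
    wins.
    """
    matches = [k for k in EXPECTED_DIRECTIONS if feature_name.endswith(k)]
    if not matches:
        raise ValidationError(
            f"feature {feature_name!r} is not in the direction catalogue"
        )
    return EXPECTED_DIRECTIONS[max(matches, key=len)]


@dataclass
class ScreeningResult:
    feature: str
    subscore: str
    spearman_rho: float
    p_value: float
    expected_direction: str
    selected: bool
    n: int
    note: str = ""


def spearman_screen(
    features: pd.DataFrame,
    subscores: pd.DataFrame,
    catalogue: dict[str, str],
    rho_threshold: float = RHO_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
) -> list[ScreeningResult]:
    """Directional Spearman screening of candidate features.

    ``catalogue`` maps a feature column in ``features`` to its matched
    subscore column in ``subscores``; both tables must carry
    ``participant_id``.  A feature is selected iff its rank correlation has
    the expected sign and is at least weakly correlated
    (|rho| > ``rho_threshold``) and/or significant (p < ``p_threshold``).
    Ties get average ranks.  Features with fewer than 3 complete pairs are
    marked unevaluable.
    """
    merged = features.merge(subscores, on="participant_id", how="inner")
    results = []
    for feat, sub in catalogue.items():
        direction = expected_direction(feat)
        pair = merged[[feat, sub]].dropna()
        if len(pair) < 3:
            results.append(ScreeningResult(
                feat, sub, float("nan"), float("nan"), direction, False,
                len(pair), "unevaluable: <3 complete pairs",
            ))
            continue
        rho, p = stats.spearmanr(pair[feat], pair[sub])
        sign_ok = (rho > 0) if direction == "positive" else (rho < 0)
        selected = bool(sign_ok and (abs(rho) > rho_threshold or p < p_threshold))
        results.append(ScreeningResult(
            feat, sub, float(rho), float(p), direction, selected, len(pair)
        ))
    return results


@dataclass
class LowessDiagnostic:
    x: np.ndarray
    smoothed: np.ndarray
    curvature_flag: bool
    max_deviation: float
    residual_sd: float


def lowess_diagnostic(
    x: Sequence[float],
    y: Sequence[float],
    frac: float = 0.8,
    flag_sd_ratio: float = 0.5,
) -> LowessDiagnostic:
    """LOWESS smooth of y on x with a curvature flag.

    The flag is raised when the smooth departs from the best straight line
    by more than ``flag_sd_ratio`` times the linear fit's residual SD,
    prompting a formal quadratic-term test.  Default span 0.8 with tricube
    weights.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 20:
        raise InsufficientDataError("lowess_diagnostic needs at least 20 points")
    if np.ptp(x) == 0:
        raise ValidationError("x is constant; LOWESS is undefined")
    fitted = sm.nonparametric.lowess(y, x, frac=frac, return_sorted=True)
    X = sm.add_constant(x)
    lin = sm.OLS(y, X).fit()
    resid_sd = float(np.sqrt(lin.mse_resid))
    lin_at = lin.params[0] + lin.params[1] * fitted[:, 0]
    max_dev = float(np.max(np.abs(fitted[:, 1] - lin_at)))
    return LowessDiagnostic(
        x=fitted[:, 0],
        smoothed=fitted[:, 1],
        curvature_flag=bool(max_dev > flag_sd_ratio * resid_sd),
        max_deviation=max_dev,
        residual_sd=resid_sd,
    )


def quadratic_term_test(
    x: Sequence[float],
    y: Sequence[float],
    covariates: Optional[pd.DataFrame] = None,
    p_threshold: float = P_THRESHOLD,
) -> tuple[bool, float]:
    """Fit y ~ x + x^2 (+ covariates); keep the square iff p < threshold."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 20:
        raise InsufficientDataError("quadratic_term_test needs at least 20 points")
    cols = {"x": x, "x_squared": x**2}
    if covariates is not None:
        for c in covariates.columns:
            cols[c] = np.asarray(covariates[c], dtype=float)
    X = sm.add_constant(pd.DataFrame(cols))
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValidationError("design matrix is collinearity-degenerate")
    fit = sm.OLS(y, X).fit()
    p = float(fit.pvalues["x_squared"])
    return p < p_threshold, p


@dataclass
class VifResult:
    predictor: str
    vif: float
    exempt: bool
    passed: bool


def vif_check(
    design: pd.DataFrame,
    threshold: float = VIF_THRESHOLD,
    exempt: Sequence[str] = ("hand_rotation_mv", "hand_rotation_mv_squared"),
) -> list[VifResult]:
    """Variance inflation factors with the linear/quadratic exemption.

    ``VIF_j = 1/(1 - R^2_j)`` from regressing predictor j on the others
    (with intercept).  The hand-rotation linear and squared terms are
    exempt from the threshold because they are inherently correlated.
    """
    X = design.to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("design matrix is rank deficient")
    results = []
    for j, name in enumerate(design.columns):
        others = sm.add_constant(np.delete(X, j, axis=1))
        r2 = sm.OLS(X[:, j], others).fit().rsquared
        vif = float(1.0 / (1.0 - r2)) if r2 < 1 else float("inf")
        is_exempt = name in exempt
        results.append(VifResult(name, vif, is_exempt, is_exempt or vif < threshold))
    return results


@dataclass
class FitResult:
    coefficients: ModelCoefficients
    conf_int: dict[str, tuple[float, float]]
    p_values: dict[str, float]
    n: int
    vif: list[VifResult] = field(default_factory=list)
    residual_sd: float = float("nan")


def fit_final_model(
    data: pd.DataFrame,
    variant: str = "with_age",
    outcome: str = "updrs3_total",
    robust: bool = False,
) -> FitResult:
    """OLS fit of the screening equation on a training table.

    ``data`` needs columns ``hand_rotation_mv``, ``finger_tapping_mv``,
    ``pegboard_time_s``, ``age_years`` (with_age only) and the outcome;
    the squared hand-rotation term is built here from the raw velocity.
    Complete cases only.  CIs and p-values use conventional normal-theory
    OLS formulas; ``robust=True`` switches to HC1 sandwich variances.
    """
    if variant not in PREDICTORS:
        raise ValidationError(f"variant must be one of {tuple(PREDICTORS)}")
    df = data.copy()
    df["hand_rotation_mv_squared"] = df["hand_rotation_mv"] ** 2
    cols = list(PREDICTORS[variant])
    missing = [c for c in cols + [outcome] if c not in df.columns]
    if missing:
        raise ValidationError(f"training table missing column(s) {missing}")
    df = df[cols + [outcome]].dropna()
    n = len(df)
    if n < len(cols) + 2:
        raise InsufficientDataError(
            f"need at least {len(cols) + 2} complete cases, got {n}"
        )
    X = sm.add_constant(df[cols])
    fit = sm.OLS(df[outcome], X).fit()
    if robust:
        fit = fit.get_robustcov_results("HC1", use_t=True)
        params = dict(zip(X.columns, fit.params))
        pvals = dict(zip(X.columns, fit.pvalues))
        ci_arr = fit.conf_int()
        ci = {name: (float(ci_arr[i, 0]), float(ci_arr[i, 1]))
              for i, name in enumerate(X.columns)}
        resid_sd = float(np.std(fit.resid, ddof=X.shape[1]))
    else:
        params = fit.params.to_dict()
        pvals = fit.pvalues.to_dict()
        ci_df = fit.conf_int()
        ci = {name: (float(ci_df.loc[name, 0]), float(ci_df.loc[name, 1]))
              for name in X.columns}
        resid_sd = float(np.sqrt(fit.mse_resid))
    coef_kwargs = {_COEF_FIELD[c]: float(params[c]) for c in cols}
    model = ModelCoefficients(
        variant=variant,
        intercept=float(params["const"]),
        version="refit",
        **coef_kwargs,
    )
    return FitResult(
        coefficients=model,
        conf_int={("intercept" if k == "const" else k): v for k, v in ci.items()},
        p_values={("intercept" if k == "const" else k): float(v)
                  for k, v in pvals.items()},
        n=n,
        vif=vif_check(df[cols]),
        residual_sd=resid_sd,
    )
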