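"""ROC/AUC validation of predicted motor scores against clinician ratings.

Validation dichotomizes the clinician-rated UPDRS3 at a gold-standard cut
(>= 10 for screening, >= 15 for functionally impairing parkinsonism) and
sweeps the predicted score as the classifier.  The empirical ROC uses the
>= positivity convention; the AUC is the trapezoidal area, identical to
the Mann-Whitney concordance probability with ties counted 1/2.  The
default AUC confidence interval is DeLong's asymptotic variance (the
conventional choice for a single empirical ROC); a seeded percentile
bootstrap is available as a sensitivity analysis.  Continuous agreement is
Spearman's rho with a Fisher-z interval using the rank-correlation
variance 1.06/(n-3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve as _sk_roc_curve

from .errors import InsufficientDataError, ValidationError


@dataclass
class RocResult:
    """Threshold sweep with per-threshold sensitivity/specificity and AUC."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci_low: Optional[float] = None
    auc_ci_high: Optional[float] = None
    gold_cut: Optional[float] = None
    n_positive: int = 0
    n_negative: int = 0


@dataclass
class AgreementResult:
    spearman_rho: float
    ci_low: float
    ci_high: float
    n: int


def _check_labels(labels: np.ndarray) -> tuple[int, int]:
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if not np.all(np.isin(labels, (0, 1))):
        raise ValidationError("labels must be 0/1")
    if n_pos == 0 or n_neg == 0:
        raise InsufficientDataError(
            "both classes must be present to construct an ROC curve "
            f"(got {n_pos} positives, {n_neg} negatives)"
        )
    return n_pos, n_neg


def roc_curve(
    scores: Sequence[float],
    labels: Sequence[int],
    gold_cut: Optional[float] = None,
) -> RocResult:
    """Empirical ROC over all distinct score thresholds (>= positive).

    AUC is the trapezoidal area under the curve, equal to the probability
    that a randomly chosen positive outscores a randomly chosen negative,
    with ties counted 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos, n_neg = _check_labels(labels)
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    auc = float(roc_auc_score(labels, scores))
    return RocResult(
        thresholds=thr,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        auc=auc,
        gold_cut=gold_cut,
        n_positive=n_pos,
        n_negative=n_neg,
    )


# -- DeLong variance of the empirical AUC ----------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def delong_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong asymptotic variance.

    Uses the structural-components formulation: with midranks T over the
    pooled sample and within each class, the placement values of positives
    and negatives estimate the two conditional concordance probabilities;
    the AUC variance is var(V10)/m + var(V01)/n.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    auc = (np.sum(tz[:m]) / m - (m + 1) / 2.0) / n
    v10 = (tz[:m] - tx) / n          # placement of each positive among negatives
    v01 = 1.0 - (tz[m:] - ty) / m    # placement of each negative among positives
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def auc_ci(
    scores: Sequence[float],
    labels: Sequence[int],
    method: str = "delong",
    alpha: float = 0.05,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """95% (by default) CI for the empirical AUC, truncated to [0, 1].

    ``method="delong"`` uses the asymptotic normal interval with DeLong's
    variance; ``method="bootstrap"`` a seeded stratified percentile
    bootstrap.  A degenerate variance (perfect separation at tiny n)
    yields a clamped interval with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos, n_neg = _check_labels(labels)
    if n_pos < 2 or n_neg < 2:
        warnings.warn(
            "fewer than 2 members in a class; AUC interval is degenerate",
            stacklevel=2,
        )
    if method == "delong":
        auc, var = delong_variance(scores, labels)
        if var <= 0:
            warnings.warn(
                "degenerate DeLong variance (AUC at the boundary); "
                "returning clamped interval",
                stacklevel=2,
            )
            return float(np.clip(auc, 0, 1)), float(np.clip(auc, 0, 1))
        z = stats.norm.ppf(1 - alpha / 2)
        half = z * np.sqrt(var)
        return float(np.clip(auc - half, 0, 1)), float(np.clip(auc + half, 0, 1))
    if method == "bootstrap":
        # stratified percentile bootstrap, vectorized over replicates:
        # AUC_b = (sum of pooled midranks of positives - m(m+1)/2) / (m*n)
        rng = np.random.default_rng(seed)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        bs_pos = rng.choice(pos, size=(n_boot, n_pos), replace=True)
        bs_neg = rng.choice(neg, size=(n_boot, n_neg), replace=True)
        pooled = np.concatenate([bs_pos, bs_neg], axis=1)
        ranks = stats.rankdata(pooled, method="average", axis=1)
        aucs = (
            ranks[:, :n_pos].sum(axis=1) - n_pos * (n_pos + 1) / 2.0
        ) / (n_pos * n_neg)
        lo, hi = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
        return float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1))
    raise ValidationError(f"unknown CI method {method!r}")


def sens_spec_at(
    scores: Sequence[float],
    labels: Sequence[int],
    cut_point: float,
) -> tuple[float, float]:
    """Sensitivity and specificity (percent) at one cut (>= positive)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_labels(labels)
    called_pos = scores >= cut_point
    tp = np.sum(called_pos & (labels == 1))
    fn = np.sum(~called_pos & (labels == 1))
    tn = np.sum(~called_pos & (labels == 0))
    fp = np.sum(called_pos & (labels == 0))
    sensitivity = 100.0 * tp / (tp + fn)
    specificity = 100.0 * tn / (tn + fp)
    return float(sensitivity), float(specificity)


def spearman_agreement(
    predicted: Sequence[float],
    observed: Sequence[float],
    alpha: float = 0.05,
    method: str = "fisher",
    n_boot: int = 2000,
    seed: int = 0,
) -> AgreementResult:
    """Spearman's rho between predicted and observed scores, with CI.

    The default interval applies the Fisher z-transform with the
    rank-correlation variance 1.06/(n-3); ``method="bootstrap"`` resamples
    pairs.  Average ranks for ties.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    n = len(predicted)
    if n < 4:
        raise InsufficientDataError("spearman_agreement needs n >= 4")
    if np.ptp(predicted) == 0 or np.ptp(observed) == 0:
        raise ValidationError("rho is undefined for a constant vector")
    rho, _ = stats.spearmanr(predicted, observed)
    rho = float(rho)
    if method == "fisher":
        z = np.arctanh(np.clip(rho, -1 + 1e-15, 1 - 1e-15))
        se = np.sqrt(1.06 / (n - 3))
        zcrit = stats.norm.ppf(1 - alpha / 2)
        lo, hi = np.tanh(z - zcrit * se), np.tanh(z + zcrit * se)
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        rhos = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            r, _ = stats.spearmanr(predicted[idx], observed[idx])
            rhos[b] = r if r == r else 0.0
        lo, hi = np.quantile(rhos, [alpha / 2, 1 - alpha / 2])
    else:
        raise ValidationError(f"unknown CI method {method!r}")
    return AgreementResult(rho, float(lo), float(hi), n)
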