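"""ROC curves, midrank AUC, DeLong comparison and operating points.

The AUC is the Mann-Whitney estimate: the probability that a random case
scores above a random control, counting ties as one half.  With midrank
tie handling the trapezoidal area under the empirical ROC curve equals
this estimate exactly, which the test suite asserts to 1e-12.  Paired
model comparison uses DeLong's structural-component estimator of the
covariance of the two AUCs and a two-sided normal z-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

from ._exceptions import ValidationError


@dataclass
class RocCurve:
    """Empirical ROC curve and its Mann-Whitney AUC."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_case: int
    n_control: int
    degenerate: bool = False

    def trapezoid_area(self) -> float:
        return float(np.trapezoid(self.tpr, self.fpr))


@dataclass
class RocComparison:
    """Paired DeLong comparison of two models scored on the same samples."""

    auc_a: float
    auc_b: float
    var_diff: float
    z: float
    p: float


def _split(scores, status):
    scores = np.asarray(scores, dtype=float)
    status = np.asarray(status, dtype=int)
    if scores.shape != status.shape:
        raise ValidationError("scores and status lengths differ")
    if not np.isfinite(scores).all():
        raise ValidationError("scores contain non-finite values")
    cases = scores[status == 1]
    controls = scores[status == 0]
    if cases.size == 0 or controls.size == 0:
        raise ValidationError("need at least one case and one control")
    return cases, controls


def _structural_components(cases, controls):
    """Midrank AUC and DeLong structural components (per case, per control)."""
    m, n = cases.size, controls.size
    all_scores = np.concatenate([cases, controls])
    tz = rankdata(all_scores)
    tx = rankdata(cases)
    ty = rankdata(controls)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v_case = (tz[:m] - tx) / n
    v_ctrl = 1.0 - (tz[m:] - ty) / m
    return float(auc), v_case, v_ctrl


def mann_whitney_auc(scores, status) -> float:
    """AUC as the midrank Mann-Whitney statistic."""
    cases, controls = _split(scores, status)
    return _structural_components(cases, controls)[0]


def roc_auc(scores, status) -> RocCurve:
    """Build the empirical ROC curve over all distinct thresholds.

    A sample is called positive when its score is >= the threshold.
    Constant scores yield the chance diagonal with AUC 0.5, flagged
    degenerate.
    """
    cases, controls = _split(scores, status)
    m, n = cases.size, controls.size
    if np.unique(np.concatenate([cases, controls])).size == 1:
        return RocCurve(
            thresholds=np.array([np.inf, float(cases[0])]),
            fpr=np.array([0.0, 1.0]),
            tpr=np.array([0.0, 1.0]),
            auc=0.5, n_case=m, n_control=n, degenerate=True,
        )
    auc = _structural_components(cases, controls)[0]
    cuts = np.unique(np.concatenate([cases, controls]))[::-1]
    tpr = (cases[None, :] >= cuts[:, None]).mean(axis=1)
    fpr = (controls[None, :] >= cuts[:, None]).mean(axis=1)
    return RocCurve(
        thresholds=np.concatenate([[np.inf], cuts]),
        fpr=np.concatenate([[0.0], fpr]),
        tpr=np.concatenate([[0.0], tpr]),
        auc=auc, n_case=m, n_control=n,
    )


def auc_variance(scores, status) -> float:
    """DeLong variance of a single AUC."""
    cases, controls = _split(scores, status)
    _, v_case, v_ctrl = _structural_components(cases, controls)
    var = (np.var(v_case, ddof=1) / cases.size
           + np.var(v_ctrl, ddof=1) / controls.size)
    return float(max(var, 0.0))


def auc_ci(scores, status, alpha: float = 0.05) -> tuple:
    """Normal-approximation CI for the AUC from the DeLong variance."""
    auc = mann_whitney_auc(scores, status)
    half = norm.ppf(1 - alpha / 2) * np.sqrt(auc_variance(scores, status))
    return (float(max(0.0, auc - half)), float(min(1.0, auc + half)))


def delong_compare(scores_a, scores_b, status) -> RocComparison:
    """DeLong paired z-test of two AUCs measured on identical samples."""
    scores_a = np.asarray(scores_a, float)
    scores_b = np.asarray(scores_b, float)
    if scores_a.shape != scores_b.shape:
        raise ValidationError("paired score vectors must have equal length")
    status = np.asarray(status, int)
    cases_a, controls_a = _split(scores_a, status)
    cases_b, controls_b = _split(scores_b, status)
    m, n = cases_a.size, controls_a.size
    auc_a, vca, vna = _structural_components(cases_a, controls_a)
    auc_b, vcb, vnb = _structural_components(cases_b, controls_b)
    s_case = np.cov(np.vstack([vca, vcb]), ddof=1)
    s_ctrl = np.cov(np.vstack([vna, vnb]), ddof=1)
    s = s_case / m + s_ctrl / n
    var_diff = float(max(s[0, 0] + s[1, 1] - 2.0 * s[0, 1], 0.0))
    diff = auc_a - auc_b
    if var_diff <= 1e-300:
        z = 0.0 if abs(diff) < 1e-12 else float(np.sign(diff)) * np.inf
    else:
        z = diff / np.sqrt(var_diff)
    return RocComparison(
        auc_a=auc_a, auc_b=auc_b, var_diff=var_diff,
        z=float(z), p=float(2.0 * norm.sf(abs(z))),
    )


def sens_spec_at(
    curve: RocCurve, criterion: str = "youden", threshold: float | None = None
) -> tuple:
    """Operating point of a curve: ``(sensitivity, specificity, threshold)``.

    ``criterion="youden"`` maximises sensitivity + specificity - 1 with
    ties broken toward higher specificity; ``criterion="fixed"`` evaluates
    the point at the given score threshold (positive when score >= t).
    """
    if criterion == "youden":
        j = curve.tpr - curve.fpr
        best = np.flatnonzero(j >= j.max() - 1e-12)
        i = best[np.argmin(curve.fpr[best])]
        return (float(curve.tpr[i]), float(1.0 - curve.fpr[i]),
                float(curve.thresholds[i]))
    if criterion == "fixed":
        if threshold is None:
            raise ValidationError("fixed criterion needs a threshold")
        at_or_above = np.flatnonzero(curve.thresholds >= threshold)
        if at_or_above.size == 0:
            return (1.0, 0.0, float(threshold))
        i = at_or_above[-1]
        return (float(curve.tpr[i]), float(1.0 - curve.fpr[i]),
                float(threshold))
    raise ValidationError(f"unknown criterion {criterion!r}")
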