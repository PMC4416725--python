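"""Age-of-onset analyses among cases.

Kaplan-Meier curves (displayed as cumulative risk, 1 - S), the k-group
log-rank test, Cox proportional-hazards fits with the Efron tie
correction (onset ages cluster on integer years), a one-way ANOVA of
onset age across PRS groups, and the difference in Kaplan-Meier median
onset between two groups.  Every case has an observed onset, so all
observations are events by default, but right-censoring is supported
throughout.  lifelines provides the estimators behind this surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError as LifelinesConvergenceError
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from ._exceptions import (
    MonotoneLikelihoodError,
    ValidationError,
)


@dataclass
class SurvivalData:
    """Onset times (years) with event flags, optional groups and covariates."""

    time: np.ndarray
    event: np.ndarray
    group: Optional[np.ndarray] = None
    covariates: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=bool)
        if self.time.shape != self.event.shape:
            raise ValidationError("time and event lengths differ")
        if not (self.time > 0).all():
            raise ValidationError("onset times must be positive")
        if self.group is not None:
            self.group = np.asarray(self.group)
            if self.group.shape != self.time.shape:
                raise ValidationError("group labels length mismatch")
        if self.covariates is not None and len(self.covariates) != self.time.size:
            raise ValidationError("covariate rows length mismatch")

    @classmethod
    def from_cases(cls, cohort, prs=None, groups=None) -> "SurvivalData":
        """Survival data for the cases of a cohort (all events)."""
        mask = cohort.is_case & np.isfinite(cohort.onset_age)
        if not mask.any():
            raise ValidationError("cohort has no cases with onset age")
        covs = pd.DataFrame({
            "age": cohort.age[mask],
            "sex": cohort.sex[mask],
            "family_history": cohort.family_history[mask],
            "ever_drinker": cohort.ever_drinker[mask],
        })
        if prs is not None:
            covs["prs"] = np.asarray(prs, float)[mask]
        return cls(
            time=cohort.onset_age[mask],
            event=np.ones(int(mask.sum()), dtype=bool),
            group=None if groups is None else np.asarray(groups)[mask],
            covariates=covs.reset_index(drop=True),
        )


@dataclass
class KMCurve:
    """Product-limit survival estimate."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: float

    def cumulative_risk(self) -> np.ndarray:
        return 1.0 - self.survival


def km_fit(data: SurvivalData) -> KMCurve:
    """Kaplan-Meier estimator; the median is the first time S(t) <= 0.5
    (infinity when the curve never reaches it)."""
    if not data.event.any():
        raise ValidationError("Kaplan-Meier needs at least one event")
    fitter = KaplanMeierFitter()
    fitter.fit(data.time, event_observed=data.event)
    table = fitter.event_table
    surv = fitter.survival_function_["KM_estimate"]
    times = surv.index.to_numpy(dtype=float)
    survival = surv.to_numpy(dtype=float)
    at_risk = table["at_risk"].reindex(surv.index).to_numpy(dtype=float)
    below = np.flatnonzero(survival <= 0.5 + 1e-12)
    median = float(times[below[0]]) if below.size else float("inf")
    return KMCurve(times=times, survival=survival, at_risk=at_risk,
                   median=median)


@dataclass
class LogrankResult:
    statistic: float
    df: int
    p: float


def logrank_test(data: SurvivalData, groups=None) -> LogrankResult:
    """Mantel-Haenszel log-rank chi-square across k groups (k-1 df)."""
    labels = data.group if groups is None else np.asarray(groups)
    if labels is None:
        raise ValidationError("log-rank test needs group labels")
    unique = pd.unique(labels)
    if unique.size < 2:
        raise ValidationError("log-rank test needs at least two groups")
    result = multivariate_logrank_test(data.time, labels, data.event)
    return LogrankResult(
        statistic=float(result.test_statistic),
        df=int(unique.size - 1),
        p=float(result.p_value),
    )


@dataclass
class CoxFit:
    """Cox proportional-hazards fit (Efron ties by default)."""

    params: pd.Series
    bse: pd.Series
    llf: float
    nobs: int
    ties: str

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.params)

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(2 * stats.norm.sf(np.abs(self.zvalues)),
                         index=self.params.index)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        half = stats.norm.ppf(1 - alpha / 2) * self.bse
        return pd.DataFrame({"low": self.params - half,
                             "high": self.params + half})

    def summary(self) -> str:
        lines = [
            f"Cox proportional hazards ({self.ties} ties)",
            f"  n = {self.nobs}, partial log-likelihood = {self.llf:.4f}",
            f"  {'term':<16}{'coef':>10}{'HR':>9}{'se':>10}{'z':>9}{'p':>12}",
        ]
        for name in self.params.index:
            lines.append(
                f"  {name:<16}{self.params[name]:>10.4f}"
                f"{self.hazard_ratios[name]:>9.4f}{self.bse[name]:>10.4f}"
                f"{self.zvalues[name]:>9.3f}{self.pvalues[name]:>12.3e}"
            )
        return "\n".join(lines)


def cox_fit(data: SurvivalData, terms: list, ties: str = "efron") -> CoxFit:
    """Fit a Cox model on the named covariate columns.

    A constant covariate is rejected up front; a monotone partial
    likelihood (e.g. a perfectly ordered binary covariate) raises
    :class:`MonotoneLikelihoodError`.
    """
    if ties != "efron":
        raise ValidationError("only the Efron tie correction is supported")
    if data.covariates is None:
        raise ValidationError("survival data carries no covariates")
    missing = [t for t in terms if t not in data.covariates.columns]
    if missing:
        raise ValidationError(f"unknown covariate terms: {missing}")
    frame = data.covariates[list(terms)].astype(float)
    keep = np.isfinite(frame.to_numpy()).all(axis=1)
    frame = frame.loc[keep]
    time, event = data.time[keep], data.event[keep]
    for term in terms:
        if np.unique(frame[term].to_numpy()).size < 2:
            raise ValidationError(f"covariate {term!r} has no variation")
    df = frame.reset_index(drop=True).copy()
    df["_time"] = time
    df["_event"] = event
    fitter = CoxPHFitter()
    try:
        # diverging fits are re-diagnosed below; lifelines' convergence
        # warnings would only duplicate that signal
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(df, duration_col="_time", event_col="_event")
    except (LifelinesConvergenceError, np.linalg.LinAlgError) as exc:
        raise MonotoneLikelihoodError(
            f"Cox partial likelihood has no finite maximum: {exc}"
        ) from None
    params = fitter.params_.copy()
    params.index = [str(i) for i in params.index]
    bse = fitter.standard_errors_.copy()
    bse.index = params.index
    if np.abs(params.to_numpy()).max() > 12:
        raise MonotoneLikelihoodError(
            "Cox coefficients diverge; monotone partial likelihood"
        )
    return CoxFit(params=params, bse=bse,
                  llf=float(fitter.log_likelihood_), nobs=len(df), ties="efron")


@dataclass
class AnovaResult:
    f_stat: float
    df_between: int
    df_within: int
    p: float


def onset_anova(onset, groups) -> AnovaResult:
    """One-way ANOVA of onset age across group labels."""
    onset = np.asarray(onset, float)
    labels = np.asarray(groups)
    samples = [onset[labels == g] for g in pd.unique(labels)]
    if len(samples) < 2 or any(s.size < 2 for s in samples):
        raise ValidationError("ANOVA needs >= 2 groups with >= 2 cases each")
    f_stat, p = stats.f_oneway(*samples)
    k, n = len(samples), onset.size
    return AnovaResult(f_stat=float(f_stat), df_between=k - 1,
                       df_within=n - k, p=float(p))


def median_onset_gap(data: SurvivalData, group_a, group_b) -> float:
    """KM median onset of group_b minus that of group_a (years)."""
    if data.group is None:
        raise ValidationError("survival data carries no group labels")
    medians = []
    for label in (group_a, group_b):
        mask = data.group == label
        if not mask.any():
            raise ValidationError(f"group {label!r} is empty")
        curve = km_fit(SurvivalData(time=data.time[mask],
                                    event=data.event[mask]))
        if not np.isfinite(curve.median):
            raise ValidationError(
                f"group {label!r}: survival never reaches 0.5; median undefined"
            )
        medians.append(curve.median)
    return float(medians[1] - medians[0])
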