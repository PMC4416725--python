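"""Polygenic risk scoring, control-quartile risk groups and risk models.

The score of an individual is the weighted sum of risk-allele counts,
``PRS = sum_i ln(OR_i) * g_i``, over the SNPs of the chosen model:

* ``snp``            - the 13 small-effect (non-HLA) variants,
* ``hla``            - the single large-effect HLA variant,
* ``snp-hla``        - all 14 variants,
* ``snp-hla-drink``  - all 14 variants plus ln(OR_drink) for ever-drinkers.

Samples are binned into four risk groups at the quartiles of the control
score distribution (linear-interpolation percentiles; group 0 is
score <= Q1, group 1 is (Q1, Q2], group 2 is (Q2, Q3], group 3 is > Q3),
and group-specific odds ratios are estimated by logistic regression with
age and sex as covariates, group 0 as the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from ._exceptions import DegenerateScoreError, ValidationError
from .data_io import Cohort, WeightPanel
from .logistic import LogisticFit, fit_logistic, lr_test

N_GROUPS = 4


class ScoreModel(str, Enum):
    SNP = "snp"
    HLA = "hla"
    SNP_HLA = "snp-hla"
    SNP_HLA_DRINK = "snp-hla-drink"


@dataclass
class PRSVector:
    """Per-sample scores under one model; dropped samples hold NaN."""

    model: ScoreModel
    scores: np.ndarray
    n_missing_dropped: int
    snp_ids: list[str]

    @property
    def retained(self) -> np.ndarray:
        return np.isfinite(self.scores)


def model_variants(panel: WeightPanel, model: ScoreModel):
    model = ScoreModel(model)
    if model is ScoreModel.SNP:
        return panel.non_hla_variants
    if model is ScoreModel.HLA:
        return panel.hla_variants
    return list(panel.variants)


def compute_prs(
    cohort: Cohort,
    panel: WeightPanel,
    model: ScoreModel = ScoreModel.SNP_HLA,
    missing_policy: str = "drop",
) -> PRSVector:
    """Score every sample under ``model``.

    ``missing_policy="drop"`` removes (NaN-scores) any sample missing a
    genotype at a model SNP, mirroring the filtering of incompletely
    genotyped subjects; ``"expected-dosage"`` substitutes twice the control
    risk-allele frequency estimated from the cohort's non-missing controls.
    """
    model = ScoreModel(model)
    variants = model_variants(panel, model)
    if not variants:
        raise ValidationError(f"panel has no variants for model {model.value}")
    if missing_policy not in ("drop", "expected-dosage"):
        raise ValidationError(f"unknown missing policy {missing_policy!r}")
    idx = [cohort.variant_index(v.snp_id) for v in variants]
    weights = np.array([v.weight for v in variants])
    dosage = cohort.dosage[:, idx]
    missing = ~np.isfinite(dosage)
    if missing_policy == "expected-dosage":
        controls = dosage[cohort.is_control]
        with np.errstate(invalid="ignore"):
            mean_ctrl = np.nanmean(controls, axis=0)
        if np.isnan(mean_ctrl).any():
            raise ValidationError(
                "cannot impute: a model SNP has no called control genotypes"
            )
        dosage = np.where(missing, mean_ctrl, dosage)
        dropped_rows = np.zeros(cohort.n_samples, dtype=bool)
    else:
        dropped_rows = missing.any(axis=1)
    scores = np.where(dropped_rows, np.nan, np.nan_to_num(dosage) @ weights)

    if model is ScoreModel.SNP_HLA_DRINK:
        if panel.environment_weight is None:
            raise ValidationError(
                "snp-hla-drink model requires an environment weight in the panel"
            )
        drink = cohort.ever_drinker
        no_drink = ~np.isfinite(drink)
        dropped_rows = dropped_rows | no_drink
        scores = np.where(
            no_drink, np.nan,
            scores + panel.environment_weight * np.nan_to_num(drink),
        )
    return PRSVector(
        model=model,
        scores=scores,
        n_missing_dropped=int(dropped_rows.sum()),
        snp_ids=[v.snp_id for v in variants],
    )


@dataclass
class RiskGroupTable:
    """Control-quartile risk groups with case/control counts and group ORs.

    ``groups`` holds 0-3 per sample (-1 for samples without a score);
    the OR fields are populated by :func:`group_or_table` (reference group
    OR fixed at 1).
    """

    cutpoints: tuple
    groups: np.ndarray
    case_counts: np.ndarray
    control_counts: np.ndarray
    ors: Optional[np.ndarray] = None
    ci_low: Optional[np.ndarray] = None
    ci_high: Optional[np.ndarray] = None
    pvalues: Optional[np.ndarray] = None
    fit: Optional[LogisticFit] = None
    undefined_groups: list = field(default_factory=list)

    def crude_ors(self) -> np.ndarray:
        """Unadjusted ORs from the count table, group 0 as reference."""
        a0, b0 = self.case_counts[0], self.control_counts[0]
        with np.errstate(divide="ignore", invalid="ignore"):
            ors = (self.case_counts * b0) / (self.control_counts * a0)
        ors[0] = 1.0
        return ors

    def case_fractions(self) -> np.ndarray:
        """Share of all cases falling in each group."""
        return self.case_counts / self.case_counts.sum()

    def to_frame(self) -> pd.DataFrame:
        q1, q2, q3 = self.cutpoints
        labels = [f"<= {q1:.3g}", f"({q1:.3g}, {q2:.3g}]",
                  f"({q2:.3g}, {q3:.3g}]", f"> {q3:.3g}"]
        data = {
            "group": np.arange(N_GROUPS),
            "prs_range": labels,
            "n_case": self.case_counts,
            "n_control": self.control_counts,
            "crude_or": self.crude_ors(),
        }
        if self.ors is not None:
            data.update(
                {"or": self.ors, "ci_low": self.ci_low,
                 "ci_high": self.ci_high, "p": self.pvalues}
            )
        return pd.DataFrame(data)


def quartile_groups(prs: PRSVector, control_mask) -> RiskGroupTable:
    """Bin samples at the control-score quartiles (counts only)."""
    control_mask = np.asarray(control_mask, dtype=bool)
    scores = prs.scores
    ctrl_scores = scores[control_mask & np.isfinite(scores)]
    if ctrl_scores.size < N_GROUPS:
        raise ValidationError("need at least 4 scored controls for quartiles")
    q1, q2, q3 = np.percentile(ctrl_scores, [25, 50, 75])
    if q1 == q3:
        raise DegenerateScoreError(
            "control scores are (nearly) constant; quartile groups undefined"
        )
    with np.errstate(invalid="ignore"):
        groups = (
            (scores > q1).astype(int) + (scores > q2) + (scores > q3)
        )
    groups = np.where(np.isfinite(scores), groups, -1)
    case_counts = np.bincount(groups[(groups >= 0) & ~control_mask],
                              minlength=N_GROUPS)
    control_counts = np.bincount(groups[(groups >= 0) & control_mask],
                                 minlength=N_GROUPS)
    return RiskGroupTable(
        cutpoints=(float(q1), float(q2), float(q3)),
        groups=groups,
        case_counts=case_counts,
        control_counts=control_counts,
    )


def _covariate_frame(age, sex) -> pd.DataFrame:
    return pd.DataFrame({"age": np.asarray(age, float),
                         "sex": np.asarray(sex, float)})


def group_or_table(
    table: RiskGroupTable, status, age=None, sex=None
) -> RiskGroupTable:
    """Complete a risk-group table with covariate-adjusted group ORs.

    One logistic fit of status on indicators for groups 1-3 (group 0 is the
    reference) plus any provided covariates; Wald 95% CIs.  An empty group
    is flagged and its OR reported as NaN.
    """
    status = np.asarray(status, float)
    groups = table.groups
    mask = groups >= 0
    columns: dict[str, np.ndarray] = {}
    present: list[int] = []
    for g in range(1, N_GROUPS):
        indicator = (groups == g).astype(float)
        if table.case_counts[g] + table.control_counts[g] == 0:
            table.undefined_groups.append(g)
            continue
        present.append(g)
        columns[f"group{g}"] = indicator
    if age is not None:
        covs = _covariate_frame(age, sex)
        mask = mask & np.isfinite(covs.age.values) & np.isfinite(covs.sex.values)
        columns["age"] = covs.age.values
        columns["sex"] = covs.sex.values
    design = pd.DataFrame({k: v[mask] for k, v in columns.items()})
    fit = fit_logistic(status[mask], design)

    ors = np.full(N_GROUPS, np.nan)
    ci_low = np.full(N_GROUPS, np.nan)
    ci_high = np.full(N_GROUPS, np.nan)
    pvals = np.full(N_GROUPS, np.nan)
    ors[0], ci_low[0], ci_high[0] = 1.0, 1.0, 1.0
    or_table = fit.odds_ratios()
    for g in present:
        row = or_table.loc[f"group{g}"]
        ors[g], ci_low[g], ci_high[g] = row["or"], row["ci_low"], row["ci_high"]
        pvals[g] = row["p"]
    table.ors, table.ci_low, table.ci_high = ors, ci_low, ci_high
    table.pvalues = pvals
    table.fit = fit
    return table


def continuous_prs_effect(prs: PRSVector, status, age=None, sex=None) -> LogisticFit:
    """Logistic fit of disease status on the continuous PRS (+ age, sex)."""
    status = np.asarray(status, float)
    mask = np.isfinite(prs.scores)
    columns = {"prs": prs.scores}
    if age is not None:
        covs = _covariate_frame(age, sex)
        mask &= np.isfinite(covs.age.values) & np.isfinite(covs.sex.values)
        columns.update({"age": covs.age.values, "sex": covs.sex.values})
    design = pd.DataFrame({k: np.asarray(v, float)[mask]
                           for k, v in columns.items()})
    return fit_logistic(status[mask], design)


def nagelkerke_r2(fit: LogisticFit) -> float:
    """Nagelkerke pseudo-R^2: Cox-Snell rescaled by its attainable maximum."""
    n = fit.nobs
    cox_snell = 1.0 - np.exp(2.0 * (fit.llnull - fit.llf) / n)
    max_cs = 1.0 - np.exp(2.0 * fit.llnull / n)
    return float(cox_snell / max_cs)


@dataclass
class InteractionResult:
    """PRS-group x exposure interaction, tested by likelihood ratio."""

    fit_full: LogisticFit
    fit_reduced: LogisticFit
    lr_stat: float
    df: int
    p_interaction: float
    empty_cells: list


def interaction_test(
    groups, exposure, status, age=None, sex=None
) -> InteractionResult:
    """Joint LRT of all group x exposure product terms.

    Empty cells of the group-by-exposure cross-table are flagged but the
    test is still attempted.
    """
    groups = np.asarray(groups, int)
    exposure = np.asarray(exposure, float)
    status = np.asarray(status, float)
    mask = (groups >= 0) & np.isfinite(exposure)
    if age is not None:
        covs = _covariate_frame(age, sex)
        mask &= np.isfinite(covs.age.values) & np.isfinite(covs.sex.values)
    g, e, y = groups[mask], exposure[mask], status[mask]
    if np.unique(e).size < 2:
        raise ValidationError("exposure is constant; interaction undefined")
    empty = [
        (int(gg), int(ee))
        for gg in range(N_GROUPS) for ee in (0, 1)
        if not ((g == gg) & (e == ee)).any()
    ]
    base: dict[str, np.ndarray] = {}
    products: dict[str, np.ndarray] = {}
    for level in range(1, N_GROUPS):
        indicator = (g == level).astype(float)
        if indicator.any():
            base[f"group{level}"] = indicator
            product = indicator * e
            # constant or indicator-collinear products (empty cells) are
            # dropped so the LRT can still be attempted
            if np.unique(product).size > 1 and not np.array_equal(product, indicator):
                products[f"group{level}:drink"] = product
    base["drink"] = e
    if age is not None:
        base["age"] = covs.age.values[mask]
        base["sex"] = covs.sex.values[mask]
    reduced = fit_logistic(y, pd.DataFrame(base))
    full = fit_logistic(y, pd.DataFrame({**base, **products}))
    stat, df, p = lr_test(full, reduced)
    return InteractionResult(fit_full=full, fit_reduced=reduced, lr_stat=stat,
                             df=df, p_interaction=p, empty_cells=empty)


@dataclass
class FamilyHistoryResult:
    """Association of PRS with positive family history among cases."""

    fit: LogisticFit
    mean_fh_pos: float
    mean_fh_neg: float
    sd_fh_pos: float
    sd_fh_neg: float
    t_stat: float
    t_p: float


def family_history_association(scores, family_history) -> FamilyHistoryResult:
    """Logistic fit of family history on PRS plus a Welch mean comparison.

    Intended for cases only (controls are screened negative, so including
    them would be circular).
    """
    scores = np.asarray(scores, float)
    fh = np.asarray(family_history, float)
    mask = np.isfinite(scores) & np.isfinite(fh)
    scores, fh = scores[mask], fh[mask]
    if np.unique(fh).size < 2:
        raise ValidationError("family history has a single class")
    fit = fit_logistic(fh, {"prs": scores})
    pos, neg = scores[fh == 1], scores[fh == 0]
    t_stat, t_p = stats.ttest_ind(pos, neg, equal_var=False)
    return FamilyHistoryResult(
        fit=fit,
        mean_fh_pos=float(pos.mean()), mean_fh_neg=float(neg.mean()),
        sd_fh_pos=float(pos.std(ddof=1)) if pos.size > 1 else float("nan"),
        sd_fh_neg=float(neg.std(ddof=1)) if neg.size > 1 else float("nan"),
        t_stat=float(t_stat), t_p=float(t_p),
    )
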