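"""Genotype quality control and single-variant association statistics.

QC applies, in order: per-sample call rate, per-SNP call rate, and an exact
Hardy-Weinberg test among controls.  The defaults keep samples and SNPs
with call rate > 90% and SNPs with control HWE p > 1e-3.  Association uses
the 1-df Pearson chi-square on the 2x2 allele-count table (no continuity
correction, matching PLINK's allelic test) with a Woolf-interval odds
ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import chi2 as chi2_dist
from scipy.stats import ncx2

from ._exceptions import EmptyCohortError, ValidationError
from .data_io import Cohort, WeightPanel
from .simulate import case_allele_freq

logger = logging.getLogger("psorprs")


@dataclass
class DroppedEntity:
    entity_id: str
    reason: str
    value: float


@dataclass
class QCReport:
    dropped_samples: list = field(default_factory=list)
    dropped_snps: list = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)
    n_samples_before: int = 0
    n_samples_after: int = 0
    n_snps_before: int = 0
    n_snps_after: int = 0

    def to_dict(self) -> dict:
        return {
            "thresholds": dict(self.thresholds),
            "n_samples_before": self.n_samples_before,
            "n_samples_after": self.n_samples_after,
            "n_snps_before": self.n_snps_before,
            "n_snps_after": self.n_snps_after,
            "dropped_samples": [
                {"id": d.entity_id, "reason": d.reason, "value": d.value}
                for d in self.dropped_samples
            ],
            "dropped_snps": [
                {"id": d.entity_id, "reason": d.reason, "value": d.value}
                for d in self.dropped_snps
            ],
        }


def apply_qc(
    cohort: Cohort,
    sample_cr: float = 0.9,
    snp_cr: float = 0.9,
    hwe_alpha: float = 1e-3,
) -> tuple[Cohort, QCReport]:
    """Filter a cohort; returns the surviving cohort and a report.

    Filter order is samples -> SNPs -> control HWE.  Thresholds are strict:
    an entity at exactly the call-rate threshold is dropped (the inclusion
    criterion is call rate *greater than* the threshold), and a SNP with
    control HWE p exactly at ``hwe_alpha`` is dropped.
    """
    if not cohort.is_control.any():
        raise ValidationError("QC needs at least one control (HWE filter)")
    report = QCReport(
        thresholds={"sample_cr": sample_cr, "snp_cr": snp_cr,
                    "hwe_alpha": hwe_alpha},
        n_samples_before=cohort.n_samples,
        n_snps_before=cohort.n_variants,
    )
    called = np.isfinite(cohort.dosage)

    sample_rate = called.mean(axis=1)
    keep_samples = sample_rate > sample_cr
    for i in np.flatnonzero(~keep_samples):
        entry = DroppedEntity(cohort.samples[i].sample_id, "sample_call_rate",
                              float(sample_rate[i]))
        report.dropped_samples.append(entry)
        logger.info("QC drop sample %s: call rate %.4f", entry.entity_id,
                    entry.value)
    if not keep_samples.any():
        raise EmptyCohortError("all samples fail the call-rate filter")
    cohort = cohort.subset(sample_mask=keep_samples)
    called = called[keep_samples]

    snp_rate = called.mean(axis=0)
    keep_snps = snp_rate > snp_cr
    for j in np.flatnonzero(~keep_snps):
        entry = DroppedEntity(cohort.variant_ids[j], "snp_call_rate",
                              float(snp_rate[j]))
        report.dropped_snps.append(entry)
        logger.info("QC drop SNP %s: call rate %.4f", entry.entity_id,
                    entry.value)
    cohort = cohort.subset(variant_mask=keep_snps)

    controls = cohort.dosage[cohort.is_control]
    keep_hwe = np.ones(cohort.n_variants, dtype=bool)
    for j, snp_id in enumerate(cohort.variant_ids):
        column = controls[:, j]
        column = column[np.isfinite(column)]
        if column.size == 0:
            keep_hwe[j] = False
            report.dropped_snps.append(
                DroppedEntity(snp_id, "no_control_genotypes", 0.0))
            continue
        p_hwe = hwe_exact_p(int((column == 2).sum()), int((column == 1).sum()),
                            int((column == 0).sum()))
        if not p_hwe > hwe_alpha:
            keep_hwe[j] = False
            report.dropped_snps.append(
                DroppedEntity(snp_id, "hwe_controls", float(p_hwe)))
            logger.info("QC drop SNP %s: control HWE p=%.3g", snp_id, p_hwe)
    cohort = cohort.subset(variant_mask=keep_hwe)

    report.n_samples_after = cohort.n_samples
    report.n_snps_after = cohort.n_variants
    return cohort, report


def hwe_exact_p(n_rr: int, n_rh: int, n_oo: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count no more probable than the observed one (the
    conventional "no more probable" definition, not mid-p).
    """
    counts = (n_rr, n_rh, n_oo)
    if any(c < 0 or c != int(c) for c in counts):
        raise ValidationError("genotype counts must be nonnegative integers")
    n = sum(counts)
    if n == 0:
        raise ValidationError("all genotype counts are zero")
    n_a = 2 * n_rr + n_rh
    n_b = 2 * n_oo + n_rh
    rare = min(n_a, n_b)
    hets = np.arange(rare % 2, rare + 1, 2)
    log_probs = (
        -gammaln((n_a - hets) / 2 + 1)
        - gammaln(hets + 1)
        - gammaln((n_b - hets) / 2 + 1)
        + hets * np.log(2.0)
    )
    log_probs -= logsumexp(log_probs)
    probs = np.exp(log_probs)
    p_obs = probs[hets == n_rh][0]
    return float(min(1.0, probs[probs <= p_obs * (1.0 + 1e-9)].sum()))


@dataclass
class AssocResult:
    """Allelic 2x2 association result for one SNP."""

    snp_id: str
    case_risk: int
    case_other: int
    ctrl_risk: int
    ctrl_other: int
    chi2: float
    p: float
    odds_ratio: float
    ci95: tuple
    haldane: bool = False

    def to_dict(self) -> dict:
        return {
            "snp_id": self.snp_id,
            "case_risk": self.case_risk, "case_other": self.case_other,
            "ctrl_risk": self.ctrl_risk, "ctrl_other": self.ctrl_other,
            "chi2": self.chi2, "p": self.p, "or": self.odds_ratio,
            "ci95_low": self.ci95[0], "ci95_high": self.ci95[1],
            "haldane": self.haldane,
        }


def allelic_chi2(
    case_risk: int, case_other: int, ctrl_risk: int, ctrl_other: int,
    snp_id: str = "",
) -> AssocResult:
    """Pearson chi-square (1 df, no continuity correction) on allele counts.

    The odds ratio is ad/bc with a Woolf 95% CI; a zero cell triggers the
    Haldane-Anscombe 0.5 correction for the OR and CI only (flagged).
    """
    a, b, c, d = case_risk, case_other, ctrl_risk, ctrl_other
    if min(a, b, c, d) < 0:
        raise ValidationError("allele counts must be nonnegative")
    if (a + b) <= 0 or (c + d) <= 0 or (a + c) <= 0 or (b + d) <= 0:
        raise ValidationError("every margin of the 2x2 table must be positive")
    n = a + b + c + d
    stat = (n * (a * d - b * c) ** 2
            / ((a + b) * (c + d) * (a + c) * (b + d)))
    p = float(chi2_dist.sf(stat, 1))
    haldane = min(a, b, c, d) == 0
    if haldane:
        a2, b2, c2, d2 = (x + 0.5 for x in (a, b, c, d))
    else:
        a2, b2, c2, d2 = a, b, c, d
    or_ = (a2 * d2) / (b2 * c2)
    se = np.sqrt(1 / a2 + 1 / b2 + 1 / c2 + 1 / d2)
    ci = (float(or_ * np.exp(-1.959963984540054 * se)),
          float(or_ * np.exp(1.959963984540054 * se)))
    return AssocResult(snp_id=snp_id, case_risk=a, case_other=b,
                       ctrl_risk=c, ctrl_other=d, chi2=float(stat), p=p,
                       odds_ratio=float(or_), ci95=ci, haldane=haldane)


def allele_counts(cohort: Cohort) -> pd.DataFrame:
    """Risk/other allele counts by status, from non-missing genotypes."""
    rows = []
    for j, snp_id in enumerate(cohort.variant_ids):
        column = cohort.dosage[:, j]
        for label, mask in (("case", cohort.is_case),
                            ("ctrl", cohort.is_control)):
            values = column[mask]
            values = values[np.isfinite(values)]
            risk = int(values.sum())
            rows.append({"snp_id": snp_id, "group": label, "risk": risk,
                         "other": int(2 * values.size - risk)})
    return pd.DataFrame(rows)


def assoc_table(cohort: Cohort) -> list[AssocResult]:
    """Per-SNP allelic chi-square association across the cohort."""
    counts = allele_counts(cohort)
    results = []
    for snp_id in cohort.variant_ids:
        case = counts[(counts.snp_id == snp_id) & (counts.group == "case")]
        ctrl = counts[(counts.snp_id == snp_id) & (counts.group == "ctrl")]
        results.append(
            allelic_chi2(int(case.risk.iloc[0]), int(case.other.iloc[0]),
                         int(ctrl.risk.iloc[0]), int(ctrl.other.iloc[0]),
                         snp_id=snp_id)
        )
    return results


def allelic_test_power(
    freq_ctrl: float, odds_ratio: float, n_case: int, n_ctrl: int,
    alpha: float = 0.05,
) -> float:
    """Power of the 1-df allelic chi-square test.

    Uses the noncentral chi-square approximation with the noncentrality
    implied by the case/control allele-frequency difference under the
    retrospective-sampling closed form.
    """
    if not 0.0 < freq_ctrl < 1.0:
        raise ValidationError("freq_ctrl must lie in (0, 1)")
    if odds_ratio <= 0 or not 0 < alpha < 1:
        raise ValidationError("bad odds_ratio or alpha")
    p1 = case_allele_freq(freq_ctrl, odds_ratio)
    p0 = freq_ctrl
    m, k = 2 * n_case, 2 * n_ctrl
    variance = p1 * (1 - p1) / m + p0 * (1 - p0) / k
    ncp = (p1 - p0) ** 2 / variance
    crit = chi2_dist.ppf(1 - alpha, 1)
    return float(ncx2.sf(crit, 1, ncp)) if ncp > 0 else float(alpha)
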