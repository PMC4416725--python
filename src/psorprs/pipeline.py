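"""End-to-end orchestration of the full risk-score analysis.

Stages, in order: genotype QC -> per-SNP allelic association -> PRS under
each requested model -> control-quartile risk groups with adjusted ORs ->
ROC / AUC and pairwise DeLong comparisons -> age-of-onset analyses among
cases.  The result is an :class:`AnalysisReport` that serialises to both a
machine-readable JSON document (the test surface) and a human-readable
text summary; identical inputs produce byte-identical JSON.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import __version__
from ._exceptions import StageError, ValidationError
from .data_io import Cohort, WeightPanel
from .onset import (
    SurvivalData,
    cox_fit,
    km_fit,
    logrank_test,
    median_onset_gap,
    onset_anova,
)
from .prs import (
    ScoreModel,
    compute_prs,
    continuous_prs_effect,
    family_history_association,
    group_or_table,
    interaction_test,
    nagelkerke_r2,
    quartile_groups,
)
from .qc import apply_qc, assoc_table
from .roc import auc_ci, delong_compare, roc_auc, sens_spec_at

DEFAULT_MODELS = (ScoreModel.SNP, ScoreModel.HLA, ScoreModel.SNP_HLA,
                  ScoreModel.SNP_HLA_DRINK)


def _clean(obj):
    """Make a structure JSON-serialisable; NaN/inf become null."""
    if isinstance(obj, dict):
        return {str(k): _clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_clean(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        value = float(obj)
        return value if math.isfinite(value) else None
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


@dataclass
class AnalysisReport:
    """Aggregated results of every stage, plus provenance."""

    sections: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return _clean(self.sections)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def to_text(self) -> str:
        lines = ["psorprs analysis report", "=" * 60]
        for name, payload in self.sections.items():
            lines.append(f"\n[{name}]")
            lines.append(json.dumps(_clean(payload), indent=2, sort_keys=True))
        return "\n".join(lines)


def cohort_summary(cohort: Cohort) -> dict:
    """Cohort characteristics by status: n, male %, age and onset moments,
    family-history count and percentage."""
    if cohort.n_samples == 0:
        raise ValidationError("empty cohort")

    def moments(values):
        values = values[np.isfinite(values)]
        if values.size == 0:
            return {"n": 0, "mean": None, "sd": None, "min": None, "max": None}
        return {
            "n": int(values.size),
            "mean": float(values.mean()),
            "sd": float(values.std(ddof=1)) if values.size > 1 else None,
            "min": float(values.min()),
            "max": float(values.max()),
        }

    summary = {}
    for label, mask in (("case", cohort.is_case), ("control", cohort.is_control)):
        n = int(mask.sum())
        sex = cohort.sex[mask]
        sex = sex[np.isfinite(sex)]
        entry = {
            "n": n,
            "n_male": int(sex.sum()),
            "male_pct": float(100.0 * sex.mean()) if sex.size else None,
            "age": moments(cohort.age[mask]),
        }
        if label == "case":
            entry["onset_age"] = moments(cohort.onset_age[mask])
            fh = cohort.family_history[mask]
            fh = fh[np.isfinite(fh)]
            entry["family_history_n"] = int(fh.sum())
            entry["family_history_pct"] = (
                float(100.0 * fh.mean()) if fh.size else None
            )
        drink = cohort.ever_drinker[mask]
        drink = drink[np.isfinite(drink)]
        entry["ever_drinker_n"] = int(drink.sum())
        entry["ever_drinker_available"] = int(drink.size)
        summary[label] = entry
    return summary


def _has_drink_data(cohort: Cohort, panel: WeightPanel) -> bool:
    return (panel.environment_weight is not None
            and np.isfinite(cohort.ever_drinker).any())


def run_full_analysis(
    cohort: Cohort,
    panel: WeightPanel,
    models=DEFAULT_MODELS,
    sample_cr: float = 0.9,
    snp_cr: float = 0.9,
    hwe_alpha: float = 1e-3,
    missing_policy: str = "drop",
    group_model: ScoreModel = ScoreModel.SNP_HLA,
    provenance: Optional[dict] = None,
) -> AnalysisReport:
    """Run every stage on a cohort; deterministic given identical inputs.

    Any stage failure raises :class:`StageError` naming the stage, with the
    partially filled report attached.
    """
    report = AnalysisReport()
    report.sections["provenance"] = {
        "package": "psorprs",
        "version": __version__,
        "models": [ScoreModel(m).value for m in models],
        "group_model": ScoreModel(group_model).value,
        "thresholds": {"sample_cr": sample_cr, "snp_cr": snp_cr,
                       "hwe_alpha": hwe_alpha},
        "missing_policy": missing_policy,
        **(provenance or {}),
    }

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - re-raised with context
                raise StageError(name, exc, partial_report=report) from exc
        return wrap

    def _qc():
        filtered, qc_report = apply_qc(cohort, sample_cr, snp_cr, hwe_alpha)
        report.sections["qc"] = qc_report.to_dict()
        return filtered

    clean = stage("qc")(_qc)

    def _summary():
        report.sections["cohort_summary"] = cohort_summary(clean)
    stage("cohort_summary")(_summary)

    def _assoc():
        results = assoc_table(clean)
        report.sections["association"] = [r.to_dict() for r in results]
    stage("association")(_assoc)

    models = [ScoreModel(m) for m in models]
    drink_ok = _has_drink_data(clean, panel)
    if ScoreModel.SNP_HLA_DRINK in models and not drink_ok:
        models = [m for m in models if m is not ScoreModel.SNP_HLA_DRINK]
        report.sections.setdefault("warnings", []).append(
            "snp-hla-drink model skipped: no drinking data or environment weight"
        )

    def _prs():
        vectors = {}
        for model in models:
            vec = compute_prs(clean, panel, model, missing_policy)
            vectors[model] = vec
        report.sections["prs"] = {
            model.value: {
                "n_scored": int(vec.retained.sum()),
                "n_missing_dropped": vec.n_missing_dropped,
                "mean_case": float(np.nanmean(vec.scores[clean.is_case])),
                "mean_control": float(np.nanmean(vec.scores[clean.is_control])),
            }
            for model, vec in vectors.items()
        }
        return vectors
    vectors = stage("prs")(_prs)

    group_model = ScoreModel(group_model)
    if group_model not in vectors:
        raise StageError("risk_groups",
                         ValidationError(f"group model {group_model.value} "
                                         "not among computed models"),
                         partial_report=report)

    def _groups():
        table = quartile_groups(vectors[group_model], clean.is_control)
        table = group_or_table(table, clean.status, clean.age, clean.sex)
        cont = continuous_prs_effect(vectors[group_model], clean.status,
                                     clean.age, clean.sex)
        report.sections["risk_groups"] = {
            "model": group_model.value,
            "cutpoints": list(table.cutpoints),
            "case_counts": table.case_counts.tolist(),
            "control_counts": table.control_counts.tolist(),
            "case_fractions": table.case_fractions().tolist(),
            "crude_ors": table.crude_ors().tolist(),
            "adjusted_ors": table.ors.tolist(),
            "ci_low": table.ci_low.tolist(),
            "ci_high": table.ci_high.tolist(),
            "p": table.pvalues.tolist(),
            "continuous_beta": float(cont.params["prs"]),
            "continuous_se": float(cont.bse["prs"]),
            "continuous_p": float(cont.pvalues["prs"]),
            "nagelkerke_r2": nagelkerke_r2(cont),
        }
        return table
    table = stage("risk_groups")(_groups)

    def _roc():
        section = {"models": {}, "comparisons": []}
        finite = {m: np.isfinite(v.scores) for m, v in vectors.items()}
        for model, vec in vectors.items():
            mask = finite[model]
            curve = roc_auc(vec.scores[mask], clean.status[mask])
            low, high = auc_ci(vec.scores[mask], clean.status[mask])
            entry = {"auc": curve.auc, "ci_low": low, "ci_high": high,
                     "n_case": curve.n_case, "n_control": curve.n_control}
            if model is group_model:
                sens, spec, thr = sens_spec_at(curve, "youden")
                entry.update({"youden_sensitivity": sens,
                              "youden_specificity": spec,
                              "youden_threshold": thr})
            section["models"][model.value] = entry
        for model_a, model_b in itertools.combinations(vectors, 2):
            both = finite[model_a] & finite[model_b]
            cmp_ = delong_compare(vectors[model_a].scores[both],
                                  vectors[model_b].scores[both],
                                  clean.status[both])
            section["comparisons"].append(
                {"model_a": model_a.value, "model_b": model_b.value,
                 "auc_a": cmp_.auc_a, "auc_b": cmp_.auc_b,
                 "z": cmp_.z, "p": cmp_.p}
            )
        report.sections["discrimination"] = section
    stage("roc")(_roc)

    def _family_history():
        cases = clean.is_case
        scores = vectors[group_model].scores
        fh = clean.family_history
        usable = cases & np.isfinite(scores) & np.isfinite(fh)
        if np.unique(fh[usable]).size < 2:
            report.sections["family_history"] = {"skipped": "single class"}
            return
        result = family_history_association(scores[usable], fh[usable])
        report.sections["family_history"] = {
            "mean_prs_fh_pos": result.mean_fh_pos,
            "mean_prs_fh_neg": result.mean_fh_neg,
            "sd_prs_fh_pos": result.sd_fh_pos,
            "sd_prs_fh_neg": result.sd_fh_neg,
            "welch_t": result.t_stat,
            "welch_p": result.t_p,
            "logistic_slope": float(result.fit.params["prs"]),
            "logistic_p": float(result.fit.pvalues["prs"]),
        }
    stage("family_history")(_family_history)

    if drink_ok:
        def _interaction():
            result = interaction_test(table.groups, clean.ever_drinker,
                                      clean.status, clean.age, clean.sex)
            report.sections["interaction"] = {
                "lr_stat": result.lr_stat,
                "df": result.df,
                "p_interaction": result.p_interaction,
                "empty_cells": result.empty_cells,
            }
        stage("interaction")(_interaction)

    def _onset():
        scores = vectors[group_model].scores
        data = SurvivalData.from_cases(clean, prs=scores, groups=table.groups)
        section = {}
        cox_prs = cox_fit(data, ["prs", "age", "sex"])
        section["cox_prs"] = {
            "hr_per_prs_unit": float(cox_prs.hazard_ratios["prs"]),
            "coef": float(cox_prs.params["prs"]),
            "se": float(cox_prs.bse["prs"]),
            "p": float(cox_prs.pvalues["prs"]),
        }
        # recruitment age necessarily exceeds onset age, so adjusting an
        # onset-time model for it can absorb real signal; the sex-only fit
        # is reported alongside
        cox_prs_sex = cox_fit(data, ["prs", "sex"])
        section["cox_prs_sex_only"] = {
            "hr_per_prs_unit": float(cox_prs_sex.hazard_ratios["prs"]),
            "p": float(cox_prs_sex.pvalues["prs"]),
        }
        if np.unique(data.covariates["family_history"].dropna()).size > 1:
            cox_fh = cox_fit(data, ["family_history", "age", "sex"])
            section["cox_family_history"] = {
                "hr": float(cox_fh.hazard_ratios["family_history"]),
                "p": float(cox_fh.pvalues["family_history"]),
            }
        grouped = data.group[data.group >= 0]
        anova = onset_anova(data.time[data.group >= 0], grouped)
        section["onset_anova"] = {
            "f": anova.f_stat, "df_between": anova.df_between,
            "df_within": anova.df_within, "p": anova.p,
        }
        extremes = np.isin(data.group, (0, 3))
        if np.unique(data.group[extremes]).size == 2:
            sub = SurvivalData(time=data.time[extremes],
                               event=data.event[extremes],
                               group=data.group[extremes])
            lr = logrank_test(sub)
            section["logrank_group0_vs_group3"] = {
                "statistic": lr.statistic, "df": lr.df, "p": lr.p,
            }
            section["median_onset_gap_years"] = median_onset_gap(sub, 3, 0)
        section["km_median_by_group"] = {
            str(int(g)): km_fit(SurvivalData(time=data.time[data.group == g],
                                             event=data.event[data.group == g])
                                ).median
            for g in sorted(set(data.group[data.group >= 0]))
        }
        report.sections["onset"] = section
    stage("onset")(_onset)

    return report
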