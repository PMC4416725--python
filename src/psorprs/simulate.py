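"""Synthetic case-control cohort generator.

The generator reproduces the statistical structure the downstream analysis
assumes, so every stage is testable without access to the original
genotypes:

* 14 independent biallelic SNPs in Hardy-Weinberg equilibrium among
  controls; one large-effect HLA-like locus (per-allele OR ~ 8) and 13
  small-effect loci (ORs 1.1-1.6).
* Retrospective (case-control) sampling: the case genotype distribution at
  each SNP is P(g | case) proportional to P(g | control) * OR^g, so the
  marginal per-allele odds ratios are exact by construction and the case
  risk-allele frequency follows the closed form p' = p*OR / (1 - p + p*OR).
* A binary ever-drinking exposure with OR ~ 2.5, independent of genotype
  given status.
* Positive family history among cases following a logistic model in the
  genetic PRS; controls are family-history negative (screened).
* Age of onset for cases from an exponential proportional-hazards model
  with rate (1/scale) * HR^PRS, left-truncated at one year.  Recruitment
  age is lifted to the onset age when the age draw falls below it, so the
  onset <= age invariant always holds and the hazard structure stays
  exactly proportional.

One integer seed drives all randomness through a single
``numpy.random.default_rng`` stream.  Draw order: per SNP (panel order)
control then case dosages; missingness mask; age; sex; drinking; family
history; onset.  Identical seeds therefore give byte-identical fixture
bundles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, replace
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.special import expit, logit
from scipy.stats import truncnorm

from ._exceptions import ValidationError
from .data_io import (
    Cohort,
    SampleRecord,
    VariantWeight,
    WeightPanel,
    write_ped_map,
    write_phenotypes,
    write_weights,
)

# Paper-like defaults: initial-stage sample sizes, one HLA-like locus with a
# large per-allele OR at a plausible control frequency, 13 modest loci, a
# drinking OR of 2.49, onset HR 1.08 per PRS unit, ~31% familial cases.
DEFAULT_CONTROL_FREQS = (
    0.14, 0.22, 0.31, 0.45, 0.28, 0.36, 0.52,
    0.19, 0.41, 0.33, 0.26, 0.48, 0.38, 0.24,
)
DEFAULT_SNP_ORS = (
    8.00, 1.25, 1.18, 1.32, 1.15, 1.42, 1.21,
    1.36, 1.13, 1.28, 1.47, 1.19, 1.55, 1.23,
)
# Synthetic stand-in identifiers; the real panel's published ids and ORs are
# an input the user supplies as a weights TSV.
DEFAULT_SNP_IDS = tuple(f"sim_snp{i + 1:02d}" for i in range(14))

_ALLELE_CYCLE = (("C", "T"), ("A", "G"), ("G", "T"), ("A", "C"))


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults emulate the study conditions."""

    n_cases: int = 3621
    n_controls: int = 3350
    snp_ids: tuple = DEFAULT_SNP_IDS
    control_freqs: tuple = DEFAULT_CONTROL_FREQS
    snp_ors: tuple = DEFAULT_SNP_ORS
    hla_index: int = 0
    drink_or: float = 2.49
    drink_prevalence_controls: float = 0.30
    onset_hr_per_prs_unit: float = 1.08
    baseline_onset_scale: float = 45.0
    family_history_rate: float = 0.3134
    family_history_slope: float = 0.15
    age_mean: float = 30.2
    age_sd: float = 11.5
    age_min: float = 3.0
    age_max: float = 81.0
    male_fraction: float = 0.585
    missing_rate: float = 0.004
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValidationError("n_cases and n_controls must be >= 1")
        n = len(self.snp_ids)
        if not (len(self.control_freqs) == len(self.snp_ors) == n):
            raise ValidationError("snp_ids, control_freqs, snp_ors lengths differ")
        if not all(0.0 < p < 1.0 for p in self.control_freqs):
            raise ValidationError("control frequencies must lie in (0, 1)")
        if not all(r > 0 for r in self.snp_ors):
            raise ValidationError("per-SNP ORs must be positive")
        if not 0 <= self.hla_index < n:
            raise ValidationError("hla_index out of range")
        for name in ("drink_prevalence_controls", "male_fraction",
                     "family_history_rate"):
            value = getattr(self, name)
            if not 0.0 < value < 1.0:
                raise ValidationError(f"{name} must lie in (0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValidationError("missing_rate must lie in [0, 1)")
        if self.drink_or <= 0 or self.onset_hr_per_prs_unit <= 0:
            raise ValidationError("ORs and hazard ratios must be positive")
        if self.baseline_onset_scale <= 0:
            raise ValidationError("baseline_onset_scale must be positive")
        if self.age_sd <= 0 or self.age_min >= self.age_max:
            raise ValidationError("bad age distribution parameters")


def paper_like_config(**overrides) -> SimulationConfig:
    """The default study-scale configuration, with optional field overrides."""
    config = replace(SimulationConfig(), **overrides)
    config.validate()
    return config


def default_panel(config: SimulationConfig) -> WeightPanel:
    """Synthetic stand-in weight panel matching the generator's ORs.

    Alleles are assigned from a fixed cycle; the drinking ln(OR) becomes
    the environment weight.
    """
    variants = []
    for i, (snp_id, or_) in enumerate(zip(config.snp_ids, config.snp_ors)):
        risk, other = _ALLELE_CYCLE[i % len(_ALLELE_CYCLE)]
        variants.append(
            VariantWeight(
                snp_id=snp_id,
                risk_allele=risk,
                other_allele=other,
                odds_ratio=or_,
                is_hla=(i == config.hla_index),
            )
        )
    return WeightPanel(variants=variants,
                       environment_weight=math.log(config.drink_or))


# ---------------------------------------------------------------------------
# closed forms for retrospective sampling
# ---------------------------------------------------------------------------

def hwe_genotype_probs(freq: float) -> np.ndarray:
    """Genotype probabilities (dosage 0, 1, 2) under HWE at risk-allele freq."""
    q = 1.0 - freq
    return np.array([q * q, 2.0 * freq * q, freq * freq])


def case_genotype_probs(freq: float, odds_ratio: float) -> np.ndarray:
    """Case genotype law under retrospective sampling: control law x OR^g."""
    probs = hwe_genotype_probs(freq) * odds_ratio ** np.arange(3)
    return probs / probs.sum()


def case_allele_freq(freq: float, odds_ratio: float) -> float:
    """Risk-allele frequency among cases, p*OR / (1 - p + p*OR)."""
    return freq * odds_ratio / (1.0 - freq + freq * odds_ratio)


def exposed_fraction_cases(prev_controls: float, odds_ratio: float) -> float:
    """Exposure prevalence among cases implied by the control prevalence."""
    odds = prev_controls / (1.0 - prev_controls) * odds_ratio
    return odds / (1.0 + odds)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate_genotypes(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> Cohort:
    """Draw dosages and status; rows are cases first, then controls."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_case, n_ctrl = config.n_cases, config.n_controls
    n = n_case + n_ctrl
    dosage = np.empty((n, len(config.snp_ids)))
    for j, (freq, or_) in enumerate(zip(config.control_freqs, config.snp_ors)):
        dosage[:n_case, j] = rng.choice(3, size=n_case,
                                        p=case_genotype_probs(freq, or_))
        dosage[n_case:, j] = rng.choice(3, size=n_ctrl,
                                        p=hwe_genotype_probs(freq))
    if config.missing_rate > 0:
        dosage[rng.random(dosage.shape) < config.missing_rate] = np.nan
    width = len(str(max(n_case, n_ctrl)))
    samples = [
        SampleRecord(sample_id=f"case{i + 1:0{width}d}", status=1)
        for i in range(n_case)
    ] + [
        SampleRecord(sample_id=f"ctrl{i + 1:0{width}d}", status=0)
        for i in range(n_ctrl)
    ]
    return Cohort(samples=samples, dosage=dosage,
                  variant_ids=list(config.snp_ids))


def _latent_prs(cohort: Cohort, panel: WeightPanel,
                config: SimulationConfig) -> np.ndarray:
    """Genetic PRS with missing dosages replaced by their control expectation."""
    weights = np.array([panel.get(s).weight for s in cohort.variant_ids])
    dosage = cohort.dosage.copy()
    expected = 2.0 * np.asarray(config.control_freqs)
    missing = np.isnan(dosage)
    dosage[missing] = np.broadcast_to(expected, dosage.shape)[missing]
    return dosage @ weights


def simulate_phenotypes(
    cohort: Cohort,
    panel: WeightPanel,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> Cohort:
    """Populate age, sex, drinking, family history and onset on a cohort."""
    config.validate()
    if list(cohort.variant_ids) != list(config.snp_ids) or \
            set(cohort.variant_ids) - set(panel.snp_ids):
        raise ValidationError("cohort/panel/config SNPs do not match")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n = cohort.n_samples
    is_case = cohort.is_case
    prs = _latent_prs(cohort, panel, config)

    a = (config.age_min - config.age_mean) / config.age_sd
    b = (config.age_max - config.age_mean) / config.age_sd
    age = truncnorm.rvs(a, b, loc=config.age_mean, scale=config.age_sd,
                        size=n, random_state=rng)
    sex = (rng.random(n) < config.male_fraction).astype(int)

    prev_case = exposed_fraction_cases(config.drink_prevalence_controls,
                                       config.drink_or)
    prevalence = np.where(is_case, prev_case, config.drink_prevalence_controls)
    drink = (rng.random(n) < prevalence).astype(int)

    case_prs = prs[is_case]
    fh_logit = (logit(config.family_history_rate)
                + config.family_history_slope * (prs - case_prs.mean()))
    family_history = np.where(
        is_case, (rng.random(n) < expit(fh_logit)).astype(int), 0
    )

    rate = (config.onset_hr_per_prs_unit ** prs) / config.baseline_onset_scale
    # exponential left-truncated at 1 year: memorylessness => 1 + Exp(rate)
    onset = 1.0 + rng.exponential(1.0, size=n) / rate
    age = np.where(is_case, np.maximum(age, onset), age)

    samples = []
    for i, old in enumerate(cohort.samples):
        case = bool(is_case[i])
        samples.append(
            SampleRecord(
                sample_id=old.sample_id,
                status=old.status,
                age=float(age[i]),
                sex=int(sex[i]),
                family_history=int(family_history[i]) if case else 0,
                ever_drinker=int(drink[i]),
                onset_age=float(onset[i]) if case else None,
            )
        )
    return Cohort(samples=samples, dosage=cohort.dosage,
                  variant_ids=list(cohort.variant_ids))


def simulate_cohort(config: SimulationConfig) -> tuple[Cohort, WeightPanel]:
    """Full genotype + phenotype simulation from a single seeded stream."""
    rng = np.random.default_rng(config.seed)
    panel = default_panel(config)
    cohort = simulate_genotypes(config, rng)
    cohort = simulate_phenotypes(cohort, panel, config, rng)
    return cohort, panel


def write_fixture_bundle(config: SimulationConfig, out_dir) -> dict:
    """Write ped/map, weights TSV and phenotypes TSV; reproducible from seed."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort, panel = simulate_cohort(config)
    paths = {
        "ped": out_dir / "cohort.ped",
        "map": out_dir / "cohort.map",
        "weights": out_dir / "weights.tsv",
        "phenotypes": out_dir / "phenotypes.tsv",
    }
    write_ped_map(cohort, panel, paths["ped"], paths["map"])
    write_weights(panel, paths["weights"])
    write_phenotypes(cohort.samples, paths["phenotypes"])
    return {k: str(v) for k, v in paths.items()}


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    for key in ("snp_ids", "control_freqs", "snp_ors"):
        d[key] = list(d[key])
    return d


def config_from_dict(data: dict) -> SimulationConfig:
    d = dict(data)
    for key in ("snp_ids", "control_freqs", "snp_ors"):
        if key in d:
            d[key] = tuple(d[key])
    config = SimulationConfig(**d)
    config.validate()
    return config
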