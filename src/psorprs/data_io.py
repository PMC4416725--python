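"""Readers/writers and the in-memory cohort model.

Three plain-text interchange formats are supported:

* PLINK text ``.ped``/``.map`` pairs (whitespace delimited, ``0`` = missing
  allele, phenotype column coded 1=control / 2=case, -9/0 = missing).
* A tab-delimited variant-weights table with header
  ``snp_id  risk_allele  other_allele  or  is_hla``.  Each variant's score
  weight is the natural log of its published per-allele odds ratio.  An
  optional footer row whose ``snp_id`` begins with ``ENV:`` (alleles ``.``)
  supplies the ln(OR) of a binary environmental exposure (ever-drinking);
  it becomes the panel's ``environment_weight``.
* A tab-delimited phenotype table with header ``sample_id  status  age  sex
  family_history  ever_drinker  onset_age`` (``NA`` for missing).

Conventions used throughout the package: status 0=control / 1=case, sex
1=male / 0=female, genotype dosage = count of the risk allele in {0, 1, 2}
with ``NaN`` for missing.  Missing genotypes are retained at read time;
what to do with them is a downstream (QC / scoring) policy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from ._exceptions import AlleleMismatchError, ParseError, ValidationError

logger = logging.getLogger("psorprs")

VALID_ALLELES = frozenset("ACGT")
MISSING_ALLELE = "0"
ENV_PREFIX = "ENV:"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantWeight:
    """One variant's risk allele and published per-allele odds ratio.

    The PRS weight ``w = ln(OR)`` is derived on construction and is not a
    free parameter.
    """

    snp_id: str
    risk_allele: str
    other_allele: str
    odds_ratio: float
    is_hla: bool = False
    weight: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.snp_id:
            raise ValidationError("variant needs a non-empty snp_id")
        for allele in (self.risk_allele, self.other_allele):
            if allele not in VALID_ALLELES:
                raise ValidationError(
                    f"{self.snp_id}: allele {allele!r} not one of A/C/G/T"
                )
        if self.risk_allele == self.other_allele:
            raise ValidationError(f"{self.snp_id}: risk and other allele identical")
        if not (self.odds_ratio > 0 and math.isfinite(self.odds_ratio)):
            raise ValidationError(
                f"{self.snp_id}: odds ratio must be a positive finite number, "
                f"got {self.odds_ratio!r}"
            )
        object.__setattr__(self, "weight", math.log(self.odds_ratio))


@dataclass
class WeightPanel:
    """An ordered panel of weighted variants, optionally with an exposure weight.

    ``environment_weight`` is the ln(OR) applied to a binary ever-drinking
    indicator in the combined genetic+environment score.
    """

    variants: list[VariantWeight]
    environment_weight: Optional[float] = None

    def __post_init__(self) -> None:
        ids = [v.snp_id for v in self.variants]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate snp_id in weight panel: {dupes}")

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def snp_ids(self) -> list[str]:
        return [v.snp_id for v in self.variants]

    @property
    def hla_variants(self) -> list[VariantWeight]:
        return [v for v in self.variants if v.is_hla]

    @property
    def non_hla_variants(self) -> list[VariantWeight]:
        return [v for v in self.variants if not v.is_hla]

    def get(self, snp_id: str) -> VariantWeight:
        for v in self.variants:
            if v.snp_id == snp_id:
                return v
        raise KeyError(snp_id)

    def require_single_hla(self) -> None:
        """Check the 13 + 1 structure of the psoriasis panel."""
        n_hla = len(self.hla_variants)
        if n_hla != 1:
            raise ValidationError(
                f"panel must flag exactly one HLA variant, found {n_hla}"
            )


@dataclass
class SampleRecord:
    """Per-sample phenotype record.

    ``onset_age`` is only defined for cases and never exceeds the recruitment
    age; controls were screened for a negative family history, so a control
    with ``family_history == 1`` is rejected.
    """

    sample_id: str
    status: int
    age: float = float("nan")
    sex: Optional[int] = None
    family_history: Optional[int] = None
    ever_drinker: Optional[int] = None
    onset_age: Optional[float] = None

    def __post_init__(self) -> None:
        if self.status not in (0, 1):
            raise ValidationError(
                f"{self.sample_id}: status must be 0 (control) or 1 (case), "
                f"got {self.status!r}"
            )
        if self.sex is not None and self.sex not in (0, 1):
            raise ValidationError(f"{self.sample_id}: sex must be 0/1")
        for name in ("family_history", "ever_drinker"):
            val = getattr(self, name)
            if val is not None and val not in (0, 1):
                raise ValidationError(f"{self.sample_id}: {name} must be 0/1")
        if self.status == 0 and self.family_history == 1:
            raise ValidationError(
                f"{self.sample_id}: controls are screened family-history negative"
            )
        if self.onset_age is not None:
            if self.status != 1:
                raise ValidationError(
                    f"{self.sample_id}: onset_age defined for a non-case"
                )
            if not self.onset_age > 0:
                raise ValidationError(f"{self.sample_id}: onset_age must be > 0")
            if not math.isnan(self.age) and self.onset_age > self.age + 1e-9:
                raise ValidationError(
                    f"{self.sample_id}: onset_age {self.onset_age} exceeds "
                    f"age {self.age}"
                )


@dataclass
class Cohort:
    """Genotype dosages plus phenotypes for a case-control sample.

    ``dosage`` is a samples x variants float matrix holding the risk-allele
    count (0/1/2) with NaN for missing genotypes; columns follow
    ``variant_ids``.
    """

    samples: list[SampleRecord]
    dosage: np.ndarray
    variant_ids: list[str]

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.variant_ids)):
            raise ValidationError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variant_ids)} variants"
            )
        finite = self.dosage[np.isfinite(self.dosage)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ValidationError("dosages must be in {0, 1, 2} or missing")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate sample_id in cohort")

    # -- convenience accessors ------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    @property
    def status(self) -> np.ndarray:
        return np.array([s.status for s in self.samples], dtype=int)

    @property
    def is_case(self) -> np.ndarray:
        return self.status == 1

    @property
    def is_control(self) -> np.ndarray:
        return self.status == 0

    @property
    def age(self) -> np.ndarray:
        return np.array([s.age for s in self.samples], dtype=float)

    @property
    def sex(self) -> np.ndarray:
        return np.array(
            [np.nan if s.sex is None else float(s.sex) for s in self.samples]
        )

    @property
    def family_history(self) -> np.ndarray:
        return np.array(
            [np.nan if s.family_history is None else float(s.family_history)
             for s in self.samples]
        )

    @property
    def ever_drinker(self) -> np.ndarray:
        return np.array(
            [np.nan if s.ever_drinker is None else float(s.ever_drinker)
             for s in self.samples]
        )

    @property
    def onset_age(self) -> np.ndarray:
        return np.array(
            [np.nan if s.onset_age is None else float(s.onset_age)
             for s in self.samples]
        )

    def variant_index(self, snp_id: str) -> int:
        try:
            return self.variant_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"variant {snp_id!r} not in cohort") from None

    def subset(
        self,
        sample_mask: Optional[np.ndarray] = None,
        variant_mask: Optional[np.ndarray] = None,
    ) -> "Cohort":
        sm = np.ones(self.n_samples, bool) if sample_mask is None else np.asarray(sample_mask, bool)
        vm = np.ones(self.n_variants, bool) if variant_mask is None else np.asarray(variant_mask, bool)
        return Cohort(
            samples=[s for s, keep in zip(self.samples, sm) if keep],
            dosage=self.dosage[np.ix_(sm, vm)],
            variant_ids=[v for v, keep in zip(self.variant_ids, vm) if keep],
        )

    def phenotype_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "status": self.status,
                "age": self.age,
                "sex": self.sex,
                "family_history": self.family_history,
                "ever_drinker": self.ever_drinker,
                "onset_age": self.onset_age,
            }
        )


# ---------------------------------------------------------------------------
# PLINK text genotypes
# ---------------------------------------------------------------------------

def _read_map(map_path: Path) -> list[str]:
    snp_ids: list[str] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) < 2:
                raise ParseError(f"{map_path}:{lineno}: expected >= 2 columns")
            snp_ids.append(tokens[1])
    if len(set(snp_ids)) != len(snp_ids):
        raise ParseError(f"{map_path}: duplicate SNP ids")
    return snp_ids


def read_ped_map(ped_path, map_path, panel: WeightPanel) -> Cohort:
    """Read a PLINK text fileset into a :class:`Cohort`.

    Dosage is the count of the panel's risk allele per genotype; ``0 0``
    allele pairs become missing.  Samples with missing phenotype (-9 or 0 in
    column 6) are dropped with a warning.  Allele symbols that match neither
    the risk nor the other allele of a SNP raise
    :class:`~psorprs._exceptions.AlleleMismatchError`.
    """
    ped_path, map_path = Path(ped_path), Path(map_path)
    snp_ids = _read_map(map_path)
    panel_by_id = {v.snp_id: v for v in panel.variants}
    unknown = [s for s in snp_ids if s not in panel_by_id]
    if unknown:
        raise ValidationError(f"map SNPs not in weight panel: {unknown}")
    variants = [panel_by_id[s] for s in snp_ids]

    samples: list[SampleRecord] = []
    rows: list[np.ndarray] = []
    expected = 6 + 2 * len(snp_ids)
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) != expected:
                raise ParseError(
                    f"{ped_path}:{lineno}: expected {expected} columns, "
                    f"got {len(tokens)}"
                )
            sample_id = tokens[1]
            sex_code, pheno = tokens[4], tokens[5]
            if pheno in ("-9", "0"):
                logger.warning(
                    "dropping sample %s (line %d): missing phenotype",
                    sample_id, lineno,
                )
                continue
            if pheno not in ("1", "2"):
                raise ParseError(
                    f"{ped_path}:{lineno}: unknown phenotype code {pheno!r}"
                )
            status = 1 if pheno == "2" else 0
            sex = {"1": 1, "2": 0}.get(sex_code)
            row = np.empty(len(snp_ids))
            for j, var in enumerate(variants):
                a1, a2 = tokens[6 + 2 * j], tokens[7 + 2 * j]
                if MISSING_ALLELE in (a1, a2):
                    row[j] = np.nan
                    continue
                count = 0
                for allele in (a1, a2):
                    if allele == var.risk_allele:
                        count += 1
                    elif allele != var.other_allele:
                        raise AlleleMismatchError(
                            f"{ped_path}:{lineno}: sample {sample_id}, SNP "
                            f"{var.snp_id}: allele {allele!r} is neither "
                            f"{var.risk_allele} nor {var.other_allele}"
                        )
                row[j] = count
            samples.append(SampleRecord(sample_id=sample_id, status=status, sex=sex))
            rows.append(row)
    dosage = np.vstack(rows) if rows else np.empty((0, len(snp_ids)))
    return Cohort(samples=samples, dosage=dosage, variant_ids=snp_ids)


def write_ped_map(cohort: Cohort, panel: WeightPanel, ped_path, map_path) -> None:
    """Write a cohort back to PLINK text; missing dosage becomes ``0 0``."""
    panel_by_id = {v.snp_id: v for v in panel.variants}
    variants = [panel_by_id[s] for s in cohort.variant_ids]
    with open(map_path, "w") as fh:
        for j, var in enumerate(variants, 1):
            fh.write(f"1\t{var.snp_id}\t0\t{j}\n")
    with open(ped_path, "w") as fh:
        for i, sample in enumerate(cohort.samples):
            sex = {1: "1", 0: "2", None: "0"}[sample.sex]
            pheno = "2" if sample.status == 1 else "1"
            fields = [sample.sample_id, sample.sample_id, "0", "0", sex, pheno]
            for j, var in enumerate(variants):
                g = cohort.dosage[i, j]
                if np.isnan(g):
                    fields += [MISSING_ALLELE, MISSING_ALLELE]
                else:
                    g = int(g)
                    fields += (
                        [var.risk_allele] * g + [var.other_allele] * (2 - g)
                    )
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# weights and phenotypes TSV
# ---------------------------------------------------------------------------

WEIGHT_COLUMNS = ["snp_id", "risk_allele", "other_allele", "or", "is_hla"]

_TRUTHY = {"1", "true", "yes"}
_FALSY = {"0", "false", "no"}


def _parse_bool(value, context: str) -> bool:
    text = str(value).strip().lower()
    if text in _TRUTHY:
        return True
    if text in _FALSY:
        return False
    raise ValidationError(f"{context}: cannot parse boolean {value!r}")


def read_weights(tsv_path) -> WeightPanel:
    """Read a variant-weights TSV into a :class:`WeightPanel`.

    File order is preserved; rows with ``snp_id`` starting ``ENV:`` set the
    panel's environment weight instead of adding a variant.
    """
    tsv_path = Path(tsv_path)
    table = pd.read_csv(tsv_path, sep="\t", dtype=str)
    missing_cols = [c for c in WEIGHT_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ParseError(f"{tsv_path}: missing columns {missing_cols}")
    variants: list[VariantWeight] = []
    environment_weight: Optional[float] = None
    for _, row in table.iterrows():
        snp_id = str(row["snp_id"]).strip()
        try:
            odds_ratio = float(row["or"])
        except (TypeError, ValueError):
            raise ValidationError(f"{tsv_path}: {snp_id}: bad OR {row['or']!r}")
        if snp_id.startswith(ENV_PREFIX):
            if environment_weight is not None:
                raise ValidationError(f"{tsv_path}: multiple ENV rows")
            if not odds_ratio > 0:
                raise ValidationError(f"{tsv_path}: {snp_id}: OR must be > 0")
            environment_weight = math.log(odds_ratio)
            continue
        variants.append(
            VariantWeight(
                snp_id=snp_id,
                risk_allele=str(row["risk_allele"]).strip(),
                other_allele=str(row["other_allele"]).strip(),
                odds_ratio=odds_ratio,
                is_hla=_parse_bool(row["is_hla"], f"{tsv_path}: {snp_id}"),
            )
        )
    return WeightPanel(variants=variants, environment_weight=environment_weight)


def write_weights(panel: WeightPanel, tsv_path) -> None:
    with open(tsv_path, "w") as fh:
        fh.write("\t".join(WEIGHT_COLUMNS) + "\n")
        for v in panel.variants:
            fh.write(
                f"{v.snp_id}\t{v.risk_allele}\t{v.other_allele}\t"
                f"{v.odds_ratio:.6g}\t{int(v.is_hla)}\n"
            )
        if panel.environment_weight is not None:
            fh.write(
                f"{ENV_PREFIX}drinking\t.\t.\t"
                f"{math.exp(panel.environment_weight):.6g}\t0\n"
            )


PHENOTYPE_COLUMNS = [
    "sample_id", "status", "age", "sex",
    "family_history", "ever_drinker", "onset_age",
]


def read_phenotypes(tsv_path) -> list[SampleRecord]:
    """Read a phenotype TSV; every row is validated on construction."""
    tsv_path = Path(tsv_path)
    table = pd.read_csv(tsv_path, sep="\t", na_values=["NA"])
    missing_cols = [c for c in ("sample_id", "status") if c not in table.columns]
    if missing_cols:
        raise ParseError(f"{tsv_path}: missing columns {missing_cols}")

    def opt_int(value):
        return None if pd.isna(value) else int(value)

    def opt_float(value):
        return None if pd.isna(value) else float(value)

    records = []
    for _, row in table.iterrows():
        status = row["status"]
        if pd.isna(status) or int(status) not in (0, 1):
            raise ValidationError(
                f"{tsv_path}: sample {row['sample_id']}: unknown status "
                f"code {status!r}"
            )
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                status=int(status),
                age=float(row.get("age", np.nan)) if not pd.isna(row.get("age")) else float("nan"),
                sex=opt_int(row.get("sex")),
                family_history=opt_int(row.get("family_history")),
                ever_drinker=opt_int(row.get("ever_drinker")),
                onset_age=opt_float(row.get("onset_age")),
            )
        )
    return records


def write_phenotypes(records: Iterable[SampleRecord], tsv_path) -> None:
    def fmt(value, as_int=False):
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return "NA"
        return str(int(value)) if as_int else f"{value:.4f}"

    with open(tsv_path, "w") as fh:
        fh.write("\t".join(PHENOTYPE_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.sample_id,
                        str(r.status),
                        fmt(r.age),
                        fmt(r.sex, as_int=True),
                        fmt(r.family_history, as_int=True),
                        fmt(r.ever_drinker, as_int=True),
                        fmt(r.onset_age),
                    ]
                )
                + "\n"
            )


def attach_phenotypes(cohort: Cohort, records: Sequence[SampleRecord]) -> Cohort:
    """Merge a phenotype table into a genotype-only cohort by sample id.

    The phenotype record wins for every field; a status conflict with the
    PLINK phenotype column is an error.  Cohort samples without a phenotype
    record are dropped with a warning.
    """
    by_id = {r.sample_id: r for r in records}
    keep = np.zeros(cohort.n_samples, dtype=bool)
    merged: list[SampleRecord] = []
    for i, sample in enumerate(cohort.samples):
        rec = by_id.get(sample.sample_id)
        if rec is None:
            logger.warning("dropping sample %s: no phenotype record", sample.sample_id)
            continue
        if rec.status != sample.status:
            raise ValidationError(
                f"{sample.sample_id}: status conflict between genotype "
                f"({sample.status}) and phenotype ({rec.status}) files"
            )
        keep[i] = True
        merged.append(rec)
    if not merged:
        raise ValidationError("no samples left after phenotype merge")
    return Cohort(
        samples=merged,
        dosage=cohort.dosage[keep],
        variant_ids=list(cohort.variant_ids),
    )
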