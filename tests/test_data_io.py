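import math

import numpy as np
import pytest

from psorprs import (
    AlleleMismatchError,
    ParseError,
    SampleRecord,
    ValidationError,
    VariantWeight,
    WeightPanel,
    attach_phenotypes,
    read_ped_map,
    read_phenotypes,
    read_weights,
    write_ped_map,
    write_phenotypes,
    write_weights,
)
from psorprs.simulate import default_panel, paper_like_config, simulate_cohort


@pytest.fixture()
def two_snp_panel():
    return WeightPanel(
        variants=[
            VariantWeight("rs1", "C", "T", 2.0, is_hla=True),
            VariantWeight("rs2", "A", "G", 1.5),
        ]
    )


def write_fixture(tmp_path, ped_lines, map_lines):
    ped = tmp_path / "toy.ped"
    mp = tmp_path / "toy.map"
    ped.write_text("\n".join(ped_lines) + "\n")
    mp.write_text("\n".join(map_lines) + "\n")
    return ped, mp


MAP_LINES = ["1 rs1 0 100", "1 rs2 0 200"]


class TestVariantWeight:
    @pytest.mark.parametrize(
        "odds_ratio, expected",
        [(1.0, 0.0), (math.e, 1.0), (2.0, math.log(2.0))],
    )
    def test_weight_is_log_odds_ratio(self, odds_ratio, expected):
        v = VariantWeight("rs1", "A", "G", odds_ratio)
        assert v.weight == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"odds_ratio": 0.0},
            {"odds_ratio": -1.3},
            {"risk_allele": "A", "other_allele": "A"},
            {"risk_allele": "N"},
        ],
    )
    def test_invalid_variants_rejected(self, kwargs):
        base = dict(snp_id="rs1", risk_allele="A", other_allele="G",
                    odds_ratio=1.5)
        with pytest.raises(ValidationError):
            VariantWeight(**{**base, **kwargs})

    def test_duplicate_snp_ids_rejected(self):
        v = VariantWeight("rs1", "A", "G", 1.5)
        with pytest.raises(ValidationError):
            WeightPanel(variants=[v, v])


class TestPedMap:
    def test_hand_counted_dosages(self, tmp_path, two_snp_panel):
        # three samples, two SNPs; risk alleles C (rs1) and A (rs2)
        ped, mp = write_fixture(
            tmp_path,
            [
                "f1 s1 0 0 1 2 C C A G",
                "f2 s2 0 0 2 1 C T G G",
                "f3 s3 0 0 1 2 T T 0 0",
            ],
            MAP_LINES,
        )
        cohort = read_ped_map(ped, mp, two_snp_panel)
        assert [s.sample_id for s in cohort.samples] == ["s1", "s2", "s3"]
        assert cohort.status.tolist() == [1, 0, 1]
        assert cohort.samples[0].sex == 1 and cohort.samples[1].sex == 0
        expected = np.array([[2, 1], [1, 0], [0, np.nan]])
        np.testing.assert_array_equal(cohort.dosage, expected)

    def test_allele_order_within_genotype_is_irrelevant(self, tmp_path,
                                                        two_snp_panel):
        ped_a, map_a = write_fixture(
            tmp_path, ["f1 s1 0 0 1 2 C T A G"], MAP_LINES)
        cohort_a = read_ped_map(ped_a, map_a, two_snp_panel)
        ped_b = tmp_path / "b.ped"
        ped_b.write_text("f1 s1 0 0 1 2 T C G A\n")
        cohort_b = read_ped_map(ped_b, map_a, two_snp_panel)
        np.testing.assert_array_equal(cohort_a.dosage, cohort_b.dosage)

    def test_missing_phenotype_sample_dropped(self, tmp_path, two_snp_panel):
        ped, mp = write_fixture(
            tmp_path,
            ["f1 s1 0 0 1 -9 C C A G", "f2 s2 0 0 1 2 C C A G"],
            MAP_LINES,
        )
        cohort = read_ped_map(ped, mp, two_snp_panel)
        assert [s.sample_id for s in cohort.samples] == ["s2"]

    def test_malformed_row_names_line(self, tmp_path, two_snp_panel):
        ped, mp = write_fixture(
            tmp_path, ["f1 s1 0 0 1 2 C C A"], MAP_LINES)
        with pytest.raises(ParseError, match="1"):
            read_ped_map(ped, mp, two_snp_panel)

    def test_foreign_allele_names_snp_and_sample(self, tmp_path, two_snp_panel):
        ped, mp = write_fixture(
            tmp_path, ["f1 s1 0 0 1 2 C G A G"], MAP_LINES)
        with pytest.raises(AlleleMismatchError, match="rs1.*s1|s1.*rs1"):
            read_ped_map(ped, mp, two_snp_panel)

    def test_round_trip_preserves_dosage_and_status(self, tmp_path):
        config = paper_like_config(n_cases=40, n_controls=40, seed=5,
                                   missing_rate=0.05)
        cohort, panel = simulate_cohort(config)
        write_ped_map(cohort, panel, tmp_path / "rt.ped", tmp_path / "rt.map")
        back = read_ped_map(tmp_path / "rt.ped", tmp_path / "rt.map", panel)
        np.testing.assert_array_equal(back.dosage, cohort.dosage)
        np.testing.assert_array_equal(back.status, cohort.status)
        assert back.variant_ids == cohort.variant_ids


class TestWeightsIO:
    def test_round_trip_and_env_row(self, tmp_path):
        panel = default_panel(paper_like_config())
        path = tmp_path / "weights.tsv"
        write_weights(panel, path)
        back = read_weights(path)
        assert back.snp_ids == panel.snp_ids
        assert len(back.hla_variants) == 1
        assert back.environment_weight == pytest.approx(
            panel.environment_weight, rel=1e-5)
        for v_in, v_out in zip(panel.variants, back.variants):
            assert v_out.weight == pytest.approx(v_in.weight, rel=1e-5)
            assert v_out.is_hla == v_in.is_hla

    def test_nonpositive_or_rejected(self, tmp_path):
        path = tmp_path / "w.tsv"
        path.write_text(
            "snp_id\trisk_allele\tother_allele\tor\tis_hla\n"
            "rs1\tA\tG\t-2.0\t0\n"
        )
        with pytest.raises(ValidationError):
            read_weights(path)

    def test_duplicate_snp_rejected(self, tmp_path):
        path = tmp_path / "w.tsv"
        path.write_text(
            "snp_id\trisk_allele\tother_allele\tor\tis_hla\n"
            "rs1\tA\tG\t2.0\t0\nrs1\tA\tG\t2.0\t0\n"
        )
        with pytest.raises(ValidationError):
            read_weights(path)


class TestPhenotypes:
    def test_valid_case_record(self):
        r = SampleRecord("s1", status=1, age=30, sex=1, onset_age=21)
        assert r.onset_age == 21

    def test_control_with_onset_rejected(self):
        with pytest.raises(ValidationError):
            SampleRecord("s1", status=0, age=30, sex=0, onset_age=21)

    def test_onset_after_recruitment_age_rejected(self):
        with pytest.raises(ValidationError):
            SampleRecord("s1", status=1, age=20, sex=1, onset_age=25)

    def test_control_with_positive_family_history_rejected(self):
        with pytest.raises(ValidationError):
            SampleRecord("s1", status=0, age=30, sex=0, family_history=1)

    def test_tsv_round_trip(self, tmp_path, small_cohort):
        cohort, _ = small_cohort
        path = tmp_path / "pheno.tsv"
        write_phenotypes(cohort.samples, path)
        back = read_phenotypes(path)
        assert len(back) == cohort.n_samples
        assert [r.status for r in back] == cohort.status.tolist()
        onset_in = cohort.onset_age
        onset_out = np.array([np.nan if r.onset_age is None else r.onset_age
                              for r in back])
        np.testing.assert_allclose(onset_out[np.isfinite(onset_in)],
                                   onset_in[np.isfinite(onset_in)], atol=1e-3)

    def test_unknown_status_code_rejected(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("sample_id\tstatus\tage\ns1\t7\t30\n")
        with pytest.raises(ValidationError):
            read_phenotypes(path)


class TestAttachPhenotypes:
    def test_status_conflict_rejected(self, tmp_path, two_snp_panel):
        ped, mp = write_fixture(
            tmp_path, ["f1 s1 0 0 1 2 C C A G"], MAP_LINES)
        cohort = read_ped_map(ped, mp, two_snp_panel)
        with pytest.raises(ValidationError, match="status conflict"):
            attach_phenotypes(cohort,
                              [SampleRecord("s1", status=0, age=30, sex=1)])

    def test_merges_ages(self, tmp_path, two_snp_panel):
        ped, mp = write_fixture(
            tmp_path, ["f1 s1 0 0 1 2 C C A G"], MAP_LINES)
        cohort = read_ped_map(ped, mp, two_snp_panel)
        merged = attach_phenotypes(
            cohort,
            [SampleRecord("s1", status=1, age=33, sex=1, onset_age=20)])
        assert merged.age.tolist() == [33.0]
        assert merged.onset_age.tolist() == [20.0]
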