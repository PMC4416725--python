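import math

import numpy as np
import pytest

from psorprs import (
    Cohort,
    DegenerateScoreError,
    SampleRecord,
    ValidationError,
    VariantWeight,
    WeightPanel,
    compute_prs,
    continuous_prs_effect,
    family_history_association,
    fit_logistic,
    group_or_table,
    interaction_test,
    quartile_groups,
)
from psorprs.prs import PRSVector, ScoreModel


def panel_of(ors, hla_index=None, env=None):
    alleles = [("C", "T"), ("A", "G")] * (len(ors) // 2 + 1)
    variants = [
        VariantWeight(f"rs{i}", alleles[i][0], alleles[i][1], or_,
                      is_hla=(i == hla_index))
        for i, or_ in enumerate(ors)
    ]
    return WeightPanel(variants=variants, environment_weight=env)


def cohort_of(dosage, status, drink=None):
    dosage = np.asarray(dosage, float)
    samples = []
    for i, s in enumerate(status):
        samples.append(SampleRecord(
            f"s{i}", status=int(s), age=30.0, sex=i % 2,
            ever_drinker=None if drink is None else int(drink[i]),
        ))
    return Cohort(samples=samples, dosage=dosage,
                  variant_ids=[f"rs{j}" for j in range(dosage.shape[1])])


class TestComputePrs:
    def test_hand_arithmetic(self):
        panel = panel_of([2.0, 3.0])
        cohort = cohort_of([[1, 2]], [1])
        vec = compute_prs(cohort, panel, ScoreModel.SNP_HLA)
        assert vec.scores[0] == pytest.approx(
            math.log(2) + 2 * math.log(3), abs=1e-12)
        assert vec.scores[0] == pytest.approx(2.8904, abs=1e-4)

    def test_unit_or_snp_contributes_nothing(self):
        base = compute_prs(cohort_of([[1, 2]], [1]), panel_of([2.0, 3.0]),
                           ScoreModel.SNP_HLA).scores
        extended = compute_prs(cohort_of([[1, 2, 2]], [1]),
                               panel_of([2.0, 3.0, 1.0]),
                               ScoreModel.SNP_HLA).scores
        np.testing.assert_allclose(extended, base)

    def test_model_partition_is_additive(self, small_cohort):
        cohort, panel = small_cohort
        policy = "expected-dosage"
        snp = compute_prs(cohort, panel, ScoreModel.SNP, policy).scores
        hla = compute_prs(cohort, panel, ScoreModel.HLA, policy).scores
        both = compute_prs(cohort, panel, ScoreModel.SNP_HLA, policy).scores
        np.testing.assert_allclose(snp + hla, both, atol=1e-12)

    def test_drop_policy_counts_missing(self):
        dosage = [[1, 2], [np.nan, 1], [0, 0]]
        vec = compute_prs(cohort_of(dosage, [1, 1, 0]), panel_of([2.0, 3.0]),
                          ScoreModel.SNP_HLA, "drop")
        assert vec.n_missing_dropped == 1
        assert np.isnan(vec.scores[1])
        assert vec.scores[2] == 0.0

    def test_expected_dosage_uses_control_frequency(self):
        # controls' mean dosage at rs0 is 1.0 -> imputed value 1.0
        dosage = [[np.nan, 1], [0, 0], [2, 0]]
        vec = compute_prs(cohort_of(dosage, [1, 0, 0]), panel_of([2.0, 3.0]),
                          ScoreModel.SNP_HLA, "expected-dosage")
        assert vec.scores[0] == pytest.approx(
            1.0 * math.log(2) + math.log(3))

    def test_drink_model_needs_exposure(self):
        panel = panel_of([2.0, 3.0], env=math.log(2.5))
        cohort = cohort_of([[0, 0]], [1])  # ever_drinker is None
        vec = compute_prs(cohort, panel, ScoreModel.SNP_HLA_DRINK)
        assert np.isnan(vec.scores[0])
        panel_no_env = panel_of([2.0, 3.0])
        with pytest.raises(ValidationError):
            compute_prs(cohort, panel_no_env, ScoreModel.SNP_HLA_DRINK)

    def test_drinker_with_zero_dosage_scores_env_weight(self):
        panel = panel_of([2.0, 3.0], env=math.log(2.5))
        cohort = cohort_of([[0, 0]], [1], drink=[1])
        vec = compute_prs(cohort, panel, ScoreModel.SNP_HLA_DRINK)
        assert vec.scores[0] == pytest.approx(math.log(2.5), abs=1e-12)


def prs_vector(scores):
    return PRSVector(model=ScoreModel.SNP_HLA,
                     scores=np.asarray(scores, float),
                     n_missing_dropped=0, snp_ids=[])


class TestQuartileGroups:
    def test_percentile_definition_and_boundaries(self):
        scores = np.r_[np.arange(1.0, 9.0), 2.75, 2.76]
        control_mask = np.r_[np.ones(8, bool), np.zeros(2, bool)]
        table = quartile_groups(prs_vector(scores), control_mask)
        assert table.cutpoints == pytest.approx((2.75, 4.5, 6.25))
        # boundary value belongs to the lower group
        assert table.groups[8] == 0
        assert table.groups[9] == 1

    def test_controls_split_evenly_without_ties(self, rng):
        scores = rng.normal(size=4000)
        control_mask = np.ones(4000, bool)
        table = quartile_groups(prs_vector(scores), control_mask)
        np.testing.assert_array_equal(table.control_counts, [1000] * 4)

    def test_degenerate_scores_rejected(self):
        with pytest.raises(DegenerateScoreError):
            quartile_groups(prs_vector(np.ones(10)), np.ones(10, bool))

    def test_needs_four_controls(self):
        with pytest.raises(ValidationError):
            quartile_groups(prs_vector([1.0, 2.0, 3.0]), np.ones(3, bool))


class TestGroupOrTable:
    def make_table(self, case_counts, control_counts):
        from psorprs import RiskGroupTable

        groups, status = [], []
        for g, (n_case, n_ctrl) in enumerate(zip(case_counts, control_counts)):
            groups += [g] * (n_case + n_ctrl)
            status += [1] * n_case + [0] * n_ctrl
        table = RiskGroupTable(
            cutpoints=(0.5, 1.5, 2.5),
            groups=np.array(groups),
            case_counts=np.array(case_counts),
            control_counts=np.array(control_counts),
        )
        return table, np.array(status)

    def test_crude_ors_equal_2x2_odds_ratios(self):
        case_counts = (114, 148, 211, 3148)
        control_counts = (853, 813, 846, 836)
        table, status = self.make_table(case_counts, control_counts)
        np.testing.assert_array_equal(table.case_counts, case_counts)
        crude = table.crude_ors()
        for g in (1, 2, 3):
            expected = (case_counts[g] * control_counts[0]) / (
                control_counts[g] * case_counts[0])
            assert crude[g] == pytest.approx(expected, rel=1e-12)

    def test_adjusted_ors_match_indicator_logistic(self):
        table, status = self.make_table((20, 30, 40, 80), (50, 50, 50, 50))
        completed = group_or_table(table, status)
        y = status.astype(float)
        design = {f"group{g}": (table.groups == g).astype(float)
                  for g in (1, 2, 3)}
        direct = fit_logistic(y, design)
        for g in (1, 2, 3):
            assert completed.ors[g] == pytest.approx(
                float(np.exp(direct.params[f"group{g}"])), rel=1e-8)
        assert completed.ors[0] == 1.0

    def test_null_simulation_cis_cover_one(self):
        # null genotype-phenotype association, scored with the usual
        # non-degenerate weights: group ORs should hover around 1
        from psorprs import default_panel, paper_like_config, simulate_cohort
        config = paper_like_config(n_cases=1000, n_controls=1000, seed=42,
                                   snp_ors=(1.0,) * 14, drink_or=1.0,
                                   onset_hr_per_prs_unit=1.0,
                                   family_history_slope=0.0)
        cohort, _ = simulate_cohort(config)
        panel = default_panel(paper_like_config())
        vec = compute_prs(cohort, panel, ScoreModel.SNP_HLA,
                          "expected-dosage")
        table = quartile_groups(vec, cohort.is_control)
        completed = group_or_table(table, cohort.status, cohort.age,
                                   cohort.sex)
        covered = sum(
            completed.ci_low[g] <= 1.0 <= completed.ci_high[g]
            for g in (1, 2, 3)
        )
        assert covered >= 2  # nominal 95% coverage, 3 intervals

    def test_paper_like_effects_are_monotone_and_concentrated(self):
        from psorprs import paper_like_config, simulate_cohort
        monotone = 0
        shares = []
        for seed in range(5):
            config = paper_like_config(n_cases=1500, n_controls=1500,
                                       seed=seed)
            cohort, panel = simulate_cohort(config)
            vec = compute_prs(cohort, panel, ScoreModel.SNP_HLA,
                              "expected-dosage")
            table = quartile_groups(vec, cohort.is_control)
            completed = group_or_table(table, cohort.status, cohort.age,
                                       cohort.sex)
            ors = completed.ors
            monotone += ors[1] < ors[2] < ors[3]
            shares.append(table.case_fractions()[3])
        assert monotone == 5
        # the large-effect HLA locus concentrates cases in the top quartile
        assert np.mean(shares) > 0.80


class TestContinuousEffect:
    def test_affine_shift_absorbed_by_intercept(self, rng):
        n = 500
        scores = rng.normal(size=n)
        y = rng.binomial(1, 1 / (1 + np.exp(-scores))).astype(float)
        fit_a = continuous_prs_effect(prs_vector(scores), y)
        fit_b = continuous_prs_effect(prs_vector(scores + 5.0), y)
        assert fit_a.params["prs"] == pytest.approx(fit_b.params["prs"],
                                                    abs=1e-6)

    def test_recovers_unit_log_odds(self, rng):
        n = 7000
        scores = rng.normal(size=n)
        y = rng.binomial(1, 1 / (1 + np.exp(-(-0.2 + 1.0 * scores))))
        fit = continuous_prs_effect(prs_vector(scores), y.astype(float))
        assert fit.params["prs"] == pytest.approx(1.0, abs=0.15)


class TestInteraction:
    def test_constant_exposure_rejected(self):
        with pytest.raises(ValidationError):
            interaction_test(np.array([0, 1, 2, 3] * 10),
                             np.ones(40), np.tile([0, 1], 20))

    def test_detects_strong_product_effect(self, rng):
        n = 3000
        groups = rng.integers(0, 4, size=n)
        exposure = rng.binomial(1, 0.5, size=n).astype(float)
        eta = -0.5 + 0.2 * groups + 1.0 * (groups == 3) * exposure
        y = rng.binomial(1, 1 / (1 + np.exp(-eta))).astype(float)
        result = interaction_test(groups, exposure, y)
        assert result.p_interaction < 0.05
        assert result.df >= 1

    def test_null_product_effect_not_flagged(self, rng):
        pvals = []
        for _ in range(20):
            n = 1500
            groups = rng.integers(0, 4, size=n)
            exposure = rng.binomial(1, 0.5, size=n).astype(float)
            eta = -0.5 + 0.3 * groups + 0.5 * exposure
            y = rng.binomial(1, 1 / (1 + np.exp(-eta))).astype(float)
            pvals.append(interaction_test(groups, exposure, y).p_interaction)
        assert 0.05 < np.mean(pvals)
        assert min(pvals) > 1e-4


class TestFamilyHistory:
    def test_identical_groups_give_zero_t(self):
        scores = np.r_[np.arange(10.0), np.arange(10.0)]
        fh = np.r_[np.ones(10), np.zeros(10)]
        result = family_history_association(scores, fh)
        assert result.t_stat == pytest.approx(0.0, abs=1e-12)
        assert result.mean_fh_pos == result.mean_fh_neg

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            family_history_association(np.arange(10.0), np.ones(10))

    def test_positive_slope_recovered(self, full_cohort):
        cohort, panel = full_cohort
        vec = compute_prs(cohort, panel, ScoreModel.SNP_HLA,
                          "expected-dosage")
        cases = cohort.is_case
        result = family_history_association(vec.scores[cases],
                                            cohort.family_history[cases])
        assert result.fit.params["prs"] > 0
        assert result.mean_fh_pos > result.mean_fh_neg
        assert result.fit.params["prs"] == pytest.approx(0.15, abs=0.1)
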