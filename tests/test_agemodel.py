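import math

import numpy as np
import pytest

import kinfolk as kf
from kinfolk.agemodel import TypeCoefficients, load_bxd_csv


def brute_poisson_tail(observed: int, lam: float, terms: int = 4000) -> float:
    """Independent oracle: direct log-space pmf summation."""
    if observed == 0:
        return 1.0
    return sum(
        math.exp(-lam + k * math.log(lam) - math.lgamma(k + 1))
        for k in range(observed, observed + terms))


def flat_coeffs(m_mat=0.5, b_mat=2.0, m_pat=0.5, b_pat=2.0,
                ref_bp=1_000_000_000):
    return kf.AgeModelCoefficients(
        per_type={t: TypeCoefficients(m_mat, b_mat, m_pat, b_pat)
                  for t in kf.MUTATION_TYPES},
        reference_genome_bp=ref_bp)


class TestExpectedCounts:
    def test_linear_arithmetic(self):
        exp = kf.expected_counts(flat_coeffs(), 30.0, 30.0)
        for t in kf.MUTATION_TYPES:
            assert exp.expected_mat[t] == pytest.approx(17.0)
            assert exp.expected_total[t] == pytest.approx(34.0)

    def test_accessibility_scale_is_multiplicative(self):
        full = kf.expected_counts(flat_coeffs(), 30.0, 30.0, 1.0)
        half = kf.expected_counts(flat_coeffs(), 30.0, 30.0, 0.5)
        for t in kf.MUTATION_TYPES:
            assert half.expected_total[t] == pytest.approx(
                full.expected_total[t] / 2)

    def test_zero_coefficients_zero_expectation(self):
        exp = kf.expected_counts(flat_coeffs(0, 0, 0, 0), 30.0, 30.0)
        assert exp.grand_total == 0.0

    def test_negative_model_value_floored(self):
        exp = kf.expected_counts(flat_coeffs(b_mat=-100.0), 30.0, 30.0)
        assert all(v == 0.0 for v in exp.expected_mat.values())

    def test_missing_type_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            kf.AgeModelCoefficients(
                per_type={"C>A": TypeCoefficients(0, 0, 0, 0)},
                reference_genome_bp=1)

    def test_family_expectation_is_sum_of_children(self):
        c = flat_coeffs()
        kids = [kf.expected_counts(c, a, a + 2) for a in (25.0, 30.0, 35.0)]
        fam = kf.combine_expectations(kids)
        for t in kf.MUTATION_TYPES:
            assert fam.expected_total[t] == pytest.approx(
                sum(k.expected_total[t] for k in kids))

    def test_coefficient_tsv_round_trip(self, tmp_path):
        c = kf.default_truth_coefficients()
        path = tmp_path / "coeffs.tsv"
        c.to_tsv(path)
        back = kf.AgeModelCoefficients.from_tsv(path)
        assert back.reference_genome_bp == c.reference_genome_bp
        assert back.per_type == dict(c.per_type)


class TestPoissonTail:
    @pytest.mark.parametrize("lam", [0.5, 1.0, 2.0, 5.0, 10.0])
    def test_matches_brute_force_summation(self, lam):
        for obs in range(0, 41):
            assert kf.poisson_upper_tail(obs, lam) == pytest.approx(
                brute_poisson_tail(obs, lam), rel=1e-9, abs=1e-300)

    def test_zero_observed_is_certain(self):
        assert kf.poisson_upper_tail(0, 3.7) == 1.0

    def test_monotone_decreasing_in_observed(self):
        ps = [kf.poisson_upper_tail(o, 4.0) for o in range(30)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            kf.poisson_upper_tail(3, 0.0)
        with pytest.raises(ValueError):
            kf.poisson_upper_tail(-1, 1.0)


class TestBurdenTest:
    def test_observed_at_expectation_not_significant(self):
        exp = kf.expected_counts(flat_coeffs(), 30.0, 30.0)
        obs = {t: round(exp.expected_total[t]) for t in kf.MUTATION_TYPES}
        res = kf.burden_test(obs, exp)
        assert not any(res.significant(k) for k in res.p_values)

    def test_family_excess_in_one_child_reaches_significance(self):
        # family C>A expectation 10; critical count from the exact tail
        c = flat_coeffs(m_mat=0.0, b_mat=2.0, m_pat=0.0, b_pat=3.0)
        kids = [kf.expected_counts(c, 30.0, 30.0) for _ in range(2)]
        fam = kf.combine_expectations(kids)
        assert fam.expected_total["C>A"] == pytest.approx(10.0)
        critical, _ = kf.detection_threshold(10.0)
        obs = {t: 5 for t in kf.MUTATION_TYPES}
        obs["C>A"] = critical  # one child carries the whole excess
        res = kf.burden_test(obs, fam, unit="family")
        assert res.significant("C>A")
        below = dict(obs, **{"C>A": critical - 1})
        assert not kf.burden_test(below, fam).significant("C>A")

    def test_group_is_elementwise_sum_of_families(self):
        c = flat_coeffs()
        fam1 = [kf.expected_counts(c, 25.0, 28.0)] * 2
        fam2 = [kf.expected_counts(c, 33.0, 40.0)] * 3
        g1 = kf.combine_expectations(fam1)
        g2 = kf.combine_expectations(fam2)
        both = kf.combine_expectations(fam1 + fam2)
        for t in kf.MUTATION_TYPES:
            assert both.expected_total[t] == pytest.approx(
                g1.expected_total[t] + g2.expected_total[t])

    def test_enrichment_ratio(self):
        exp = kf.expected_counts(flat_coeffs(), 30.0, 30.0)  # 34 per type
        obs = {t: 17 for t in kf.MUTATION_TYPES}
        res = kf.burden_test(obs, exp)
        assert res.enrichment["C>A"] == pytest.approx(0.5)


class TestDetectionThreshold:
    def test_frozen_oracle_value_for_expected_five(self):
        # smallest c with P(X >= c | 5) < 0.05, by direct pmf summation
        c_oracle = 1
        while brute_poisson_tail(c_oracle, 5.0) >= 0.05:
            c_oracle += 1
        assert c_oracle == 10
        critical, extra = kf.detection_threshold(5.0)
        assert critical == c_oracle
        assert extra == pytest.approx(5.0)

    def test_tiny_expectation_gives_critical_one(self):
        critical, _ = kf.detection_threshold(1e-6)
        assert critical == 1

    def test_non_decreasing_in_expected(self):
        crits = [kf.detection_threshold(lam)[0]
                 for lam in np.linspace(0.1, 30, 100)]
        assert all(a <= b for a, b in zip(crits, crits[1:]))

    @pytest.mark.parametrize("lam", [0.5, 1.0, 2.0, 5.0, 10.0])
    def test_matches_brute_force_definition(self, lam):
        c = 1
        while brute_poisson_tail(c, lam) >= 0.05:
            c += 1
        assert kf.detection_threshold(lam)[0] == c


class TestFoldElevation:
    def test_excess_attributed_to_carrier_mother(self):
        assert kf.parental_fold_elevation(6, 1.0, 3.0, "mother") == pytest.approx(3.0)

    def test_no_excess_gives_fold_one(self):
        assert kf.parental_fold_elevation(4, 1.0, 3.0, "mother") == pytest.approx(1.0)

    def test_carrier_father_larger_denominator(self):
        assert kf.parental_fold_elevation(6, 1.0, 3.0, "father") == pytest.approx(5 / 3)

    def test_zero_carrier_expectation_rejected(self):
        with pytest.raises(ValueError):
            kf.parental_fold_elevation(6, 0.0, 3.0, "mother")

    def test_min_detectable_fold_worked_fixture(self):
        # C>A expectations: maternal 2, paternal 6, total 8
        c = flat_coeffs(m_mat=0.0, b_mat=2.0, m_pat=0.0, b_pat=6.0)
        exp = kf.expected_counts(c, 30.0, 30.0)
        crit = 1
        while brute_poisson_tail(crit, 8.0) >= 0.05:
            crit += 1
        expected_fold_mat = (2.0 + (crit - 8.0)) / 2.0
        expected_fold_pat = (6.0 + (crit - 8.0)) / 6.0
        assert kf.min_detectable_fold(exp, "mother") == pytest.approx(expected_fold_mat)
        assert kf.min_detectable_fold(exp, "father") == pytest.approx(expected_fold_pat)
        # the carrier with the larger expectation needs a smaller fold
        assert expected_fold_pat < expected_fold_mat

    def test_symmetric_when_parents_equal(self):
        c = flat_coeffs(m_mat=0.0, b_mat=4.0, m_pat=0.0, b_pat=4.0)
        exp = kf.expected_counts(c, 30.0, 30.0)
        assert kf.min_detectable_fold(exp, "mother") == pytest.approx(
            kf.min_detectable_fold(exp, "father"))


def make_bxd_records(rng, n_per_class=50, slope=1.05e-9,
                     intercept_b=4.39e-10, intercept_d=7.96e-10,
                     min_gt=0.2, max_gt=0.63, noise_sd=0.0,
                     accessible_bp=2_500_000_000):
    """Synthetic strains generated from a known linear model; counts are
    rounded to integers via the rate definition so noise_sd=0 recovery is
    only exact up to rounding — use large accessible_bp to make rounding
    negligible."""
    records = []
    for g, intercept in (("B", intercept_b), ("D", intercept_d)):
        for i in range(n_per_class):
            gt = rng.uniform(min_gt, max_gt) if i else min_gt
            rate = intercept + slope * (gt - min_gt)
            if noise_sd:
                rate = max(rate + rng.normal(0, noise_sd), 1e-12)
            n_gen = int(rng.integers(20, 100))
            records.append(kf.BXDStrainRecord(
                strain=f"BXD_{g}{i}", mutyh_genotype=g,
                n_generations=n_gen, n_years=gt * n_gen,
                ca_count=int(round(rate * n_gen * accessible_bp)),
                accessible_bp=accessible_bp))
    return records


class TestBXDRegression:
    def test_exact_recovery_on_noise_free_data(self):
        rng = np.random.default_rng(0)
        recs = make_bxd_records(rng, accessible_bp=10**12)
        res = kf.bxd_regression(recs)
        assert res.slope == pytest.approx(1.05e-9, rel=1e-3)
        assert res.intercept_B == pytest.approx(4.39e-10, rel=1e-3)
        assert res.intercept_D == pytest.approx(7.96e-10, rel=1e-3)
        assert res.p_slope < 1e-6 and res.p_genotype < 1e-6

    def test_noisy_recovery_within_two_se(self):
        rng = np.random.default_rng(1)
        recs = make_bxd_records(rng, n_per_class=50, noise_sd=5e-11,
                                accessible_bp=10**12)
        res = kf.bxd_regression(recs)
        # 2 SE of the slope under this design is well under 30%
        assert res.slope == pytest.approx(1.05e-9, rel=0.3)

    def test_no_interaction_in_parallel_lines(self):
        rng = np.random.default_rng(2)
        recs = make_bxd_records(rng, noise_sd=3e-11, accessible_bp=10**12)
        res = kf.bxd_regression(recs)
        assert res.p_interaction > 0.05

    def test_single_genotype_rejected(self):
        rng = np.random.default_rng(3)
        recs = [r for r in make_bxd_records(rng) if r.mutyh_genotype == "B"]
        with pytest.raises(ValueError, match="genotype D"):
            kf.bxd_regression(recs)

    def test_generation_time_and_rate_definitions(self):
        r = kf.BXDStrainRecord("s", "B", n_generations=40, n_years=10.0,
                               ca_count=80, accessible_bp=2_000_000_000)
        assert r.generation_time == pytest.approx(0.25)
        assert r.ca_rate == pytest.approx(80 / 40 / 2e9)

    def test_csv_round_trip(self, tmp_path):
        path = tmp_path / "bxd.csv"
        path.write_text(
            "strain,genotype,n_generations,n_years,ca_count,accessible_bp\n"
            "BXD1,B,40,10.0,80,2000000000\n")
        recs = load_bxd_csv(path)
        assert recs[0].mutyh_genotype == "B"
        assert recs[0].generation_time == pytest.approx(0.25)


class TestFunctionScore:
    def test_wild_type_scores_zero(self):
        assert kf.function_score(0.4, 0.4) == 0.0

    def test_half_activity_scores_minus_one(self):
        assert kf.function_score(0.2, 0.4) == pytest.approx(-1.0)

    def test_zero_variant_uses_pseudocount(self):
        assert kf.function_score(0.0, 0.5) == pytest.approx(math.log2(0.002))

    def test_zero_wild_type_rejected(self):
        with pytest.raises(ValueError):
            kf.function_score(0.1, 0.0)
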