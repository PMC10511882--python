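"""Genetic contrast models: ORs, Woolf CIs, chi-squares, applicability."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from vtgrs.association_models import (
    allele_table,
    allelic_association,
    association_results,
    cohort_association_table,
    genotypic_association,
    model_association,
    trend_association,
)
from vtgrs.cohort_model import AlleleTable, GenotypeCounts
from vtgrs.synthetic_cohort import reconstruct_allele_counts

counts_strategy = st.tuples(
    st.integers(1, 200), st.integers(1, 200), st.integers(1, 200)
).map(lambda t: GenotypeCounts(*t))


class TestAlleleTable:
    def test_each_subject_contributes_two_alleles(self):
        t = allele_table(GenotypeCounts(1, 1, 1), GenotypeCounts(2, 0, 0))
        assert (t.case_risk, t.case_other) == (3, 3)
        assert (t.control_risk, t.control_other) == (0, 4)

    def test_empty_group_gives_zero_row(self):
        t = allele_table(GenotypeCounts(0, 0, 0), GenotypeCounts(1, 2, 3))
        assert t.case_risk == 0 and t.case_other == 0


class TestAllelicAssociation:
    @pytest.mark.parametrize(
        "case_f,ctrl_f,or2,ci,chi2",
        [
            (0.203, 0.0675, 3.52, (2.50, 4.95), 57.21),
            (0.2836, 0.2312, 1.32, (1.03, 1.68), 4.94),
            (0.6191, 0.5412, 1.38, (1.11, 1.71), 8.47),
            (0.5956, 0.5262, 1.33, (1.07, 1.64), 6.66),
            (0.0302, 0.02, 1.53, (0.77, 3.02), 1.50),
        ],
    )
    def test_reconstructed_study_tables(self, case_f, ctrl_f, or2, ci, chi2):
        t = AlleleTable(
            *reconstruct_allele_counts(case_f, 298),
            *reconstruct_allele_counts(ctrl_f, 400),
        )
        res = allelic_association(t)
        assert round(res.odds_ratio, 2) == or2
        assert (round(res.ci_low, 2), round(res.ci_high, 2)) == ci
        assert res.chi_square == pytest.approx(chi2, abs=0.05)

    def test_protective_allele_is_inverse(self):
        t = AlleleTable(
            *reconstruct_allele_counts(0.5956, 298),
            *reconstruct_allele_counts(0.5262, 400),
        )
        res = allelic_association(t.swapped())
        assert round(res.odds_ratio, 2) == 0.75

    def test_identical_frequencies_null(self):
        res = allelic_association(AlleleTable(30, 70, 60, 140))
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.chi_square == pytest.approx(0.0)

    def test_zero_cell_not_applicable(self):
        res = allelic_association(AlleleTable(0, 100, 10, 90))
        assert not res.applicable and np.isnan(res.odds_ratio)

    def test_haldane_correction_recovers_estimate(self):
        res = allelic_association(AlleleTable(0, 100, 10, 90), haldane=True)
        assert not res.applicable  # still flagged: the raw table has a zero
        assert np.isfinite(res.odds_ratio)


class TestCollapsedModels:
    def test_dominant_collapse_matches_brute_force(self, rng):
        for _ in range(50):
            case = GenotypeCounts(*map(int, rng.integers(1, 100, 3)))
            ctrl = GenotypeCounts(*map(int, rng.integers(1, 100, 3)))
            res = model_association(case, ctrl, "dominant")
            a = case.n_het + case.n_hom_risk
            expected = (a * ctrl.n_hom_other) / (
                case.n_hom_other * (ctrl.n_het + ctrl.n_hom_risk)
            )
            assert res.odds_ratio == pytest.approx(expected)

    def test_recessive_zero_control_homozygotes_is_na(self):
        # the rule used for rare variants: an empty cell disables the test
        res = model_association(
            GenotypeCounts(280, 17, 1), GenotypeCounts(384, 16, 0), "recessive"
        )
        assert not res.applicable
        assert np.isnan(res.chi_square) and np.isnan(res.odds_ratio)

    def test_dominant_no_carriers_anywhere(self):
        res = model_association(
            GenotypeCounts(10, 0, 0), GenotypeCounts(10, 0, 0), "dominant"
        )
        assert not res.applicable


class TestTrendAssociation:
    def brute_force_trend(self, case, ctrl):
        r, n = case.as_array(), case.as_array() + ctrl.as_array()
        s = np.array([0, 1, 2])
        N, R = n.sum(), r.sum()
        num = (N * (s * r).sum() - R * (s * n).sum()) ** 2
        den = R * (N - R) / N * (N * (s**2 * n).sum() - (s * n).sum() ** 2)
        return num / den

    def test_statistic_equals_direct_formula(self, rng):
        for _ in range(50):
            case = GenotypeCounts(*map(int, rng.integers(1, 120, 3)))
            ctrl = GenotypeCounts(*map(int, rng.integers(1, 120, 3)))
            res = trend_association(case, ctrl)
            assert res.chi_square == pytest.approx(self.brute_force_trend(case, ctrl))

    def test_identical_distributions_give_zero(self):
        g = GenotypeCounts(50, 30, 20)
        assert trend_association(g, g).chi_square == pytest.approx(0.0)

    def test_or_equals_multiplicative_or(self):
        case, ctrl = GenotypeCounts(60, 30, 10), GenotypeCounts(80, 15, 5)
        trend = trend_association(case, ctrl)
        mult = allelic_association(allele_table(case, ctrl))
        assert trend.odds_ratio == mult.odds_ratio
        assert trend.chi_square != pytest.approx(mult.chi_square)

    @given(counts_strategy, counts_strategy)
    @settings(derandomize=True, max_examples=100)
    def test_trend_never_exceeds_genotypic_chi2(self, case, ctrl):
        trend = trend_association(case, ctrl)
        geno = genotypic_association(case, ctrl)
        assert trend.chi_square <= geno.chi_square + 1e-9


class TestGenotypicAssociation:
    def test_chi2_matches_scipy_pearson(self, rng):
        for _ in range(50):
            case = GenotypeCounts(*map(int, rng.integers(1, 120, 3)))
            ctrl = GenotypeCounts(*map(int, rng.integers(1, 120, 3)))
            res = genotypic_association(case, ctrl)
            ref = chi2_contingency(
                np.array([case.as_array(), ctrl.as_array()]), correction=False
            )
            assert res.chi_square == pytest.approx(ref.statistic)
            assert res.p_value == pytest.approx(ref.pvalue)
            assert res.df == 2

    def test_identical_distributions_null(self):
        g = GenotypeCounts(50, 30, 20)
        res = genotypic_association(g, g)
        assert res.chi_square == pytest.approx(0.0)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.odds_ratio_hom == pytest.approx(1.0)

    def test_collapsing_reproduces_allele_table(self):
        case, ctrl = GenotypeCounts(10, 20, 30), GenotypeCounts(40, 30, 10)
        t = allele_table(case, ctrl)
        assert t.case_risk == 2 * 30 + 20
        assert t.control_other == 2 * 40 + 30


class TestProperties:
    @given(counts_strategy, counts_strategy)
    @settings(derandomize=True, max_examples=100)
    def test_allele_swap_inverts_or_and_keeps_chi2(self, case, ctrl):
        base = association_results(case, ctrl)
        swapped = association_results(case.swapped(), ctrl.swapped())
        for model in ("multiplicative", "additive"):
            b, s = base[model], swapped[model]
            assert s.odds_ratio == pytest.approx(1 / b.odds_ratio)
            assert s.chi_square == pytest.approx(b.chi_square)
        # dominant <-> recessive exchange roles under the swap
        assert swapped["dominant"].chi_square == pytest.approx(
            base["recessive"].chi_square
        )
        assert swapped["genotypic"].chi_square == pytest.approx(
            base["genotypic"].chi_square
        )

    @given(counts_strategy, counts_strategy, st.integers(2, 5))
    @settings(derandomize=True, max_examples=50)
    def test_woolf_ci_contains_or_and_narrows_with_n(self, case, ctrl, factor):
        res = allelic_association(allele_table(case, ctrl))
        assert res.ci_low <= res.odds_ratio <= res.ci_high
        big = AlleleTable(
            *(factor * x for x in (case.risk_allele_count, case.other_allele_count,
                                   ctrl.risk_allele_count, ctrl.other_allele_count))
        )
        res_big = allelic_association(big)
        assert (np.log(res_big.ci_high) - np.log(res_big.ci_low)) < (
            np.log(res.ci_high) - np.log(res.ci_low)
        ) + 1e-12

    def test_ci_coverage_in_logistic_mode(self):
        # true per-allele OR 3.5 at the study design size: the Woolf 95% CI
        # should cover the truth in about 95% of replicates
        from vtgrs.cohort_model import MarkerDef, tabulate
        from vtgrs.synthetic_cohort import SimConfig, simulate_cohort_logistic

        covered = 0
        reps = 500
        cfg_base = dict(
            n_cases=298, n_controls=400,
            markers=(MarkerDef("rsX", "T", "C"),),
            case_freqs=(0.2,), control_freqs=(0.0675,),
        )
        for seed in range(reps):
            cohort = simulate_cohort_logistic(
                SimConfig(seed=seed, **cfg_base), np.array([np.log(3.5)]),
                intercept=-4.5,
            )
            case, ctrl = tabulate(cohort, 0)
            res = allelic_association(allele_table(case, ctrl))
            if res.applicable and res.ci_low <= 3.5 <= res.ci_high:
                covered += 1
        assert 0.92 <= covered / reps <= 0.98


def test_cohort_association_table_shape_and_flags(study_cohort):
    table = cohort_association_table(study_cohort, correction_threshold=0.01)
    assert len(table) == study_cohort.n_markers * 5
    assert set(table["model"]) == {
        "multiplicative", "additive", "dominant", "recessive", "genotypic"
    }
    applicable = table[table["applicable"]]
    assert (
        applicable["significant_after_correction"]
        == (applicable["p_value"] < 0.01)
    ).all()
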