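"""Demographics, Fisher enrichment (vs exact hypergeometric oracle), comorbidity."""

import numpy as np
import pytest
from scipy import stats

from rarephenome.cohorts import DiagnosisRole, DiseaseCohort, PersonRecord, Sex
from rarephenome.comorbidity import (
    DemographicSummary,
    age_comparisons,
    comorbidity_profile,
    compare_enrichment,
    complex_disease_members,
    demographic_summary,
    enrichment_matrix,
    fisher_test,
    pairwise_comorbidity,
    sex_age_correlation,
    sex_bias_test,
)


def hypergeom_fisher_p(table) -> float:
    """Exact two-sided Fisher p by enumerating the hypergeometric support."""
    (a, b), (c, d) = table
    n = a + b + c + d
    row1, col1 = a + b, a + c
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    pmf = {k: stats.hypergeom.pmf(k, n, col1, row1) for k in range(lo, hi + 1)}
    p_obs = pmf[a]
    return float(sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-9)))


ORACLE_TABLES = [
    ((3, 7), (12, 28)),
    ((0, 10), (10, 30)),
    ((5, 0), (20, 25)),
    ((1, 1), (1, 1)),
    ((0, 0), (25, 25)),
    ((10, 2), (3, 35)),
    ((8, 17), (25, 0)),
    ((30, 10), (470, 490)),
]


class TestFisherOracle:
    @pytest.mark.parametrize("table", ORACLE_TABLES)
    def test_p_matches_exhaustive_enumeration(self, table):
        _, p = fisher_test(table)
        assert p == pytest.approx(hypergeom_fisher_p(table), rel=1e-9)

    def test_all_small_margin_tables(self):
        """Sweep of tables with margins <= 50 against the enumeration oracle."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 26, size=4)
            if a + b + c + d == 0:
                continue
            _, p = fisher_test(((a, b), (c, d)))
            assert p == pytest.approx(hypergeom_fisher_p(((a, b), (c, d))), rel=1e-9)

    def test_zero_cell_odds_ratios(self):
        oddsr, _ = fisher_test(((0, 10), (10, 30)))
        assert oddsr == 0.0
        oddsr, _ = fisher_test(((5, 0), (20, 25)))
        assert oddsr == np.inf

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            fisher_test(((-1, 2), (3, 4)))


def make_persons(n_male, n_female, group_size_male, group_size_female):
    persons, group = [], set()
    for i in range(n_male):
        pid = f"m{i}"
        persons.append(PersonRecord(pid, Sex.MALE, 55, []))
        if i < group_size_male:
            group.add(pid)
    for i in range(n_female):
        pid = f"f{i}"
        persons.append(PersonRecord(pid, Sex.FEMALE, 55, []))
        if i < group_size_female:
            group.add(pid)
    return persons, group


class TestSexBias:
    def test_population_ratio_gives_unit_odds(self):
        persons, group = make_persons(100, 100, 20, 20)
        res = sex_bias_test(group, persons)
        assert res.odds_ratio == pytest.approx(1.0, abs=1e-6)
        assert res.p_value == 1.0

    def test_matches_oracle_on_printed_table(self):
        persons, group = make_persons(500, 500, 30, 10)
        res = sex_bias_test(group, persons)
        assert res.table == ((30, 10), (470, 490))
        assert res.p_value == pytest.approx(hypergeom_fisher_p(res.table), rel=1e-9)

    def test_single_sex_population_degenerate(self):
        persons, group = make_persons(50, 0, 10, 0)
        res = sex_bias_test(group, persons)
        assert res.p_value == 1.0
        assert np.isnan(res.odds_ratio)

    def test_empty_group_rejected(self):
        persons, _ = make_persons(5, 5, 0, 0)
        with pytest.raises(ValueError):
            sex_bias_test(set(), persons)


class TestDemographics:
    def test_small_cohort_suppressed(self):
        persons = [PersonRecord(f"p{i}", Sex.MALE, 50 + i, []) for i in range(4)]
        cohort = DiseaseCohort("ORPHA:1", set(), {p.person_id for p in persons}, 100)
        assert demographic_summary(cohort, persons).suppressed

    def test_all_male_cohort(self):
        persons = [PersonRecord(f"p{i}", Sex.MALE, 50 + i, []) for i in range(6)]
        cohort = DiseaseCohort("ORPHA:1", set(), {p.person_id for p in persons}, 100)
        s = demographic_summary(cohort, persons)
        assert s.percent_male == 100.0
        assert s.median_age == 52.5

    def test_empty_cohort(self):
        s = demographic_summary(DiseaseCohort("ORPHA:1", set(), set(), 10), [])
        assert s.n == 0 and s.suppressed

    def test_planted_sex_ratio_recovered(self):
        from rarephenome.simulate import default_config, gen_population

        config = default_config(3)
        config.n_persons = 60_000
        population = gen_population(config)
        # ORPHA:33226 planted with male:female odds 1.8
        members = population.truth_memberships["ORPHA:33226"]
        res = sex_bias_test(members, population.persons)
        (m, f), _ = res.table
        n = m + f
        p_male_expected = 1.8 / 2.8
        ci = 3 * np.sqrt(p_male_expected * (1 - p_male_expected) / n)
        assert m / n == pytest.approx(p_male_expected, abs=ci)


class TestAgeComparisons:
    def _population(self, ages_rare, ages_none):
        persons = [
            PersonRecord(f"r{i}", Sex.MALE, a, []) for i, a in enumerate(ages_rare)
        ] + [PersonRecord(f"n{i}", Sex.FEMALE, a, []) for i, a in enumerate(ages_none)]
        cohort = DiseaseCohort("ORPHA:1", set(), {f"r{i}" for i in range(len(ages_rare))}, 1)
        return persons, [cohort]

    def test_identical_distributions_null(self):
        ages = list(range(40, 70)) * 3
        persons, cohorts = self._population(ages, ages)
        df = age_comparisons(persons, cohorts)
        row = df[df.comparison == "any_rare_vs_none"].iloc[0]
        assert row.fold_change == 1.0
        assert row.p_value > 0.9

    def test_fold_change_of_printed_medians(self):
        # medians 60 vs 58 give FC = 1.0344..., printing as 1.03
        persons, cohorts = self._population([59, 60, 61], [57, 58, 59])
        df = age_comparisons(persons, cohorts)
        row = df[df.comparison == "any_rare_vs_none"].iloc[0]
        assert row.median_a == 60 and row.median_b == 58
        assert round(row.fold_change, 2) == 1.03

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(42)
        ages_rare = rng.integers(45, 70, size=400)
        ages_none = rng.integers(40, 65, size=4000)
        persons, cohorts = self._population(list(ages_rare), list(ages_none))
        df = age_comparisons(persons, cohorts)
        row = df[df.comparison == "any_rare_vs_none"].iloc[0]
        assert row.p_value < 1e-6
        assert row.fold_change > 1

    def test_empty_arm_skipped(self):
        persons, cohorts = self._population([50, 51], [])
        df = age_comparisons(persons, cohorts)
        assert "any_rare_vs_none" not in set(df.get("comparison", []))


class TestSexAgeCorrelation:
    def test_three_points_closed_form(self):
        summaries = [
            DemographicSummary("a", 10, 20.0, 50.0, 50.0),
            DemographicSummary("b", 10, 50.0, 55.0, 55.0),
            DemographicSummary("c", 10, 80.0, 63.0, 63.0),
        ]
        r, _ = sex_age_correlation(summaries)
        x = np.array([20, 50, 80.0])
        y = np.array([50, 55, 63.0])
        expected = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert r == pytest.approx(expected)

    def test_constant_age_errors(self):
        summaries = [DemographicSummary(str(i), 10, 10.0 * i, 50.0, 50.0) for i in range(5)]
        with pytest.raises(ValueError):
            sex_age_correlation(summaries)

    def test_too_few_points_errors(self):
        summaries = [
            DemographicSummary("a", 10, 20.0, 50.0, 50.0),
            DemographicSummary("b", 2, 50.0, 55.0, 55.0),  # suppressed
            DemographicSummary("c", 10, 80.0, 63.0, 63.0),
        ]
        with pytest.raises(ValueError):
            sex_age_correlation(summaries)


class TestComorbidityProfile:
    def _five_person_setup(self):
        # index disease: ORPHA:1 via E27.1; comorbidities hand-countable
        persons = [
            PersonRecord("p0", Sex.MALE, 50, [("E27.1", DiagnosisRole.PRIMARY)]),
            PersonRecord("p1", Sex.MALE, 50, [("E27.1", DiagnosisRole.PRIMARY),
                                              ("I10", DiagnosisRole.SECONDARY)]),
            PersonRecord("p2", Sex.MALE, 50, [("E27.1", DiagnosisRole.PRIMARY),
                                              ("I10", DiagnosisRole.SECONDARY),
                                              ("J45.0", DiagnosisRole.SECONDARY)]),
            PersonRecord("p3", Sex.FEMALE, 50, [("E27.1", DiagnosisRole.PRIMARY),
                                                ("C44.9", DiagnosisRole.SECONDARY)]),
            PersonRecord("p4", Sex.FEMALE, 50, [("E27.1", DiagnosisRole.PRIMARY),
                                                ("E11.9", DiagnosisRole.SECONDARY)]),
        ]
        cohort = DiseaseCohort("ORPHA:1", {"E271"}, {f"p{i}" for i in range(5)}, 5)
        return persons, [cohort]

    def test_hand_counted_percentages(self):
        persons, cohorts = self._five_person_setup()
        profile = comorbidity_profile("ORPHA:1", cohorts, persons)
        assert profile["Circulatory"] == 40.0  # p1, p2
        assert profile["Respiratory"] == 20.0  # p2
        assert profile["Neoplasms"] == 20.0  # p3
        assert profile["Endocrine/metabolic"] == 20.0  # p4 (index codes removed)
        assert profile["Blood"] == 0.0

    def test_member_with_only_index_codes_contributes_zero(self):
        persons = [PersonRecord("p0", Sex.MALE, 50, [("E27.1", DiagnosisRole.PRIMARY)])] * 1
        cohort = DiseaseCohort("ORPHA:1", {"E271"}, {"p0"}, 5)
        profile = comorbidity_profile("ORPHA:1", [cohort], persons, suppress=False)
        assert all(v == 0.0 for v in profile.values())

    def test_suppressed_profile_withheld(self):
        persons, cohorts = self._five_person_setup()
        small = DiseaseCohort("ORPHA:2", {"E271"}, {"p0", "p1"}, 5)
        assert comorbidity_profile("ORPHA:2", cohorts + [small], persons) is None

    def test_percentages_bounded_and_duplication_invariant(self):
        persons, cohorts = self._five_person_setup()
        profile = comorbidity_profile("ORPHA:1", cohorts, persons)
        assert all(0 <= v <= 100 for v in profile.values())
        doubled = [
            PersonRecord(p.person_id, p.sex, p.age_at_recruitment, p.diagnoses * 2)
            for p in persons
        ]
        assert comorbidity_profile("ORPHA:1", cohorts, doubled) == profile


class TestEnrichmentMatrix:
    def test_null_assignment_gives_unit_odds(self):
        rng = np.random.default_rng(7)
        background = {f"p{i}" for i in range(4000)}
        rare_groups = {
            "A": {p for p in background if rng.random() < 0.5},
            "B": {p for p in background if rng.random() < 0.5},
        }
        comorb = {
            f"c{j}": {p for p in background if rng.random() < 0.3} for j in range(10)
        }
        results = enrichment_matrix(rare_groups, comorb, background)
        raw_hits = sum(r.p_value < 0.05 for r in results)
        ors = [r.odds_ratio for r in results]
        assert np.median(ors) == pytest.approx(1.0, abs=0.15)
        assert raw_hits <= max(3, 0.05 * len(results) * 4)
        assert not any(r.adjusted_significant for r in results)

    def test_planted_association_recovered(self):
        rng = np.random.default_rng(8)
        n = 6000
        in_group = rng.random(n) < 0.4
        base = 0.2
        odds = base / (1 - base) * 3.0
        p_link = odds / (1 + odds)
        has_c = np.where(in_group, rng.random(n) < p_link, rng.random(n) < base)
        ids = np.array([f"p{i}" for i in range(n)])
        results = enrichment_matrix(
            {"G": set(ids[in_group])},
            {"C": set(ids[has_c])},
            set(ids),
        )
        (res,) = results
        assert res.adjusted_significant
        assert res.odds_ratio == pytest.approx(3.0, rel=0.25)

    def test_single_group_matrix(self):
        background = {"p1", "p2", "p3"}
        results = enrichment_matrix(
            {"G": {"p1"}}, {"c1": {"p1"}, "c2": {"p2"}, "c3": set()}, background
        )
        assert len(results) == 3

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            enrichment_matrix({"G": set()}, {"c": set()}, set())

    def test_bonferroni_subset_of_fdr(self):
        rng = np.random.default_rng(9)
        background = {f"p{i}" for i in range(2000)}
        rare = {l: {p for p in background if rng.random() < 0.3} for l in "ABC"}
        com = {l: {p for p in background if rng.random() < 0.25} for l in "xyzw"}
        results = enrichment_matrix(rare, com, background)
        for r in results:
            if r.adjusted_significant:
                assert r.fdr_significant


class TestPairwiseComorbidity:
    def _persons(self, n):
        return [PersonRecord(f"p{i}", Sex.MALE, 50, []) for i in range(n)]

    def test_identical_cohorts_perfect_cooccurrence(self):
        members = {f"p{i}" for i in range(20)}
        cohorts = [
            DiseaseCohort("ORPHA:1", set(), members, 100),
            DiseaseCohort("ORPHA:2", set(), members, 100),
        ]
        (res,) = pairwise_comorbidity(cohorts, self._persons(100))
        assert res.odds_ratio == np.inf
        assert res.p_value < 1e-15

    def test_independent_cohorts_stay_null(self):
        rng = np.random.default_rng(10)
        persons = self._persons(3000)
        cohorts = [
            DiseaseCohort(
                f"ORPHA:{k}",
                set(),
                {p.person_id for p in persons if rng.random() < 0.05},
                3000,
            )
            for k in range(8)
        ]
        results = pairwise_comorbidity(cohorts, persons)
        assert sum(r.adjusted_significant for r in results) == 0

    def test_hand_built_table_matches_oracle(self):
        persons = self._persons(50)
        a = {f"p{i}" for i in range(15)}
        b = {f"p{i}" for i in range(10, 30)}
        cohorts = [
            DiseaseCohort("ORPHA:1", set(), a, 50),
            DiseaseCohort("ORPHA:2", set(), b, 50),
        ]
        (res,) = pairwise_comorbidity(cohorts, persons)
        assert res.table == ((5, 10), (15, 20))
        assert res.p_value == pytest.approx(hypergeom_fisher_p(res.table), rel=1e-9)

    def test_rare_by_complex_pairs_included(self):
        persons = self._persons(40)
        cohorts = [
            DiseaseCohort("ORPHA:1", set(), {"p0", "p1"}, 40),
            DiseaseCohort("ORPHA:2", set(), {"p2"}, 40),
        ]
        results = pairwise_comorbidity(
            cohorts, persons, complex_members={"I10": {"p0", "p3"}}
        )
        labels = {(r.unit_a, r.unit_b) for r in results}
        assert ("ORPHA:1", "I10") in labels and ("ORPHA:2", "I10") in labels


class TestCompareEnrichment:
    def _matrix(self, or_values):
        from rarephenome.comorbidity import EnrichmentResult

        return [
            EnrichmentResult(a, b, ((1, 1), (1, 1)), v, 0.5)
            for (a, b), v in or_values.items()
        ]

    def test_matrix_minus_itself_is_zero(self):
        m = self._matrix({("A", "x"): 2.0, ("A", "y"): 0.5})
        diff = compare_enrichment(m, m)
        assert (diff.or_difference == 0).all()

    def test_hand_built_differences(self):
        a = self._matrix({("A", "x"): 3.0})
        b = self._matrix({("A", "x"): 1.25})
        diff = compare_enrichment(a, b)
        assert diff.or_difference.tolist() == [1.75]

    def test_disjoint_labels_error(self):
        a = self._matrix({("A", "x"): 1.0})
        b = self._matrix({("B", "y"): 1.0})
        with pytest.raises(ValueError, match="label"):
            compare_enrichment(a, b)


def test_complex_disease_members_excludes_rare_categories():
    persons = [
        PersonRecord("p0", Sex.MALE, 50, [("E27.1", DiagnosisRole.PRIMARY),
                                          ("I10", DiagnosisRole.SECONDARY)]),
        PersonRecord("p1", Sex.MALE, 50, [("I10", DiagnosisRole.SECONDARY)]),
    ]
    members = complex_disease_members(persons, {"E271"})
    assert members == {"I10": {"p0", "p1"}}
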