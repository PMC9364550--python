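"""Demographics, sex-bias tests, comorbidity profiles and enrichment.

All 2x2 enrichment questions (sex bias of a disease group, comorbidity
group co-occurrence, disease-pair co-occurrence) are answered with
two-sided Fisher exact tests; odds ratios use the conditional-MLE
convention except for degenerate tables with a zero cell, which report
the sample odds ratio (0 or inf).  Family-wise control is Bonferroni
over the tests actually performed in a batch, with a BH-FDR flag
computed alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohorts import (
    SUPPRESSION_THRESHOLD,
    DiseaseCohort,
    GroupScheme,
    PersonRecord,
    Sex,
    default_group_scheme,
)

logger = logging.getLogger(__name__)


@dataclass
class DemographicSummary:
    orpha: str
    n: int
    percent_male: float | None
    mean_age: float | None
    median_age: float | None

    @property
    def suppressed(self) -> bool:
        return self.n < SUPPRESSION_THRESHOLD


@dataclass
class EnrichmentResult:
    """Outcome of one 2x2 Fisher exact test.

    ``table`` is [[a, b], [c, d]] with unit_a membership on rows and
    unit_b membership on columns.
    """

    unit_a: str
    unit_b: str
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float
    adjusted_significant: bool = False
    fdr_significant: bool = False
    correction: str = "none"


def fisher_test(table) -> tuple[float, float]:
    """Two-sided Fisher exact test: (odds ratio, p).

    The odds ratio is the conditional MLE; tables with a zero cell fall
    back to the sample odds ratio, giving 0 or inf rather than a
    continuity-corrected estimate.
    """
    t = np.asarray(table, dtype=int)
    if t.min() < 0:
        raise ValueError("2x2 table cells must be nonnegative")
    _, p = stats.fisher_exact(t, alternative="two-sided")
    (a, b), (c, d) = t
    if min(a, b, c, d) == 0:
        if a * d == 0 and b * c == 0:
            oddsr = float("nan")
        elif b * c == 0:
            oddsr = float("inf")
        else:
            oddsr = 0.0
    else:
        oddsr = float(stats.contingency.odds_ratio(t, kind="conditional").statistic)
    return oddsr, float(p)


def demographic_summary(cohort: DiseaseCohort, persons: Sequence[PersonRecord]) -> DemographicSummary:
    """Per-disease n, percent male and age statistics.

    An empty cohort yields an n=0 summary; summaries with n below the
    suppression threshold carry values internally but are withheld from
    exports via the ``suppressed`` flag.
    """
    by_id = {p.person_id: p for p in persons}
    members = [by_id[pid] for pid in cohort.members if pid in by_id]
    n = len(members)
    if n == 0:
        return DemographicSummary(cohort.orpha, 0, None, None, None)
    ages = np.array([p.age_at_recruitment for p in members], dtype=float)
    males = sum(1 for p in members if p.sex is Sex.MALE)
    return DemographicSummary(
        cohort.orpha,
        n,
        100.0 * males / n,
        float(ages.mean()),
        float(np.median(ages)),
    )


def sex_bias_test(
    group_members: set[str], persons: Sequence[PersonRecord], label: str = "group"
) -> EnrichmentResult:
    """Fisher test of the group's sex split against the rest of the population."""
    if not group_members:
        raise ValueError("sex_bias_test requires a nonempty group")
    m_in = f_in = m_out = f_out = 0
    for p in persons:
        inside = p.person_id in group_members
        if p.sex is Sex.MALE:
            m_in, m_out = m_in + inside, m_out + (not inside)
        else:
            f_in, f_out = f_in + inside, f_out + (not inside)
    table = ((m_in, f_in), (m_out, f_out))
    oddsr, p = fisher_test(table)
    return EnrichmentResult(label, "sex", table, oddsr, p)


def age_comparisons(
    persons: Sequence[PersonRecord], cohorts: Sequence[DiseaseCohort]
) -> pd.DataFrame:
    """Mann-Whitney age comparisons between rare-disease strata.

    Two comparisons: people with any rare disease against people with
    none, and people with more than one rare disease against people with
    exactly one.  FC is the ratio of medians (first arm over second).
    Empty arms are skipped with a warning.
    """
    per_person: dict[str, set[str]] = {}
    for cohort in cohorts:
        for pid in cohort.members:
            per_person.setdefault(pid, set()).add(cohort.orpha)

    ages = {p.person_id: p.age_at_recruitment for p in persons}
    any_rare = [ages[pid] for pid in per_person if pid in ages]
    none = [ages[pid] for pid in ages if pid not in per_person]
    multi = [ages[pid] for pid, ds in per_person.items() if len(ds) > 1 and pid in ages]
    single = [ages[pid] for pid, ds in per_person.items() if len(ds) == 1 and pid in ages]

    rows = []
    for name, a, b in [
        ("any_rare_vs_none", any_rare, none),
        ("multiple_vs_single", multi, single),
    ]:
        if not a or not b:
            logger.warning("age comparison %s skipped: empty arm", name)
            continue
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        med_a, med_b = float(np.median(a)), float(np.median(b))
        rows.append(
            {
                "comparison": name,
                "n_a": len(a),
                "n_b": len(b),
                "median_a": med_a,
                "median_b": med_b,
                "fold_change": med_a / med_b if med_b else np.inf,
                "p_value": float(p),
            }
        )
    return pd.DataFrame(rows)


def sex_age_correlation(
    summaries: Iterable[DemographicSummary], age_stat: str = "median"
) -> tuple[float, float]:
    """Pearson correlation across diseases of percent male vs age at recruitment.

    ``age_stat`` selects the per-disease age statistic ("median" or
    "mean"); both are reported in exports.  Requires >= 3 non-suppressed
    diseases and non-constant values.
    """
    points = [
        (s.percent_male, s.median_age if age_stat == "median" else s.mean_age)
        for s in summaries
        if not s.suppressed
    ]
    if len(points) < 3:
        raise ValueError("sex/age correlation needs >= 3 non-suppressed diseases")
    x, y = map(np.asarray, zip(*points))
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("sex/age correlation undefined for constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def comorbidity_profile(
    orpha: str,
    cohorts: Mapping[str, DiseaseCohort] | Sequence[DiseaseCohort],
    persons: Sequence[PersonRecord],
    scheme: GroupScheme | None = None,
    suppress: bool = True,
) -> dict[str, float] | None:
    """Percent of a disease's cohort with >= 1 comorbidity in each group.

    The index disease's own ICD-10 codes are removed from each member's
    diagnosis list first; every remaining diagnosis (rare or not) counts
    toward its chapter group.  Returns None for suppressed cohorts when
    ``suppress`` is set.
    """
    scheme = scheme or default_group_scheme()
    if not isinstance(cohorts, Mapping):
        cohorts = {c.orpha: c for c in cohorts}
    cohort = cohorts[orpha]
    if suppress and cohort.suppressed:
        return None
    by_id = {p.person_id: p for p in persons}
    own_codes = cohort.icd10_codes
    counts = {label: 0 for label in scheme.labels}
    n = 0
    for pid in cohort.members:
        person = by_id.get(pid)
        if person is None:
            continue
        n += 1
        groups_hit = set()
        for code in person.codes - own_codes:
            try:
                groups_hit.add(scheme.group_of(code))
            except ValueError:
                logger.warning("diagnosis %s outside the chapter scheme; ignored", code)
        for g in groups_hit:
            counts[g] += 1
    if n == 0:
        return {label: 0.0 for label in scheme.labels}
    return {label: 100.0 * counts[label] / n for label in scheme.labels}


def _apply_corrections(results: list[EnrichmentResult], alpha: float, correction: str) -> None:
    if not results:
        return
    pvals = np.array([r.p_value for r in results])
    bonf = pvals < alpha / len(pvals)
    fdr = multipletests(pvals, alpha=alpha, method="fdr_bh")[0]
    for r, b, f in zip(results, bonf, fdr):
        r.adjusted_significant = bool(b if correction == "bonferroni" else f)
        r.fdr_significant = bool(f)
        r.correction = correction


def enrichment_matrix(
    rare_group_members: Mapping[str, set[str]],
    comorbidity_members: Mapping[str, set[str]],
    background: set[str],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Fisher enrichment of each comorbidity group within each rare-disease group.

    Tests are run inside ``background`` (typically everyone with any rare
    disease): cell a = in rare group and has the comorbidity, etc.
    Bonferroni significance is computed over all cells of the matrix.
    """
    if not background:
        raise ValueError("enrichment_matrix requires a nonempty background")
    results = []
    for g_label, g_members in sorted(rare_group_members.items()):
        g = g_members & background
        for c_label, c_members in sorted(comorbidity_members.items()):
            c = c_members & background
            a = len(g & c)
            b = len(g) - a
            cc = len(c) - a
            d = len(background) - a - b - cc
            oddsr, p = fisher_test(((a, b), (cc, d)))
            results.append(EnrichmentResult(g_label, c_label, ((a, b), (cc, d)), oddsr, p))
    _apply_corrections(results, alpha, "bonferroni")
    return results


def pairwise_comorbidity(
    cohorts: Sequence[DiseaseCohort],
    persons: Sequence[PersonRecord],
    complex_members: Mapping[str, set[str]] | None = None,
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> list[EnrichmentResult]:
    """Co-occurrence tests for rare-disease pairs and rare x complex pairs.

    Each test is a 2x2 Fisher over the full population (has A x has B).
    ``complex_members`` maps a complex-disease label (e.g. a 3-character
    ICD-10 category outside the rare map) to its person set.  The
    correction denominator is the number of tests actually run, recorded
    on each result via the correction flags.
    """
    if len(cohorts) < 2 and not complex_members:
        raise ValueError("pairwise_comorbidity needs >= 2 diseases")
    n_total = len(persons)
    results: list[EnrichmentResult] = []

    def test_pair(label_a, members_a, label_b, members_b):
        a = len(members_a & members_b)
        b = len(members_a) - a
        c = len(members_b) - a
        d = n_total - a - b - c
        oddsr, p = fisher_test(((a, b), (c, d)))
        results.append(EnrichmentResult(label_a, label_b, ((a, b), (c, d)), oddsr, p))

    for i, ca in enumerate(cohorts):
        for cb in cohorts[i + 1 :]:
            test_pair(ca.orpha, ca.members, cb.orpha, cb.members)
    if complex_members:
        for cohort in cohorts:
            for label, members in sorted(complex_members.items()):
                test_pair(cohort.orpha, cohort.members, label, members)
    _apply_corrections(results, alpha, correction)
    return results


def complex_disease_members(
    persons: Sequence[PersonRecord],
    rare_icd10_codes: set[str],
    scheme: GroupScheme | None = None,
    by: str = "category",
) -> dict[str, set[str]]:
    """Person sets for complex (non-rare) diseases.

    A complex disease is any 3-character ICD-10 category not contributing
    to the rare map.  ``by="group"`` pools the categories into chapter
    groups instead.
    """
    scheme = scheme or default_group_scheme()
    rare_categories = {c[:3] for c in rare_icd10_codes}
    members: dict[str, set[str]] = {}
    for person in persons:
        for code in person.codes:
            category = code[:3]
            if category in rare_categories or code in rare_icd10_codes:
                continue
            key = scheme.group_of(category) if by == "group" else category
            members.setdefault(key, set()).add(person.person_id)
    return members


def compare_enrichment(
    matrix_a: Sequence[EnrichmentResult], matrix_b: Sequence[EnrichmentResult]
) -> pd.DataFrame:
    """Elementwise odds-ratio differences between two aligned enrichment matrices."""
    a = {(r.unit_a, r.unit_b): r.odds_ratio for r in matrix_a}
    b = {(r.unit_a, r.unit_b): r.odds_ratio for r in matrix_b}
    if set(a) != set(b):
        missing = sorted(set(a) ^ set(b))
        raise ValueError(f"enrichment matrices are not label-aligned; offending labels: {missing}")
    rows = [
        {"unit_a": ua, "unit_b": ub, "or_difference": a[(ua, ub)] - b[(ua, ub)]}
        for ua, ub in sorted(a)
    ]
    return pd.DataFrame(rows)


def write_enrichment_table(results: Sequence[EnrichmentResult], path) -> None:
    rows = [
        {
            "unit_a": r.unit_a,
            "unit_b": r.unit_b,
            "a": r.table[0][0],
            "b": r.table[0][1],
            "c": r.table[1][0],
            "d": r.table[1][1],
            "odds_ratio": r.odds_ratio,
            "p_value": r.p_value,
            "adjusted_significant": r.adjusted_significant,
            "fdr_significant": r.fdr_significant,
            "correction": r.correction,
            "n_tests": len(results),
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
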