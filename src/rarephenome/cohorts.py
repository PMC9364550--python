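"""Cohort extraction, prevalence estimation, rarity classification, grouping.

A disease cohort is the set of people carrying any of the disease's
ICD-10 codes as a primary or secondary diagnosis.  Prevalence is the
cohort size over the whole study population.  Rarity follows the two
regulatory definitions: the European one (fewer than 1 in 2,000 people)
and the US one (fewer than 200,000 affected nationwide, evaluated by
extrapolating the observed prevalence to the US population).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .codes import normalize_code

logger = logging.getLogger(__name__)

EU_RARE_THRESHOLD = 1 / 2000  # strict: prevalence < 1/2000
US_RARE_AFFECTED = 200_000  # strict: extrapolated affected < 200,000
DEFAULT_US_POPULATION = 330_000_000
SUPPRESSION_THRESHOLD = 5  # person counts below this are suppressed in reports


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class DiagnosisRole(str, Enum):
    PRIMARY = "primary"
    SECONDARY = "secondary"


@dataclass
class PersonRecord:
    person_id: str
    sex: Sex
    age_at_recruitment: float
    diagnoses: list[tuple[str, DiagnosisRole]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.age_at_recruitment < 0:
            raise ValueError(f"person {self.person_id}: negative age")
        self.diagnoses = [(normalize_code(c), DiagnosisRole(r)) for c, r in self.diagnoses]

    @property
    def codes(self) -> set[str]:
        return {c for c, _ in self.diagnoses}


@dataclass
class DiseaseCohort:
    orpha: str
    icd10_codes: set[str]
    members: set[str]
    denominator: int

    @property
    def count(self) -> int:
        return len(self.members)

    @property
    def prevalence(self) -> float:
        return self.count / self.denominator

    @property
    def suppressed(self) -> bool:
        return self.count < SUPPRESSION_THRESHOLD


def extract_cohorts(
    persons: Sequence[PersonRecord],
    orpha_to_icd10: Mapping[str, set[str]],
) -> list[DiseaseCohort]:
    """Build one cohort per ORPHA code; zero-member cohorts are kept.

    Membership is a set: a person with the same code recorded repeatedly,
    or with several of the disease's codes, counts once.  Primary and
    secondary diagnoses both qualify.
    """
    denominator = len(persons)
    code_to_orphas: dict[str, set[str]] = {}
    for orpha, codes in orpha_to_icd10.items():
        for code in codes:
            code_to_orphas.setdefault(normalize_code(code), set()).add(orpha)

    members: dict[str, set[str]] = {orpha: set() for orpha in orpha_to_icd10}
    for person in persons:
        for code in person.codes:
            for orpha in code_to_orphas.get(code, ()):
                members[orpha].add(person.person_id)

    return [
        DiseaseCohort(
            orpha,
            {normalize_code(c) for c in orpha_to_icd10[orpha]},
            members[orpha],
            denominator,
        )
        for orpha in sorted(orpha_to_icd10)
    ]


def classify_rarity(
    cohort: DiseaseCohort,
    denominator: int | None = None,
    us_population: int | None = DEFAULT_US_POPULATION,
) -> tuple[bool, bool | None]:
    """EU and US rarity of a cohort (strict inequalities at both thresholds).

    ``us_rare`` is ``None`` (unknown) when no US population size is given.
    """
    denom = denominator if denominator is not None else cohort.denominator
    if denom <= 0:
        raise ValueError("denominator must be positive")
    prevalence = cohort.count / denom
    eu_rare = prevalence < EU_RARE_THRESHOLD
    if us_population is None:
        return eu_rare, None
    us_rare = prevalence * us_population < US_RARE_AFFECTED
    return eu_rare, us_rare


# ---------------------------------------------------------------------------
# ICD-10 chapter grouping

@dataclass(frozen=True)
class GroupRule:
    start: str  # first 3-character category, inclusive
    end: str  # last 3-character category, inclusive
    label: str


class GroupScheme:
    """Ordered range rules assigning every ICD-10 code to exactly one group."""

    def __init__(self, rules: Sequence[GroupRule]):
        self.rules = list(rules)

    def group_of(self, icd10_code: str) -> str:
        category = normalize_code(icd10_code)[:3]
        for rule in self.rules:
            if rule.start <= category <= rule.end:
                return rule.label
        raise ValueError(f"ICD-10 code {icd10_code!r} falls in no known chapter")

    @property
    def labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for rule in self.rules:
            seen.setdefault(rule.label, None)
        return list(seen)


def default_group_scheme() -> GroupScheme:
    """Chapter-derived disease groups.

    Chapters are merged/split as follows: D80-D89 is split off chapter III
    as Other Immune; mental (V) and nervous-system (VI) chapters combine
    into Neurological; eye (VII) and ear (VIII) into Eye/Ear; pregnancy
    (XV) and perinatal (XVI) into Pregnancy/childbirth; symptoms (XVIII),
    external causes (XX), health-status factors (XXI) and special codes
    (XXII) into Miscellaneous.
    """
    return GroupScheme(
        [
            GroupRule("D80", "D89", "Other Immune"),  # before the wider chapter III range
            GroupRule("A00", "B99", "Infectious/parasitic"),
            GroupRule("C00", "D48", "Neoplasms"),
            GroupRule("D50", "D79", "Blood"),
            GroupRule("E00", "E90", "Endocrine/metabolic"),
            GroupRule("F00", "G99", "Neurological"),
            GroupRule("H00", "H95", "Eye/Ear"),
            GroupRule("I00", "I99", "Circulatory"),
            GroupRule("J00", "J99", "Respiratory"),
            GroupRule("K00", "K93", "Digestive"),
            GroupRule("L00", "L99", "Skin/subcutaneous"),
            GroupRule("M00", "M99", "Musculoskeletal"),
            GroupRule("N00", "N99", "Genitourinary"),
            GroupRule("O00", "P96", "Pregnancy/childbirth"),
            GroupRule("Q00", "Q99", "Congenital"),
            GroupRule("R00", "R99", "Miscellaneous"),
            GroupRule("S00", "T98", "Injury/poisoning"),
            GroupRule("U00", "U99", "Miscellaneous"),
            GroupRule("V01", "Y98", "Miscellaneous"),
            GroupRule("Z00", "Z99", "Miscellaneous"),
        ]
    )


def assign_group(
    icd10_codes: str | Iterable[str],
    scheme: GroupScheme | None = None,
) -> str:
    """Group label of a disease from its ICD-10 code(s).

    For a multi-code disease the lexicographically first code decides; a
    warning is logged when the codes disagree on the group.
    """
    scheme = scheme or default_group_scheme()
    if isinstance(icd10_codes, str):
        codes = [icd10_codes]
    else:
        codes = sorted(normalize_code(c) for c in icd10_codes)
        if not codes:
            raise ValueError("no ICD-10 codes supplied")
    groups = [scheme.group_of(c) for c in codes]
    if len(set(groups)) > 1:
        logger.warning("codes %s span groups %s; using %s", codes, sorted(set(groups)), groups[0])
    return groups[0]


def multi_disease_summary(cohorts: Iterable[DiseaseCohort]) -> tuple[int, int]:
    """(people with >= 1 rare disease, people with > 1 rare disease).

    Counted over distinct ORPHA codes: two codes for the same disease
    contribute one disease.
    """
    per_person: dict[str, set[str]] = {}
    for cohort in cohorts:
        for pid in cohort.members:
            per_person.setdefault(pid, set()).add(cohort.orpha)
    n_any = len(per_person)
    n_multiple = sum(1 for orphas in per_person.values() if len(orphas) > 1)
    return n_any, n_multiple


# ---------------------------------------------------------------------------
# Person-table IO

def read_persons(person_path, diagnosis_path) -> list[PersonRecord]:
    """Read persons (person_id, sex, age) + long-format diagnoses (person_id, icd10, role)."""
    import pandas as pd

    people = pd.read_csv(person_path, sep="\t", dtype={"person_id": str})
    diags = pd.read_csv(diagnosis_path, sep="\t", dtype={"person_id": str, "icd10": str})
    by_person: dict[str, list[tuple[str, DiagnosisRole]]] = {}
    for row in diags.itertuples():
        by_person.setdefault(row.person_id, []).append((row.icd10, DiagnosisRole(row.role)))
    return [
        PersonRecord(
            row.person_id,
            Sex(row.sex),
            float(row.age),
            by_person.get(row.person_id, []),
        )
        for row in people.itertuples()
    ]


def write_persons(persons: Sequence[PersonRecord], person_path, diagnosis_path) -> None:
    import pandas as pd

    from .codes import format_icd

    pd.DataFrame(
        [
            {"person_id": p.person_id, "sex": p.sex.value, "age": p.age_at_recruitment}
            for p in persons
        ]
    ).to_csv(person_path, sep="\t", index=False)
    pd.DataFrame(
        [
            {"person_id": p.person_id, "icd10": format_icd(c), "role": r.value}
            for p in persons
            for c, r in p.diagnoses
        ],
        columns=["person_id", "icd10", "role"],
    ).to_csv(diagnosis_path, sep="\t", index=False)


def write_cohort_table(
    cohorts: Sequence[DiseaseCohort],
    path,
    scheme: GroupScheme | None = None,
    us_population: int | None = DEFAULT_US_POPULATION,
    labels: Mapping[str, str] | None = None,
) -> None:
    """Cohort summary TSV: disease name, ORPHA, ICD-10 set, count, prevalence, rarity, group.

    Counts below the suppression threshold are printed as ``<5``.
    """
    import pandas as pd

    from .codes import format_icd

    scheme = scheme or default_group_scheme()
    rows = []
    for cohort in cohorts:
        eu_rare, us_rare = classify_rarity(cohort, us_population=us_population)
        rows.append(
            {
                "disease_name": (labels or {}).get(cohort.orpha, ""),
                "orpha": cohort.orpha,
                "icd10_codes": ",".join(sorted(format_icd(c) for c in cohort.icd10_codes)),
                "count": "<5" if cohort.suppressed else str(cohort.count),
                "prevalence": "" if cohort.suppressed else f"{cohort.prevalence:.6g}",
                "eu_rare": eu_rare,
                "us_rare": "" if us_rare is None else us_rare,
                "group": assign_group(cohort.icd10_codes, scheme),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
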