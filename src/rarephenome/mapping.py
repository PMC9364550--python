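"""Consensus mapping of ICD-10 codes to ORPHA rare-disease identifiers.

Orphanet links rare-disease (ORPHA) concepts to ICD-10 billing codes, but
many of those links point at ORPHA concepts that are *narrower* than the
ICD-10 code: a patient carrying the ICD-10 code cannot be assumed to have
the rare disease.  This module selects, for each ICD-10 code, a single
ORPHA code that is as specific as possible but no more specific than the
ICD-10 code, and requires a 2-of-3 majority among independent voters
before the assignment enters the final map.  The final map is also
required to be an antichain in the ICD-10 hierarchy: no mapped code may
be an ancestor of another mapped code.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from .codes import CodeHierarchy, format_icd, normalize_code

logger = logging.getLogger(__name__)

N_VOTERS = 3
MAJORITY = 2


class Relation(str, Enum):
    """Specificity of the ORPHA concept relative to the ICD-10 concept."""

    EXACT = "exact"
    ORPHA_BROADER = "orpha_broader"
    ORPHA_NARROWER = "orpha_narrower"
    UNKNOWN = "unknown"


class Verdict(str, Enum):
    ACCEPT = "accept"
    REJECT = "reject"
    ABSTAIN = "abstain"


@dataclass(frozen=True)
class MappingCandidate:
    """One candidate (ICD-10, ORPHA) link, as distributed by an ontology source."""

    icd10: str
    orpha: str
    relation: Relation = Relation.UNKNOWN
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "icd10", normalize_code(self.icd10))
        object.__setattr__(self, "orpha", normalize_code(self.orpha))


@dataclass(frozen=True)
class VoterAssessment:
    """One voter's verdict on one ICD-10 code.

    An *accept* names the ORPHA code the voter endorses for that ICD-10
    code; *reject* means the voter considers no candidate reliable.
    Missing assessments count as abstentions.
    """

    voter_id: str
    icd10: str
    verdict: Verdict
    orpha: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "icd10", normalize_code(self.icd10))
        if self.orpha is not None:
            object.__setattr__(self, "orpha", normalize_code(self.orpha))
        if self.verdict is Verdict.ACCEPT and self.orpha is None:
            raise ValueError("an accept verdict must name an ORPHA code")


@dataclass
class ConsensusMapEntry:
    """A finalized (or flagged-and-excluded) ICD-10 -> ORPHA assignment."""

    icd10: str
    orpha: str | None
    votes_for: int = 0
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.icd10 = normalize_code(self.icd10)
        if self.orpha is not None:
            self.orpha = normalize_code(self.orpha)

    @property
    def mapped(self) -> bool:
        return not self.flags and self.orpha is not None


def classify_specificity(
    candidate: MappingCandidate,
    icd10_hierarchy: CodeHierarchy,
    orpha_hierarchy: CodeHierarchy,
    all_candidates: Sequence[MappingCandidate] | None = None,
) -> Relation:
    """Infer how specific an ORPHA concept is relative to its ICD-10 code.

    An explicit relation flag on the candidate always wins: ontology
    distributors ship these flags and the hierarchy extract may be
    incomplete.  Without a flag, the relation is inferred from where else
    in the ICD-10 hierarchy the same ORPHA code attaches:

    * identical normalized codes or identical labels -> ``exact``;
    * the ORPHA code also attaches to a strict *descendant* of this
      ICD-10 code -> the ORPHA concept is at least as narrow as that
      descendant, hence ``orpha_narrower`` here;
    * the ORPHA code also attaches to a strict *ancestor* (and to no
      descendant) -> ``orpha_broader``;
    * otherwise ``unknown``.  Unknown codes never raise.
    """
    if candidate.relation is not Relation.UNKNOWN:
        return candidate.relation
    icd, orp = candidate.icd10, candidate.orpha
    if icd == orp:
        return Relation.EXACT
    if icd in icd10_hierarchy and orp in orpha_hierarchy:
        li = icd10_hierarchy.label(icd).strip().casefold()
        lo = orpha_hierarchy.label(orp).strip().casefold()
        if li and li == lo:
            return Relation.EXACT
    if all_candidates and icd in icd10_hierarchy:
        attached = {c.icd10 for c in all_candidates if c.orpha == orp}
        if any(icd10_hierarchy.is_ancestor(icd, other) for other in attached):
            return Relation.ORPHA_NARROWER
        if any(icd10_hierarchy.is_ancestor(other, icd) for other in attached):
            return Relation.ORPHA_BROADER
    return Relation.UNKNOWN


def _more_specific(a: str, b: str, orpha_hierarchy: CodeHierarchy) -> bool:
    """True when ORPHA ``a`` is a strict descendant of ``b`` (a narrower concept)."""
    return orpha_hierarchy.is_ancestor(b, a)


def select_consensus(
    candidates: Iterable[MappingCandidate],
    assessments: Iterable[VoterAssessment],
    icd10_hierarchy: CodeHierarchy,
    orpha_hierarchy: CodeHierarchy,
) -> list[ConsensusMapEntry]:
    """Choose at most one ORPHA code per ICD-10 code by specificity + majority.

    Per ICD-10 code the eligible pool is every candidate whose relation is
    not ``orpha_narrower`` (a narrower ORPHA concept would over-diagnose
    carriers of the broader ICD-10 code).  Exact candidates outrank the
    rest; otherwise the most specific eligible candidate (deepest in the
    ORPHA hierarchy) is chosen.  Two or more maximally specific distinct
    candidates yield an ``ambiguous`` entry, excluded from the final map.
    The chosen ORPHA code then needs accepts from at least 2 of the 3
    voters; short of a majority the entry is flagged ``manual_review`` and
    likewise excluded.  Codes with no eligible candidate are absent from
    the output entirely.

    Duplicate (icd10, orpha) candidate rows are deduplicated with a
    warning; conflicting relation flags on duplicates keep the first row.
    """
    all_candidates = list(candidates)
    seen: set[tuple[str, str]] = set()
    deduped: list[MappingCandidate] = []
    for cand in all_candidates:
        key = (cand.icd10, cand.orpha)
        if key in seen:
            logger.warning("duplicate candidate row %s -> %s dropped", *key)
            continue
        seen.add(key)
        deduped.append(cand)

    accepts: dict[str, dict[str, set[str]]] = defaultdict(lambda: defaultdict(set))
    for assessment in assessments:
        if assessment.verdict is Verdict.ACCEPT:
            accepts[assessment.icd10][assessment.orpha].add(assessment.voter_id)

    by_icd10: dict[str, list[MappingCandidate]] = defaultdict(list)
    for cand in deduped:
        by_icd10[cand.icd10].append(cand)

    entries: list[ConsensusMapEntry] = []
    for icd10 in sorted(by_icd10):
        pool = [
            c
            for c in by_icd10[icd10]
            if classify_specificity(c, icd10_hierarchy, orpha_hierarchy, deduped)
            is not Relation.ORPHA_NARROWER
        ]
        if not pool:
            continue
        exacts = [
            c
            for c in pool
            if classify_specificity(c, icd10_hierarchy, orpha_hierarchy, deduped)
            is Relation.EXACT
        ]
        if exacts:
            pool = exacts
        # maximal elements of the "more specific" partial order
        maximal = [
            c
            for c in pool
            if not any(
                _more_specific(other.orpha, c.orpha, orpha_hierarchy)
                for other in pool
                if other.orpha != c.orpha
            )
        ]
        chosen_orphas = {c.orpha for c in maximal}
        if len(chosen_orphas) > 1:
            entries.append(ConsensusMapEntry(icd10, None, 0, {"ambiguous"}))
            continue
        orpha = chosen_orphas.pop()
        votes = len(accepts[icd10][orpha])
        if votes >= MAJORITY:
            entries.append(ConsensusMapEntry(icd10, orpha, votes))
        else:
            entries.append(ConsensusMapEntry(icd10, orpha, votes, {"manual_review"}))
    return entries


def final_map(entries: Iterable[ConsensusMapEntry]) -> dict[str, str]:
    """The unflagged portion of a consensus output: icd10 -> orpha."""
    return {e.icd10: e.orpha for e in entries if e.mapped}


def validate_antichain(
    entries: Iterable[ConsensusMapEntry], icd10_hierarchy: CodeHierarchy
) -> list[tuple[str, str]]:
    """Every (ancestor, descendant) pair among the mapped ICD-10 codes.

    An empty list certifies the map: no mapped code subsumes another, so
    cohort definitions never double-count along the hierarchy.
    """
    mapped = sorted(final_map(entries))
    violations = []
    for a in mapped:
        for b in mapped:
            if a != b and icd10_hierarchy.is_ancestor(a, b):
                violations.append((a, b))
    return violations


def invert_map(entries: Iterable[ConsensusMapEntry]) -> dict[str, set[str]]:
    """Invert a consensus map to orpha -> set of ICD-10 codes."""
    inverted: dict[str, set[str]] = defaultdict(set)
    for icd10, orpha in final_map(entries).items():
        inverted[orpha].add(icd10)
    return dict(inverted)


# ---------------------------------------------------------------------------
# TSV interfaces

def read_candidates(path) -> list[MappingCandidate]:
    """Read a candidate-mapping TSV with columns icd10, orpha, relation, source."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return [
        MappingCandidate(
            row.icd10,
            row.orpha,
            Relation(row.relation) if row.relation else Relation.UNKNOWN,
            row.source,
        )
        for row in df.itertuples()
    ]


def read_assessments(path) -> list[VoterAssessment]:
    """Read a voter TSV with columns voter_id, icd10, verdict, orpha."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return [
        VoterAssessment(row.voter_id, row.icd10, Verdict(row.verdict), row.orpha or None)
        for row in df.itertuples()
    ]


def write_consensus_map(entries: Iterable[ConsensusMapEntry], path) -> None:
    import pandas as pd

    rows = [
        {
            "icd10": format_icd(e.icd10),
            "orpha": e.orpha or "",
            "votes_for": e.votes_for,
            "flags": ",".join(sorted(e.flags)),
        }
        for e in entries
    ]
    pd.DataFrame(rows, columns=["icd10", "orpha", "votes_for", "flags"]).to_csv(
        path, sep="\t", index=False
    )


def read_consensus_map(path) -> list[ConsensusMapEntry]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"icd10": str, "orpha": str}).fillna("")
    return [
        ConsensusMapEntry(
            normalize_code(row.icd10),
            normalize_code(row.orpha) or None,
            int(row.votes_for),
            set(str(row.flags).split(",")) - {""},
        )
        for row in df.itertuples()
    ]
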