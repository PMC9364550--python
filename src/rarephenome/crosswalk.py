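"""ICD-10 -> ICD-9 crosswalking through General Equivalence Mappings (GEMs).

The CMS General Equivalence Mappings are whitespace-delimited flat files:
source code, target code, and a five-digit flag field whose digits mean,
in order: approximate, no-map, combination, scenario, choice list.  A
disease (ORPHA code) is carried over to ICD-9 only when *every one* of
its ICD-10 codes has at least one clean equivalence — not approximate,
not a no-map placeholder, and not a combination entry — so that the
ICD-9 cohort definition is exactly as strict as the ICD-10 one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .codes import normalize_code


class GemsParseError(ValueError):
    pass


@dataclass(frozen=True)
class GemsRecord:
    source_code: str  # ICD-10
    target_code: str  # ICD-9
    approximate: bool
    no_map: bool
    combination: bool
    scenario: int
    choice_list: int

    @property
    def clean(self) -> bool:
        """A one-to-one equivalence usable for cohort transfer."""
        return not (self.approximate or self.no_map or self.combination)


def parse_gems(lines: Iterable[str]) -> list[GemsRecord]:
    """Parse GEMs flat-file lines into records.

    Blank lines are ignored.  A malformed flag field (not exactly five
    digits) raises :class:`GemsParseError` naming the offending line.
    """
    records = []
    for lineno, line in enumerate(lines, start=1):
        parts = line.split()
        if not parts:
            continue
        if len(parts) != 3:
            raise GemsParseError(f"line {lineno}: expected 3 fields, got {len(parts)}: {line!r}")
        source, target, flags = parts
        if len(flags) != 5 or not flags.isdigit():
            raise GemsParseError(f"line {lineno}: flag field {flags!r} is not 5 digits")
        records.append(
            GemsRecord(
                source_code=normalize_code(source),
                target_code=normalize_code(target),
                approximate=flags[0] == "1",
                no_map=flags[1] == "1",
                combination=flags[2] == "1",
                scenario=int(flags[3]),
                choice_list=int(flags[4]),
            )
        )
    return records


@dataclass
class ExcludedDisease:
    orpha: str
    reason: str


def derive_icd9_map(
    orpha_to_icd10: Mapping[str, set[str]],
    gems_records: Iterable[GemsRecord],
) -> tuple[dict[str, set[str]], list[ExcludedDisease]]:
    """Convert an ORPHA -> ICD-10 map to ORPHA -> ICD-9 via clean GEMs rows.

    Returns the retained mapping plus the excluded diseases with reasons.
    A disease is retained iff every ICD-10 member code has >= 1 clean GEMs
    record; its ICD-9 set is the union of those records' targets.  An
    ICD-10 code entirely absent from the GEMs file counts as no-map.
    """
    clean_targets: dict[str, set[str]] = {}
    seen_sources: set[str] = set()
    for rec in gems_records:
        seen_sources.add(rec.source_code)
        if rec.clean:
            clean_targets.setdefault(rec.source_code, set()).add(rec.target_code)

    retained: dict[str, set[str]] = {}
    excluded: list[ExcludedDisease] = []
    for orpha, icd10_codes in orpha_to_icd10.items():
        codes = {normalize_code(c) for c in icd10_codes}
        bad = []
        for code in sorted(codes):
            if code not in seen_sources:
                bad.append(f"{code}: absent from GEMs (treated as no-map)")
            elif code not in clean_targets:
                bad.append(f"{code}: only approximate/no-map/combination equivalences")
        if bad:
            excluded.append(ExcludedDisease(orpha, "; ".join(bad)))
        else:
            retained[orpha] = set().union(*(clean_targets[c] for c in sorted(codes)))
    return retained, excluded


def write_icd9_map(
    retained: Mapping[str, set[str]],
    orpha_to_icd10: Mapping[str, set[str]],
    path,
) -> None:
    """Write the crosswalk as TSV: orpha, icd9_codes, icd10_codes."""
    import pandas as pd

    from .codes import format_icd

    rows = [
        {
            "orpha": orpha,
            "icd9_codes": ",".join(sorted(format_icd(c) for c in icd9s)),
            "icd10_codes": ",".join(sorted(format_icd(c) for c in orpha_to_icd10[orpha])),
        }
        for orpha, icd9s in sorted(retained.items())
    ]
    pd.DataFrame(rows, columns=["orpha", "icd9_codes", "icd10_codes"]).to_csv(
        path, sep="\t", index=False
    )
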