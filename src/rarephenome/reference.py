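"""Packaged reference tables and recomputations over them.

``variant_associations.tsv`` is a curated transcription of the published
Bonferroni-significant variant-level rare-disease associations from a
large population-biobank exome screen (one row per disease/variant pair,
with the reported p-value, case minor-allele count, number of cases,
percent of carriers affected, control MAF, ACMG/AMP class, and whether
the association was previously reported as pathogenic in ClinVar for
that disease).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

def load_variant_associations() -> pd.DataFrame:
    """The curated table of significant variant-level associations."""
    path = resources.files("rarephenome") / "data" / "variant_associations.tsv"
    with path.open() as fh:
        return pd.read_csv(fh, sep="\t")


def reported_fraction(table: pd.DataFrame | None = None) -> tuple[int, int, float]:
    """Recount how many significant associations were previously reported.

    Returns ``(n_reported, n_total, percent)`` over the variant-level
    association table's ClinVar "reported" column.
    """
    if table is None:
        table = load_variant_associations()
    n_total = len(table)
    n_reported = int((table["reported"].str.strip().str.lower() == "yes").sum())
    return n_reported, n_total, 100.0 * n_reported / n_total
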