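"""End-to-end orchestration: simulate -> map -> crosswalk -> cohorts -> stats.

Every run writes its stage outputs as plain-text tables plus a JSON
manifest recording the seed, the configuration digest, and a SHA-256
digest of every artifact, so identical config + seed reproduces
byte-identical outputs and every file is traceable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import assoc, cohorts as cohorts_mod, comorbidity, crosswalk, mapping, simulate
from .codes import format_icd, normalize_code

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunManifest:
    seed: int
    config_digest: str
    version: str = "0.1.0"
    stages: list[dict[str, Any]] = field(default_factory=list)

    def record(self, stage: str, outputs: dict[str, Path]) -> None:
        self.stages.append(
            {
                "stage": stage,
                "outputs": {
                    name: {"path": str(p), "sha256": _digest(p)} for name, p in outputs.items()
                },
            }
        )

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: simulate.SimConfig, outdir: str | Path) -> dict[str, Any]:
    """Run every stage on a synthetic study; returns the in-memory results.

    Stage order: ontology/consensus map -> GEMs crosswalk -> cohort
    extraction and rarity -> demographics and comorbidity enrichment ->
    rare-variant association.  A stage failure raises ``StageError``
    naming the stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_digest = hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = RunManifest(seed=config.seed, config_digest=cfg_digest)
    results: dict[str, Any] = {"config": config}

    def stage(name):
        def wrap(fn):
            t0 = time.monotonic()
            try:
                out = fn()
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s finished in %.2fs", name, time.monotonic() - t0)
            return out

        return wrap

    # --- consensus mapping
    def _map():
        ontology = simulate.gen_ontology_and_votes(config)
        entries = mapping.select_consensus(
            ontology.candidates,
            ontology.assessments,
            ontology.icd10_hierarchy,
            ontology.orpha_hierarchy,
        )
        violations = mapping.validate_antichain(entries, ontology.icd10_hierarchy)
        if violations:
            raise ValueError(f"consensus map violates the antichain rule: {violations}")
        map_path = outdir / "consensus_map.tsv"
        mapping.write_consensus_map(entries, map_path)
        manifest.record("map", {"consensus_map": map_path})
        return ontology, entries

    ontology, entries = stage("map")(_map)
    results["ontology"] = ontology
    results["consensus_entries"] = entries
    orpha_to_icd10 = mapping.invert_map(entries)
    results["orpha_to_icd10"] = orpha_to_icd10

    # --- ICD-9 crosswalk
    def _crosswalk():
        lines, _ = simulate.gen_gems_lines(config)
        records = crosswalk.parse_gems(lines)
        retained, excluded = crosswalk.derive_icd9_map(orpha_to_icd10, records)
        path = outdir / "icd9_map.tsv"
        crosswalk.write_icd9_map(retained, orpha_to_icd10, path)
        manifest.record("crosswalk", {"icd9_map": path})
        return retained, excluded

    results["icd9_map"], results["icd9_excluded"] = stage("crosswalk")(_crosswalk)

    # --- cohorts
    def _cohorts():
        population = simulate.gen_population(config)
        cohort_list = cohorts_mod.extract_cohorts(population.persons, orpha_to_icd10)
        persons_path = outdir / "persons.tsv"
        diag_path = outdir / "diagnoses.tsv"
        cohorts_mod.write_persons(population.persons, persons_path, diag_path)
        table_path = outdir / "cohorts.tsv"
        cohorts_mod.write_cohort_table(cohort_list, table_path)
        manifest.record(
            "cohorts", {"persons": persons_path, "diagnoses": diag_path, "cohorts": table_path}
        )
        return population, cohort_list

    population, cohort_list = stage("cohorts")(_cohorts)
    results["population"] = population
    results["cohorts"] = cohort_list

    # --- demographics + comorbidity
    def _demog():
        persons = population.persons
        scheme = cohorts_mod.default_group_scheme()
        summaries = [comorbidity.demographic_summary(c, persons) for c in cohort_list]
        ages = comorbidity.age_comparisons(persons, cohort_list)

        rare_codes = set().union(*orpha_to_icd10.values()) if orpha_to_icd10 else set()
        group_members: dict[str, set[str]] = {}
        for cohort in cohort_list:
            label = cohorts_mod.assign_group(cohort.icd10_codes, scheme)
            group_members.setdefault(label, set()).update(cohort.members)
        background = set().union(*group_members.values()) if group_members else set()
        complex_by_group = comorbidity.complex_disease_members(
            persons, rare_codes, scheme, by="group"
        )
        matrix = comorbidity.enrichment_matrix(group_members, complex_by_group, background)
        complex_by_cat = comorbidity.complex_disease_members(persons, rare_codes, scheme)
        pairs = comorbidity.pairwise_comorbidity(cohort_list, persons, complex_by_cat)

        demog_path = outdir / "demographics.tsv"
        pd.DataFrame(
            [
                {
                    "orpha": s.orpha,
                    "n": s.n,
                    "percent_male": None if s.suppressed else s.percent_male,
                    "mean_age": None if s.suppressed else s.mean_age,
                    "median_age": None if s.suppressed else s.median_age,
                    "suppressed": s.suppressed,
                }
                for s in summaries
            ]
        ).to_csv(demog_path, sep="\t", index=False)
        ages_path = outdir / "age_comparisons.tsv"
        ages.to_csv(ages_path, sep="\t", index=False)
        matrix_path = outdir / "group_enrichment.tsv"
        comorbidity.write_enrichment_table(matrix, matrix_path)
        pairs_path = outdir / "pairwise_comorbidity.tsv"
        comorbidity.write_enrichment_table(pairs, pairs_path)
        manifest.record(
            "demographics",
            {
                "demographics": demog_path,
                "age_comparisons": ages_path,
                "group_enrichment": matrix_path,
                "pairwise_comorbidity": pairs_path,
            },
        )
        return summaries, ages, matrix, pairs

    (
        results["demographics"],
        results["age_comparisons"],
        results["group_enrichment"],
        results["pairwise_comorbidity"],
    ) = stage("demographics")(_demog)

    # --- association
    def _assoc():
        sim_geno = simulate.gen_genotypes(config, population)
        all_results = []
        by_id = {c.orpha: c for c in cohort_list}
        for spec in config.causal_variants:
            orpha = normalize_code(spec.orpha)
            cohort = by_id.get(orpha)
            if cohort is None or cohort.count < assoc.CASE_MAC_MIN:
                continue
            variant_results = assoc.adjust_significance(
                assoc.variant_level_tests(
                    sim_geno.genotypes, sim_geno.annotations, cohort.members, orpha
                )
            )
            gene_results = assoc.adjust_significance(
                assoc.gene_burden_test(
                    sim_geno.genotypes, sim_geno.annotations, cohort.members, orpha
                )
            )
            lof_results = assoc.adjust_significance(
                assoc.lof_subset_analysis(
                    sim_geno.genotypes, sim_geno.annotations, cohort.members, orpha
                )
            )
            all_results += variant_results + gene_results + lof_results
        path = outdir / "associations.tsv"
        assoc.results_table(all_results).to_csv(path, sep="\t", index=False)
        manifest.record("association", {"associations": path})
        return sim_geno, all_results

    results["genotypes"], results["assoc_results"] = stage("association")(_assoc)

    manifest.write(outdir / "manifest.json")
    results["manifest"] = manifest
    return results


def export_disease_bundle(
    orpha: str,
    cohort_list: list,
    persons: list,
    labels: dict[str, str] | None = None,
) -> dict[str, Any]:
    """JSON-ready record for one disease, for the interactive table export.

    Demographic and comorbidity fields are omitted entirely for
    suppressed cohorts (fewer than five people); the bundle never
    contains person-level identifiers.
    """
    orpha = normalize_code(orpha)
    by_id = {c.orpha: c for c in cohort_list}
    if orpha not in by_id:
        raise KeyError(f"unknown disease {orpha!r}")
    cohort = by_id[orpha]
    eu_rare, us_rare = cohorts_mod.classify_rarity(cohort)
    bundle: dict[str, Any] = {
        "name": (labels or {}).get(orpha, ""),
        "orpha": orpha,
        "icd10_codes": sorted(format_icd(c) for c in cohort.icd10_codes),
        "count": "<5" if cohort.suppressed else cohort.count,
        "group": cohorts_mod.assign_group(cohort.icd10_codes),
        "prevalence": None if cohort.suppressed else cohort.prevalence,
        "eu_rare": eu_rare,
        "us_rare": us_rare,
    }
    if not cohort.suppressed:
        summary = comorbidity.demographic_summary(cohort, persons)
        bundle["demographics"] = {
            "n": summary.n,
            "percent_male": summary.percent_male,
            "mean_age": summary.mean_age,
            "median_age": summary.median_age,
        }
        profile = comorbidity.comorbidity_profile(orpha, cohort_list, persons)
        bundle["comorbidity_percentages"] = profile
    return bundle
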