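"""Synthetic study generator with planted ground truth.

Emits every input the pipeline consumes — a code ontology with noisy
mapping candidates and three imperfect voters, GEMs-style equivalence
rows, a person-level diagnosis table with configured per-disease
prevalence / sex bias / age shifts / comorbidity links, and a rare
genotype matrix with planted causal variants under extreme case/control
imbalance — so that every stage can be validated against known truth
without any external download.

The population emulates a middle-aged volunteer cohort: recruitment ages
are drawn uniformly on 40-69 (the design of the large UK population
biobank this kind of pipeline targets), disease prevalences sit in the
rare range (1e-4 .. 1e-3) with one deliberately non-rare disease to
exercise the rarity boundary, and comorbidity links multiply the odds of
a complex-disease code among carriers of a linked rare disease (the
shared Bernoulli factor *is* the disease indicator, the simplest latent
structure with a tunable odds ratio).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codes import CodeHierarchy, CodeNode, System, normalize_code
from .cohorts import DiagnosisRole, PersonRecord, Sex
from .mapping import MappingCandidate, Relation, Verdict, VoterAssessment
from .assoc import Impact, VariantAnnotation


@dataclass(frozen=True)
class DiseaseSpec:
    """One planted rare disease."""

    orpha: str
    icd10_codes: tuple[str, ...]
    prevalence: float
    sex_bias_or: float = 1.0  # odds of disease in males over females
    age_shift: float = 0.0  # years added to affected members' recruitment age

    def __post_init__(self) -> None:
        if not 0 <= self.prevalence <= 1:
            raise ValueError(f"{self.orpha}: prevalence outside [0,1]")
        if self.sex_bias_or <= 0:
            raise ValueError(f"{self.orpha}: sex bias OR must be positive")


@dataclass(frozen=True)
class ComorbidityLink:
    """Odds multiplier for a complex-disease code among a rare disease's cases."""

    orpha: str
    complex_code: str
    odds_ratio: float


@dataclass(frozen=True)
class CausalVariantSpec:
    orpha: str
    odds_ratio: float = 8.0
    maf: float = 0.005


@dataclass
class SimConfig:
    """Full configuration of one synthetic study; the seed is mandatory."""

    seed: int
    n_persons: int = 40_000
    diseases: tuple[DiseaseSpec, ...] = ()
    voter_error_rates: tuple[float, float, float] = (0.05, 0.05, 0.02)
    decoy_candidate_rate: float = 0.5  # chance of an extra too-narrow candidate per code
    n_decoy_icd10: int = 6  # ICD-10 codes whose only candidates are too narrow
    complex_code_rate: float = 0.03  # baseline per-person rate of each complex code
    comorbidity_links: tuple[ComorbidityLink, ...] = ()
    gems_approximate_fraction: float = 0.25
    n_variants: int = 200
    maf_range: tuple[float, float] = (0.001, 0.01)
    causal_variants: tuple[CausalVariantSpec, ...] = ()
    genotype_missing_rate: float = 0.01
    variants_per_gene: int = 5

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if len(self.voter_error_rates) != 3:
            raise ValueError("exactly three voter error rates required")
        for e in self.voter_error_rates:
            if not 0 <= e <= 1:
                raise ValueError("voter error rates must lie in [0,1]")
        if not self.diseases:
            self.diseases = default_disease_panel()

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one stage, derived from the master seed."""
        return np.random.default_rng([int(self.seed) % (2**31), stream])

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "diseases" in d:
            d["diseases"] = tuple(DiseaseSpec(**s) for s in d["diseases"])
        if "comorbidity_links" in d:
            d["comorbidity_links"] = tuple(ComorbidityLink(**s) for s in d["comorbidity_links"])
        if "causal_variants" in d:
            d["causal_variants"] = tuple(CausalVariantSpec(**s) for s in d["causal_variants"])
        for key in ("voter_error_rates", "maf_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


# Complex (non-rare) comorbidity codes available to the generator, spread
# over chapter groups; their 3-character categories never collide with the
# rare panel below.
COMPLEX_CODES = ("E11.9", "I10", "J45.0", "K21.0", "M54.5", "F32.9", "C44.9", "N39.0")


def default_disease_panel() -> tuple[DiseaseSpec, ...]:
    """A small panel spanning chapter groups, sex biases and age shifts.

    Prevalences sit around the rare range; the last entry is planted
    above the European 1/2,000 threshold to exercise the rarity boundary,
    and one disease owns three sibling ICD-10 codes to exercise
    many-to-one mapping.
    """
    return (
        DiseaseSpec("ORPHA:85138", ("E27.1",), 4.8e-4),
        DiseaseSpec("ORPHA:33226", ("C88.0",), 2.2e-4, sex_bias_or=1.8, age_shift=4.0),
        DiseaseSpec("ORPHA:558", ("Q87.4",), 1.9e-4),
        DiseaseSpec("ORPHA:848", ("D56.1",), 1.4e-4),
        DiseaseSpec("ORPHA:389", ("C96.0", "C96.5", "C96.6"), 1.0e-4),
        DiseaseSpec("ORPHA:3096", ("G93.7",), 6e-5, age_shift=-6.0),
        DiseaseSpec("ORPHA:797", ("D86.0",), 6.5e-4, sex_bias_or=0.6),
        DiseaseSpec("ORPHA:3002", ("D69.3",), 3.6e-4),
        DiseaseSpec("ORPHA:729", ("M35.7",), 1.5e-3, sex_bias_or=0.5),  # non-rare by design
    )


def default_config(seed: int) -> SimConfig:
    """Study defaults: panel above, one planted comorbidity link and one causal variant.

    The causal variant is attached to the panel's most prevalent disease
    so the default population yields enough cases for the minor-allele
    count filters to be exercised.
    """
    return SimConfig(
        seed=seed,
        comorbidity_links=(ComorbidityLink("ORPHA:3002", "C44.9", 3.0),),
        causal_variants=(CausalVariantSpec("ORPHA:729", odds_ratio=8.0, maf=0.01),),
    )


def assoc_study_config(
    seed: int,
    n_persons: int = 50_000,
    case_prevalence: float = 0.01,
    odds_ratio: float = 8.0,
    maf: float = 0.005,
    n_variants: int = 50,
) -> SimConfig:
    """Single-disease configuration for the association calibration studies.

    One phenotype at 1% prevalence in a 50,000-person cohort — the
    unbalanced-but-testable regime the variant filters target — with one
    planted causal variant at the given odds ratio and MAF.  Setting
    ``odds_ratio=1`` yields a pure null study.
    """
    causal: tuple[CausalVariantSpec, ...] = (
        CausalVariantSpec("ORPHA:901000", odds_ratio=odds_ratio, maf=maf),
    )
    return SimConfig(
        seed=seed,
        n_persons=n_persons,
        diseases=(DiseaseSpec("ORPHA:901000", ("E88.8",), case_prevalence),),
        n_variants=n_variants,
        causal_variants=causal,
    )


# ---------------------------------------------------------------------------
# Ontology + votes

@dataclass
class SimOntology:
    icd10_hierarchy: CodeHierarchy
    orpha_hierarchy: CodeHierarchy
    candidates: list[MappingCandidate]
    assessments: list[VoterAssessment]
    truth_map: dict[str, str]  # icd10 -> orpha


VOTER_IDS = ("voter1", "voter2", "voter3")


def gen_ontology_and_votes(config: SimConfig) -> SimOntology:
    """Hierarchies, candidate mappings, three voter files, and the truth map.

    The truth map pairs each disease's (leaf) ICD-10 codes with its ORPHA
    code via exact-relation candidates; only leaves are mapped, so the
    truth satisfies the antichain rule by construction.  Noise comes from
    decoy candidates flagged as too narrow (subtypes of the true ORPHA
    concept) and from voters who, at their configured error rate, either
    reject a true pair or endorse a decoy.
    """
    rng = config.rng(1)
    icd_nodes: dict[str, CodeNode] = {}
    orpha_nodes: dict[str, CodeNode] = {}
    candidates: list[MappingCandidate] = []
    truth_map: dict[str, str] = {}

    def ensure_icd(code: str, label: str = "") -> None:
        norm = normalize_code(code)
        category = norm[:3]
        if category not in icd_nodes:
            icd_nodes[category] = CodeNode(System.ICD10, category, f"category {category}")
        if norm != category and norm not in icd_nodes:
            icd_nodes[norm] = CodeNode(System.ICD10, norm, label, parents=[category])

    for disease in config.diseases:
        orpha = normalize_code(disease.orpha)
        orpha_nodes.setdefault(orpha, CodeNode(System.ORPHA, orpha, f"disease {orpha}"))
        for icd in disease.icd10_codes:
            ensure_icd(icd, f"condition {icd}")
            truth_map[normalize_code(icd)] = orpha
            candidates.append(
                MappingCandidate(icd, orpha, Relation.EXACT, source="ontology")
            )
            if rng.random() < config.decoy_candidate_rate:
                decoy = f"{orpha}9"
                orpha_nodes.setdefault(
                    decoy, CodeNode(System.ORPHA, decoy, f"subtype of {orpha}", parents=[orpha])
                )
                candidates.append(
                    MappingCandidate(icd, decoy, Relation.ORPHA_NARROWER, source="ontology")
                )

    # ICD-10 codes whose only candidates are narrower ORPHA concepts: the
    # broad-code trap the consensus must leave unmapped.
    for i in range(config.n_decoy_icd10):
        icd = f"L{50 + i}.1"
        ensure_icd(icd, f"broad condition {icd}")
        decoy = f"ORPHA:9{i:03d}"
        parent = f"ORPHA:8{i:03d}"
        orpha_nodes.setdefault(parent, CodeNode(System.ORPHA, parent, f"family {parent}"))
        orpha_nodes.setdefault(
            decoy, CodeNode(System.ORPHA, decoy, f"rare subtype {decoy}", parents=[parent])
        )
        candidates.append(MappingCandidate(icd, decoy, Relation.ORPHA_NARROWER, source="ontology"))

    assessments: list[VoterAssessment] = []
    decoy_for = {c.icd10: c.orpha for c in candidates if c.relation is Relation.ORPHA_NARROWER}
    for icd, orpha in sorted(truth_map.items()):
        for voter, err in zip(VOTER_IDS, config.voter_error_rates):
            if rng.random() >= err:
                assessments.append(VoterAssessment(voter, icd, Verdict.ACCEPT, orpha))
            elif icd in decoy_for and rng.random() < 0.5:
                assessments.append(VoterAssessment(voter, icd, Verdict.ACCEPT, decoy_for[icd]))
            else:
                assessments.append(VoterAssessment(voter, icd, Verdict.REJECT))

    return SimOntology(
        CodeHierarchy(System.ICD10, icd_nodes.values()),
        CodeHierarchy(System.ORPHA, orpha_nodes.values()),
        candidates,
        assessments,
        truth_map,
    )


# ---------------------------------------------------------------------------
# GEMs equivalences

def gen_gems_lines(config: SimConfig) -> tuple[list[str], dict[str, str]]:
    """GEMs-style flat-file lines for every mapped ICD-10 code.

    A configured fraction of codes get only an approximate equivalence
    (their diseases must be excluded downstream); the rest get one clean
    ICD-9 target.  Returns the lines plus the clean-target truth.
    """
    rng = config.rng(2)
    lines: list[str] = []
    clean_targets: dict[str, str] = {}
    counter = 100
    for disease in config.diseases:
        for icd in disease.icd10_codes:
            norm = normalize_code(icd)
            icd9 = f"{counter}0"
            counter += 1
            if rng.random() < config.gems_approximate_fraction:
                lines.append(f"{norm} {icd9} 10000")
            else:
                lines.append(f"{norm} {icd9} 00000")
                clean_targets[norm] = icd9
    return lines, clean_targets


# ---------------------------------------------------------------------------
# Population

@dataclass
class SimPopulation:
    persons: list[PersonRecord]
    truth_memberships: dict[str, set[str]]  # orpha -> person ids


def _sex_split_probabilities(prevalence: float, odds_ratio: float) -> tuple[float, float]:
    """Per-sex disease probabilities whose average is the target prevalence.

    For the rare prevalences used here risks approximate odds, so the
    male/female risk ratio is taken equal to the configured odds ratio.
    """
    p_female = 2 * prevalence / (1 + odds_ratio)
    p_male = odds_ratio * p_female
    return min(p_male, 1.0), min(p_female, 1.0)


def gen_population(config: SimConfig) -> SimPopulation:
    """Person records with planted cohorts, sex bias, age shifts, comorbidities."""
    total = sum(d.prevalence for d in config.diseases)
    if total > 1:
        raise ValueError(f"summed disease prevalence {total:.3f} exceeds 1")
    rng = config.rng(3)
    n = config.n_persons
    ids = np.array([f"P{i:07d}" for i in range(n)])
    is_male = rng.random(n) < 0.5
    base_age = rng.integers(40, 70, size=n).astype(float)

    membership: dict[str, np.ndarray] = {}
    for disease in config.diseases:
        p_male, p_female = _sex_split_probabilities(disease.prevalence, disease.sex_bias_or)
        p = np.where(is_male, p_male, p_female)
        membership[disease.orpha] = rng.random(n) < p

    age = base_age.copy()
    for disease in config.diseases:
        age[membership[disease.orpha]] += disease.age_shift
    age = np.clip(age, 40, 69)

    links = {(normalize_code(l.complex_code)): l for l in config.comorbidity_links}
    complex_flags: dict[str, np.ndarray] = {}
    for code in COMPLEX_CODES:
        norm = normalize_code(code)
        base = config.complex_code_rate
        p = np.full(n, base)
        link = links.get(norm)
        if link is not None:
            odds = base / (1 - base) * link.odds_ratio
            p_linked = odds / (1 + odds)
            p = np.where(membership[normalize_code(link.orpha)], p_linked, p)
        complex_flags[norm] = rng.random(n) < p

    persons: list[PersonRecord] = []
    role_draw = rng.random(n)
    for i in range(n):
        diagnoses: list[tuple[str, DiagnosisRole]] = []
        for disease in config.diseases:
            if membership[disease.orpha][i]:
                code = disease.icd10_codes[int(rng.integers(len(disease.icd10_codes)))]
                role = DiagnosisRole.PRIMARY if role_draw[i] < 0.3 else DiagnosisRole.SECONDARY
                diagnoses.append((code, role))
        for code, flags in complex_flags.items():
            if flags[i]:
                diagnoses.append((code, DiagnosisRole.SECONDARY))
        persons.append(
            PersonRecord(
                ids[i],
                Sex.MALE if is_male[i] else Sex.FEMALE,
                float(age[i]),
                diagnoses,
            )
        )

    truth = {
        normalize_code(d.orpha): set(ids[membership[d.orpha]]) for d in config.diseases
    }
    return SimPopulation(persons, truth)


# ---------------------------------------------------------------------------
# Genotypes

@dataclass
class SimGenotypes:
    genotypes: pd.DataFrame  # persons x variants, dosage 0/1/2 with NaN missing
    annotations: dict[str, VariantAnnotation]
    causal_variant_ids: dict[str, str]  # orpha -> variant id


def gen_genotypes(config: SimConfig, population: SimPopulation) -> SimGenotypes:
    """Dosage matrix, annotation table, and which variant is causal for which disease.

    Non-causal variants are Binomial(2, MAF) independent of phenotype.  A
    causal variant keeps its control carrier frequency but multiplies the
    carrier odds among the linked disease's cases by the configured odds
    ratio.  The causal variant always receives a qualifying annotation
    (high impact, loss of function, high pathogenicity score).
    """
    rng = config.rng(4)
    ids = [p.person_id for p in population.persons]
    n = len(ids)
    impacts = np.array(["high", "moderate", "low", "modifier"])
    impact_probs = np.array([0.05, 0.25, 0.40, 0.30])

    for spec in config.causal_variants:
        if normalize_code(spec.orpha) not in population.truth_memberships:
            raise ValueError(f"causal disease {spec.orpha} absent from the population")

    columns: dict[str, np.ndarray] = {}
    annotations: dict[str, VariantAnnotation] = {}
    causal_ids: dict[str, str] = {}
    lo, hi = config.maf_range
    causal_slots = {
        int(j): spec
        for j, spec in zip(
            rng.choice(config.n_variants, size=len(config.causal_variants), replace=False),
            config.causal_variants,
        )
    }

    for j in range(config.n_variants):
        vid = f"var{j:05d}"
        gene = f"GENE{j // config.variants_per_gene:04d}"
        spec = causal_slots.get(j)
        if spec is None:
            maf = float(rng.uniform(lo, hi))
            g = rng.binomial(2, maf, size=n).astype(float)
            impact = Impact(rng.choice(impacts, p=impact_probs))
            score = float(rng.random()) if rng.random() < 0.8 else None
            lof = impact is Impact.HIGH and rng.random() < 0.5
            annotations[vid] = VariantAnnotation(vid, gene, min(maf, 0.5), impact, score, lof)
        else:
            maf = spec.maf
            cases = population.truth_memberships[normalize_code(spec.orpha)]
            case_mask = np.array([pid in cases for pid in ids])
            q0 = 1 - (1 - maf) ** 2  # control carrier frequency
            odds1 = spec.odds_ratio * q0 / (1 - q0)
            p1 = odds1 / (1 + odds1)
            g = rng.binomial(2, maf, size=n).astype(float)
            g[case_mask] = (rng.random(case_mask.sum()) < p1).astype(float)
            annotations[vid] = VariantAnnotation(vid, gene, maf, Impact.HIGH, 0.95, True)
            causal_ids[normalize_code(spec.orpha)] = vid
        columns[vid] = g

    G = pd.DataFrame(columns, index=ids)
    if config.genotype_missing_rate > 0:
        mask = rng.random(G.shape) < config.genotype_missing_rate
        G = G.mask(mask)
    return SimGenotypes(G, annotations, causal_ids)
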