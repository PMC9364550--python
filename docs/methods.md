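# Methods

This note documents the models and procedures implemented in
`rarephenome`, the parameters that matter, the design choices that were
genuinely open, and what the synthetic studies do and do not demonstrate.

## Consensus ontology mapping

The mapping problem: Orphanet links ORPHA rare-disease concepts to ICD-10
billing codes, but many links attach an ORPHA concept that is *narrower*
than the ICD-10 code, so carriers of the code cannot be assumed to have
the disease.  The mapper selects, per ICD-10 code, one ORPHA code that is
as specific as possible but no more specific than the ICD-10 code.

**Specificity classification.**  An explicit relation flag on a candidate
(`exact` / `orpha_broader` / `orpha_narrower`) always takes precedence:
ontology distributors ship such flags and any hierarchy extract may be
incomplete.  Without a flag, the relation is inferred from (i) code or
label identity (→ exact) and (ii) where else in the ICD-10 hierarchy the
same ORPHA code attaches: attachment to a strict descendant of the code at
hand implies the ORPHA concept is at least that narrow (→
`orpha_narrower`); attachment to a strict ancestor, with no descendant
attachment, implies `orpha_broader`.  Codes absent from both hierarchies
yield `unknown`, never an exception.  This cross-attachment heuristic is
deliberately conservative; when it cannot decide, the candidate survives
as `unknown` and ties are surfaced rather than guessed.

**Selection and voting.**  Candidates flagged `orpha_narrower` are
discarded (they over-diagnose).  Exact candidates outrank broader ones;
among broader/unknown survivors the deepest concept in the ORPHA
hierarchy wins.  Two or more maximally specific distinct survivors make
the code `ambiguous` — emitted but excluded from the final map, mirroring
the exclusion of non-specific mappings rather than guessing between, say,
two parasitologically distinct diseases sharing one code.  The chosen
ORPHA then needs accepts from at least 2 of the 3 voters; fewer accepts
flag the code `manual_review` and exclude it.  Abstentions (missing
verdicts) are non-accepts, so a 1-accept/2-abstain code is withheld: the
automated run never resolves disagreements that human adjudication
resolved in practice, it only flags them.

**Antichain validation.**  `validate_antichain` returns every
(ancestor, descendant) pair among the mapped codes; an empty list
certifies that no cohort definition subsumes another.  The check is a
brute-force pairwise sweep — map sizes (hundreds to thousands of codes)
do not justify anything cleverer.

## ICD-9 crosswalk

GEMs flat files carry a five-digit flag field (approximate, no-map,
combination, scenario, choice list).  Exclusion is **disease-level**: one
ICD-10 member code without a clean (non-approximate, non-no-map,
non-combination) equivalence disqualifies the whole disease, because
code-level exclusion would silently change the cohort definition between
coding systems.  Combination rows are treated as disqualifying even
though they are not literally approximate — a combination equivalence is
not a 1:1 code identity, and treating it as clean would let a single
ICD-9 code stand in for a code cluster.  Codes absent from the GEMs file
count as no-map.  Only the ICD-10→ICD-9 direction is consulted.

## Cohorts, prevalence, rarity, groups

A person joins a disease cohort if *any* diagnosis, primary or secondary,
is in the disease's ICD-10 set; membership is a set, so duplicated
records change nothing.  Prevalence divides by the whole dataset
population.  Rarity uses strict inequalities: European, prevalence
< 1/2,000; US, extrapolated affected count < 200,000 at a configurable
US population (default 330,000,000 — the definition names an absolute
count, not a rate, so the constant must be chosen).  Zero-member cohorts
are retained so mapping coverage is auditable; counts below five are
suppressed at report time only.

Chapter groups follow ICD-10 structure with the conventional merges:
D80–D89 split off as Other Immune; mental + nervous chapters as
Neurological; eye + ear as Eye/Ear; pregnancy + perinatal as
Pregnancy/childbirth; symptoms, external causes, health-status factors
and special codes as Miscellaneous.  A multi-code disease takes the group
of its lexicographically first code, with a warning if its codes
disagree — no real mapping has been observed to need more than the
warning path.

## Demographics and enrichment

All 2×2 questions use two-sided Fisher exact tests.  Odds ratios follow
the conditional-MLE convention; degenerate tables with a zero cell report
the sample odds ratio (0 or ∞) rather than a continuity-corrected value —
exactness is preferred over smoothing, and the p-value is exact either
way.  Bonferroni significance always uses the number of tests actually
performed in the batch (recorded in the output), with a BH-FDR flag
computed alongside; by construction the Bonferroni-significant set is
contained in the BH set at the same α.

Age comparisons are two-sided Mann-Whitney tests with a median-ratio fold
change.  The across-disease sex/age correlation is Pearson's r and
defaults to per-disease **median** age with mean available as an option;
both are exported, because the two conventions are both in circulation
and they differ in skewed cohorts — the package surfaces rather than
resolves the discrepancy.

Comorbidity profiles remove the index disease's own codes from each
member's record first; every remaining diagnosis (rare or not) counts
toward its chapter group.  "Complex diseases" for pairwise testing are
the 3-character ICD-10 categories not contributing to the rare map.

## Rare-variant association

**Qualification** requires population MAF ≤ 1 % (annotation value), case
minor-allele count ≥ 3, overall MAC > 3, and predicted deleteriousness
(high/moderate impact, or pathogenicity score ≥ 0.75).  Dosages are
oriented to the minor allele internally; ties at 0.5 keep input
orientation.  Missing genotypes are mean-imputed per variant, preserving
allele frequency.  Unrelated individuals are assumed — there is no
relatedness matrix; principal components can be passed as covariates.

**Testing.**  The null logistic model is fitted once per disease; each
genotype is residualized onto the covariate space in the
working-weight metric, making the score statistic
S = Σ g̃ᵢ(yᵢ − μ̂ᵢ) with variance Σ g̃ᵢ² μ̂ᵢ(1−μ̂ᵢ).  p-values:

- |z| < 2: normal approximation.  The threshold of two standardized units
  is the conventional switch point for this test family: below it the
  normal and saddlepoint answers agree to within a few percent and the
  root-finding is wasted effort.
- |z| ≥ 2: saddlepoint approximation.  K′(ζ) = s is solved by Brent's
  method on an exponentially expanded bracket; the two-sided p sums the
  Barndorff-Nielsen tail at +|s| and −|s|.  Scores beyond the support of
  S get tail probability 0 from that side.
- Saddlepoint failure (bracket not found, non-convex CGF at the root):
  Firth penalized likelihood-ratio fallback.  Both Firth fits use the
  full design with the genotype column; the null fit constrains the
  genotype coefficient to zero while evaluating the Jeffreys penalty on
  the full information matrix — the convention under which the penalized
  LRT is asymptotically χ²₁.  (Penalizing each model by its own
  determinant inflates the statistic by ~½·log n and is *not* used.)

The method used is recorded on every result.  Gene-level burden collapses
a gene's qualifying variants to a carrier indicator (≥ 1 minor allele);
the loss-of-function analysis restricts variant-level tests to
LoF-flagged qualifying variants.  Variant, gene and LoF analyses are
separate correction batches, and batches are per disease — the emitted
metadata (batch size m) makes any global re-correction reproducible.

**Calibration.**  Under a seeded null with 1 % cases (n = 10,000, MAF
0.01, 2,000 replicates) the empirical rate of p < 0.05 is ≈ 0.045:
slightly conservative, because the score statistic of a rare variant with
~100 cases is discrete and the exact tail cannot equal 0.05.  The
contrast appears in the far tail: at α = 10⁻³ with 20 cases in 2,000, the
plain normal approximation rejects ~15× too often while the saddlepoint
test stays at the level (see `tests/test_assoc.py`).

## Synthetic-study generator

The generator emulates a middle-aged volunteer biobank: recruitment ages
uniform on 40–69 (matching the recruitment window of the population
cohort this pipeline targets, so demographic edge cases match the study
design), sex split 50/50, per-disease prevalences in the rare range
(6×10⁻⁵–8×10⁻⁴) with one disease planted at 1.5×10⁻³ to exercise the
non-rare side of the European boundary, per-disease sex-bias odds ratios
and age shifts, and one disease holding three sibling ICD-10 codes to
exercise many-to-one mapping.

Mapping noise: truth pairs are exact-relation candidates; decoy
candidates attach a too-narrow ORPHA subtype to true codes (rate 0.5) and
to six trap codes that have *only* narrower candidates and must stay
unmapped.  Voters accept the truth at 1 − e (defaults e = 0.05, 0.05,
0.02) and otherwise reject or endorse a decoy.  Under 2-of-3 voting the
per-code mapping probability is the analytic majority bound, which the
tests check within binomial error.

Comorbidity links multiply the odds of a complex-disease code among a
linked rare disease's cases by a configured odds ratio — the shared
Bernoulli factor is the disease indicator itself, the simplest latent
structure whose induced 2×2 odds ratio equals the configured value at
small prevalence.  The generator therefore does **not** produce diffuse
background correlation between unlinked code pairs, dated records,
diagnostic miscoding, LD between variants, sequencing error or ancestry
structure; passing tests demonstrate the pipeline's statistical behavior
under its stated model, not robustness to those real-data features.

Genotypes: non-causal variants are Binomial(2, MAF) independent of
phenotype with MAF ~ U(0.001, 0.01); a causal variant keeps its control
carrier frequency and multiplies carrier odds among cases by the
configured odds ratio (default 8, MAF 0.005); 1 % of entries are missing.
The causal variant always receives a qualifying annotation (high impact,
LoF, score 0.95).

**Problem sizes.**  The default end-to-end study uses 40,000 people —
large enough that the most prevalent planted disease (~60 cases) clears
the case-MAC ≥ 3 qualification filter with high probability, so every
stage runs by default.  The association calibration studies use the
dedicated single-disease configuration: 50,000 people, 1 % cases, 50
variants; the null study uses 2,000 replicates at n = 10,000.  Power at
these sizes: the OR-8 causal variant is the top association in ≥ 90 % of
20 seeded replicates.

**Determinism.**  All randomness flows from `numpy.random.default_rng`
seeded with (master seed, stage index); identical configuration and seed
reproduce byte-identical outputs, which the pipeline manifest certifies
with SHA-256 digests.

## Known limitations

- Specificity inference without relation flags relies on cross-attachment
  patterns and labels; a sparse candidate table degrades gracefully to
  `unknown` but then requires flags to map anything.
- The voting model cannot reproduce adjudicated resolutions; codes the
  humans resolved by discussion appear as `manual_review` exclusions.
- The association tests assume unrelated individuals and an adequate null
  model; confounding that a sparse relatedness matrix would absorb is out
  of scope.
- US rarity extrapolates biobank prevalence to a national count, which
  inherits every selection bias of the source cohort.
- Suppression (< 5) is enforced in exports and bundles, not inside
  in-memory objects, which intentionally retain exact counts for
  computation.
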