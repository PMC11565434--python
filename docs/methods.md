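# Methods

## The reanalysis procedure

`hcmkit` models a gene-centric exome reanalysis for hypertrophic
cardiomyopathy (HCM). The unit of analysis is a *variant observation*: one
patient carrying one annotated variant (gene, transcript, exon, cDNA/protein
change, genotype, CADD, gnomAD allele frequency, predictor calls, curated
ACMG and ClinVar classes). Observations of the same physical variant across
patients are linked by a normalized key — gene plus canonicalized protein
change, or cDNA change for splice variants, case/whitespace/parenthesis
insensitive, with `fsTer`/`fs*` stop-codon spellings collapsed. The
transcript is deliberately not part of the key: nomenclature is assumed to
be on one MANE select transcript per gene, which is how per-gene distinct
counts are reported in practice.

The pipeline composes four stages in a fixed order:

1. **Rarity** — keep gnomAD AF < 1% (strict) or absent. Absence means "not
   observed in gnomAD", and is kept: many pathogenic alleles are absent from
   population databases, and absent ≠ 0 ≠ common.
2. **Consequence** — remove intergenic, deep-intronic and synonymous
   changes. Intronic changes carrying a splice-region offset (±1, ±2, but
   also non-canonical offsets such as +4) are splicing and are kept; the
   offset is retained as metadata rather than split into sub-types.
3. **In-silico consensus** — a missense change is high-confidence when at
   least `min_deleterious_tools` (default 3) of SIFT / PolyPhen-2 /
   MutationTaster call it deleterious **and** CADD > 15 (strict; 15.0
   exactly is low confidence). Truncating and splice variants bypass this
   stage: their CADD is frequently unscored in curated tables, and their
   assessment belongs to the gene-mechanism stage. By default, records in
   panel genes that fail the consensus are *retained with a low-confidence
   flag* rather than dropped — prioritized tables legitimately include
   benign-class co-occurring alleles, and a strict mode
   (`retain_in_established_genes=False`) is available to drop them.
4. **Gene-mechanism rules** — annotation, not filtering. In
   haploinsufficiency genes (MYBPC3) truncating alleles are
   mechanism-concordant; in LoF-tolerant dominant-negative genes (MYH7)
   missense alleles are concordant and truncating alleles are flagged
   discordant but retained (a review flag — the absence of MYH7 PTVs in
   case cohorts is an observation, not a pre-filter). In
   autosomal-recessive genes (TRIM63, ALPK3) homozygous or multi-variant
   carriers are inheritance-concordant.

Stage order matters (the consensus depends on the consequence class), so the
pipeline asserts the fixed order rather than claiming commutativity. The
cascade is idempotent, each drop stage is monotone, and the audit's
per-stage drop reasons always reconcile with the in/out counts.

## ACMG/AMP combination

Evidence criteria are combined by the published rule clauses over criterion
counts per strength bucket (very strong / strong / moderate / supporting on
the pathogenic side; stand-alone / strong / supporting on the benign side).
Strength-modified criteria (`PVS1_moderate`) count in their modified bucket,
which is required for truncating variants in genes of disputed validity.
Two deliberate semantics:

- *Contradiction*: if both rule sets are satisfied, or a satisfied rule set
  is opposed by strong-or-stronger evidence on the other side (e.g. PS1
  together with BA1), the result is VUS. Supporting-level opposition does
  not void a classification.
- *Curated precedence*: fixture-curated classes are data; the heuristic
  auto-assigner (PVS1 for truncating alleles in haploinsufficiency genes,
  PM2 below 1e-4 or absent, PP3 for high-confidence missense, BA1 above 5%,
  BS1 above 1%) is only reported alongside, with disagreements logged and
  counted, never asserted. The auto-assigner does not emit PP3 for
  truncating variants, avoiding double-counting of the same signal as PVS1.

## Cohort statistics

Distinct-variant counts run on normalized keys; carrier counts on distinct
patient identifiers (a patient with two rows in one gene is one carrier).
Percentages are computed on the cohort denominator (default 200) and
rounded half-up to integer percent; the homozygote fraction is reported to
one decimal. P/LP counts are per distinct variant, using curated classes.

Patient-level merging spans all tables. Cross-references in the
"additional variant" column are resolved against the patient's own rows; a
cross-reference that matches no tabulated row is kept as a *phantom gene*
for multilocus classification (same-gene multi / digenic / oligogenic by
distinct gene count) but excluded from per-gene carrier and variant counts.
This mirrors how such tables are tallied in practice, where a co-occurring
variant may be cross-referenced without receiving a row of its own.

Yield enhancement for newly added genes reports the per-gene carrier total
(`carriers_any`, counting a patient once per gene, as such tallies are
printed), the count of patients whose only prioritized variant lies in a
new gene (`carriers_sole`), and the latter as a percentage of the cohort —
the headline enhancement figure.

Control-cohort allele frequencies are exact rationals (allele count /
allele number); the display string reproduces printed-table style by
truncation, never rounding: four decimal places (trailing zeros stripped)
at or above 1e-3, otherwise scientific notation with a five-significant-
digit truncated mantissa (1/1920 → `5.2083e-4`, 28/1920 → `0.0145`).

Gene–disease validity tallies are dominant-centric: when a gene's strongest
curation is recessive-only and a dominant curation exists (TRIM63:
moderate-AR / disputed-AD), the dominant row governs the tally while the
strongest row remains exposed as the primary validity. Semidominant
curations (CSRP3) are not demoted.

## Synthetic cohorts

The simulator emulates the statistical structure of a 200-patient HCM
reanalysis cohort, not its sequence content. Defaults, chosen once from the
reference cohort's description: per-gene carrier prevalences equal to the
observed carrier counts over 200 (MYBPC3 0.255, MYH7 0.08, …, TRIM63 0.06,
FHOD3 0.05, SVIL 0.065); recurrence probability 0.3 (a carrier re-draws an
existing variant of the gene rather than founding a new one); homozygote
rate 0.25 per carried variant in recessive genes (3 of 12 TRIM63 carriers
were homozygous) and 0.01 elsewhere; young-onset fraction 0.135, familial
fraction 0.34, male fraction 0.66 (132:68); ages drawn from a uniform
19–40 / 40–91 mixture calibrated so 86.5% of patients are above 40 (no
per-patient ages are published, so ages exist only synthetically).

Annotations are class-conditional: pathogenic-like alleles draw CADD around
30, are absent from gnomAD 60% of the time (else below 1e-4), and collect
deleterious predictor calls with probability 0.95 per tool; benign-like
alleles draw CADD below 15 and frequencies up to 5e-3; uncertain alleles
sit between. Planted decoys — common alleles (AF ≥ 1%) and synonymous
changes, each at an expected 0.3 per patient — are the cascade's negative
controls. Every planted fact (carriers per gene, founded keys, decoys,
homozygotes, ages) is written to a ledger, and the pipeline-recovery
property holds exactly: the cascade keeps precisely the non-decoy records,
for every seed tested.

What passing simulator-based tests does **not** show: performance on real
annotation noise (discordant predictors, multi-population AF fields,
transcript mismatches), on genes outside the configured panel, or on
sequence-level artifacts (alignment error, genotyping error) — none of
which are modelled. Loci are synthetic labels; no genomic coordinates,
haplotypes or pedigrees are generated.

## Numerical and design choices

- Thresholds are strict inequalities (AF < 0.01, CADD > 15) as stated in
  the filtering protocol; the cascade config rejects a zero AF threshold
  (the rarity filter's contract is an open interval).
- Recurrence ties break lexicographically on the variant key; reports are
  stable under input shuffling.
- Variant-type classification returns a generic frameshift when the indel
  kind is unknowable from protein notation alone; an optional hint refines
  it. Fixture agreement is therefore checked at the frameshift-family
  level for those rows and exactly elsewhere — 100% of fixture rows agree.
- VCF ingestion maps 0/1 → het and 1/1 → hom, skipping reference-only
  calls; coordinates are carried verbatim (1-based VCF convention), never
  re-based; no allele normalization or liftover is attempted. Synthetic
  VCF scores are written as typed strings so text round trips are exact.
- Fixture integrity is guarded by SHA-256 manifest checks at load time.

## Problem sizes

The packaged cohort is 200 patients / 162 observations; tests and the
acceptance script run it in seconds. Simulation-based checks use n = 200
cohorts for behavioural properties, n = 1000 for the zygosity-rate check,
n = 5000 for prevalence-recovery (3 binomial standard errors), and 60 seeds
for the repeated-cohort binomial-mean check.
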