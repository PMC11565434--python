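# hcmkit

Exome-reanalysis toolkit for hypertrophic cardiomyopathy (HCM) cohorts.

Roughly half of HCM patients leave genetic testing without a causal variant.
Reanalysing stored exome data several years later — against an updated,
gene-tiered panel that includes recently disease-associated genes — recovers
part of that missing yield. `hcmkit` implements that reanalysis procedure as
a reusable pipeline for clinical genetics groups:

- **Gene panel registry** (`hcmkit.panel`): genes tiered as core sarcomeric
  (MYBPC3, MYH7, TNNT2, TNNI3, TPM1, ACTC1, MYL2, MYL3), minor, emerging
  (TRIM63, FHOD3, SVIL) or excluded (TTN, syndromic phenocopies), with
  disease mechanism, inheritance and ClinGen-style gene–disease validity;
  panel assembly from OMIM/ClinGen/literature sources with a Venn split
  against the original panel, and HPO-term-driven panel expansion.
- **Prioritization cascade** (`hcmkit.cascade`): rarity (gnomAD AF < 1%,
  strict), consequence (intergenic/deep-intronic/synonymous removed,
  splice-region kept), in-silico consensus (≥ 3 deleterious calls from
  SIFT/PolyPhen-2/MutationTaster **and** CADD > 15 for missense; truncating
  variants are gated by gene mechanism instead), and gene-mechanism rules
  (truncating alleles concordant in haploinsufficiency genes such as MYBPC3;
  missense concordant in LoF-tolerant dominant-negative genes such as MYH7;
  homozygous/biallelic carriers concordant in recessive genes such as
  TRIM63). Every stage writes per-record drop reasons to an audit.
- **ACMG/AMP engine** (`hcmkit.acmg`): evidence criteria (PVS1 … BP7, with
  strength modifiers) combined into the five-tier P/LP/VUS/LB/B
  classification by the published combining rules; contradictory evidence
  resolves to VUS. A documented heuristic auto-assigner (PVS1/PM2/PP3/BA1/
  BS1) supports synthetic data and triage but never overrides curated
  classes.
- **Cohort statistics** (`hcmkit.summary`): per-gene distinct variants (by
  normalized variant key), carriers, variant-type decomposition, P/LP
  counts, recurrence spectra, sole-variant ("unique") carriers, zygosity,
  same-gene/digenic/oligogenic carriers, and diagnostic-yield enhancement
  from newly added genes.
- **Control cohort** (`hcmkit.controls`): exact-rational allele frequencies
  from allele count / allele number, printed-table display formatting, and
  case/control overlap reporting.
- **Synthetic cohorts** (`hcmkit.simulate`): a seeded simulator emitting
  annotated cohorts (TSV and VCF) with per-gene prevalences, recurrence,
  zygosity and class-conditional annotation distributions, plus a
  ground-truth ledger of every planted fact; and packaged fixtures
  transcribing a published 200-patient reanalysis (162 prioritized variant
  observations in 20 genes, a 960-individual French control table, and the
  gene–disease validity curations).

## Worked example

The packaged fixtures are the pipeline's own published output, so running
the cascade over them drops nothing, and the summary reproduces the cohort's
headline numbers:

```sh
$ hcmkit summarize --out demo
20 genes, 5 homozygote carriers (2.5%), report in demo
```

`demo/summary.json` then contains, among others: MYBPC3 with 40 distinct
variants (24 missense, 4 splice, 6 stopgain, 6 frameshift) in 51 carriers
(26% of 200), 22 of the 40 classified P/LP, 42 sole-variant carriers, and
the splice allele c.1928-2A>G recurring in 7 patients (3.5%); MYH7 with 16
distinct missense variants, 8 P/LP; 6 carriers across TNNT2/MYL2/MYL3;
TRIM63 with 7 distinct variants in 12 patients, FHOD3 in 10, SVIL in 13,
and 18 patients whose only prioritized variant lies in one of those three
newly added genes — a 9% yield enhancement; homozygotes in 2.5% of the
cohort; 7 case variants present in the control cohort.

The same machinery runs on your own data (`--input table.tsv`, or a VCF via
`hcmkit.variants.read_annotated_vcf`) and on simulated cohorts:

```sh
$ hcmkit simulate --n-patients 100 --seed 7 --out demo-sim --no-vcf
simulated 131 records for 100 patients -> demo-sim
```

```python
from hcmkit import load_fixtures, summarize_gene

records = load_fixtures()["records"]
s = summarize_gene(records, "MYBPC3", n_patients_total=200)
print(s.distinct_variants, s.carriers, s.carrier_percent)  # 40 51 26.0
```

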