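"""Cohort-level statistics over prioritized variant observations.

All distinct-variant arithmetic runs on normalized variant keys; all carrier
arithmetic runs on distinct patient identifiers (a patient with two rows in
one gene is one carrier of that gene).  Percentages are computed on the
cohort denominator and rounded half-up to the nearest integer percent, except
the homozygote fraction which is reported to one decimal.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

from .variants import (
    AcmgClass,
    Genotype,
    PatientGenotype,
    VariantKey,
    VariantRecord,
    VariantType,
    merge_patients,
    normalize_key,
)

__all__ = [
    "GeneSummary",
    "CohortSummary",
    "percent",
    "summarize_gene",
    "recurrence",
    "sole_variant_carriers",
    "zygosity_summary",
    "multilocus_summary",
    "yield_enhancement",
    "subgroup_distribution",
    "summarize_cohort",
]


def percent(numerator: int, denominator: int, decimals: int = 0) -> float:
    """Half-up percentage rounding (51/200 -> 26, 5/200 -> 2.5 at one decimal)."""
    if denominator == 0:
        return 0.0
    q = Decimal(numerator) * 100 / Decimal(denominator)
    exp = Decimal(1).scaleb(-decimals)
    return float(q.quantize(exp, rounding=ROUND_HALF_UP))


@dataclass
class GeneSummary:
    gene: str
    carriers: int = 0
    carrier_percent: float = 0.0
    distinct_variants: int = 0
    type_decomposition: dict[str, int] = field(default_factory=dict)
    n_plp_variants: int = 0
    recurrent: dict[str, int] = field(default_factory=dict)
    sole_variant_carriers: int = 0


@dataclass
class CohortSummary:
    n_patients_total: int
    genes: dict[str, GeneSummary] = field(default_factory=dict)
    n_genes_identified: int = 0
    homozygote_carriers: int = 0
    homozygote_percent: float = 0.0
    homozygotes_by_gene: dict[str, int] = field(default_factory=dict)
    same_gene_multi: list[str] = field(default_factory=list)
    digenic: list[str] = field(default_factory=list)
    oligogenic: list[str] = field(default_factory=list)


def _frameshift_bucket(vt: VariantType) -> str:
    return "frameshift" if vt.is_frameshift else vt.value


def summarize_gene(
    records: Iterable[VariantRecord],
    gene: str,
    n_patients_total: int = 200,
) -> GeneSummary:
    """Per-gene block: distinct variants (by key), carriers (distinct
    patients), variant-type decomposition of the distinct variants, and the
    count of distinct P/LP variants by curated class.  Frameshift deletions
    and insertions share one decomposition bucket."""
    gene = gene.upper()
    records = list(records)
    sub = [r for r in records if r.gene == gene]
    summary = GeneSummary(gene=gene)
    if not sub:
        return summary
    by_key: dict[VariantKey, list[VariantRecord]] = {}
    for r in sub:
        by_key.setdefault(normalize_key(r), []).append(r)
    summary.distinct_variants = len(by_key)
    summary.carriers = len({r.patient_id for r in sub})
    summary.carrier_percent = percent(summary.carriers, n_patients_total)
    decomposition: Counter[str] = Counter()
    n_plp = 0
    for key, observations in by_key.items():
        decomposition[_frameshift_bucket(observations[0].variant_type)] += 1
        classes = {r.acmg_class for r in observations if r.acmg_class is not None}
        if any(c.is_plp for c in classes):
            n_plp += 1
    summary.type_decomposition = dict(decomposition)
    summary.n_plp_variants = n_plp
    summary.recurrent = {
        str(k): n for k, n in recurrence(sub, gene).items() if n > 1
    }
    summary.sole_variant_carriers = len(sole_variant_carriers(records, {gene}))
    return summary


def recurrence(
    records: Iterable[VariantRecord], gene: str | None = None
) -> dict[VariantKey, int]:
    """Distinct-carrier count per variant key, sorted by descending count
    then lexicographic key."""
    carriers: dict[VariantKey, set[str]] = {}
    for r in records:
        if gene is not None and r.gene != gene.upper():
            continue
        carriers.setdefault(normalize_key(r), set()).add(r.patient_id)
    ordered = sorted(carriers.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    return {k: len(v) for k, v in ordered}


def sole_variant_carriers(
    records: Iterable[VariantRecord], gene_set: set[str]
) -> set[str]:
    """Patients whose entire prioritized record set is exactly one record
    lying within ``gene_set`` — the "unique variant" carriers of those genes.
    Patient merging spans all genes, so a patient with a second variant
    anywhere is excluded."""
    gene_set = {g.upper() for g in gene_set}
    patients = merge_patients(list(records))
    return {
        pid
        for pid, pg in patients.items()
        if pg.is_sole_variant_carrier and pg.records[0].gene in gene_set
    }


def zygosity_summary(
    records: Iterable[VariantRecord], n_patients_total: int = 200
) -> tuple[int, dict[str, int], float]:
    """(homozygote carriers, per-gene breakdown, percent to one decimal)."""
    hom_patients: dict[str, set[str]] = {}
    all_hom: set[str] = set()
    for r in records:
        if r.genotype is Genotype.HOM:
            hom_patients.setdefault(r.gene, set()).add(r.patient_id)
            all_hom.add(r.patient_id)
    by_gene = {g: len(p) for g, p in sorted(hom_patients.items())}
    return len(all_hom), by_gene, percent(len(all_hom), n_patients_total, decimals=1)


def multilocus_summary(
    patients: Mapping[str, PatientGenotype] | Iterable[VariantRecord],
    restrict_to_genes: set[str] | None = None,
) -> tuple[list[str], list[str], list[str]]:
    """(same-gene multi-variant, digenic, oligogenic) patient lists.

    Classification counts distinct genes per patient, including cross-
    referenced genes whose own row was never tabulated.  With
    ``restrict_to_genes`` only patients carrying at least one record in those
    genes are classified (e.g. the sarcomere-positive subset).
    """
    if not isinstance(patients, Mapping):
        patients = merge_patients(list(patients))
    same_gene, digenic, oligogenic = [], [], []
    for pid in sorted(patients):
        pg = patients[pid]
        if restrict_to_genes is not None and not (
            pg.genes & {g.upper() for g in restrict_to_genes}
        ):
            continue
        if pg.is_same_gene_multi:
            same_gene.append(pid)
        elif pg.is_digenic:
            digenic.append(pid)
        elif pg.is_oligogenic:
            oligogenic.append(pid)
    return same_gene, digenic, oligogenic


def yield_enhancement(
    records: Iterable[VariantRecord],
    new_genes: set[str],
    n_patients_total: int = 200,
) -> dict[str, float]:
    """Diagnostic-yield enhancement from genes absent in the initial analysis.

    ``carriers_any`` totals per-gene carriers over the new genes (a patient
    carrying variants in two of them counts once per gene, matching how
    per-gene carrier tallies are reported); ``carriers_sole`` counts patients
    whose only prioritized variant lies in a new gene, and ``percent_sole``
    is the headline enhancement on the cohort denominator.
    """
    new_genes = {g.upper() for g in new_genes}
    records = list(records)
    per_gene_carriers = {
        g: len({r.patient_id for r in records if r.gene == g}) for g in new_genes
    }
    sole = sole_variant_carriers(records, new_genes)
    return {
        "carriers_any": sum(per_gene_carriers.values()),
        "carriers_sole": len(sole),
        "percent_sole": percent(len(sole), n_patients_total),
    }


def subgroup_distribution(
    records: Iterable[VariantRecord],
    patient_ages: Mapping[str, float],
    age_max: float,
    genes: Sequence[str] | None = None,
) -> dict[str, float]:
    """Per-gene share (percent) of carriers within the young-onset subgroup
    (patients with onset age below ``age_max``).  Ages must be supplied —
    they come from study metadata or a simulation, not from variant tables."""
    if patient_ages is None:
        raise ValueError("patient ages are required for subgroup analysis")
    records = list(records)
    subgroup = {p for p, a in patient_ages.items() if a < age_max}
    sub_records = [r for r in records if r.patient_id in subgroup]
    carriers_total = {r.patient_id for r in sub_records}
    if genes is None:
        genes = sorted({r.gene for r in sub_records})
    out = {}
    for g in genes:
        carriers = {r.patient_id for r in sub_records if r.gene == g.upper()}
        out[g.upper()] = percent(len(carriers), len(carriers_total)) if carriers_total else 0.0
    return out


def summarize_cohort(
    records: Iterable[VariantRecord],
    n_patients_total: int = 200,
    sarcomere_genes: set[str] | None = None,
) -> CohortSummary:
    """Full cohort block: per-gene summaries plus cohort-wide zygosity and
    multilocus statistics (the latter on the sarcomere-positive subset when
    ``sarcomere_genes`` is given)."""
    records = list(records)
    genes = sorted({r.gene for r in records})
    summary = CohortSummary(n_patients_total=n_patients_total)
    for g in genes:
        summary.genes[g] = summarize_gene(records, g, n_patients_total)
    summary.n_genes_identified = len(genes)
    n_hom, by_gene, pct = zygosity_summary(records, n_patients_total)
    summary.homozygote_carriers = n_hom
    summary.homozygotes_by_gene = by_gene
    summary.homozygote_percent = pct
    sg, dg, og = multilocus_summary(records, restrict_to_genes=sarcomere_genes)
    summary.same_gene_multi, summary.digenic, summary.oligogenic = sg, dg, og
    return summary
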