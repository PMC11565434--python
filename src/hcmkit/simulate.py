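"""Packaged fixtures and a seeded synthetic-cohort simulator.

The fixtures transcribe the published prioritized-variant tables (per-gene
case tables, the French control-cohort counts, and the gene–disease validity
curations); :func:`load_fixtures` verifies their content hashes against the
shipped manifest.

The simulator emits an annotated cohort with the statistical structure the
cascade assumes: per-gene carrier prevalences, a recurrence spectrum (a
carrier either re-draws an existing variant of the gene or founds a novel
one), per-gene zygosity rates (elevated for recessive genes), and
class-conditional annotation distributions — pathogenic-like alleles are
rare or absent from population databases with high CADD and concordant
predictor calls, benign-like alleles sit below the CADD cut with higher
frequencies.  Planted high-frequency and synonymous decoys exercise the
rarity and consequence filters; every planted fact is written to a ground-
truth ledger so tests can compare pipeline output against it exactly.

No sequence-level realism is attempted: loci are labeled gene/exon/change
strings consistent with the parser's grammar, not genome coordinates.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

from .controls import ControlVariantRecord, read_control_table
from .panel import GenePanel, default_panel
from .variants import (
    AcmgClass,
    Genotype,
    PredictorCall,
    VariantRecord,
    VariantType,
    normalize_key,
    read_variant_table,
    write_variant_table,
)

__all__ = [
    "FIXTURE_TABLES",
    "load_fixtures",
    "SyntheticCohortConfig",
    "generate_cohort",
    "write_cohort_table",
    "write_cohort_vcf",
]


FIXTURE_TABLES = (
    "variants_mybpc3.tsv",
    "variants_myh7.tsv",
    "variants_tnnt2.tsv",
    "variants_mlc.tsv",
    "variants_minor.tsv",
    "variants_trim63.tsv",
    "variants_fhod3.tsv",
    "variants_svil.tsv",
)


class FixtureIntegrityError(RuntimeError):
    pass


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_fixtures(verify: bool = True) -> dict:
    """Load the packaged case tables, control table and gene panel.

    Returns a dict with ``records`` (all case observations, concatenated),
    ``tables`` (per-table record lists), ``controls`` and ``panel``.  With
    ``verify`` the files' SHA-256 digests are checked against the manifest.
    """
    data = resources.files("hcmkit.data")
    manifest = json.loads((data / "manifest.json").read_text())
    tables: dict[str, list[VariantRecord]] = {}
    records: list[VariantRecord] = []
    for name in FIXTURE_TABLES + ("controls_french.tsv", "gene_validity.tsv", "panel.tsv"):
        with resources.as_file(data / name) as p:
            if verify:
                digest = _sha256(p)
                if manifest.get(name) != digest:
                    raise FixtureIntegrityError(
                        f"fixture {name} hash mismatch: {digest} != {manifest.get(name)}"
                    )
    for name in FIXTURE_TABLES:
        with resources.as_file(data / name) as p:
            tables[name] = read_variant_table(p)
        records.extend(tables[name])
    with resources.as_file(data / "controls_french.tsv") as p:
        controls = read_control_table(p)
    return {
        "records": records,
        "tables": tables,
        "controls": controls,
        "panel": default_panel(),
    }


# ---------------------------------------------------------------------------
# Simulator


#: per-gene carrier prevalences mirroring the reference cohort's carrier
#: counts on a 200-patient denominator
DEFAULT_PREVALENCE = {
    "MYBPC3": 0.255,
    "MYH7": 0.08,
    "TNNT2": 0.01,
    "MYL2": 0.005,
    "MYL3": 0.015,
    "FLNC": 0.065,
    "MYH6": 0.04,
    "MYPN": 0.03,
    "ACTN2": 0.025,
    "ALPK3": 0.02,
    "CSRP3": 0.02,
    "MYLK2": 0.015,
    "NEXN": 0.01,
    "CAV3": 0.01,
    "VCL": 0.01,
    "TCAP": 0.005,
    "JPH2": 0.005,
    "TRIM63": 0.06,
    "FHOD3": 0.05,
    "SVIL": 0.065,
}

#: genes with autosomal-recessive inheritance get an elevated homozygote rate
AR_GENES = frozenset({"TRIM63", "ALPK3"})

_RESIDUES = (
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
)

_TOOLS = ("SIFT", "PolyPhen-2", "MutationTaster")


@dataclass
class SyntheticCohortConfig:
    n_patients: int = 200
    gene_prevalence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE)
    )
    #: probability a carrier re-draws an already-founded variant of the gene
    recurrence_prob: float = 0.3
    #: homozygote probability per carried variant
    hom_rate_ad: float = 0.01
    hom_rate_ar: float = 0.25
    #: true-class spectrum per drawn variant (pathogenic-like, uncertain, benign-like)
    class_weights: tuple[float, float, float] = (0.4, 0.4, 0.2)
    #: expected planted decoys per patient
    decoy_high_af_rate: float = 0.3
    decoy_synonymous_rate: float = 0.3
    young_fraction: float = 0.135
    familial_fraction: float = 0.34
    male_fraction: float = 0.66  # 132 men : 68 women
    age_young_range: tuple[float, float] = (19.0, 40.0)
    age_old_range: tuple[float, float] = (40.0, 91.0)

    def __post_init__(self) -> None:
        for g, p in self.gene_prevalence.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"prevalence for {g} out of [0,1]: {p}")
        if abs(sum(self.class_weights) - 1.0) > 1e-9:
            raise ValueError("class_weights must sum to 1")


def _class_annotations(rng: np.random.Generator, klass: str) -> dict:
    """Class-conditional CADD, gnomAD AF and predictor-call parameters."""
    if klass == "pathogenic":
        cadd = float(np.clip(rng.normal(30.0, 3.0), 20.0, 45.0))
        af = None if rng.random() < 0.6 else float(10 ** rng.uniform(-6, -4))
        p_del = 0.95
        acmg = AcmgClass.LP if rng.random() < 0.6 else AcmgClass.P
    elif klass == "uncertain":
        cadd = float(np.clip(rng.normal(24.0, 3.0), 15.1, 34.0))
        af = None if rng.random() < 0.3 else float(10 ** rng.uniform(-6, -3.5))
        p_del = 0.7
        acmg = AcmgClass.VUS
    else:  # benign-like
        cadd = float(np.clip(rng.normal(12.0, 2.0), 0.1, 14.9))
        af = float(10 ** rng.uniform(-4, np.log10(5e-3)))
        p_del = 0.2
        acmg = AcmgClass.B if rng.random() < 0.6 else AcmgClass.LB
    calls = {
        t: PredictorCall.DELETERIOUS if rng.random() < p_del else PredictorCall.TOLERATED
        for t in _TOOLS
    }
    return {"cadd": cadd, "gnomad_af": af, "predictor_calls": calls, "acmg": acmg}


def _variant_type_for(rng: np.random.Generator, gene: str) -> VariantType:
    if gene == "MYBPC3":
        # truncating-rich spectrum for the haploinsufficiency gene
        types = [
            VariantType.MISSENSE,
            VariantType.SPLICING,
            VariantType.STOPGAIN,
            VariantType.FRAMESHIFT_DELETION,
            VariantType.FRAMESHIFT_INSERTION,
        ]
        return types[int(rng.choice(len(types), p=[0.6, 0.1, 0.15, 0.075, 0.075]))]
    if gene == "TRIM63":
        return (
            VariantType.MISSENSE
            if rng.random() < 0.7
            else VariantType.STOPGAIN
        )
    return VariantType.MISSENSE


@dataclass
class _FoundedVariant:
    gene: str
    variant_type: VariantType
    exon: int
    protein_change: str | None
    cdna_change: str | None
    annotations: dict


def _found_variant(
    rng: np.random.Generator, gene: str, serial: int, cfg: SyntheticCohortConfig
) -> _FoundedVariant:
    vtype = _variant_type_for(rng, gene)
    exon = int(rng.integers(1, 35))
    pos = 50 * serial + int(rng.integers(1, 50))  # unique residue positions per gene
    klass = ("pathogenic", "uncertain", "benign")[
        int(rng.choice(3, p=cfg.class_weights))
    ]
    if vtype.is_truncating:
        klass = "pathogenic" if rng.random() < 0.8 else "uncertain"
    ann = _class_annotations(rng, klass)
    ann["true_class"] = klass
    protein = cdna = None
    ref, alt = rng.choice(len(_RESIDUES), size=2, replace=False)
    if vtype is VariantType.MISSENSE:
        protein = f"p.({_RESIDUES[ref]}{pos}{_RESIDUES[alt]})"
    elif vtype is VariantType.STOPGAIN:
        protein = f"p.({_RESIDUES[ref]}{pos}*)"
    elif vtype.is_frameshift:
        protein = f"p.({_RESIDUES[ref]}{pos}{_RESIDUES[alt]}fsTer{int(rng.integers(2, 90))})"
    elif vtype is VariantType.SPLICING:
        offset = int(rng.choice([1, 2, 4]))
        sign = "+" if rng.random() < 0.5 else "-"
        cdna = f"c.{pos * 3}{sign}{offset}{'G' if sign == '-' else 'T'} > A"
        ann["cadd"] = None if rng.random() < 0.5 else ann["cadd"]
    elif vtype is VariantType.SYNONYMOUS:
        protein = f"p.({_RESIDUES[ref]}{pos}{_RESIDUES[ref]})"
    return _FoundedVariant(gene, vtype, exon, protein, cdna, ann)


def generate_cohort(
    config: SyntheticCohortConfig | None = None, seed: int = 0
) -> tuple[list[VariantRecord], dict]:
    """Simulate an annotated cohort; deterministic for a fixed seed.

    Returns (records, ledger).  The ledger records every planted fact:
    carriers per gene, founded variant keys, decoy records, homozygous
    patients, per-patient ages/sex/familial flags, and the exact set of
    record indices the cascade should keep.
    """
    cfg = config or SyntheticCohortConfig()
    rng = np.random.default_rng(seed)
    records: list[VariantRecord] = []
    ledger: dict = {
        "seed": seed,
        "n_patients": cfg.n_patients,
        "carriers_by_gene": {g: [] for g in cfg.gene_prevalence},
        "founded_keys": {g: [] for g in cfg.gene_prevalence},
        "kept_keys": [],
        "decoy_high_af": [],
        "decoy_synonymous": [],
        "hom_patients": [],
        "ages": {},
        "sex": {},
        "familial": [],
        "young": [],
    }
    pools: dict[str, list[_FoundedVariant]] = {g: [] for g in cfg.gene_prevalence}
    serials: dict[str, int] = {g: 0 for g in cfg.gene_prevalence}
    panel_genes = sorted(cfg.gene_prevalence)
    width = len(str(cfg.n_patients))

    for i in range(cfg.n_patients):
        pid = f"SIM-{i + 1:0{width}d}"
        # demographics
        young = rng.random() < cfg.young_fraction
        lo, hi = cfg.age_young_range if young else cfg.age_old_range
        age = float(rng.uniform(lo, hi))
        ledger["ages"][pid] = age
        if young:
            ledger["young"].append(pid)
        ledger["sex"][pid] = "M" if rng.random() < cfg.male_fraction else "F"
        if rng.random() < cfg.familial_fraction:
            ledger["familial"].append(pid)

        true_records: list[VariantRecord] = []
        decoy_records: list[VariantRecord] = []
        for gene in panel_genes:
            if rng.random() >= cfg.gene_prevalence[gene]:
                continue
            ledger["carriers_by_gene"][gene].append(pid)
            if pools[gene] and rng.random() < cfg.recurrence_prob:
                fv = pools[gene][int(rng.integers(len(pools[gene])))]
            else:
                fv = _found_variant(rng, gene, serials[gene], cfg)
                serials[gene] += 1
                pools[gene].append(fv)
            hom_rate = cfg.hom_rate_ar if gene in AR_GENES else cfg.hom_rate_ad
            genotype = Genotype.HOM if rng.random() < hom_rate else Genotype.HET
            rec = VariantRecord(
                patient_id=pid,
                gene=gene,
                genotype=genotype,
                variant_type=fv.variant_type,
                exon=fv.exon,
                protein_change=fv.protein_change,
                cdna_change=fv.cdna_change,
                cadd=fv.annotations["cadd"],
                gnomad_af=fv.annotations["gnomad_af"],
                acmg_class=fv.annotations["acmg"],
                predictor_calls=dict(fv.annotations["predictor_calls"]),
            )
            true_records.append(rec)
            if genotype is Genotype.HOM:
                ledger["hom_patients"].append(pid)
            key = normalize_key(rec)
            ledger["kept_keys"].append([pid, str(key)])
            if str(key) not in ledger["founded_keys"][gene]:
                ledger["founded_keys"][gene].append(str(key))

        # planted decoys: common alleles (rarity filter) and synonymous
        # changes (consequence filter) in panel genes
        if rng.random() < cfg.decoy_high_af_rate:
            gene = panel_genes[int(rng.integers(len(panel_genes)))]
            pos = 1_000_000 + int(rng.integers(1, 100_000))
            ref, alt = rng.choice(len(_RESIDUES), size=2, replace=False)
            rec = VariantRecord(
                patient_id=pid,
                gene=gene,
                genotype=Genotype.HET,
                variant_type=VariantType.MISSENSE,
                exon=1,
                protein_change=f"p.({_RESIDUES[ref]}{pos}{_RESIDUES[alt]})",
                cadd=float(rng.uniform(1, 25)),
                gnomad_af=float(rng.uniform(0.01, 0.2)),
            )
            decoy_records.append(rec)
            ledger["decoy_high_af"].append([pid, str(normalize_key(rec))])
        if rng.random() < cfg.decoy_synonymous_rate:
            gene = panel_genes[int(rng.integers(len(panel_genes)))]
            pos = 2_000_000 + int(rng.integers(1, 100_000))
            ref = int(rng.integers(len(_RESIDUES)))
            rec = VariantRecord(
                patient_id=pid,
                gene=gene,
                genotype=Genotype.HET,
                variant_type=VariantType.SYNONYMOUS,
                exon=1,
                protein_change=f"p.({_RESIDUES[ref]}{pos}{_RESIDUES[ref]})",
                cadd=float(rng.uniform(0, 10)),
                gnomad_af=float(10 ** rng.uniform(-5, -3)),
            )
            decoy_records.append(rec)
            ledger["decoy_synonymous"].append([pid, str(normalize_key(rec))])

        # cross-reference the patient's true variants against each other;
        # decoys are not cross-referenced (they never survive the cascade)
        for rec in true_records:
            others = [r for r in true_records if r is not rec]
            rec.additional_variant_refs = [
                (r.gene, r.protein_change or r.cdna_change) for r in others
            ]
        records.extend(true_records)
        records.extend(decoy_records)

    ledger["hom_patients"] = sorted(set(ledger["hom_patients"]))
    ledger["emitted_records"] = len(records)
    return records, ledger


def write_cohort_table(records: Sequence[VariantRecord], path: str | Path) -> None:
    """TSV emission, round-trippable by :func:`hcmkit.variants.read_variant_table`."""
    write_variant_table(records, path)


def write_cohort_vcf(records: Sequence[VariantRecord], path: str | Path) -> None:
    """Write a VCF 4.2 with one site per distinct variant and per-sample
    genotypes, annotated with the INFO fields the reader expects
    (GENE/EXON/PCHANGE/CCHANGE/VTYPE/CADD/GNOMAD_AF and predictor calls).

    Loci are synthetic: sites are laid out on contig ``1`` in key order;
    scores are stored as typed strings to survive a text round trip exactly.
    """
    import pysam

    header = pysam.VariantHeader()
    header.contigs.add("1", length=500_000_000)
    for field_id, desc in [
        ("GENE", "Gene symbol"),
        ("TRANSCRIPT", "Transcript accession"),
        ("EXON", "Exon number"),
        ("PCHANGE", "Protein change"),
        ("CCHANGE", "Coding DNA change"),
        ("VTYPE", "Variant type"),
        ("CADD", "CADD PHRED score"),
        ("GNOMAD_AF", "gnomAD allele frequency"),
        ("SIFT", "SIFT call"),
        ("POLYPHEN", "PolyPhen-2 call"),
        ("MUTTASTER", "MutationTaster call"),
    ]:
        header.info.add(field_id, 1, "String", desc)
    header.formats.add("GT", 1, "String", "Genotype")
    samples = sorted({r.patient_id for r in records})
    for s in samples:
        header.add_sample(s)

    by_key: dict = {}
    for r in records:
        by_key.setdefault(normalize_key(r), []).append(r)

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for pos0, (key, observations) in enumerate(sorted(by_key.items())):
            proto = observations[0]
            site = out.new_record(
                contig="1", start=pos0 * 10 + 100, alleles=("A", "T")
            )
            if proto.rsid:
                site.id = proto.rsid
            info = site.info
            info["GENE"] = proto.gene
            if proto.transcript:
                info["TRANSCRIPT"] = proto.transcript
            if proto.exon is not None:
                info["EXON"] = str(proto.exon)
            if proto.protein_change:
                info["PCHANGE"] = proto.protein_change.replace(" ", "")
            if proto.cdna_change:
                info["CCHANGE"] = proto.cdna_change.replace(" ", "")
            info["VTYPE"] = proto.variant_type.value
            if proto.cadd is not None:
                info["CADD"] = repr(proto.cadd)
            if proto.gnomad_af is not None:
                info["GNOMAD_AF"] = repr(proto.gnomad_af)
            for tool, key_name in [
                ("SIFT", "SIFT"),
                ("PolyPhen-2", "POLYPHEN"),
                ("MutationTaster", "MUTTASTER"),
            ]:
                call = proto.predictor_calls.get(tool)
                if call is not None and call is not PredictorCall.ABSENT:
                    info[key_name] = call.value
            genotypes = {o.patient_id: o.genotype for o in observations}
            for s in samples:
                gt = genotypes.get(s)
                if gt is None:
                    site.samples[s]["GT"] = (0, 0)
                elif gt is Genotype.HET:
                    site.samples[s]["GT"] = (0, 1)
                else:
                    site.samples[s]["GT"] = (1, 1)
            out.write(site)
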