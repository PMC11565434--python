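"""Domain types for per-patient variant observations and change-notation parsing.

A variant observation is one row of a prioritized-variant table: one patient,
one gene, one coding or protein change, with its annotations (CADD,
population allele frequency, in-silico predictor calls) and curated
classifications (ACMG/AMP class, ClinVar assertion).  Observations of the
same physical variant in different patients are linked through a normalized
:class:`VariantKey`, which is what every distinct-variant count in a cohort
report is computed on.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Genotype",
    "VariantType",
    "ClinvarClass",
    "PredictorCall",
    "VariantRecord",
    "VariantKey",
    "PatientGenotype",
    "VariantParseError",
    "TableSchemaError",
    "classify_variant_type",
    "normalize_change",
    "normalize_key",
    "read_variant_table",
    "write_variant_table",
    "read_annotated_vcf",
    "merge_patients",
]


class Genotype(str, enum.Enum):
    HET = "het"
    HOM = "hom"


class VariantType(str, enum.Enum):
    MISSENSE = "missense"
    STOPGAIN = "stopgain"
    FRAMESHIFT = "frameshift"  # indel kind unknown
    FRAMESHIFT_DELETION = "frameshift_deletion"
    FRAMESHIFT_INSERTION = "frameshift_insertion"
    SPLICING = "splicing"
    INFRAME_INDEL = "inframe_indel"
    STOPLOSS = "stoploss"
    SYNONYMOUS = "synonymous"
    INTRONIC = "intronic"
    INTERGENIC = "intergenic"
    OTHER = "other"

    @property
    def is_frameshift(self) -> bool:
        return self in (
            VariantType.FRAMESHIFT,
            VariantType.FRAMESHIFT_DELETION,
            VariantType.FRAMESHIFT_INSERTION,
        )

    @property
    def is_truncating(self) -> bool:
        """Protein-truncating: stopgain, frameshift, or splice-site."""
        return self is VariantType.STOPGAIN or self is VariantType.SPLICING or self.is_frameshift


class AcmgClass(str, enum.Enum):
    """Five-tier ACMG/AMP classification, ordered P > LP > VUS > LB > B."""

    P = "P"
    LP = "LP"
    VUS = "VUS"
    LB = "LB"
    B = "B"

    @property
    def rank(self) -> int:
        return {"P": 4, "LP": 3, "VUS": 2, "LB": 1, "B": 0}[self.value]

    @property
    def is_plp(self) -> bool:
        return self in (AcmgClass.P, AcmgClass.LP)


class ClinvarClass(str, enum.Enum):
    P = "P"
    LP = "LP"
    VUS = "VUS"
    LB = "LB"
    B = "B"
    CONFLICTING = "conflicting"


class PredictorCall(str, enum.Enum):
    DELETERIOUS = "deleterious"
    TOLERATED = "tolerated"
    ABSENT = "absent"


#: the three predictors used for the in-silico consensus
CONSENSUS_TOOLS = ("SIFT", "PolyPhen-2", "MutationTaster")


class VariantParseError(ValueError):
    """A change-notation string could not be interpreted; carries the token."""

    def __init__(self, message: str, token: str | None = None):
        super().__init__(message)
        self.token = token


class TableSchemaError(ValueError):
    """A tabular input is missing a mandatory column or has a bad row."""


@dataclass
class VariantRecord:
    patient_id: str
    gene: str
    genotype: Genotype
    variant_type: VariantType
    transcript: str | None = None
    exon: int | None = None
    cdna_change: str | None = None
    protein_change: str | None = None
    rsid: str | None = None
    cadd: float | None = None
    acmg_class: AcmgClass | None = None
    clinvar_class: ClinvarClass | None = None
    gnomad_af: float | None = None
    predictor_calls: dict[str, PredictorCall] = field(default_factory=dict)
    #: cross-references to the patient's other variants, as (gene, change) pairs;
    #: an empty list is a sole ("unique") prioritized variant
    additional_variant_refs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.gnomad_af is not None and not (0.0 <= self.gnomad_af <= 1.0):
            raise ValueError(f"gnomad_af out of [0,1]: {self.gnomad_af}")
        if self.cadd is not None and self.cadd < 0:
            raise ValueError(f"negative CADD: {self.cadd}")
        if self.cdna_change is None and self.protein_change is None:
            raise ValueError("record needs at least one change notation")

    @property
    def is_sole_variant(self) -> bool:
        return not self.additional_variant_refs

    def deleterious_call_count(self) -> int:
        return sum(
            1 for c in self.predictor_calls.values() if c is PredictorCall.DELETERIOUS
        )


@dataclass(frozen=True, order=True)
class VariantKey:
    """Normalized identity of a physical variant: gene + canonical change."""

    gene: str
    change: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.gene}:{self.change}"


_EXON_PREFIX = re.compile(r"^ex(on)?\s*(\d+)\s*:\s*", re.IGNORECASE)
_AA3 = (
    "Ala|Arg|Asn|Asp|Cys|Gln|Glu|Gly|His|Ile|Leu|Lys|Met|Phe|Pro|Ser|Thr|Trp|Tyr|Val|Ter|Sec"
)
_MISSENSE_RE = re.compile(rf"^({_AA3})(\d+)({_AA3})$", re.IGNORECASE)
_STOPGAIN_RE = re.compile(rf"^({_AA3})(\d+)(\*|ter)$", re.IGNORECASE)
_FS_RE = re.compile(r"fs", re.IGNORECASE)
_INTRONIC_RE = re.compile(r"^c\.[\d_*-]+\s*([+-])\s*(\d+)")


def split_exon_prefix(change: str) -> tuple[int | None, str]:
    """Strip a leading ``ExN:`` exon tag, returning (exon or None, remainder)."""
    m = _EXON_PREFIX.match(change.strip())
    if m:
        return int(m.group(2)), change.strip()[m.end():].strip()
    return None, change.strip()


def _strip_protein(change: str) -> str:
    s = change.strip()
    _, s = split_exon_prefix(s)
    s = re.sub(r"^p\.", "", s)
    s = s.replace("(", "").replace(")", "").replace(" ", "")
    return s


def splice_offset(cdna_change: str) -> int | None:
    """Signed intronic offset of a cDNA change (e.g. +2, -2, +4), if any."""
    _, s = split_exon_prefix(cdna_change)
    s = s.replace(" ", "")
    m = _INTRONIC_RE.match(s)
    if not m:
        return None
    return int(m.group(1) + m.group(2))


def classify_variant_type(
    protein_change: str | None,
    cdna_change: str | None,
    indel_kind: str | None = None,
) -> VariantType:
    """Map HGVS-style change notation to a variant-type category.

    The protein notation is authoritative when present; a cDNA-only change
    with an intronic offset (e.g. ``c.505+2T>A``) is splicing.  ``indel_kind``
    ("deletion"/"insertion") refines a frameshift call when the underlying
    indel kind is known from annotation; without it a generic frameshift is
    returned.
    """
    if protein_change is None and cdna_change is None:
        raise VariantParseError("no change notation")
    if protein_change is not None:
        s = _strip_protein(protein_change)
        if _FS_RE.search(s):
            if indel_kind == "deletion":
                return VariantType.FRAMESHIFT_DELETION
            if indel_kind == "insertion":
                return VariantType.FRAMESHIFT_INSERTION
            return VariantType.FRAMESHIFT
        if _STOPGAIN_RE.match(s):
            return VariantType.STOPGAIN
        m = _MISSENSE_RE.match(s)
        if m:
            ref, alt = m.group(1).capitalize(), m.group(3).capitalize()
            if ref == "Ter":
                return VariantType.STOPLOSS
            if alt == "Ter":
                return VariantType.STOPGAIN
            if ref == alt:
                return VariantType.SYNONYMOUS
            return VariantType.MISSENSE
        if re.search(r"ext(\*|ter)?", s, re.IGNORECASE):
            return VariantType.STOPLOSS
        if re.search(r"(del|dup|ins)", s, re.IGNORECASE):
            return VariantType.INFRAME_INDEL
        if s == "=":
            return VariantType.SYNONYMOUS
        raise VariantParseError(f"unrecognized protein change: {protein_change!r}", s)
    # cDNA only
    _, s = split_exon_prefix(cdna_change)
    s = s.replace(" ", "")
    if splice_offset(cdna_change) is not None:
        return VariantType.SPLICING
    if not s.startswith("c."):
        raise VariantParseError(f"unrecognized cDNA change: {cdna_change!r}", s)
    return VariantType.OTHER


def normalize_change(change: str) -> str:
    """Canonical, whitespace/case/parenthesis-insensitive change spelling.

    Idempotent; ``fsTer`` and ``fs*`` spellings collapse, as do trailing
    ``Ter``/``*`` stop codons, so that cross-table spellings of one variant
    compare equal.
    """
    _, s = split_exon_prefix(change)
    s = s.replace(" ", "").replace("(", "").replace(")", "")
    s = s.casefold()
    s = s.replace("fster", "fs*")
    s = re.sub(r"(?<=\d)ter$", "*", s)
    return s


def normalize_key(record: VariantRecord) -> VariantKey:
    """Deduplication key: gene + protein change, or cDNA change for splice
    variants (which have no protein-level notation).  The transcript is not
    part of the key — one MANE transcript per gene is assumed."""
    if not record.gene:
        raise VariantParseError("record has no gene symbol")
    if record.protein_change is not None:
        change = normalize_change(record.protein_change)
    elif record.cdna_change is not None:
        change = normalize_change(record.cdna_change)
    else:  # pragma: no cover - guarded by VariantRecord validation
        raise VariantParseError("record has no change notation")
    return VariantKey(gene=record.gene.upper(), change=change)


# ---------------------------------------------------------------------------
# Tabular I/O


_MANDATORY_COLUMNS = ("Patient ID", "Genotype", "Variant type", "AA change")

_TYPE_TOKENS = {
    "missense": VariantType.MISSENSE,
    "stopgain": VariantType.STOPGAIN,
    "frameshift deletion": VariantType.FRAMESHIFT_DELETION,
    "frameshift insertion": VariantType.FRAMESHIFT_INSERTION,
    "frameshift": VariantType.FRAMESHIFT,
    "splicing": VariantType.SPLICING,
    "inframe indel": VariantType.INFRAME_INDEL,
    "stoploss": VariantType.STOPLOSS,
    "synonymous": VariantType.SYNONYMOUS,
    "other": VariantType.OTHER,
}

_TYPE_LABELS = {
    VariantType.MISSENSE: "Missense",
    VariantType.STOPGAIN: "Stopgain",
    VariantType.FRAMESHIFT_DELETION: "Frameshift deletion",
    VariantType.FRAMESHIFT_INSERTION: "Frameshift insertion",
    VariantType.FRAMESHIFT: "Frameshift",
    VariantType.SPLICING: "Splicing",
    VariantType.INFRAME_INDEL: "Inframe indel",
    VariantType.STOPLOSS: "Stoploss",
    VariantType.SYNONYMOUS: "Synonymous",
    VariantType.OTHER: "Other",
}


def _absent(token: str) -> bool:
    return token.strip() in ("", "NA", "na", ".", "None")


def _parse_acmg_clinvar(token: str) -> tuple[AcmgClass | None, ClinvarClass | None]:
    if _absent(token):
        return None, None
    parts = [p.strip() for p in token.split("/")]
    acmg = None if _absent(parts[0]) else AcmgClass(parts[0].upper())
    clinvar = None
    if len(parts) > 1 and not _absent(parts[1]):
        t = parts[1].strip().lower()
        clinvar = ClinvarClass.CONFLICTING if t == "conflicting" else ClinvarClass(parts[1].upper())
    return acmg, clinvar


def _parse_refs(token: str) -> list[tuple[str, str]]:
    if _absent(token) or token.strip().lower() in ("unique variant", "none"):
        return []
    refs: list[tuple[str, str]] = []
    for part in token.split(";"):
        part = part.strip()
        if not part:
            continue
        gene, _, change = part.partition(":")
        if not change:
            raise VariantParseError(f"unparseable cross-reference: {part!r}", part)
        refs.append((gene.strip().upper(), change.strip()))
    return refs


def _record_from_row(
    row: Mapping[str, str],
    line_no: int,
    default_gene: str | None,
    default_transcript: str | None,
) -> VariantRecord:
    gene = row.get("Gene", "").strip() or (default_gene or "")
    if not gene:
        raise TableSchemaError(f"row {line_no}: no gene and no default gene given")
    gt_token = row["Genotype"].strip().lower()
    try:
        genotype = Genotype(gt_token)
    except ValueError:
        raise TableSchemaError(f"row {line_no}: unknown genotype {row['Genotype']!r}")
    vt_token = row["Variant type"].strip().lower()
    if vt_token not in _TYPE_TOKENS:
        raise TableSchemaError(f"row {line_no}: unknown variant type {row['Variant type']!r}")
    variant_type = _TYPE_TOKENS[vt_token]
    exon, change = split_exon_prefix(row["AA change"])
    protein_change = change if change.startswith("p.") else None
    cdna_change = change if change.replace(" ", "").startswith("c.") else None
    if protein_change is None and cdna_change is None:
        raise TableSchemaError(f"row {line_no}: unparseable change {row['AA change']!r}")
    acmg, clinvar = _parse_acmg_clinvar(row.get("ACMG/ClinVar", "NA"))
    af_token = row.get("GnomAD-AF", "NA")
    gnomad_af = None if _absent(af_token) else float(af_token)
    cadd_token = row.get("CADD", "NA")
    cadd = None if _absent(cadd_token) else float(cadd_token)
    rsid_token = row.get("rs ID", "NA")
    return VariantRecord(
        patient_id=row["Patient ID"].strip(),
        gene=gene.upper(),
        transcript=row.get("Transcript", "").strip() or default_transcript,
        genotype=genotype,
        variant_type=variant_type,
        exon=exon,
        protein_change=protein_change,
        cdna_change=cdna_change,
        rsid=None if _absent(rsid_token) else rsid_token.strip(),
        cadd=cadd,
        acmg_class=acmg,
        clinvar_class=clinvar,
        gnomad_af=gnomad_af,
        additional_variant_refs=_parse_refs(row.get("Additional variant", "")),
    )


def read_variant_table(
    path: str | Path,
    default_gene: str | None = None,
    default_transcript: str | None = None,
) -> list[VariantRecord]:
    """Read a prioritized-variant TSV (one row per patient-variant observation).

    Mandatory columns: Patient ID, Genotype, Variant type, AA change; a Gene
    column may be replaced by ``default_gene`` for single-gene tables.  "NA"
    and empty cells denote absent values.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, na_filter=False)
    missing = [c for c in _MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise TableSchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    records = []
    for i, row in enumerate(df.to_dict("records"), start=2):
        records.append(_record_from_row(row, i, default_gene, default_transcript))
    return records


_TABLE_COLUMNS = [
    "Patient ID", "Gene", "Transcript", "Genotype", "Variant type",
    "AA change", "rs ID", "CADD", "ACMG/ClinVar", "GnomAD-AF",
    "Additional variant",
]


def write_variant_table(records: Sequence[VariantRecord], path: str | Path) -> None:
    """Inverse of :func:`read_variant_table` (column order fixed, "NA" for absent)."""
    rows = []
    for r in records:
        change = r.protein_change if r.protein_change is not None else r.cdna_change
        aa = f"Ex{r.exon}:{change}" if r.exon is not None else change
        if r.acmg_class is None and r.clinvar_class is None:
            ac = "NA"
        else:
            left = r.acmg_class.value if r.acmg_class else "NA"
            right = (
                "Conflicting"
                if r.clinvar_class is ClinvarClass.CONFLICTING
                else (r.clinvar_class.value if r.clinvar_class else "NA")
            )
            ac = f"{left}/{right}"
        rows.append(
            {
                "Patient ID": r.patient_id,
                "Gene": r.gene,
                "Transcript": r.transcript or "NA",
                "Genotype": r.genotype.value.capitalize(),
                "Variant type": _TYPE_LABELS[r.variant_type],
                "AA change": aa,
                "rs ID": r.rsid or "NA",
                "CADD": "NA" if r.cadd is None else f"{r.cadd:g}",
                "ACMG/ClinVar": ac,
                "GnomAD-AF": "NA" if r.gnomad_af is None else f"{r.gnomad_af:.10g}",
                "Additional variant": "Unique variant"
                if not r.additional_variant_refs
                else "; ".join(f"{g}: {c}" for g, c in r.additional_variant_refs),
            }
        )
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF ingestion


DEFAULT_VCF_FIELDS = {
    "gene": "GENE",
    "transcript": "TRANSCRIPT",
    "exon": "EXON",
    "protein_change": "PCHANGE",
    "cdna_change": "CCHANGE",
    "variant_type": "VTYPE",
    "cadd": "CADD",
    "gnomad_af": "GNOMAD_AF",
    "predictors": {"SIFT": "SIFT", "PolyPhen-2": "POLYPHEN", "MutationTaster": "MUTTASTER"},
}


def read_annotated_vcf(
    path: str | Path,
    field_map: Mapping[str, object] | None = None,
    on_missing: str = "skip",
) -> list[VariantRecord]:
    """Read an annotated VCF into variant observations, one per carrier sample.

    ``field_map`` names the INFO keys holding gene/consequence/score
    annotations (see :data:`DEFAULT_VCF_FIELDS`).  Heterozygous calls (0/1)
    map to ``het`` and homozygous-alt (1/1) to ``hom``; reference-only samples
    emit nothing.  Sites lacking a mandatory annotation are skipped with a
    warning (``on_missing="skip"``) or raise (``on_missing="fail"``).
    """
    import warnings

    from cyvcf2 import VCF

    fmap = dict(DEFAULT_VCF_FIELDS)
    if field_map:
        fmap.update(field_map)
    records: list[VariantRecord] = []
    vcf = VCF(str(path))
    samples = vcf.samples
    for site in vcf:
        info = dict(site.INFO)
        gene = info.get(fmap["gene"])
        if gene is None:
            if on_missing == "fail":
                raise TableSchemaError(f"site {site.CHROM}:{site.POS} lacks {fmap['gene']}")
            warnings.warn(f"skipping {site.CHROM}:{site.POS}: no {fmap['gene']} annotation")
            continue
        pchange = info.get(fmap["protein_change"])
        cchange = info.get(fmap["cdna_change"])
        vtype_token = info.get(fmap["variant_type"], "other")
        vtype = _TYPE_TOKENS.get(str(vtype_token).replace("_", " ").lower(), VariantType.OTHER)
        cadd = info.get(fmap["cadd"])
        af = info.get(fmap["gnomad_af"])
        exon = info.get(fmap["exon"])
        calls = {}
        for tool, key in fmap["predictors"].items():
            val = info.get(key)
            if val is not None:
                calls[tool] = PredictorCall(str(val).lower())
        for sample_i, gt in enumerate(site.gt_types):
            # cyvcf2: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
            if gt == 1:
                genotype = Genotype.HET
            elif gt == 3:
                genotype = Genotype.HOM
            else:
                continue
            records.append(
                VariantRecord(
                    patient_id=samples[sample_i],
                    gene=str(gene).upper(),
                    transcript=info.get(fmap["transcript"]),
                    genotype=genotype,
                    variant_type=vtype,
                    exon=int(exon) if exon is not None else None,
                    protein_change=pchange,
                    cdna_change=cchange,
                    rsid=site.ID,
                    cadd=float(cadd) if cadd is not None else None,
                    gnomad_af=float(af) if af is not None else None,
                    predictor_calls=calls,
                )
            )
    return records


# ---------------------------------------------------------------------------
# Patient-level merge


@dataclass
class PatientGenotype:
    """All prioritized observations of one patient, merged across tables.

    ``phantom_genes`` holds genes mentioned in the patient's cross-reference
    column that have no tabulated row of their own; multilocus classification
    counts them, per-gene carrier counts do not.
    """

    patient_id: str
    records: list[VariantRecord] = field(default_factory=list)
    phantom_genes: set[str] = field(default_factory=set)

    @property
    def genes(self) -> set[str]:
        return {r.gene for r in self.records}

    @property
    def genes_with_phantoms(self) -> set[str]:
        return self.genes | self.phantom_genes

    @property
    def is_sole_variant_carrier(self) -> bool:
        return len(self.records) == 1 and not self.phantom_genes

    @property
    def is_same_gene_multi(self) -> bool:
        return len(self.records) >= 2 and len(self.genes_with_phantoms) == 1

    @property
    def is_digenic(self) -> bool:
        return len(self.genes_with_phantoms) == 2

    @property
    def is_oligogenic(self) -> bool:
        return len(self.genes_with_phantoms) >= 3

    @property
    def has_homozygous(self) -> bool:
        return any(r.genotype is Genotype.HOM for r in self.records)


def merge_patients(records: Iterable[VariantRecord]) -> dict[str, PatientGenotype]:
    """Group observations by patient and resolve cross-references.

    A cross-reference that matches one of the patient's own rows (same gene,
    same canonical change) is confirmation; one that matches nothing becomes a
    phantom-gene entry, so the patient's locus count reflects the printed
    cross-reference even when the referenced row was never tabulated.
    """
    patients: dict[str, PatientGenotype] = {}
    for rec in records:
        patients.setdefault(rec.patient_id, PatientGenotype(rec.patient_id)).records.append(rec)
    for pg in patients.values():
        own = {(r.gene, normalize_change(c)) for r in pg.records
               for c in (r.protein_change, r.cdna_change) if c is not None}
        for rec in pg.records:
            for gene, change in rec.additional_variant_refs:
                if (gene, normalize_change(change)) not in own:
                    pg.phantom_genes.add(gene)
        pg.phantom_genes -= pg.genes
    return patients
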