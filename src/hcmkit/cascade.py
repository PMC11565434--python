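"""The variant prioritization cascade.

Stage order is fixed: rarity (gnomAD AF < 1%), consequence (drop intergenic,
deep-intronic and synonymous changes), in-silico consensus (>= 3 deleterious
predictor calls and CADD > 15 for missense changes), then gene-mechanism
rules (haploinsufficiency genes favour truncating alleles, LoF-tolerant
dominant-negative genes favour missense, recessive genes need homozygous or
multi-variant carriers).  Each stage reports per-record drop reasons in a
:class:`CascadeAudit`.

Thresholds are strict inequalities: an allele at exactly 1% frequency is
dropped, a CADD of exactly 15 is low confidence.  Absent allele frequency
means "not observed in gnomAD" and is kept — many pathogenic alleles are
absent from population databases, and treating absence as zero would be the
same thing; treating it as common would be wrong.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .panel import GenePanel, Mechanism, Inheritance, Tier
from .variants import VariantRecord, VariantType, merge_patients

__all__ = [
    "CascadeConfig",
    "CascadeAudit",
    "Confidence",
    "GeneRuleFlag",
    "filter_rarity",
    "filter_consequence",
    "insilico_consensus",
    "apply_gene_rules",
    "run_cascade",
]


@dataclass
class CascadeConfig:
    af_threshold: float = 0.01
    cadd_min: float = 15.0
    min_deleterious_tools: int = 3
    retain_in_established_genes: bool = True
    population: str = "gnomAD global"

    def __post_init__(self) -> None:
        if not (0.0 < self.af_threshold <= 1.0):
            raise ValueError("af_threshold must be in (0, 1]")
        if self.min_deleterious_tools < 1:
            raise ValueError("min_deleterious_tools must be >= 1")


class Confidence(str, enum.Enum):
    HIGH = "high_confidence"
    LOW = "low_confidence"


class GeneRuleFlag(str, enum.Enum):
    MECHANISM_CONCORDANT = "mechanism_concordant"
    MECHANISM_DISCORDANT = "mechanism_discordant"
    INHERITANCE_CONCORDANT = "inheritance_concordant"
    PANEL_UNKNOWN = "panel_unknown"
    NONE = "none"


@dataclass
class StageAudit:
    stage: str
    n_in: int
    n_out: int
    drop_reasons: list[tuple[VariantRecord, str]] = field(default_factory=list)


@dataclass
class CascadeAudit:
    stages: list[StageAudit] = field(default_factory=list)
    #: per-record stage annotations (confidence, gene-rule flags)
    confidence: dict[int, Confidence] = field(default_factory=dict)
    rule_flags: dict[int, GeneRuleFlag] = field(default_factory=dict)

    def add(self, stage: StageAudit) -> None:
        if len(stage.drop_reasons) != stage.n_in - stage.n_out:
            raise ValueError("audit drop count does not match in/out difference")
        self.stages.append(stage)

    def as_rows(self) -> list[dict]:
        return [
            {"stage": s.stage, "in": s.n_in, "out": s.n_out, "dropped": s.n_in - s.n_out}
            for s in self.stages
        ]


def filter_rarity(
    records: list[VariantRecord], config: CascadeConfig | None = None
) -> tuple[list[VariantRecord], StageAudit]:
    """Keep records with gnomAD AF strictly below the threshold or absent."""
    config = config or CascadeConfig()
    kept, dropped = [], []
    for r in records:
        if r.gnomad_af is not None and r.gnomad_af < 0:  # pragma: no cover - model guards
            raise ValueError(f"negative allele frequency on {r.patient_id}/{r.gene}")
        if r.gnomad_af is None or r.gnomad_af < config.af_threshold:
            kept.append(r)
        else:
            dropped.append((r, f"af {r.gnomad_af:g} >= {config.af_threshold:g}"))
    return kept, StageAudit("rarity", len(records), len(kept), dropped)


def filter_consequence(
    records: list[VariantRecord],
) -> tuple[list[VariantRecord], StageAudit]:
    """Drop intergenic, deep-intronic and synonymous records; splice-region
    intronic changes (those carrying an offset) are splicing and are kept."""
    kept, dropped = [], []
    for r in records:
        if r.variant_type in (
            VariantType.SYNONYMOUS,
            VariantType.INTRONIC,
            VariantType.INTERGENIC,
        ):
            dropped.append((r, r.variant_type.value))
        else:
            kept.append(r)
    return kept, StageAudit("consequence", len(records), len(kept), dropped)


def insilico_consensus(
    record: VariantRecord, config: CascadeConfig | None = None
) -> Confidence:
    """High confidence of pathogenicity for a missense change requires both a
    predictor consensus (deleterious calls from at least
    ``min_deleterious_tools`` of SIFT / PolyPhen-2 / MutationTaster) and
    CADD > ``cadd_min``.  Truncating and splice records are gated by gene
    mechanism instead of predictor scores (their CADD is often unscored);
    they score high by type, falling back to the CADD cut when scored.
    """
    config = config or CascadeConfig()
    if record.variant_type.is_truncating:
        if record.cadd is None or record.cadd > config.cadd_min:
            return Confidence.HIGH
        return Confidence.LOW
    if record.cadd is None or record.cadd <= config.cadd_min:
        return Confidence.LOW
    if record.deleterious_call_count() >= config.min_deleterious_tools:
        return Confidence.HIGH
    return Confidence.LOW


def apply_gene_rules(
    records: list[VariantRecord],
    panel: GenePanel,
) -> tuple[dict[int, GeneRuleFlag], StageAudit]:
    """Annotate records with mechanism/inheritance concordance flags.

    Haploinsufficiency genes: truncating alleles are mechanism-concordant.
    LoF-tolerant (dominant-negative) genes: missense alleles are concordant
    and truncating alleles are flagged discordant but retained — discordance
    is a review flag, not a filter.  For recessive genes, homozygous or
    multi-variant carriers are inheritance-concordant.  Genes absent from
    the panel are flagged unknown and retained.
    """
    patients = merge_patients(records)
    flags: dict[int, GeneRuleFlag] = {}
    for r in records:
        entry = panel.get(r.gene)
        if entry is None:
            flags[id(r)] = GeneRuleFlag.PANEL_UNKNOWN
            continue
        flag = GeneRuleFlag.NONE
        if entry.mechanism is Mechanism.HAPLOINSUFFICIENCY:
            if r.variant_type.is_truncating:
                flag = GeneRuleFlag.MECHANISM_CONCORDANT
        elif entry.mechanism in (Mechanism.DOMINANT_NEGATIVE, Mechanism.LOF_TOLERANT):
            if r.variant_type is VariantType.MISSENSE:
                flag = GeneRuleFlag.MECHANISM_CONCORDANT
            elif r.variant_type.is_truncating:
                flag = GeneRuleFlag.MECHANISM_DISCORDANT
        if entry.inheritance is Inheritance.AR:
            pg = patients[r.patient_id]
            n_in_gene = sum(1 for x in pg.records if x.gene == r.gene)
            if r.genotype.value == "hom" or n_in_gene >= 2:
                flag = GeneRuleFlag.INHERITANCE_CONCORDANT
        flags[id(r)] = flag
    return flags, StageAudit("gene_rules", len(records), len(records), [])


def run_cascade(
    records: list[VariantRecord],
    panel: GenePanel,
    config: CascadeConfig | None = None,
) -> tuple[list[VariantRecord], CascadeAudit]:
    """Compose the four stages in the published order.

    Records in panel genes (core/minor/emerging) that fail the in-silico
    consensus are retained with a low-confidence flag when
    ``retain_in_established_genes`` (default) — published prioritized tables
    include benign-class co-occurring alleles — and dropped in strict mode.
    Excluded-tier genes are never emitted.
    """
    config = config or CascadeConfig()
    audit = CascadeAudit()

    excl_kept, excl_dropped = [], []
    for r in records:
        entry = panel.get(r.gene)
        if entry is not None and entry.tier is Tier.EXCLUDED:
            excl_dropped.append((r, "excluded gene"))
        else:
            excl_kept.append(r)
    audit.add(StageAudit("panel_exclusion", len(records), len(excl_kept), excl_dropped))

    rare, st = filter_rarity(excl_kept, config)
    audit.add(st)
    conseq, st = filter_consequence(rare)
    audit.add(st)

    kept, dropped = [], []
    for r in conseq:
        conf = insilico_consensus(r, config)
        audit.confidence[id(r)] = conf
        in_panel = r.gene in panel and panel[r.gene].tier is not Tier.EXCLUDED
        if conf is Confidence.HIGH or (config.retain_in_established_genes and in_panel):
            kept.append(r)
        else:
            dropped.append((r, "low in-silico confidence"))
    audit.add(StageAudit("insilico_consensus", len(conseq), len(kept), dropped))

    flags, st = apply_gene_rules(kept, panel)
    audit.rule_flags.update(flags)
    audit.add(st)
    return kept, audit
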