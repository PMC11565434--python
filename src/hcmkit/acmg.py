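"""ACMG/AMP evidence combination.

Evidence criteria (PVS1, PS1–PS4, PM1–PM6, PP1–PP5 on the pathogenic side;
BA1, BS1–BS4, BP1–BP7 on the benign side) are combined into the five-tier
classification (P / LP / VUS / LB / B) by the standard combining rules.
A criterion may carry a strength modifier, in which case it counts in its
modified bucket (e.g. PVS1_moderate counts as moderate evidence).  When the
pathogenic and the benign rule sets are both satisfied the evidence is
contradictory and the result is VUS.

The heuristic auto-assigner derives a small, documented subset of criteria
from annotations and gene mechanism; it is a tool for synthetic data and
triage, never an override of curated classifications.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Iterable

from .cascade import CascadeConfig, Confidence, insilico_consensus
from .panel import GenePanel, Mechanism
from .variants import AcmgClass, VariantRecord

__all__ = [
    "Strength",
    "AcmgCriterion",
    "AcmgEvidence",
    "AcmgClass",
    "combine_criteria",
    "auto_assign",
    "PATHOGENIC_CRITERIA",
    "BENIGN_CRITERIA",
]

PATHOGENIC_CRITERIA = (
    "PVS1",
    "PS1", "PS2", "PS3", "PS4",
    "PM1", "PM2", "PM3", "PM4", "PM5", "PM6",
    "PP1", "PP2", "PP3", "PP4", "PP5",
)
BENIGN_CRITERIA = (
    "BA1",
    "BS1", "BS2", "BS3", "BS4",
    "BP1", "BP2", "BP3", "BP4", "BP5", "BP6", "BP7",
)
_VALID_IDS = frozenset(PATHOGENIC_CRITERIA) | frozenset(BENIGN_CRITERIA)


class Strength(str, enum.Enum):
    STAND_ALONE = "stand_alone"  # benign only (BA)
    VERY_STRONG = "very_strong"
    STRONG = "strong"
    MODERATE = "moderate"
    SUPPORTING = "supporting"


_DEFAULT_STRENGTH = {
    "PVS": Strength.VERY_STRONG,
    "PS": Strength.STRONG,
    "PM": Strength.MODERATE,
    "PP": Strength.SUPPORTING,
    "BA": Strength.STAND_ALONE,
    "BS": Strength.STRONG,
    "BP": Strength.SUPPORTING,
}

_PREFIX_RE = re.compile(r"^(PVS|PS|PM|PP|BA|BS|BP)")


@dataclass(frozen=True)
class AcmgCriterion:
    """One criterion flag, e.g. ``PVS1`` or ``PVS1_moderate``."""

    id: str
    strength: Strength | None = None  # None = the criterion's default bucket

    def __post_init__(self) -> None:
        if self.id not in _VALID_IDS:
            raise ValueError(f"unknown ACMG criterion id: {self.id!r}")

    @property
    def prefix(self) -> str:
        return _PREFIX_RE.match(self.id).group(1)

    @property
    def is_pathogenic_side(self) -> bool:
        return self.prefix in ("PVS", "PS", "PM", "PP")

    @property
    def effective_strength(self) -> Strength:
        return self.strength or _DEFAULT_STRENGTH[self.prefix]

    @classmethod
    def parse(cls, token: str) -> "AcmgCriterion":
        """Parse ``PM2`` or ``PVS1_moderate`` style tokens."""
        cid, _, mod = token.strip().partition("_")
        return cls(cid.upper(), Strength(mod.lower()) if mod else None)


@dataclass
class AcmgEvidence:
    criteria: frozenset[AcmgCriterion] = frozenset()
    heuristic: bool = False

    def __post_init__(self) -> None:
        ids = [c.id for c in self.criteria]
        if len(ids) != len(set(ids)):
            raise ValueError("a criterion id may appear at most once")
        object.__setattr__(self, "criteria", frozenset(self.criteria))

    @classmethod
    def of(cls, *tokens: str, heuristic: bool = False) -> "AcmgEvidence":
        return cls(frozenset(AcmgCriterion.parse(t) for t in tokens), heuristic=heuristic)

    def count(self, pathogenic: bool, strength: Strength) -> int:
        return sum(
            1
            for c in self.criteria
            if c.is_pathogenic_side == pathogenic and c.effective_strength is strength
        )


def _pathogenic_met(ev: AcmgEvidence) -> tuple[bool, bool]:
    """(pathogenic rule satisfied, likely-pathogenic rule satisfied)."""
    nvs = ev.count(True, Strength.VERY_STRONG)
    ns = ev.count(True, Strength.STRONG)
    nm = ev.count(True, Strength.MODERATE)
    np_ = ev.count(True, Strength.SUPPORTING)

    pathogenic = (
        (nvs >= 1 and (ns >= 1 or nm >= 2 or (nm == 1 and np_ >= 1) or np_ >= 2))
        or nvs >= 2
        or ns >= 2
        or (ns == 1 and (nm >= 3 or (nm == 2 and np_ >= 2) or (nm == 1 and np_ >= 4)))
    )
    likely = (
        (nvs >= 1 and nm >= 1)
        or (ns == 1 and 1 <= nm <= 2)
        or (ns == 1 and np_ >= 2)
        or nm >= 3
        or (nm == 2 and np_ >= 2)
        or (nm == 1 and np_ >= 4)
    )
    return pathogenic, likely


def _benign_met(ev: AcmgEvidence) -> tuple[bool, bool]:
    """(benign rule satisfied, likely-benign rule satisfied)."""
    nsa = ev.count(False, Strength.STAND_ALONE)
    nbs = ev.count(False, Strength.STRONG)
    nbp = ev.count(False, Strength.SUPPORTING)
    benign = nsa >= 1 or nbs >= 2
    likely = (nbs == 1 and nbp >= 1) or nbp >= 2
    return benign, likely


def combine_criteria(evidence: AcmgEvidence | Iterable[str]) -> AcmgClass:
    """Apply the combining rules to an evidence set.

    Contradictory evidence (both a pathogenic and a benign rule satisfied)
    and evidence satisfying no rule both classify as VUS.
    """
    if not isinstance(evidence, AcmgEvidence):
        evidence = AcmgEvidence.of(*evidence)
    path, likely_path = _pathogenic_met(evidence)
    benign, likely_benign = _benign_met(evidence)
    path_side = path or likely_path
    benign_side = benign or likely_benign
    # strong-or-stronger evidence on the opposite side voids a classification:
    # the evidence is contradictory, not resolved by either rule set
    strong_path = any(
        c.is_pathogenic_side
        and c.effective_strength in (Strength.VERY_STRONG, Strength.STRONG)
        for c in evidence.criteria
    )
    strong_benign = any(
        not c.is_pathogenic_side
        and c.effective_strength in (Strength.STAND_ALONE, Strength.STRONG)
        for c in evidence.criteria
    )
    if (path_side and benign_side) or (benign_side and strong_path) or (path_side and strong_benign):
        return AcmgClass.VUS
    if path:
        return AcmgClass.P
    if likely_path:
        return AcmgClass.LP
    if benign:
        return AcmgClass.B
    if likely_benign:
        return AcmgClass.LB
    return AcmgClass.VUS


@dataclass
class AutoAssignConfig:
    rare_af: float = 1e-4       # PM2 bound: absent or rarer than this
    ba1_af: float = 0.05        # stand-alone common-allele bound
    bs1_af: float = 0.01        # greater than expected for the disorder


def auto_assign(
    record: VariantRecord,
    panel: GenePanel,
    config: CascadeConfig | None = None,
    assign_config: AutoAssignConfig | None = None,
) -> AcmgEvidence:
    """Heuristic evidence from annotations and gene mechanism.

    PVS1 for a truncating allele in a haploinsufficiency gene; PM2 for an
    allele absent from gnomAD or rarer than the PM2 bound; PP3 for an
    in-silico high-confidence call; BA1 above 5% allele frequency; BS1 above
    the disease-incidence bound.  The result is marked heuristic and must
    never overwrite a curated class.
    """
    cfg = assign_config or AutoAssignConfig()
    tokens: list[str] = []
    entry = panel.get(record.gene)
    if (
        entry is not None
        and entry.mechanism is Mechanism.HAPLOINSUFFICIENCY
        and record.variant_type.is_truncating
    ):
        tokens.append("PVS1")
    if record.gnomad_af is None or record.gnomad_af < cfg.rare_af:
        tokens.append("PM2")
    if insilico_consensus(record, config) is Confidence.HIGH and not record.variant_type.is_truncating:
        tokens.append("PP3")
    if record.gnomad_af is not None:
        if record.gnomad_af > cfg.ba1_af:
            tokens.append("BA1")
        elif record.gnomad_af > cfg.bs1_af:
            tokens.append("BS1")
    return AcmgEvidence.of(*tokens, heuristic=True)


def classify_record(
    record: VariantRecord,
    panel: GenePanel,
    config: CascadeConfig | None = None,
) -> tuple[AcmgClass, AcmgEvidence | None, bool]:
    """Report the curated class when present, else the heuristic one.

    Returns (reported class, heuristic evidence, disagreement flag); the
    disagreement flag is true when a curated class exists and the heuristic
    engine disagrees with it — logged by callers, never asserted.
    """
    evidence = auto_assign(record, panel, config)
    heuristic_class = combine_criteria(evidence)
    if record.acmg_class is not None:
        return record.acmg_class, evidence, record.acmg_class is not heuristic_class
    return heuristic_class, evidence, False
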