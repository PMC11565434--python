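"""Gene panel registry: tiers, disease mechanisms, inheritance, and
gene–disease validity, plus panel assembly and ontology-term expansion.

The panel model follows how reanalysis pipelines tier their search space:
the eight core sarcomeric genes with definitive disease association
(MYBPC3, MYH7, TNNT2, TNNI3, TPM1, ACTC1, MYL2, MYL3), minor established
genes, recently emerging genes, and an explicit exclusion list (TTN,
syndromic genes and phenocopies) that the filtering stages never emit.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Tier",
    "Mechanism",
    "Inheritance",
    "Validity",
    "GenePanelEntry",
    "GenePanel",
    "PanelVenn",
    "build_panel",
    "expand_by_ontology",
    "validity_tally",
    "read_panel_table",
    "read_validity_table",
    "default_panel",
    "CORE_SARCOMERIC",
]

CORE_SARCOMERIC = frozenset(
    {"MYBPC3", "MYH7", "TNNT2", "TNNI3", "TPM1", "ACTC1", "MYL3", "MYL2"}
)


class Tier(str, enum.Enum):
    CORE_SARCOMERIC = "core_sarcomeric"
    MINOR = "minor"
    EMERGING = "emerging"
    EXCLUDED = "excluded"


class Mechanism(str, enum.Enum):
    HAPLOINSUFFICIENCY = "haploinsufficiency"
    DOMINANT_NEGATIVE = "dominant_negative"
    LOF_TOLERANT = "lof_tolerant"
    UNKNOWN = "unknown"


class Inheritance(str, enum.Enum):
    AD = "AD"
    AR = "AR"
    SD = "SD"
    BOTH = "both"
    UNKNOWN = "unknown"


class Validity(str, enum.Enum):
    DEFINITIVE = "definitive"
    MODERATE = "moderate"
    LIMITED = "limited"
    DISPUTED = "disputed"
    NOT_CURATED = "not_curated"
    UNDER_CURATION = "under_curation"

    @property
    def strength(self) -> int:
        order = {
            "definitive": 5,
            "moderate": 4,
            "limited": 3,
            "disputed": 2,
            "under_curation": 1,
            "not_curated": 0,
        }
        return order[self.value]


@dataclass
class GenePanelEntry:
    symbol: str
    tier: Tier = Tier.MINOR
    mechanism: Mechanism = Mechanism.UNKNOWN
    inheritance: Inheritance = Inheritance.UNKNOWN
    #: all curated (validity, inheritance) pairs for the phenotype; a gene may
    #: carry both a recessive and a dominant curation (e.g. TRIM63, CSRP3)
    validity_rows: list[tuple[Validity, Inheritance]] = field(default_factory=list)
    provenance: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.tier is Tier.CORE_SARCOMERIC and self.symbol not in CORE_SARCOMERIC:
            raise ValueError(f"{self.symbol} is not a core sarcomeric gene")

    @property
    def primary_validity(self) -> Validity:
        """Strongest curated validity (definitive > moderate > limited > disputed)."""
        if not self.validity_rows:
            return Validity.NOT_CURATED
        return max((v for v, _ in self.validity_rows), key=lambda v: v.strength)

    @property
    def tally_validity(self) -> Validity:
        """Validity used for dominant-centric headline tallies.

        When a gene's strongest evidence is for recessive disease only and a
        dominant curation also exists (TRIM63: moderate-AR / disputed-AD),
        the dominant row governs the tally — recessive-only evidence does not
        elevate a gene in a dominant-acting cohort summary.
        """
        if not self.validity_rows:
            return Validity.NOT_CURATED
        best_v, best_i = max(self.validity_rows, key=lambda vi: vi[0].strength)
        if best_i is Inheritance.AR:
            ad_rows = [v for v, i in self.validity_rows if i is Inheritance.AD]
            if ad_rows:
                return max(ad_rows, key=lambda v: v.strength)
        return best_v


@dataclass
class PanelVenn:
    """Three-way gene categorization across the initial and current analyses."""

    previously_analyzed: set[str]
    overlapping: set[str]
    newly_identified: set[str]

    def __post_init__(self) -> None:
        if (
            self.previously_analyzed & self.overlapping
            or self.previously_analyzed & self.newly_identified
            or self.overlapping & self.newly_identified
        ):
            raise ValueError("Venn sets must be pairwise disjoint")


class GenePanel:
    """Mapping of gene symbol to :class:`GenePanelEntry`."""

    def __init__(self, entries: Iterable[GenePanelEntry] = ()):
        self._entries: dict[str, GenePanelEntry] = {}
        for e in entries:
            self._entries[e.symbol.upper()] = e

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in self._entries

    def __getitem__(self, symbol: str) -> GenePanelEntry:
        return self._entries[symbol.upper()]

    def get(self, symbol: str) -> GenePanelEntry | None:
        return self._entries.get(symbol.upper())

    def __iter__(self):
        return iter(self._entries.values())

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def symbols(self) -> set[str]:
        return set(self._entries)

    def active_symbols(self) -> set[str]:
        """Genes searched by the cascade (everything not excluded)."""
        return {s for s, e in self._entries.items() if e.tier is not Tier.EXCLUDED}

    def genes_in_tier(self, tier: Tier) -> set[str]:
        return {s for s, e in self._entries.items() if e.tier is tier}

    def add(self, entry: GenePanelEntry) -> None:
        self._entries[entry.symbol.upper()] = entry


def build_panel(
    omim_genes: set[str],
    clingen_entries: Mapping[str, list[tuple[Validity, Inheritance]]] | None,
    literature_genes: set[str],
    initial_panel: set[str],
    exclusions: set[str],
    tiers: Mapping[str, Tier] | None = None,
    mechanisms: Mapping[str, Mechanism] | None = None,
) -> tuple[GenePanel, PanelVenn]:
    """Assemble the reanalysis panel and the initial-vs-current Venn split.

    The current panel is the union of the OMIM-matched, ClinGen-curated and
    literature-mined sources minus the exclusions; provenance is recorded per
    gene.  A gene present both in a source and in the exclusion list stays
    excluded (with a warning).  Excluded genes are carried as ``excluded``
    tier entries so downstream stages can reject them explicitly.
    """
    omim = {g.upper() for g in omim_genes}
    lit = {g.upper() for g in literature_genes}
    initial = {g.upper() for g in initial_panel}
    excl = {g.upper() for g in exclusions}
    clingen = {g.upper(): rows for g, rows in (clingen_entries or {}).items()}

    sources = omim | lit | set(clingen)
    for g in sorted(sources & excl):
        logger.warning("gene %s is in both a panel source and the exclusion list; kept excluded", g)
    current = sources - excl

    panel = GenePanel()
    for g in sorted(current | excl | (initial & excl)):
        provenance = set()
        if g in omim:
            provenance.add("omim_hcm")
        if g in clingen:
            provenance.add("clingen")
        if g in lit:
            provenance.add("literature")
        if g in initial:
            provenance.add("initial_panel")
        tier = Tier.EXCLUDED if g in excl else (tiers or {}).get(g, Tier.MINOR)
        if tier is not Tier.EXCLUDED and g in CORE_SARCOMERIC:
            tier = Tier.CORE_SARCOMERIC
        panel.add(
            GenePanelEntry(
                symbol=g,
                tier=tier,
                mechanism=(mechanisms or {}).get(g, Mechanism.UNKNOWN),
                validity_rows=clingen.get(g, []),
                provenance=provenance,
            )
        )
    venn = PanelVenn(
        previously_analyzed=initial - current,
        overlapping=initial & current,
        newly_identified=current - initial,
    )
    return panel, venn


def expand_by_ontology(
    term_ids: Iterable[str],
    term2gene: Mapping[str, set[str]],
    panel_genes: set[str] = frozenset(),
) -> set[str]:
    """Union of the genes annotated to the queried ontology terms, minus the
    genes already on the panel — the "additional genes" of a phenotype-driven
    panel extension.  Unknown terms are skipped with a warning."""
    genes: set[str] = set()
    for term in term_ids:
        if term not in term2gene:
            logger.warning("unknown ontology term %s skipped", term)
            continue
        genes |= {g.upper() for g in term2gene[term]}
    return genes - {g.upper() for g in panel_genes}


def validity_tally(entries: Iterable[GenePanelEntry]) -> dict[Validity, int]:
    """Count genes per gene–disease validity class (dominant-centric bucketing,
    see :attr:`GenePanelEntry.tally_validity`).  "Robust" association means
    definitive."""
    counts: dict[Validity, int] = {}
    for e in entries:
        v = e.tally_validity
        counts[v] = counts.get(v, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# Curated-table I/O


def read_validity_table(path: str | Path) -> dict[str, list[tuple[Validity, Inheritance]]]:
    """Read a gene-validity TSV (columns: Gene symbol, HCM validity,
    Inheritance), one row per curation; genes may repeat."""
    df = pd.read_csv(path, sep="\t", dtype=str, na_filter=False)
    rows: dict[str, list[tuple[Validity, Inheritance]]] = {}
    for _, r in df.iterrows():
        inh_token = r["Inheritance"].strip()
        inh = Inheritance.UNKNOWN if inh_token in ("", "NA") else Inheritance(inh_token)
        rows.setdefault(r["Gene symbol"].strip().upper(), []).append(
            (Validity(r["HCM validity"].strip()), inh)
        )
    return rows


def read_panel_table(
    path: str | Path,
    validity: Mapping[str, list[tuple[Validity, Inheritance]]] | None = None,
) -> GenePanel:
    """Read a panel TSV (columns: Symbol, Tier, Mechanism, Inheritance,
    Provenance) into a :class:`GenePanel`, attaching validity curations."""
    df = pd.read_csv(path, sep="\t", dtype=str, na_filter=False)
    panel = GenePanel()
    for _, r in df.iterrows():
        sym = r["Symbol"].strip().upper()
        panel.add(
            GenePanelEntry(
                symbol=sym,
                tier=Tier(r["Tier"].strip()),
                mechanism=Mechanism(r["Mechanism"].strip()),
                inheritance=Inheritance(r["Inheritance"].strip()),
                validity_rows=(validity or {}).get(sym, []),
                provenance=set(filter(None, r.get("Provenance", "").split(","))),
            )
        )
    return panel


def default_panel() -> GenePanel:
    """The packaged reanalysis panel with its gene–disease validity curations."""
    data = resources.files("hcmkit.data")
    with resources.as_file(data / "gene_validity.tsv") as p:
        validity = read_validity_table(p)
    with resources.as_file(data / "panel.tsv") as p:
        return read_panel_table(p, validity)
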