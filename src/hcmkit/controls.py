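"""Control-cohort allele-frequency arithmetic and case/control overlap.

Allele frequencies are kept as exact rationals (allele count over allele
number); the display string mimics how control-cohort tables are printed:
values at or above 1e-3 are truncated — not rounded — to four decimal places
with trailing zeros stripped, smaller values use scientific notation with a
five-significant-digit truncated mantissa (3/1920 prints "0.0015", 1/1920
prints "5.2083e-4").
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable

import pandas as pd

from .variants import VariantKey, VariantRecord, normalize_change, normalize_key

__all__ = [
    "ControlVariantRecord",
    "compute_af",
    "format_af",
    "read_control_table",
    "overlap_report",
    "control_retention_filter",
]


@dataclass(frozen=True)
class ControlVariantRecord:
    variant: VariantKey
    allele_count: int
    n_homozygotes: int
    allele_number: int
    highest_pop_label: str | None = None

    def __post_init__(self) -> None:
        if self.allele_number <= 0:
            raise ValueError("allele_number must be positive")
        if self.allele_count < 0 or self.allele_count > self.allele_number:
            raise ValueError("allele_count must lie in [0, allele_number]")
        if 2 * self.n_homozygotes > self.allele_count:
            raise ValueError("2 * n_homozygotes cannot exceed allele_count")

    @property
    def af(self) -> Fraction:
        return compute_af(self.allele_count, self.allele_number)

    @property
    def af_display(self) -> str:
        return format_af(self.af)


def compute_af(allele_count: int, allele_number: int) -> Fraction:
    """Exact allele frequency: count / number as a rational."""
    if allele_number == 0:
        raise ValueError("allele_number must be positive")
    return Fraction(allele_count, allele_number)


def _truncate(value: Fraction, decimals: int) -> str:
    scaled = int(value * 10**decimals)  # floor for non-negative values
    s = f"{scaled / 10**decimals:.{decimals}f}"
    s = s.rstrip("0").rstrip(".")
    return s or "0"


def format_af(af: Fraction) -> str:
    """Printed-table display style (truncating, never rounding up)."""
    if af == 0:
        return "0"
    if af >= Fraction(1, 1000):
        return _truncate(af, 4)
    # scientific notation, mantissa truncated to 5 significant digits
    exponent = 0
    x = af
    while x < 1:
        x *= 10
        exponent -= 1
    mantissa = int(x * 10**4) / 10**4  # 1 digit before the point + 4 after
    m = f"{mantissa:.4f}".rstrip("0").rstrip(".")
    return f"{m}e{exponent}"


def read_control_table(path: str | Path) -> list[ControlVariantRecord]:
    """Read a control-cohort TSV (Variant, Allele count, Number of
    homozygotes, Allele number, ...); the variant column holds
    ``GENE: p.Change`` labels."""
    df = pd.read_csv(path, sep="\t", dtype=str, na_filter=False)
    out = []
    for _, r in df.iterrows():
        gene, _, change = r["Variant"].partition(":")
        pop_cols = [c for c in df.columns if "population" in c.lower()]
        out.append(
            ControlVariantRecord(
                variant=VariantKey(gene.strip().upper(), normalize_change(change.strip())),
                allele_count=int(r["Allele count"]),
                n_homozygotes=int(r["Number of homozygotes"]),
                allele_number=int(r["Allele number"]),
                highest_pop_label=r[pop_cols[0]].strip() if pop_cols else None,
            )
        )
    return out


def overlap_report(
    case_records: Iterable[VariantRecord],
    control_table: Iterable[ControlVariantRecord],
) -> tuple[list[dict], list[VariantKey]]:
    """Inner join of case variants with the control table on variant key.

    Returns (matched rows with case carrier counts and control AFs, case
    keys absent from the controls).  Duplicate control rows collapse onto
    distinct keys, so the match count is join-idempotent.
    """
    controls = {c.variant: c for c in control_table}
    case_carriers: dict[VariantKey, set[str]] = {}
    for r in case_records:
        case_carriers.setdefault(normalize_key(r), set()).add(r.patient_id)
    matched, absent = [], []
    for key in sorted(case_carriers):
        if key in controls:
            c = controls[key]
            matched.append(
                {
                    "variant": str(key),
                    "case_carriers": len(case_carriers[key]),
                    "control_allele_count": c.allele_count,
                    "control_allele_number": c.allele_number,
                    "control_homozygotes": c.n_homozygotes,
                    "control_af": c.af_display,
                    "highest_population": c.highest_pop_label,
                }
            )
        else:
            absent.append(key)
    return matched, absent


def control_retention_filter(
    records: Iterable[VariantRecord],
    af_threshold: float = 0.01,
) -> list[VariantRecord]:
    """Retention rule for control call sets: keep protein-truncating and
    splice-site variants with population AF at most the threshold (absent
    counts as rare).  The packaged control table is already post-filter; this
    is for synthetic control call sets."""
    kept = []
    for r in records:
        if not r.variant_type.is_truncating:
            continue
        if r.gnomad_af is not None and r.gnomad_af > af_threshold:
            continue
        kept.append(r)
    return kept
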