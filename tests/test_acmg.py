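"""ACMG/AMP engine: combining rules vs an independent brute-force rule table,
monotonicity, strength modifiers, and the heuristic auto-assigner."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from hcmkit.acmg import (
    BENIGN_CRITERIA,
    PATHOGENIC_CRITERIA,
    AcmgClass,
    AcmgCriterion,
    AcmgEvidence,
    Strength,
    auto_assign,
    combine_criteria,
)
from hcmkit.cascade import CascadeConfig
from hcmkit.variants import Genotype, PredictorCall, VariantRecord, VariantType

ALL_IDS = PATHOGENIC_CRITERIA + BENIGN_CRITERIA


# --- independent oracle -----------------------------------------------------
# A literal transcription of the published combining-rule table, written as
# explicit clause lists over criterion-count tuples, sharing no code with the
# engine.  Conflict semantics: both rule sets met, or a met rule set opposed
# by strong-or-stronger evidence, is contradictory (VUS).

def _counts(ids):
    vs = sum(1 for c in ids if c == "PVS1")
    s = sum(1 for c in ids if c.startswith("PS"))
    m = sum(1 for c in ids if c.startswith("PM"))
    p = sum(1 for c in ids if c.startswith("PP"))
    ba = sum(1 for c in ids if c == "BA1")
    bs = sum(1 for c in ids if c.startswith("BS"))
    bp = sum(1 for c in ids if c.startswith("BP"))
    return vs, s, m, p, ba, bs, bp


def oracle_combine(ids) -> AcmgClass:
    vs, s, m, p, ba, bs, bp = _counts(ids)
    path_clauses = [
        vs >= 1 and s >= 1,
        vs >= 1 and m >= 2,
        vs >= 1 and m == 1 and p >= 1,
        vs >= 1 and p >= 2,
        vs >= 2,
        s >= 2,
        s == 1 and m >= 3,
        s == 1 and m == 2 and p >= 2,
        s == 1 and m == 1 and p >= 4,
    ]
    lp_clauses = [
        vs == 1 and m == 1,
        s == 1 and m in (1, 2),
        s == 1 and p >= 2,
        m >= 3,
        m == 2 and p >= 2,
        m == 1 and p >= 4,
    ]
    b_clauses = [ba >= 1, bs >= 2]
    lb_clauses = [bs == 1 and bp >= 1, bp >= 2]
    path_side = any(path_clauses) or any(lp_clauses)
    benign_side = any(b_clauses) or any(lb_clauses)
    if path_side and benign_side:
        return AcmgClass.VUS
    if benign_side and (vs >= 1 or s >= 1):
        return AcmgClass.VUS
    if path_side and (ba >= 1 or bs >= 1):
        return AcmgClass.VUS
    if any(path_clauses):
        return AcmgClass.P
    if any(lp_clauses):
        return AcmgClass.LP
    if any(b_clauses):
        return AcmgClass.B
    if any(lb_clauses):
        return AcmgClass.LB
    return AcmgClass.VUS


# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "tokens, expected",
    [
        ((), AcmgClass.VUS),
        (("BA1",), AcmgClass.B),
        (("PVS1", "PM2"), AcmgClass.LP),
        (("PVS1", "PS1"), AcmgClass.P),
        (("PS1", "BA1"), AcmgClass.VUS),  # contradictory evidence
        (("PVS1", "PM2", "PP3"), AcmgClass.P),
        (("PM1", "PM2", "PM4"), AcmgClass.LP),
        (("BS1", "BS2"), AcmgClass.B),
        (("BS1", "BP4"), AcmgClass.LB),
        (("PP1", "PP2"), AcmgClass.VUS),
    ],
)
def test_combining_examples(tokens, expected):
    assert combine_criteria(tokens) is expected


def test_exhaustive_small_sets_match_oracle():
    """Engine == brute-force rule table on every evidence set of <= 3
    default-strength criteria (3,682 sets)."""
    mismatches = []
    for k in (1, 2, 3):
        for combo in itertools.combinations(ALL_IDS, k):
            if combine_criteria(combo) is not oracle_combine(combo):
                mismatches.append(combo)
    assert mismatches == []


def test_unknown_criterion_rejected():
    with pytest.raises(ValueError):
        AcmgCriterion("PX9")


def test_duplicate_id_rejected():
    with pytest.raises(ValueError):
        AcmgEvidence(frozenset({AcmgCriterion("PM2"), AcmgCriterion("PM2", Strength.STRONG)}))


def test_strength_modifier_counts_in_modified_bucket():
    # default PVS1 + PM2 reaches LP, but PVS1 downgraded to moderate gives
    # two moderates, which no likely-pathogenic clause accepts
    assert combine_criteria(AcmgEvidence.of("PVS1", "PM2")) is AcmgClass.LP
    assert combine_criteria(AcmgEvidence.of("PVS1_moderate", "PM2")) is AcmgClass.VUS
    # PM2 upgraded to strong: two strongs -> P
    assert combine_criteria(AcmgEvidence.of("PS1", "PM2_strong")) is AcmgClass.P


_CLASS_ORDER = {AcmgClass.B: 0, AcmgClass.LB: 1, AcmgClass.VUS: 2,
                AcmgClass.LP: 3, AcmgClass.P: 4}


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    base=st.sets(st.sampled_from(ALL_IDS), max_size=4),
    extra=st.sampled_from(PATHOGENIC_CRITERIA),
)
def test_adding_pathogenic_criterion_never_moves_toward_benign(base, extra):
    if extra in base:
        return
    before = combine_criteria(base)
    after = combine_criteria(tuple(base) + (extra,))
    if after is AcmgClass.VUS:
        return  # contradiction is an allowed outcome
    assert _CLASS_ORDER[after] >= _CLASS_ORDER[before]


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    base=st.sets(st.sampled_from(ALL_IDS), max_size=4),
    extra=st.sampled_from(BENIGN_CRITERIA),
)
def test_adding_benign_criterion_never_moves_toward_pathogenic(base, extra):
    if extra in base:
        return
    before = combine_criteria(base)
    after = combine_criteria(tuple(base) + (extra,))
    if after is AcmgClass.VUS:
        return
    assert _CLASS_ORDER[after] <= _CLASS_ORDER[before]


# --- heuristic auto-assigner ------------------------------------------------


def _rec(gene, vtype, af=None, cadd=None, calls=0, change="p.(Ala100Thr)"):
    tools = ("SIFT", "PolyPhen-2", "MutationTaster")
    return VariantRecord(
        patient_id="P1", gene=gene, genotype=Genotype.HET, variant_type=vtype,
        protein_change=change, gnomad_af=af, cadd=cadd,
        predictor_calls={t: PredictorCall.DELETERIOUS for t in tools[:calls]},
    )


class TestAutoAssign:
    def test_truncating_in_haploinsufficiency_gene(self, panel):
        rec = _rec("MYBPC3", VariantType.STOPGAIN, change="p.(Gln205*)")
        ev = auto_assign(rec, panel)
        assert {c.id for c in ev.criteria} == {"PVS1", "PM2"}
        assert ev.heuristic
        assert combine_criteria(ev) is AcmgClass.LP

    def test_common_missense_is_benign(self, panel):
        rec = _rec("MYH7", VariantType.MISSENSE, af=0.06)
        ev = auto_assign(rec, panel)
        assert {c.id for c in ev.criteria} == {"BA1"}
        assert combine_criteria(ev) is AcmgClass.B

    def test_unannotated_unknown_gene_is_vus(self, panel):
        rec = _rec("NOTAGENE", VariantType.MISSENSE, af=0.001)
        ev = auto_assign(rec, panel)
        assert combine_criteria(ev) is AcmgClass.VUS

    def test_deleterious_consensus_adds_pp3(self, panel):
        rec = _rec("MYH7", VariantType.MISSENSE, cadd=30, calls=3)
        assert "PP3" in {c.id for c in auto_assign(rec, panel).criteria}

    def test_curated_class_never_overwritten(self, records, panel):
        from hcmkit.acmg import classify_record

        curated = [r for r in records if r.acmg_class is not None]
        for rec in curated[:20]:
            reported, _, _ = classify_record(rec, panel)
            assert reported is rec.acmg_class
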