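"""Variant domain model: change-notation parsing, key normalization, I/O."""

import pytest

from hcmkit.variants import (
    Genotype,
    TableSchemaError,
    VariantParseError,
    VariantRecord,
    VariantType,
    classify_variant_type,
    merge_patients,
    normalize_change,
    normalize_key,
    read_variant_table,
    splice_offset,
    write_variant_table,
)


@pytest.mark.parametrize(
    "protein, cdna, expected",
    [
        ("p.(Ser139*)", None, VariantType.STOPGAIN),
        (None, "c.505 + 2 T > A", VariantType.SPLICING),
        ("p.(Arg177His)", None, VariantType.MISSENSE),
        ("p.(Phe305ProfsTer27)", None, VariantType.FRAMESHIFT),
        ("p.(Cys1202Leufs*35)", None, VariantType.FRAMESHIFT),
        (None, "c.1928-2A > G", VariantType.SPLICING),
        (None, "c.1624 + 4A > T", VariantType.SPLICING),
        ("Ex5:p.(Gln205*)", None, VariantType.STOPGAIN),
        ("p.(Met71Thr)", None, VariantType.MISSENSE),
        ("p.(Gly92Gly)", None, VariantType.SYNONYMOUS),
        ("p.(Ter565Gln)", None, VariantType.STOPLOSS),
        ("p.(Lys217del)", None, VariantType.INFRAME_INDEL),
        (None, "c.1234A > G", VariantType.OTHER),
    ],
)
def test_classify_variant_type(protein, cdna, expected):
    assert classify_variant_type(protein, cdna) is expected


def test_classify_frameshift_with_indel_kind_hint():
    assert (
        classify_variant_type("p.(Phe305ProfsTer27)", None, indel_kind="deletion")
        is VariantType.FRAMESHIFT_DELETION
    )
    assert (
        classify_variant_type("p.(Lys754GlufsTer79)", None, indel_kind="insertion")
        is VariantType.FRAMESHIFT_INSERTION
    )


def test_classify_errors():
    with pytest.raises(VariantParseError):
        classify_variant_type(None, None)
    with pytest.raises(VariantParseError) as exc:
        classify_variant_type("p.(blargh!!)", None)
    assert exc.value.token is not None


def test_splice_offset_retained_as_metadata():
    assert splice_offset("Ex20:c.1928-2A > G") == -2
    assert splice_offset("c.1624 + 4A > T") == 4
    assert splice_offset("c.1234A>G") is None


def test_classify_agrees_with_fixture_type_column(records):
    """The parser reproduces the curated variant-type column on every fixture
    row (frameshift deletions/insertions match the generic frameshift call)."""
    for r in records:
        got = classify_variant_type(r.protein_change, r.cdna_change)
        if r.variant_type.is_frameshift:
            assert got.is_frameshift, r
        else:
            assert got is r.variant_type, r


class TestNormalizeKey:
    def test_same_variant_same_key_across_patients(self, records):
        splice = [
            r
            for r in records
            if r.cdna_change and "1928" in r.cdna_change and r.gene == "MYBPC3"
        ]
        assert len(splice) == 7  # seven carriers of one splice allele
        assert len({normalize_key(r) for r in splice}) == 1

    def test_case_space_paren_insensitive_and_idempotent(self):
        variants = ["p.(Arg502Trp)", "p.Arg502Trp", "P.(ARG502TRP)", " p.( Arg502Trp )"]
        keys = {normalize_change(v) for v in variants}
        assert len(keys) == 1
        canon = keys.pop()
        assert normalize_change(canon) == canon

    def test_fster_and_star_spellings_collapse(self):
        assert normalize_change("p.(Cys1202LeufsTer35)") == normalize_change(
            "p.(Cys1202Leufs*35)"
        )

    def test_partitions_fixture_tables(self, fixtures):
        t = fixtures["tables"]
        keys1 = {normalize_key(r) for r in t["variants_mybpc3.tsv"]}
        keys2 = {normalize_key(r) for r in t["variants_myh7.tsv"]}
        assert len(keys1) == 40
        assert len(keys2) == 16


class TestReadVariantTable:
    def test_fixture_row_counts(self, fixtures):
        t = fixtures["tables"]
        assert len(t["variants_trim63.tsv"]) == 12
        assert len(t["variants_fhod3.tsv"]) == 10
        assert len(t["variants_svil.tsv"]) == 13
        hom = [r for r in t["variants_trim63.tsv"] if r.genotype is Genotype.HOM]
        assert len(hom) == 3

    def test_empty_table(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("Patient ID\tGene\tGenotype\tVariant type\tAA change\n")
        assert read_variant_table(p) == []

    def test_missing_column_names_the_column(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("Patient ID\tGene\tVariant type\tAA change\nX\tG\tMissense\tp.(Ala2Thr)\n")
        with pytest.raises(TableSchemaError, match="Genotype"):
            read_variant_table(p)

    def test_bad_genotype_token_is_row_error(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(
            "Patient ID\tGene\tGenotype\tVariant type\tAA change\n"
            "X\tMYH7\tHet/Hom\tMissense\tp.(Ala2Thr)\n"
        )
        with pytest.raises(TableSchemaError, match="genotype"):
            read_variant_table(p)

    def test_unique_variant_column_maps_to_empty_refs(self, records):
        sole = [r for r in records if not r.additional_variant_refs]
        multi = [r for r in records if r.additional_variant_refs]
        assert sole and multi
        assert all(isinstance(ref, tuple) and len(ref) == 2 for r in multi
                   for ref in r.additional_variant_refs)

    def test_empty_classification_cells_are_absent(self, fixtures):
        svil = {r.patient_id: r for r in fixtures["tables"]["variants_svil.tsv"]}
        assert svil["HCM-39"].acmg_class is None
        assert svil["HCM-139"].acmg_class is None
        assert svil["HCM-39"].gnomad_af is None

    def test_na_cadd_is_absent_not_zero(self, fixtures):
        t1 = fixtures["tables"]["variants_mybpc3.tsv"]
        fs = [r for r in t1 if r.variant_type.is_frameshift]
        assert any(r.cadd is None for r in fs)
        assert all(r.cadd != 0 for r in fs if r.cadd is None)


def test_table_round_trip(records, tmp_path):
    """write -> read reproduces the record set (identity = key + patient +
    genotype + annotations)."""
    out = tmp_path / "rt.tsv"
    write_variant_table(records, out)
    back = read_variant_table(out)

    def sig(rs):
        return sorted(
            (r.patient_id, str(normalize_key(r)), r.genotype.value,
             r.variant_type.value, r.cadd, r.gnomad_af,
             r.acmg_class.value if r.acmg_class else None)
            for r in rs
        )

    assert sig(back) == sig(records)


def test_record_validation():
    with pytest.raises(ValueError):
        VariantRecord("P1", "MYH7", Genotype.HET, VariantType.MISSENSE,
                      protein_change="p.(Ala2Thr)", gnomad_af=1.5)
    with pytest.raises(ValueError):
        VariantRecord("P1", "MYH7", Genotype.HET, VariantType.MISSENSE)


class TestMergePatients:
    def test_one_patient_per_id_across_tables(self, records):
        patients = merge_patients(records)
        # HCM-5 appears twice in one table, HCM-44 in three tables
        assert len(patients["HCM-5"].records) == 2
        assert len(patients["HCM-44"].records) == 3
        assert patients["HCM-44"].is_oligogenic

    def test_flags(self, records):
        patients = merge_patients(records)
        assert patients["HCM-1"].is_sole_variant_carrier
        assert patients["HCM-5"].is_same_gene_multi
        assert patients["HCM-9"].is_digenic
        assert patients["HCM-26"].has_homozygous

    def test_dangling_cross_reference_becomes_phantom_gene(self, records):
        # one table cross-references a partner variant that has no row of its own
        patients = merge_patients(records)
        assert patients["HCM-57"].phantom_genes == {"SVIL"}
        assert patients["HCM-57"].is_digenic
        assert not patients["HCM-57"].is_sole_variant_carrier
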