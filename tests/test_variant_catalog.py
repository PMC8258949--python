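"""Variant ingestion and pathogenicity-filter behaviour."""

import textwrap

import pytest

from rcdpburden import (
    ClinicalStatus,
    Consequence,
    GenomicInterval,
    PolyphenCall,
    Rule,
    SiftCall,
    classify_variant,
    consequence_class_summary,
    read_variant_table,
)
from rcdpburden.variant_catalog import VariantFormatError, parse_polyphen

from conftest import make_variant

TSV_HEADER = "variant_id\tgene\tchrom\tpos\tref\talt\tconsequence\tsift\tpolyphen\tclinical\tAC\tAN\tdataset\n"


def _row(vid="rs1", gene="PEX7", pos=100, csq="missense", sift="deleterious",
         polyphen="probably_damaging", clinical="unreported", ac=3, an=250000,
         dataset="US"):
    return f"{vid}\t{gene}\t1\t{pos}\tA\tT\t{csq}\t{sift}\t{polyphen}\t{clinical}\t{ac}\t{an}\t{dataset}\n"


class TestReadVariantTable:
    def test_well_formed_tsv(self, tmp_path):
        p = tmp_path / "v.tsv"
        p.write_text(TSV_HEADER + _row("rs1") + _row("rs2", csq="stop_gained",
                     sift="unknown", polyphen="unknown") + _row("rs3", ac=0))
        records = read_variant_table(p)
        assert len(records) == 3
        assert records[0].variant_id == "rs1"
        assert records[1].consequence is Consequence.STOP_GAINED
        assert records[2].allele_count == 0

    def test_ac_exceeding_an_is_rejected_with_row_number(self, tmp_path):
        p = tmp_path / "v.tsv"
        p.write_text(TSV_HEADER + _row("rs_bad", ac=12, an=10))
        with pytest.raises(ValueError, match="rs_bad"):
            read_variant_table(p)

    def test_missing_column_names_the_column(self, tmp_path):
        p = tmp_path / "v.tsv"
        p.write_text("variant_id\tgene\n" + "rs1\tPEX7\n")
        with pytest.raises(VariantFormatError, match="chrom"):
            read_variant_table(p)

    def test_vcf_line_ac_an_extraction(self, tmp_path):
        vcf = tmp_path / "v.vcf"
        vcf.write_text(textwrap.dedent("""\
            ##fileformat=VCFv4.2
            ##INFO=<ID=AC,Number=A,Type=Integer,Description="Allele count">
            ##INFO=<ID=AN,Number=1,Type=Integer,Description="Allele number">
            ##contig=<ID=6>
            #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
            6\t42932573\trs1805137\tT\tA\t.\t.\tAC=7;AN=251496
            """))
        sidecar = tmp_path / "anno.tsv"
        sidecar.write_text(
            "variant_id\tgene\tconsequence\tsift\tpolyphen\tclinical\tdataset\n"
            "6-42932573-T-A\tPEX7\tstop_gained\tunknown\tunknown\treported_pathogenic\tUS\n"
        )
        (rec,) = read_variant_table(vcf, dialect="vcf", annotations=sidecar)
        assert rec.variant_id == "6-42932573-T-A"
        assert rec.gene == "PEX7"
        assert rec.chrom == "6"
        assert rec.pos == 42932573
        assert rec.ref == "T" and rec.alt == "A"
        assert rec.consequence is Consequence.STOP_GAINED
        assert rec.clinical_status is ClinicalStatus.PATHOGENIC
        assert rec.allele_count == 7
        assert rec.allele_number == 251496

    def test_vcf_requires_sidecar(self, tmp_path):
        p = tmp_path / "x.vcf"
        p.write_text("##fileformat=VCFv4.2\n#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        with pytest.raises(VariantFormatError, match="sidecar"):
            read_variant_table(p, dialect="vcf")


class TestPolyphenMapping:
    @pytest.mark.parametrize("raw,expected", [
        ("probably_damaging", PolyphenCall.DAMAGING),
        ("possibly_damaging", PolyphenCall.DAMAGING),
        ("benign", PolyphenCall.BENIGN),
        (".", PolyphenCall.UNKNOWN),
    ])
    def test_default_mapping(self, raw, expected):
        assert parse_polyphen(raw) is expected

    def test_strict_mode_demotes_possibly_damaging(self):
        assert parse_polyphen("possibly_damaging", possibly_damaging_is_damaging=False) \
            is PolyphenCall.BENIGN


class TestClassifyVariant:
    @pytest.mark.parametrize("overrides,expected_rule", [
        # concordant damaging missense is included
        (dict(), Rule.MISSENSE_CONCORDANT),
        # any predicted-LoF consequence is included regardless of predictions
        (dict(consequence=Consequence.STOP_GAINED, sift_call=SiftCall.UNKNOWN,
              polyphen_call=PolyphenCall.UNKNOWN), Rule.PREDICTED_LOF),
        (dict(consequence=Consequence.FRAMESHIFT), Rule.PREDICTED_LOF),
        (dict(consequence=Consequence.SPLICE_DONOR), Rule.PREDICTED_LOF),
        (dict(consequence=Consequence.SPLICE_ACCEPTOR), Rule.PREDICTED_LOF),
        (dict(consequence=Consequence.START_LOST), Rule.PREDICTED_LOF),
        # clinical pathogenic overrides discordant predictions
        (dict(polyphen_call=PolyphenCall.BENIGN,
              clinical_status=ClinicalStatus.PATHOGENIC), Rule.CLINICAL),
        # discordant missense is excluded ("both tools" requirement)
        (dict(polyphen_call=PolyphenCall.BENIGN), Rule.EXCLUDED_DISCORDANT),
        (dict(sift_call=SiftCall.TOLERATED), Rule.EXCLUDED_DISCORDANT),
        (dict(sift_call=SiftCall.UNKNOWN), Rule.EXCLUDED_DISCORDANT),
        # clinical benign overrides concordant damaging predictions
        (dict(clinical_status=ClinicalStatus.BENIGN), Rule.EXCLUDED_BENIGN),
        # clinical benign overrides even predicted LoF
        (dict(consequence=Consequence.STOP_GAINED,
              clinical_status=ClinicalStatus.BENIGN), Rule.EXCLUDED_BENIGN),
        # uncertain significance falls through to the prediction rules
        (dict(clinical_status=ClinicalStatus.UNCERTAIN), Rule.MISSENSE_CONCORDANT),
        # non-canonical splice region is NOT auto-included
        (dict(consequence=Consequence.SPLICE_REGION, sift_call=SiftCall.UNKNOWN,
              polyphen_call=PolyphenCall.UNKNOWN), Rule.EXCLUDED_OTHER),
        (dict(consequence=Consequence.INFRAME_INDEL), Rule.EXCLUDED_OTHER),
    ])
    def test_decision_procedure(self, overrides, expected_rule):
        call = classify_variant(make_variant(**overrides))
        assert call.rule_fired is expected_rule
        assert call.included == (expected_rule in
                                 {Rule.CLINICAL, Rule.PREDICTED_LOF, Rule.MISSENSE_CONCORDANT})

    def test_region_restriction_excludes_outside_interval(self):
        interval = GenomicInterval("1", 500, 2000)
        inside = classify_variant(make_variant(pos=1000), interval)
        outside = classify_variant(make_variant(pos=5000), interval)
        assert inside.rule_fired is Rule.MISSENSE_CONCORDANT
        assert outside.rule_fired is Rule.EXCLUDED_REGION
        assert not outside.included

    def test_region_restriction_beats_clinical_pathogenic(self):
        interval = GenomicInterval("1", 500, 2000)
        v = make_variant(pos=9999, clinical_status=ClinicalStatus.PATHOGENIC)
        assert classify_variant(v, interval).rule_fired is Rule.EXCLUDED_REGION

    def test_deterministic(self):
        v = make_variant()
        assert classify_variant(v) == classify_variant(v)


class TestConsequenceSummary:
    def test_sums_per_class_and_partitions_gene_total(self):
        an = 200_000
        variants = [
            make_variant(variant_id="v1", consequence=Consequence.STOP_GAINED,
                         sift_call=SiftCall.UNKNOWN, polyphen_call=PolyphenCall.UNKNOWN,
                         allele_count=20, allele_number=an),
            make_variant(variant_id="v2", consequence=Consequence.STOP_GAINED,
                         sift_call=SiftCall.UNKNOWN, polyphen_call=PolyphenCall.UNKNOWN,
                         allele_count=10, allele_number=an),
            make_variant(variant_id="v3", allele_count=40, allele_number=an),
            make_variant(variant_id="v4", allele_count=8, allele_number=an),
            make_variant(variant_id="v5", consequence=Consequence.FRAMESHIFT,
                         allele_count=6, allele_number=an),
            # excluded: must not appear in any class
            make_variant(variant_id="v6", polyphen_call=PolyphenCall.BENIGN,
                         allele_count=1000, allele_number=an),
        ]
        calls = [classify_variant(v) for v in variants]
        table = consequence_class_summary(variants, calls)
        by_class = dict(zip(table["consequence"], table["aggregate_af"]))
        assert by_class["stop_gained"] == pytest.approx(30 / an)
        assert by_class["missense"] == pytest.approx(48 / an)
        assert by_class["frameshift"] == pytest.approx(6 / an)
        # classes partition the included set: sums equal the gene total
        assert table["aggregate_af"].sum() == pytest.approx(84 / an)

    def test_empty_included_set_gives_empty_table(self):
        v = make_variant(polyphen_call=PolyphenCall.BENIGN)
        table = consequence_class_summary([v], [classify_variant(v)])
        assert table.empty


class TestRecordInvariants:
    def test_negative_position_rejected(self):
        with pytest.raises(ValueError, match="position"):
            make_variant(pos=0)

    def test_ac_above_an_rejected(self):
        with pytest.raises(ValueError, match="AC"):
            make_variant(allele_count=11, allele_number=10)
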