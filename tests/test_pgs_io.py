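"""Scoring-file parsing, serialization round trips, and annotation tables."""

from __future__ import annotations

import gzip

import pytest

from pgsrank import (
    AnnotationTableError,
    EmptyScoringFileError,
    ScoringFile,
    ScoringFileError,
    load_annotation_table,
    parse_scoring_file,
    write_scoring_file,
)
from pgsrank.pgs_io import MISSING_TOKENS

from conftest import MINIMAL_TEXT, make_file


RECORD_FIELDS = (
    "rsid", "chr", "pos", "effect_allele", "other_allele",
    "effect_weight", "hm_rsid", "hm_chr", "hm_pos",
)


def records_equal(a, b) -> bool:
    return all(getattr(a, f) == getattr(b, f) for f in RECORD_FIELDS)


class TestParse:
    def test_minimal_file(self, minimal_scoring_path):
        sf = parse_scoring_file(minimal_scoring_path)
        assert sf.pgs_id == "PGS000001"
        assert sf.genome_build == "GRCh38"
        assert len(sf.records) == 2
        assert sf.records[0].rsid == "rs111"
        assert sf.records[0].effect_weight == 0.5
        assert sf.records[1].effect_weight == -0.25

    def test_gzipped_autodetected(self, tmp_path):
        path = tmp_path / "PGS000001.txt.gz"
        with gzip.open(path, "wt") as fh:
            fh.write(MINIMAL_TEXT)
        sf = parse_scoring_file(path)
        assert [r.rsid for r in sf.records] == ["rs111", "rs222"]

    @pytest.mark.parametrize("token", sorted(MISSING_TOKENS))
    def test_missing_tokens_parse_to_missing(self, tmp_path, token):
        path = tmp_path / "f.txt"
        path.write_text(
            "#pgs_id=PGS000002\n"
            "rsID\teffect_allele\tother_allele\teffect_weight\n"
            f"rs1\tA\t{token}\t{token}\n"
            "rs2\tC\tT\t0.1\n"
        )
        sf = parse_scoring_file(path)
        assert sf.records[0].effect_weight is None
        assert sf.records[0].other_allele is None

    def test_na_weight_row_retained(self, tmp_path):
        path = tmp_path / "f.txt"
        path.write_text(
            "#pgs_id=PGS000002\n"
            "rsID\teffect_allele\teffect_weight\n"
            "rs1\tA\tNA\n"
            "rs2\tC\t0.1\n"
        )
        sf = parse_scoring_file(path)
        assert len(sf.records) == 2
        assert sf.records[0].effect_weight is None

    def test_scientific_notation_weights(self, tmp_path):
        path = tmp_path / "f.txt"
        path.write_text(
            "#pgs_id=PGS000002\n"
            "rsID\teffect_allele\teffect_weight\n"
            "rs1\tA\t5.82e-7\n"
        )
        sf = parse_scoring_file(path)
        assert sf.records[0].effect_weight == pytest.approx(5.82e-7)
        assert sf.records[0].weight_text == "5.82e-7"

    def test_harmonized_columns_dialect(self, tmp_path):
        path = tmp_path / "f.txt"
        path.write_text(
            "#pgs_id=PGS000003\n"
            "#HmPOS_build=GRCh38\n"
            "hm_rsID\thm_chr\thm_pos\teffect_allele\teffect_weight\n"
            "rs429358\t19\t44908684\tC\t1.2\n"
        )
        sf = parse_scoring_file(path)
        r = sf.records[0]
        assert (r.hm_rsid, r.hm_chr, r.hm_pos) == ("rs429358", "19", 44908684)
        assert sf.genome_build == "GRCh38"

    def test_unknown_columns_kept_as_extra(self, tmp_path):
        path = tmp_path / "f.txt"
        path.write_text(
            "#pgs_id=PGS000003\n"
            "rsID\teffect_allele\teffect_weight\tallelefrequency_effect\n"
            "rs1\tA\t0.3\t0.12\n"
        )
        sf = parse_scoring_file(path)
        assert sf.records[0].extra == {"allelefrequency_effect": "0.12"}

    def test_empty_data_section_is_error(self, tmp_path):
        path = tmp_path / "f.txt"
        path.write_text("#pgs_id=PGS000002\nrsID\teffect_allele\teffect_weight\n")
        with pytest.raises(EmptyScoringFileError):
            parse_scoring_file(path)

    def test_missing_weight_column_is_error(self, tmp_path):
        path = tmp_path / "f.txt"
        path.write_text("#pgs_id=PGS000002\nrsID\teffect_allele\nrs1\tA\n")
        with pytest.raises(ScoringFileError, match="effect_weight"):
            parse_scoring_file(path)

    def test_unparseable_weight_reports_row_index(self, tmp_path):
        path = tmp_path / "f.txt"
        path.write_text(
            "#pgs_id=PGS000002\n"
            "rsID\teffect_allele\teffect_weight\n"
            "rs1\tA\t0.1\n"
            "rs2\tC\tbogus\n"
        )
        with pytest.raises(ScoringFileError, match="row 1"):
            parse_scoring_file(path)

    def test_unlocatable_rows_rejected_with_count(self, tmp_path):
        path = tmp_path / "f.txt"
        path.write_text(
            "#pgs_id=PGS000002\n"
            "rsID\tchr_name\tchr_position\teffect_allele\teffect_weight\n"
            "rs1\t1\t100\tA\t0.1\n"
            "NA\t1\tNA\tC\t0.2\n"  # chr without pos: unlocatable
        )
        sf = parse_scoring_file(path)
        assert len(sf.records) == 1
        assert sf.n_rejected == 1

    def test_invalid_accession_rejected(self):
        with pytest.raises(ScoringFileError, match="accession"):
            ScoringFile(pgs_id="PGS12", records=[])


class TestWrite:
    def test_round_trip_identity(self, minimal_scoring_path, tmp_path):
        sf = parse_scoring_file(minimal_scoring_path)
        out = tmp_path / "out.txt"
        write_scoring_file(sf, out)
        back = parse_scoring_file(out)
        assert back.pgs_id == sf.pgs_id
        assert back.genome_build == sf.genome_build
        assert len(back.records) == len(sf.records)
        assert all(records_equal(a, b) for a, b in zip(sf.records, back.records))

    def test_missing_cells_written_as_na(self, tmp_path):
        sf = make_file("PGS000009", {"rs1": None, "rs2": 0.5})
        out = tmp_path / "out.txt"
        write_scoring_file(sf, out)
        text = out.read_text()
        assert "\tNA\t" in text
        back = parse_scoring_file(out)
        assert back.records[0].effect_weight is None
        assert back.records[0].other_allele == "G"

    def test_gzip_chosen_by_suffix(self, tmp_path):
        sf = make_file("PGS000009", {"rs1": 0.5})
        out = tmp_path / "out.txt.gz"
        write_scoring_file(sf, out)
        assert out.read_bytes()[:2] == b"\x1f\x8b"
        assert parse_scoring_file(out).records[0].effect_weight == 0.5

    def test_refuses_empty_file(self, tmp_path):
        sf = make_file("PGS000009", {"rs1": 0.5})
        sf.records.clear()
        with pytest.raises(ScoringFileError, match="empty"):
            write_scoring_file(sf, tmp_path / "out.txt")


class TestAnnotationTable:
    def test_direct_mapping(self, annotation_path):
        ann = load_annotation_table(annotation_path)
        assert ann["rs429358"] == [("APOE", "exonic")]
        assert ann["19:44908684"] == [("APOC1", "upstream")]

    def test_multi_gene_assignments_retained(self, annotation_path):
        ann = load_annotation_table(annotation_path)
        assert sorted(g for g, _ in ann["rs111"]) == ["GENE1", "GENE2"]

    def test_duplicate_rows_deduplicated(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text("rsid\tgene\tfunc\nrs1\tG1\texonic\nrs1\tG1\texonic\n")
        ann = load_annotation_table(path)
        assert ann["rs1"] == [("G1", "exonic")]

    def test_annovar_style_columns(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text(
            "Chr\tStart\tEnd\tFunc.refGene\tGene.refGene\tavsnp150\n"
            "chr19\t44908684\t44908684\texonic\tAPOE\trs429358\n"
        )
        ann = load_annotation_table(path)
        assert ann["rs429358"] == [("APOE", "exonic")]

    def test_missing_gene_column_is_error(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text("rsid\tfunc\nrs1\texonic\n")
        with pytest.raises(AnnotationTableError, match="gene"):
            load_annotation_table(path)
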