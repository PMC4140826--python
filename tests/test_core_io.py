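"""I/O round-trips, coordinate conventions, and validation errors."""

import pytest

from lncsnp.core_io import (
    GenomicInterval,
    ParseError,
    SchemaError,
    ValidationError,
    Variant,
    read_fasta,
    read_gene_bed,
    read_repeatmasker_out,
    read_table,
    read_variant_table,
    write_fasta,
    write_gene_bed,
    write_repeatmasker_out,
    write_variant_table,
)
from .conftest import make_gene, make_lnc, make_variant


class TestGenomicInterval:
    def test_length_is_end_minus_start(self):
        assert len(GenomicInterval("chr1", 100, 250, "+")) == 150

    @pytest.mark.parametrize("start,end", [(5, 5), (10, 3), (-1, 10)])
    def test_rejects_degenerate_coordinates(self, start, end):
        with pytest.raises(ValidationError):
            GenomicInterval("chr1", start, end, "+")

    def test_half_open_overlap(self):
        a = GenomicInterval("chr1", 0, 100, "+")
        assert a.overlap_bp(GenomicInterval("chr1", 100, 200, "+")) == 0
        assert a.overlap_bp(GenomicInterval("chr1", 99, 200, "+")) == 1
        assert a.overlap_bp(GenomicInterval("chr2", 0, 100, "+")) == 0


class TestGeneBed:
    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.bed"
        path.write_text("")
        assert read_gene_bed(path) == []

    def test_bed6_single_exon(self, tmp_path):
        path = tmp_path / "g.bed"
        path.write_text("chr1 100 200 G1 0 +\n")
        (gene,) = read_gene_bed(path)
        assert gene.interval == GenomicInterval("chr1", 100, 200, "+")
        assert len(gene.exons) == 1

    def test_bed12_block_arithmetic(self, tmp_path):
        # blockSizes 50,50 at blockStarts 0,150 on a gene starting at 100:
        # exons [100,150) and [250,300) by the BED12 block rules
        path = tmp_path / "g.bed"
        path.write_text(
            "chr1\t100\t300\tG1\t0\t-\t100\t300\t0\t2\t50,50,\t0,150,\n"
        )
        (gene,) = read_gene_bed(path)
        assert [(e.start, e.end) for e in gene.exons] == [(100, 150), (250, 300)]

    def test_unstranded_dot(self, tmp_path):
        path = tmp_path / "g.bed"
        path.write_text("chr1 100 200 G1 0 .\n")
        (gene,) = read_gene_bed(path)
        assert gene.interval.strand == "."

    def test_end_before_start_raises_with_line_number(self, tmp_path):
        path = tmp_path / "g.bed"
        path.write_text("chr1 200 100 G1 0 +\n")
        with pytest.raises(ValidationError, match="line 1"):
            read_gene_bed(path)

    def test_malformed_line_names_line_number(self, tmp_path):
        path = tmp_path / "g.bed"
        path.write_text("chr1 100 200 G1 0 +\nchr1 nonsense\n")
        with pytest.raises(ParseError, match="line 2"):
            read_gene_bed(path)

    def test_round_trip(self, tmp_path):
        genes = [
            make_gene("A", start=0, end=5000, strand="-",
                      exons=(GenomicInterval("chr1", 0, 100, "-"),
                             GenomicInterval("chr1", 4900, 5000, "-"))),
            make_gene("B", chrom="chr2", start=10, end=900, strand="+",
                      exons=(GenomicInterval("chr2", 10, 900, "+"),)),
        ]
        path = tmp_path / "rt.bed"
        write_gene_bed(genes, path)
        back = read_gene_bed(path)
        assert [(g.gene_id, g.interval, g.exons) for g in back] == [
            (g.gene_id, g.interval, g.exons) for g in genes
        ]


class TestVariantTable:
    def test_one_based_to_zero_based(self, tmp_path):
        path = tmp_path / "v.tsv"
        path.write_text(
            "id\tchrom\tpos\tref\talt\tIBD\tT1D\n"
            "rs3757247\tchr6\t90957463\tA\tG\t5.44e-03\t8.05e-08\n"
        )
        (v,) = read_variant_table(path)
        assert v.pos == 90957462
        assert v.assoc_p == {"IBD": 5.44e-03, "T1D": 8.05e-08}

    def test_header_only_gives_empty_list(self, tmp_path):
        path = tmp_path / "v.tsv"
        path.write_text("id\tchrom\tpos\tref\talt\tIBD\n")
        assert read_variant_table(path) == []

    def test_p_zero_rejected(self, tmp_path):
        path = tmp_path / "v.tsv"
        path.write_text("id\tchrom\tpos\tref\talt\tIBD\nrs1\tchr1\t10\tA\tG\t0.0\n")
        with pytest.raises(ValidationError):
            read_variant_table(path)

    def test_ref_equals_alt_rejected(self):
        with pytest.raises(ValidationError):
            Variant(id="rs1", chrom="chr1", pos=1, ref="A", alt="A")

    def test_missing_p_drops_label(self, tmp_path):
        path = tmp_path / "v.tsv"
        path.write_text(
            "id\tchrom\tpos\tref\talt\tIBD\tT1D\nrs1\tchr1\t10\tA\tG\t0.5\t\n"
        )
        (v,) = read_variant_table(path)
        assert "T1D" not in v.assoc_p

    def test_round_trip(self, tmp_path):
        variants = [
            make_variant("rs1", pos=99, p={"IBD": 0.002}),
            make_variant("rs2", pos=500, ref="C", alt="T",
                         p={"IBD": 0.5, "T1D": 1e-7}),
        ]
        path = tmp_path / "rt.tsv"
        write_variant_table(variants, path)
        assert read_variant_table(path) == variants


class TestFasta:
    def test_t_transcribed_to_u(self, tmp_path):
        path = tmp_path / "s.fa"
        path.write_text(">x\nACGT\n")
        assert read_fasta(path) == {"x": "ACGU"}

    def test_two_records_and_header_token(self, tmp_path):
        path = tmp_path / "s.fa"
        path.write_text(">x some description\nAC\n>y\nGG\n")
        assert read_fasta(path) == {"x": "AC", "y": "GG"}

    def test_duplicate_id_rejected(self, tmp_path):
        path = tmp_path / "s.fa"
        path.write_text(">x\nACGT\n>x\nGG\n")
        with pytest.raises(ParseError, match="duplicate"):
            read_fasta(path)

    def test_non_iupac_rejected(self, tmp_path):
        path = tmp_path / "s.fa"
        path.write_text(">x\nAC1T\n")
        with pytest.raises(ParseError):
            read_fasta(path)

    def test_round_trip(self, tmp_path):
        seqs = {"a": "ACGU" * 40, "b": "GGGCCC"}
        path = tmp_path / "rt.fa"
        write_fasta(seqs, path)
        assert read_fasta(path) == seqs


class TestTables:
    def test_fpkm_like_tsv(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("gene_id\tliver\theart\tbrain\ng1\t1.5\t0.1\t2\ng2\t0\t3\t4\n")
        df = read_table(path, {"gene_id": str, "liver": float, "heart": float,
                               "brain": float})
        assert len(df) == 2
        assert df["liver"].tolist() == [1.5, 0.0]

    def test_missing_required_column(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("variant_id\tscore\nrs1\t5\n")
        with pytest.raises(SchemaError, match="ihs"):
            read_table(path, {"variant_id": str, "ihs": float})

    def test_repeatmasker_toy(self, tmp_path):
        from lncsnp.core_io import RepeatRecord

        rec = RepeatRecord(GenomicInterval("chr1", 99, 400, "+"), "SINE", "AluSx")
        path = tmp_path / "r.out"
        write_repeatmasker_out([rec], path)
        (back,) = read_repeatmasker_out(path)
        assert back.repeat_class == "SINE"
        assert back.repeat_name == "AluSx"
        assert (back.interval.start, back.interval.end) == (99, 400)


class TestDomainInvariants:
    def test_exon_outside_gene_rejected(self):
        with pytest.raises(ValidationError):
            make_gene(exons=(GenomicInterval("chr1", 0, 10, "+"),))

    def test_transcript_length_must_match_exons(self):
        with pytest.raises(ValidationError):
            make_lnc(start=0, end=10, seq="ACGU")  # 10 bp exon, 4 nt transcript

    def test_variant_occupies_one_base(self):
        v = make_variant(pos=42)
        iv = GenomicInterval(v.chrom, v.pos, v.pos + 1, ".")
        assert len(iv) == 1
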