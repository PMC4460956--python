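"""Format readers/writers: coordinate conventions, splitting, round trips."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from rnaedit.errors import (
    FastaFormatError,
    GtfFormatError,
    RepeatFormatError,
    ResourceFormatError,
    VcfFormatError,
)
from rnaedit.formats_io import (
    GenomeSequence,
    RepeatInterval,
    VcfRecord,
    normalize_chrom,
    read_fasta,
    read_gtf,
    read_repeat_intervals,
    read_resource_table,
    read_vcf,
    write_vcf,
)

VCF_HEADER = "##fileformat=VCFv4.2\n#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestVcf:
    def test_header_only_gives_empty_list(self, tmp_path):
        p = _write(tmp_path, "e.vcf", VCF_HEADER)
        assert read_vcf(p) == []

    def test_multiallelic_split_and_skips(self, tmp_path):
        # 3 data lines, one multiallelic -> 4 records (manual parse oracle);
        # the indel and symbolic alleles must be skipped.
        body = (
            "chr1\t100\t.\tA\tG\t60\t.\t.\n"
            "chr1\t200\trs9\tT\tG,C\t.\tPASS\t.\n"
            "chr1\t300\t.\tC\tA\t10\t.\t.\n"
            "chr1\t400\t.\tC\tCAT\t10\t.\t.\n"
            "chr2\t500\t.\tG\t<DEL>\t10\t.\t.\n"
        )
        recs = read_vcf(_write(tmp_path, "m.vcf", VCF_HEADER + body))
        assert len(recs) == 4
        assert [(r.chrom, r.pos, r.ref_base, r.alt_base) for r in recs] == [
            ("1", 100, "A", "G"), ("1", 200, "T", "G"),
            ("1", 200, "T", "C"), ("1", 300, "C", "A")]

    def test_chr_prefix_policies(self, tmp_path):
        p = _write(tmp_path, "c.vcf", VCF_HEADER + "chr1\t5\t.\tA\tG\t.\t.\t.\n")
        assert read_vcf(p, chrom_policy="strip")[0].chrom == "1"
        assert read_vcf(p, chrom_policy="none")[0].chrom == "chr1"
        p2 = _write(tmp_path, "c2.vcf", VCF_HEADER + "1\t5\t.\tA\tG\t.\t.\t.\n")
        assert read_vcf(p2, chrom_policy="add")[0].chrom == "chr1"

    def test_missing_header_is_format_error(self, tmp_path):
        p = _write(tmp_path, "bad.vcf", "chr1\t100\t.\tA\tG\t60\t.\t.\n")
        with pytest.raises(VcfFormatError):
            read_vcf(p)

    def test_non_integer_pos_is_format_error(self, tmp_path):
        p = _write(tmp_path, "pos.vcf", VCF_HEADER + "chr1\tabc\t.\tA\tG\t.\t.\t.\n")
        with pytest.raises(VcfFormatError):
            read_vcf(p)

    def test_record_invariants(self):
        with pytest.raises(VcfFormatError):
            VcfRecord(chrom="1", pos=0, id=None, ref_base="A", alt_base="G")
        with pytest.raises(VcfFormatError):
            VcfRecord(chrom="1", pos=5, id=None, ref_base="A", alt_base="A")

    @given(st.lists(
        st.builds(
            VcfRecord,
            chrom=st.sampled_from(["1", "2", "X"]),
            pos=st.integers(min_value=1, max_value=10**6),
            id=st.one_of(st.none(), st.just("rs1")),
            ref_base=st.just("A"),
            alt_base=st.sampled_from(["C", "G", "T"]),
            qual=st.one_of(st.none(), st.just(50.0)),
            filter_field=st.sampled_from([".", "PASS", "q10"]),
            info=st.dictionaries(st.sampled_from(["DP", "NS"]),
                                 st.just("3"), max_size=2),
        ),
        max_size=8,
    ))
    def test_round_trip_identity(self, records):
        import tempfile, os

        fd, path = tempfile.mkstemp(suffix=".vcf")
        os.close(fd)
        try:
            write_vcf(records, path)
            again = read_vcf(path, chrom_policy="none")
            assert again == records
        finally:
            os.unlink(path)


class TestGtf:
    def test_empty_file(self, tmp_path):
        assert read_gtf(_write(tmp_path, "e.gtf", "")) == []

    def test_fixture_parse(self, tmp_path):
        # 1 gene / 1 transcript / 2 exons / 2 CDS -> 6 records (manual oracle)
        attr = 'gene_id "G1"; transcript_id "T1"; gene_name "FOO";'
        lines = [
            f"chr1\tsrc\tgene\t100\t500\t.\t+\t.\t{attr}",
            f"chr1\tsrc\ttranscript\t100\t500\t.\t+\t.\t{attr}",
            f'chr1\tsrc\texon\t100\t200\t.\t+\t.\t{attr} exon_id "E1";',
            f'chr1\tsrc\texon\t300\t500\t.\t+\t.\t{attr} exon_id "E2";',
            f"chr1\tsrc\tCDS\t150\t200\t.\t+\t0\t{attr}",
            f"chr1\tsrc\tCDS\t300\t400\t.\t+\t2\t{attr}",
        ]
        recs = read_gtf(_write(tmp_path, "f.gtf", "\n".join(lines) + "\n"))
        assert len(recs) == 6
        assert recs[0].attributes["gene_id"] == "G1"
        assert recs[2].attributes["exon_id"] == "E1"
        assert recs[4].frame == 0 and recs[5].frame == 2
        assert all(r.seqname == "1" for r in recs)

    def test_start_after_end_rejected(self, tmp_path):
        line = 'chr1\tsrc\texon\t500\t100\t.\t+\t.\tgene_id "G";\n'
        with pytest.raises(GtfFormatError):
            read_gtf(_write(tmp_path, "b.gtf", line))

    def test_wrong_column_count_rejected(self, tmp_path):
        with pytest.raises(GtfFormatError):
            read_gtf(_write(tmp_path, "w.gtf", "chr1\tsrc\texon\t1\t2\n"))


class TestRepeats:
    def test_bed_row_coordinates(self, tmp_path):
        iv = read_repeat_intervals(
            _write(tmp_path, "r.bed", "chr1\t99\t120\tAluSx\n"))[0]
        # 1-based positions 100..120 overlap; brute-force check of the rule
        covered = [p for p in range(95, 126) if iv.contains_position(p)]
        assert covered == list(range(100, 121))
        assert iv.is_alu

    def test_repeatmasker_out_dialect(self, tmp_path):
        text = (
            "   SW  perc perc perc  query      position in query    matching repeat\n"
            "score  div. del. ins.  sequence   begin  end   left    repeat  class/family  begin end left ID\n"
            "  463  1.3  0.6  1.7  chr1       100    399   (0)  +  AluY    SINE/Alu      1 300 (0) 1\n"
        )
        iv = read_repeat_intervals(_write(tmp_path, "rm.out", text))[0]
        assert (iv.start, iv.end) == (99, 399)   # normalised to 0-based half-open
        assert iv.repeat_name == "AluY" and iv.repeat_family == "SINE/Alu"

    def test_empty_and_degenerate(self, tmp_path):
        assert read_repeat_intervals(_write(tmp_path, "e.bed", "")) == []
        with pytest.raises(RepeatFormatError):
            RepeatInterval(chrom="1", start=5, end=5, repeat_name="AluSx")


class TestFasta:
    def test_case_normalisation_and_indexing(self, tmp_path):
        g = read_fasta(_write(tmp_path, "g.fa", ">chr1\nacgt\n"))
        assert g.sequence("1") == "ACGT"
        assert g.base("1", 3) == "G"   # 1-based

    def test_two_chromosomes(self, tmp_path):
        g = read_fasta(_write(tmp_path, "g.fa", ">a\nAAAA\n>b\nCCCC\n"))
        assert g.chroms() == ["a", "b"]
        assert g.fetch("b", 2, 2) == "CC"

    def test_duplicate_header_rejected(self, tmp_path):
        with pytest.raises(FastaFormatError):
            read_fasta(_write(tmp_path, "d.fa", ">a\nAAAA\n>a\nCCCC\n"))

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(FastaFormatError):
            GenomeSequence({"c": "ACGU"})


class TestResourceTable:
    HEADER = "chrom\tpos\tin_dna\tin_rna\tstrand\tsource\tpubmed\n"

    def test_fixture_parse(self, tmp_path):
        rows = "".join(
            f"chr1\t{100 + i}\tA\tG\t+\tbrain\t123\n" for i in range(5))
        recs = read_resource_table(
            _write(tmp_path, "r.tsv", self.HEADER + rows), "DARNED")
        assert len(recs) == 5
        assert all(r.resource_id == "DARNED" for r in recs)
        assert recs[0].tissue_sources == ("brain",)

    def test_lowercase_bases_uppercased(self, tmp_path):
        recs = read_resource_table(
            _write(tmp_path, "r.tsv", self.HEADER + "1\t10\ta\tg\t.\t\t\n"), "X")
        assert (recs[0].dna_base, recs[0].rna_base) == ("A", "G")
        assert recs[0].strand == "unknown"

    def test_identical_bases_row_skipped(self, tmp_path):
        recs = read_resource_table(
            _write(tmp_path, "r.tsv",
                   self.HEADER + "1\t10\tA\tA\t+\t\t\n1\t11\tA\tG\t+\t\t\n"), "X")
        assert len(recs) == 1 and recs[0].pos == 11

    def test_missing_columns_rejected(self, tmp_path):
        with pytest.raises(ResourceFormatError):
            read_resource_table(
                _write(tmp_path, "r.tsv", "chrom\tpos\n1\t10\n"), "X")

    def test_empty_table(self, tmp_path):
        assert read_resource_table(_write(tmp_path, "e.tsv", ""), "X") == []


def test_normalize_chrom_policies():
    assert normalize_chrom("chr1", "strip") == "1"
    assert normalize_chrom("1", "add") == "chr1"
    assert normalize_chrom("chrX", "none") == "chrX"
    with pytest.raises(ValueError):
        normalize_chrom("chr1", "bogus")
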