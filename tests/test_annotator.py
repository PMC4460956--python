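"""Transcript models, genomic-feature classification, coding effects, rows."""

import random
from itertools import product

import pytest

from rnaedit.annotator import (
    TABLE_COLUMNS,
    AnnotatedRow,
    TranscriptIndex,
    annotate_coding_effect,
    annotate_sites,
    build_transcript_models,
    classify_genomic_feature,
    read_annotation_csv,
    write_annotation_csv,
)
from rnaedit.formats_io import GenomeSequence, GtfRecord, VcfRecord
from rnaedit.knowledgebase import integrate_resources
from rnaedit.formats_io import ResourceRecord

from oracles import COMPLEMENT, TxSpec, brute_force_feature, codon_substitution_status


def _gtf(feature, start, end, strand="+", frame=None, **attrs):
    base = {"gene_id": "G1", "transcript_id": "T1", "gene_name": "FOO"}
    base.update(attrs)
    return GtfRecord("1", feature, start, end, strand, frame, base)


@pytest.fixture()
def two_exon_minus_model():
    """Minus-strand 2-exon coding transcript: exons 100-200 and 300-500,
    CDS 150-200 and 300-420 (manually constructed oracle)."""
    recs = [
        _gtf("exon", 300, 500, "-", exon_id="E1"),
        _gtf("exon", 100, 200, "-", exon_id="E2"),
        _gtf("CDS", 300, 420, "-", frame=0),
        _gtf("CDS", 150, 200, "-", frame=1),
    ]
    return build_transcript_models(recs)


class TestTranscriptModels:
    def test_manual_two_exon_construction(self, two_exon_minus_model):
        m = two_exon_minus_model.models["T1"]
        assert len(m.exons) == 2 and len(m.cds_segments) == 2
        assert m.exons[0][0] == 100 and m.exons[-1][1] == 500
        assert m.tss == 500          # minus strand: TSS = max(end)
        assert m.tes == 100
        assert m.coding

    def test_exon_only_transcript_is_noncoding(self):
        idx = build_transcript_models([_gtf("exon", 100, 200)])
        assert not idx.models["T1"].coding

    def test_exon_without_transcript_id_skipped(self):
        rec = GtfRecord("1", "exon", 10, 20, "+", None, {"gene_id": "G"})
        assert len(build_transcript_models([rec])) == 0

    def test_intron_point_query_returns_transcript_but_no_exon(self, two_exon_minus_model):
        m = two_exon_minus_model.transcripts_at("1", 250)
        assert [t.transcript_id for t in m] == ["T1"]
        # linear-scan oracle over exon list
        assert not any(s <= 250 <= e for s, e, _ in m[0].exons)
        assert m[0].exon_at(250) is None


class TestFeatureClassification:
    def test_splice_window_two_bp(self, two_exon_minus_model):
        # junction after exon end 200: intron positions 201,202 splice; 203 intronic
        assert classify_genomic_feature("1", 202, two_exon_minus_model).primary_feature == "splicing"
        assert classify_genomic_feature("1", 203, two_exon_minus_model).primary_feature == "intronic"

    def test_upstream_flank_boundary(self):
        idx = build_transcript_models([_gtf("exon", 5000, 6000, "+")])
        assert classify_genomic_feature("1", 4000, idx).primary_feature == "upstream"
        assert classify_genomic_feature("1", 3999, idx).primary_feature == "intergenic"
        assert classify_genomic_feature("1", 7000, idx).primary_feature == "downstream"
        assert classify_genomic_feature("1", 7001, idx).primary_feature == "intergenic"

    def test_unknown_chromosome_is_intergenic(self, two_exon_minus_model):
        assert classify_genomic_feature("99", 150, two_exon_minus_model).primary_feature == "intergenic"

    def test_exhaustive_sweep_matches_brute_force(self, locus, transcript_index):
        """Every position of the locus agrees with the literal-definition oracle."""
        assert locus.length >= 5000
        specs = [TxSpec(t.strand,
                        [(s, e) for s, e, _ in t.exons],
                        [(s, e) for s, e, _ in t.cds_segments],
                        coding=t.coding)
                 for t in locus.transcripts]
        mismatches = []
        for pos in range(1, locus.length + 1):
            got = classify_genomic_feature(locus.chrom, pos, transcript_index).primary_feature
            want = brute_force_feature(pos, specs)
            if got != want:
                mismatches.append((pos, got, want))
        assert mismatches == []

    def test_sweep_covers_all_feature_classes(self, locus, transcript_index):
        seen = {classify_genomic_feature(locus.chrom, pos, transcript_index).primary_feature
                for pos in range(1, locus.length + 1, 3)}
        assert {"exonic", "splicing", "utr5", "utr3", "intronic",
                "upstream", "downstream", "intergenic"} <= seen

    def test_transcript_order_does_not_change_primary(self, locus):
        records = list(locus.gtf_records)
        rng = random.Random(0)
        base = build_transcript_models(records)
        positions = list(range(1, locus.length + 1, 37))
        expected = [classify_genomic_feature(locus.chrom, p, base).primary_feature
                    for p in positions]
        for _ in range(3):
            rng.shuffle(records)
            idx = build_transcript_models(records)
            got = [classify_genomic_feature(locus.chrom, p, idx).primary_feature
                   for p in positions]
            assert got == expected

    def test_ncrna_flag_tracks_noncoding_overlap(self, locus, transcript_index):
        for t in locus.transcripts:
            pos = t.exons[0][0] + 1
            ann = classify_genomic_feature(locus.chrom, pos, transcript_index)
            if not t.coding:
                assert ann.ncrna_flag


class TestCodingEffect:
    def _single_codon_setup(self, codon):
        seq = "GG" + codon + "GG"
        genome = GenomeSequence({"1": seq})
        idx = build_transcript_models([
            _gtf("exon", 1, 7, "+", exon_id="E1"),
            _gtf("CDS", 3, 5, "+", frame=0),
        ])
        return genome, idx.models["T1"]

    def test_forced_synonymous_example(self):
        genome, model = self._single_codon_setup("CTT")
        eff = annotate_coding_effect("1", 5, "T", "C", model, genome)
        assert eff.status == "synonymous"          # CTT->CTC, Leu->Leu
        assert (eff.ref_codon, eff.alt_codon) == ("CTT", "CTC")
        assert eff.codon_position == 3

    def test_exhaustive_codon_oracle(self):
        """All 64 codons x 3 positions x 3 alternatives vs the literal code table."""
        n = 0
        for codon in ("".join(c) for c in product("ACGT", repeat=3)):
            genome, model = self._single_codon_setup(codon)
            for i in range(3):
                for alt in "ACGT":
                    if alt == codon[i]:
                        continue
                    eff = annotate_coding_effect("1", 3 + i, codon[i], alt,
                                                 model, genome)
                    assert eff.status == codon_substitution_status(codon, i, alt), \
                        (codon, i, alt)
                    n += 1
        assert n == 576

    def test_minus_strand_matches_reverse_complement_construction(self):
        """A minus-strand edit gives the same amino-acid pair as the equivalent
        plus-strand construction on the reverse-complemented sequence."""
        for codon in ("CTT", "ATG", "TGG", "GAC", "TAC"):
            genome_p, model_p = self._single_codon_setup(codon)
            # mirror genome: revcomp of the 7-mer; CDS still at 3..5
            seq = "GG" + codon + "GG"
            rc = "".join(COMPLEMENT[b] for b in reversed(seq))
            genome_m = GenomeSequence({"1": rc})
            idx_m = build_transcript_models([
                _gtf("exon", 1, 7, "-", exon_id="E1"),
                _gtf("CDS", 3, 5, "-", frame=0),
            ])
            model_m = idx_m.models["T1"]
            for i in range(3):
                for alt in "ACGT":
                    if alt == codon[i]:
                        continue
                    eff_p = annotate_coding_effect("1", 3 + i, codon[i], alt,
                                                   model_p, genome_p)
                    # same edit seen from the minus strand: mirrored position,
                    # complemented bases
                    pos_m = 8 - (3 + i)
                    eff_m = annotate_coding_effect("1", pos_m, COMPLEMENT[codon[i]],
                                                   COMPLEMENT[alt], model_m, genome_m)
                    assert (eff_p.ref_aa, eff_p.alt_aa) == (eff_m.ref_aa, eff_m.alt_aa)
                    assert eff_p.status == eff_m.status

    def test_intronic_position_not_applicable(self, two_exon_minus_model):
        genome = GenomeSequence({"1": "A" * 600})
        m = two_exon_minus_model.models["T1"]
        assert annotate_coding_effect("1", 250, "A", "G", m, genome).status == \
            "not_applicable"

    def test_cds_not_divisible_by_three_is_not_applicable(self):
        genome = GenomeSequence({"1": "GGATGCGG"})
        idx = build_transcript_models([
            _gtf("exon", 1, 8, "+", exon_id="E1"),
            _gtf("CDS", 3, 6, "+", frame=0),   # length 4
        ])
        eff = annotate_coding_effect("1", 4, "T", "C", idx.models["T1"], genome)
        assert eff.status == "not_applicable"

    def test_genome_base_wins_on_mismatch(self, caplog):
        genome, model = self._single_codon_setup("CTT")
        with caplog.at_level("WARNING"):
            eff = annotate_coding_effect("1", 5, "G", "C", model, genome)
        assert eff.ref_codon == "CTT"      # genome says T, not G
        assert "genome base" in caplog.text


class TestAnnotateSites:
    def _kb(self):
        recs = [ResourceRecord(resource_id=r, chrom="1", pos=5, dna_base="T",
                               rna_base="C", strand="+")
                for r in ("DARNED", "RADAR")]
        return integrate_resources(recs)

    def test_known_only_by_default_and_keep_novel(self):
        genome, model = GenomeSequence({"1": "GGCTTGG"}), None
        idx = build_transcript_models([
            _gtf("exon", 1, 7, "+", exon_id="E1"), _gtf("CDS", 3, 5, "+", frame=0)])
        kb = self._kb()
        records = [VcfRecord("1", 5, None, "T", "C"),   # known
                   VcfRecord("1", 4, None, "T", "A")]   # novel
        rows = annotate_sites(records, kb, idx, genome)
        assert len(rows) == 1 and rows[0].evidence_level == "D"
        rows2 = annotate_sites(records, kb, idx, genome, keep_novel=True)
        assert len(rows2) == 2
        novel = [r for r in rows2 if r.pos == 4][0]
        assert novel.evidence_level == "" and novel.data_reference == ""
        assert novel.syn_nonsyn in ("synonymous", "nonsynonymous")

    def test_empty_vcf_gives_empty_output_with_header(self, tmp_path):
        p = tmp_path / "out.csv"
        write_annotation_csv([], p)
        text = p.read_text().strip().split("\n")
        assert len(text) == 1
        assert text[0].split(",")[0] == "Chr"
        assert read_annotation_csv(p) == []

    def test_every_row_serialises_to_17_columns(self, tmp_path):
        assert len(TABLE_COLUMNS) == 17
        row = AnnotatedRow(chrom="1", pos=5, in_dna="T", in_rna="C")
        assert len(row.to_list()) == 17
        p = tmp_path / "out.csv"
        write_annotation_csv([row], p)
        import csv
        with open(p, newline="") as fh:
            rows = list(csv.reader(fh))
        assert [len(r) for r in rows] == [17, 17]
        assert tuple(rows[0]) == TABLE_COLUMNS

    def test_csv_round_trip(self, tmp_path):
        row = AnnotatedRow(chrom="1", pos=5, in_dna="T", in_rna="C",
                           gene="FOO", evidence_level="D", strand="+",
                           genomic_feature="exonic", syn_nonsyn="synonymous")
        p = tmp_path / "out.csv"
        write_annotation_csv([row], p)
        assert read_annotation_csv(p) == [row]
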