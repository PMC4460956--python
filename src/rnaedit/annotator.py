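"""Site annotation: genomic feature, coding effect, ncRNA flag, evidence.

Feature taxonomy
----------------
Each site is tested against every transcript overlapping it (including the
1-kb upstream/downstream flanks) and resolved per transcript:

* ``exonic`` — the position overlaps a coding (CDS) exon base;
* ``splicing`` — within 2 bp of an exon/intron junction on either side,
  unless the position is itself exonic-coding (exonic wins the tie);
* ``ncRNA`` — exonic in a transcript without any CDS annotation;
* ``utr5`` / ``utr3`` — exonic in a coding transcript, outside the CDS
  extent, on the 5' / 3' side (strand-aware); UTRs are always derived from
  the CDS extent, so GTF UTR features are not required;
* ``intronic`` — within the transcript span but not exonic;
* ``upstream`` / ``downstream`` — within the 1,000-bp flank beyond the
  transcription start / end site (strand-aware; 1,000 bp away is still
  flank, 1,001 bp is intergenic);
* ``intergenic`` — none of the above.

Per-transcript labels are combined by a fixed precedence
``exonic = splicing > ncRNA > utr5 > utr3 > intronic > upstream = downstream
> intergenic``; equal-rank ties break deterministically toward the label
listed first, so transcript iteration order never matters.

Coding effect
-------------
The reference codon is rebuilt from the genome across the spliced CDS
(reverse-complemented for minus-strand transcripts), the edited base is
substituted, and both codons are translated with the standard nuclear code;
identical amino acids mean a synonymous substitution. Sites outside any CDS
are ``not_applicable``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from Bio.Seq import Seq
from intervaltree import IntervalTree

from .formats_io import GenomeSequence, GtfRecord, VcfRecord
from .knowledgebase import Knowledgebase, assign_evidence_level

logger = logging.getLogger(__name__)

FLANK_BP = 1000      # upstream/downstream window beyond the transcript
SPLICE_WINDOW = 2    # bases around an exon/intron junction called "splicing"

FEATURE_PRECEDENCE = {
    "exonic": 0, "splicing": 0,
    "ncRNA": 1,
    "utr5": 2, "utr3": 3,
    "intronic": 4,
    "upstream": 5, "downstream": 5,
    "intergenic": 6,
}
# Tie-break among equal-rank labels: earlier in this list wins.
FEATURE_ORDER = ("exonic", "splicing", "ncRNA", "utr5", "utr3",
                 "intronic", "upstream", "downstream", "intergenic")

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: The annotation output header, in fixed column order.
TABLE_COLUMNS = (
    "Chr", "Pos", "In DNA", "In RNA", "Gene", "Evidence level", "Strand",
    "Source", "PubMed ID", "Alu", "Data reference", "ENSG", "ENST", "ENSE",
    "Genomic feature", "Synonymous or nonsynonymous", "Noncoding RNA",
)


# ---------------------------------------------------------------------------
# Transcript models
# ---------------------------------------------------------------------------

@dataclass
class TranscriptModel:
    """Gene/transcript/exon/CDS structure for one transcript."""

    transcript_id: str
    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    exons: tuple            # ((start, end, exon_id), ...) 1-based closed, sorted
    cds_segments: tuple     # ((start, end, frame), ...) sorted by start
    biotype: str = ""

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        """Transcription start site (strand-aware)."""
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def coding(self) -> bool:
        """Non-coding iff no CDS segments (biotype is advisory only)."""
        return bool(self.cds_segments)

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e, _ in self.cds_segments)

    @property
    def cds_extent(self) -> tuple[int, int] | None:
        if not self.cds_segments:
            return None
        return (self.cds_segments[0][0], self.cds_segments[-1][1])

    def exon_at(self, pos: int) -> str | None:
        for s, e, exon_id in self.exons:
            if s <= pos <= e:
                return exon_id
        return None

    def in_cds(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e, _ in self.cds_segments)

    def near_splice_junction(self, pos: int, window: int = SPLICE_WINDOW) -> bool:
        """Within ``window`` bp of an internal exon/intron boundary.

        A junction sits between exon end ``e`` and ``e+1`` (or between
        ``s-1`` and exon start ``s``); the window covers ``window`` bases on
        each side of that edge. Transcript outer ends are not junctions.
        """
        if len(self.exons) < 2:
            return False
        for i, (s, e, _) in enumerate(self.exons):
            if i > 0 and s - window <= pos <= s + window - 1:
                return True
            if i < len(self.exons) - 1 and e - window + 1 <= pos <= e + window:
                return True
        return False


class TranscriptIndex:
    """Transcript models with an interval index for point queries."""

    def __init__(self, models: Iterable[TranscriptModel], flank: int = FLANK_BP):
        self.flank = flank
        self.models: dict[str, TranscriptModel] = {}
        self._trees: dict[str, IntervalTree] = {}
        for m in models:
            self.models[m.transcript_id] = m
            tree = self._trees.setdefault(m.chrom, IntervalTree())
            # Tree is 0-based half-open over the span extended by the flank.
            tree.addi(m.start - flank - 1, m.end + flank, m.transcript_id)

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models.values())

    def transcripts_at(self, chrom: str, pos: int) -> list[TranscriptModel]:
        """Transcripts whose flank-extended span contains 1-based ``pos``."""
        tree = self._trees.get(chrom)
        if not tree:
            return []
        hits = [self.models[h.data] for h in tree[pos - 1]]
        return sorted(hits, key=lambda m: m.transcript_id)


def build_transcript_models(gtf_records: Iterable[GtfRecord],
                            flank: int = FLANK_BP) -> TranscriptIndex:
    """Assemble one :class:`TranscriptModel` per ``transcript_id``.

    Only ``exon`` and ``CDS`` features are used; exons lacking a
    ``transcript_id`` attribute are skipped with a warning. A
    protein-coding transcript whose summed CDS length is not divisible by 3
    is kept but its coding effects come back ``not_applicable``.
    """
    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    meta: dict[str, dict] = {}
    for rec in gtf_records:
        if rec.feature_kind not in ("exon", "CDS"):
            continue
        tid = rec.attributes.get("transcript_id")
        if not tid:
            logger.warning("%s %s:%d-%d without transcript_id; skipped",
                           rec.feature_kind, rec.seqname, rec.start, rec.end)
            continue
        meta.setdefault(tid, {
            "gene_id": rec.attributes.get("gene_id", ""),
            "gene_name": rec.attributes.get("gene_name", rec.attributes.get("gene_id", "")),
            "chrom": rec.seqname,
            "strand": rec.strand,
            "biotype": rec.attributes.get("gene_biotype",
                                          rec.attributes.get("transcript_biotype", "")),
        })
        if rec.feature_kind == "exon":
            exons.setdefault(tid, []).append(
                (rec.start, rec.end, rec.attributes.get("exon_id", f"{tid}.{rec.start}")))
        else:
            cds.setdefault(tid, []).append((rec.start, rec.end, rec.frame or 0))

    models = []
    for tid, info in meta.items():
        tx_exons = sorted(exons.get(tid, []), key=lambda x: x[0])
        if not tx_exons:
            logger.warning("transcript %s has CDS but no exons; skipped", tid)
            continue
        tx_cds = tuple(sorted(cds.get(tid, []), key=lambda x: x[0]))
        m = TranscriptModel(
            transcript_id=tid,
            gene_id=info["gene_id"],
            gene_name=info["gene_name"],
            chrom=info["chrom"],
            strand=info["strand"],
            exons=tuple(tx_exons),
            cds_segments=tx_cds,
            biotype=info["biotype"],
        )
        if m.coding and m.cds_length % 3 != 0:
            logger.warning("transcript %s CDS length %d not divisible by 3; "
                           "coding effects will be not_applicable", tid, m.cds_length)
        models.append(m)
    return TranscriptIndex(models, flank=flank)


# ---------------------------------------------------------------------------
# Genomic-feature classification
# ---------------------------------------------------------------------------

@dataclass
class FeatureAnnotation:
    primary_feature: str
    gene_names: tuple = ()
    ensg: tuple = ()
    enst: tuple = ()
    ense: tuple = ()
    ncrna_flag: bool = False


def transcript_feature(model: TranscriptModel, pos: int,
                       flank: int = FLANK_BP) -> str:
    """Feature label of ``pos`` relative to one transcript (see module doc)."""
    if model.start <= pos <= model.end:
        if model.in_cds(pos):
            return "exonic"
        if model.near_splice_junction(pos):
            return "splicing"
        if model.exon_at(pos) is not None:
            if not model.coding:
                return "ncRNA"
            lo, hi = model.cds_extent
            if pos < lo:
                return "utr5" if model.strand == "+" else "utr3"
            if pos > hi:
                return "utr3" if model.strand == "+" else "utr5"
            return "exonic"  # between CDS segments inside an exon (malformed model)
        return "intronic"
    if model.strand == "+":
        if model.start - flank <= pos < model.start:
            return "upstream"
        if model.end < pos <= model.end + flank:
            return "downstream"
    else:
        if model.end < pos <= model.end + flank:
            return "upstream"
        if model.start - flank <= pos < model.start:
            return "downstream"
    return "intergenic"


def classify_genomic_feature(chrom: str, pos: int,
                             index: TranscriptIndex) -> FeatureAnnotation:
    """Resolve the primary feature of a site across all overlapping transcripts."""
    candidates = index.transcripts_at(chrom, pos)
    if not candidates:
        return FeatureAnnotation(primary_feature="intergenic")

    labelled = [(transcript_feature(m, pos, index.flank), m) for m in candidates]
    labelled = [(lab, m) for lab, m in labelled if lab != "intergenic"]
    if not labelled:
        return FeatureAnnotation(primary_feature="intergenic")
    primary = min(
        (lab for lab, _ in labelled),
        key=lambda lab: (FEATURE_PRECEDENCE[lab], FEATURE_ORDER.index(lab)),
    )

    # Gene/transcript columns come from transcripts whose span contains the
    # site; for pure flank hits, from the transcripts providing the flank.
    span_models = [m for m in candidates if m.start <= pos <= m.end]
    if span_models:
        sources = span_models
    else:
        sources = [m for lab, m in labelled if lab in ("upstream", "downstream")]
    ense = sorted({eid for m in span_models
                   if (eid := m.exon_at(pos)) is not None})
    return FeatureAnnotation(
        primary_feature=primary,
        gene_names=tuple(sorted({m.gene_name for m in sources})),
        ensg=tuple(sorted({m.gene_id for m in sources})),
        enst=tuple(sorted({m.transcript_id for m in sources})),
        ense=tuple(ense),
        ncrna_flag=any(not m.coding for m in span_models),
    )


# ---------------------------------------------------------------------------
# Coding effect
# ---------------------------------------------------------------------------

@dataclass
class CodingEffect:
    status: str                 # synonymous | nonsynonymous | not_applicable
    ref_codon: str = ""
    alt_codon: str = ""
    ref_aa: str = ""
    alt_aa: str = ""
    codon_position: int = 0     # 1..3 within the codon

    @classmethod
    def not_applicable(cls) -> "CodingEffect":
        return cls(status="not_applicable")


def annotate_coding_effect(chrom: str, pos: int, dna_base: str, rna_base: str,
                           model: TranscriptModel,
                           genome: GenomeSequence) -> CodingEffect:
    """Coding consequence of substituting ``rna_base`` at ``pos``.

    ``dna_base``/``rna_base`` are given on the plus strand (VCF convention);
    for a minus-strand transcript both codon and edited base are
    reverse-complemented before translation. When the genome base disagrees
    with ``dna_base`` the genome wins and the mismatch is logged.
    """
    if not model.coding or not model.in_cds(pos):
        return CodingEffect.not_applicable()
    if model.cds_length % 3 != 0:
        logger.warning("transcript %s: CDS length %d not divisible by 3",
                       model.transcript_id, model.cds_length)
        return CodingEffect.not_applicable()

    genome_base = genome.base(chrom, pos)
    if genome_base != dna_base.upper():
        logger.warning("%s:%d genome base %s != reported DNA base %s; using genome",
                       chrom, pos, genome_base, dna_base)

    segs = model.cds_segments
    plus_offset = 0
    for s, e, _ in segs:
        if s <= pos <= e:
            plus_offset += pos - s
            break
        plus_offset += e - s + 1
    cds_plus = "".join(genome.fetch(chrom, s, e - s + 1) for s, e, _ in segs)
    if model.strand == "+":
        cds_seq = cds_plus
        idx = plus_offset
        edited = rna_base.upper()
    else:
        cds_seq = str(Seq(cds_plus).reverse_complement())
        idx = len(cds_plus) - 1 - plus_offset
        edited = COMPLEMENT[rna_base.upper()]

    codon_i, codon_pos = divmod(idx, 3)
    ref_codon = cds_seq[codon_i * 3:codon_i * 3 + 3]
    alt_codon = ref_codon[:codon_pos] + edited + ref_codon[codon_pos + 1:]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    status = "synonymous" if ref_aa == alt_aa else "nonsynonymous"
    return CodingEffect(status=status, ref_codon=ref_codon, alt_codon=alt_codon,
                        ref_aa=ref_aa, alt_aa=alt_aa, codon_position=codon_pos + 1)


# ---------------------------------------------------------------------------
# Full annotation rows
# ---------------------------------------------------------------------------

@dataclass
class AnnotatedRow:
    """One 17-column annotation record (column order fixed by TABLE_COLUMNS)."""

    chrom: str
    pos: int
    in_dna: str
    in_rna: str
    gene: str = ""
    evidence_level: str = ""
    strand: str = "."
    source: str = ""
    pubmed_id: str = ""
    alu: str = ""
    data_reference: str = ""
    ensg: str = ""
    enst: str = ""
    ense: str = ""
    genomic_feature: str = ""
    syn_nonsyn: str = ""
    noncoding_rna: str = "no"
    sample: str = ""            # optional leading column in compare outputs

    def to_list(self) -> list[str]:
        return [
            self.chrom, str(self.pos), self.in_dna, self.in_rna, self.gene,
            self.evidence_level, self.strand, self.source, self.pubmed_id,
            self.alu, self.data_reference, self.ensg, self.enst, self.ense,
            self.genomic_feature, self.syn_nonsyn, self.noncoding_rna,
        ]


def _coding_effect_for_site(chrom: str, pos: int, dna: str, rna: str,
                            index: TranscriptIndex,
                            genome: GenomeSequence) -> CodingEffect:
    """First applicable effect across coding transcripts (sorted by id)."""
    for m in index.transcripts_at(chrom, pos):
        if m.coding and m.in_cds(pos):
            eff = annotate_coding_effect(chrom, pos, dna, rna, m, genome)
            if eff.status != "not_applicable":
                return eff
    return CodingEffect.not_applicable()


def annotate_sites(vcf_records: Iterable[VcfRecord],
                   kb: Knowledgebase | None,
                   index: TranscriptIndex,
                   genome: GenomeSequence,
                   keep_novel: bool = False) -> list[AnnotatedRow]:
    """Annotate VCF records against the knowledgebase and gene models.

    By default only sites present in the knowledgebase are reported (known-
    site annotation mode); with ``keep_novel`` every input site is kept and
    unknown sites carry empty evidence columns.
    """
    rows = []
    for rec in vcf_records:
        site = kb.query(*rec.key) if kb is not None else None
        if site is None and not keep_novel:
            continue
        feat = classify_genomic_feature(rec.chrom, rec.pos, index)
        eff = _coding_effect_for_site(rec.chrom, rec.pos, rec.ref_base,
                                      rec.alt_base, index, genome)
        row = AnnotatedRow(
            chrom=rec.chrom,
            pos=rec.pos,
            in_dna=rec.ref_base,
            in_rna=rec.alt_base,
            gene=",".join(feat.gene_names),
            genomic_feature=feat.primary_feature,
            syn_nonsyn="" if eff.status == "not_applicable" else eff.status,
            noncoding_rna="yes" if feat.ncrna_flag else "no",
            ensg=",".join(feat.ensg),
            enst=",".join(feat.enst),
            ense=",".join(feat.ense),
        )
        if site is not None:
            ev = assign_evidence_level(site, kb.registry)
            row.evidence_level = ev.class_letter
            row.strand = site.strand if site.strand in ("+", "-") else "."
            row.source = ",".join(site.tissue_sources)
            row.pubmed_id = ",".join(site.pubmed_ids)
            row.alu = site.alu_name or ""
            row.data_reference = ",".join(site.data_references)
        rows.append(row)
    return rows


def write_annotation_csv(rows: Iterable[AnnotatedRow], path,
                         leading_column: str | None = None) -> None:
    """Write rows as CSV with the fixed 17-column header.

    ``leading_column`` prepends a sample/set column (compare outputs).
    """
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        header = list(TABLE_COLUMNS)
        if leading_column:
            header = [leading_column] + header
        writer.writerow(header)
        for row in rows:
            values = row.to_list()
            if leading_column:
                values = [row.sample] + values
            writer.writerow(values)


def read_annotation_csv(path) -> list[AnnotatedRow]:
    """Read back an annotation CSV (with or without a leading sample column)."""
    import csv

    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            return []
        offset = 0
        sample_col = None
        if tuple(header) != TABLE_COLUMNS:
            if tuple(header[1:]) == TABLE_COLUMNS:
                offset, sample_col = 1, 0
            else:
                raise ValueError(f"{path}: unexpected annotation header {header}")
        for rec in reader:
            vals = rec[offset:]
            rows.append(AnnotatedRow(
                chrom=vals[0], pos=int(vals[1]), in_dna=vals[2], in_rna=vals[3],
                gene=vals[4], evidence_level=vals[5], strand=vals[6],
                source=vals[7], pubmed_id=vals[8], alu=vals[9],
                data_reference=vals[10], ensg=vals[11], enst=vals[12],
                ense=vals[13], genomic_feature=vals[14], syn_nonsyn=vals[15],
                noncoding_rna=vals[16],
                sample=rec[sample_col] if sample_col is not None else "",
            ))
    return rows
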