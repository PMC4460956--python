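"""Deterministic toy fixtures: genomes, gene models, resource tables, VCFs.

Everything here is a pure function of an integer seed, so tests and demos
run without downloads. The generator writes the same standard formats the
readers consume (FASTA/GTF/BED/VCF/TSV) plus a JSON manifest recording the
planted ground truth: germline variants, RNA-DNA difference (RDD) sites
with their expected edit type / genomic feature / coding effect, and the
expected resource memberships and evidence class of every knowledgebase
site.

Planted RDD sites are biased 70% toward A-to-G / T-to-C substitutions,
echoing the predominance of ADAR-mediated A-to-I editing in human data;
the proportion is configurable. Loci are tens of kilobases with 1-4-exon
transcripts on both strands and CDS lengths divisible by 3 (start codon,
no internal stops, terminal stop), which is enough structure to exercise
every feature class; real-data properties such as sequencing error, read
depth and polymorphism background are deliberately absent.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from .errors import DataError
from .formats_io import (
    GenomeSequence,
    GtfRecord,
    RepeatInterval,
    ResourceRecord,
    VcfRecord,
    write_fasta,
    write_gtf,
    write_repeats_bed,
    write_resource_table,
    write_vcf,
)

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
STOP_CODONS = ("TAA", "TAG", "TGA")
NONSTOP_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOP_CODONS
)

#: Canonical resource compositions per evidence class (one row per class).
CLASS_COMPOSITIONS = {
    "A": (("DARNED", "ENCODE", "BAHN", "RADAR"), True),
    "B": (("DARNED", "RADAR", "BAHN"), True),
    "C": (("DARNED", "BAHN", "RADAR"), False),
    "D": (("DARNED", "RADAR"), False),
    "E": (("DARNED",), False),
}

DEFAULT_CLASS_MIX = (
    {"class_letter": "A", "n": 1},
    {"class_letter": "B", "n": 1},
    {"class_letter": "C", "n": 2},
    {"class_letter": "D", "n": 3},
    {"class_letter": "E", "n": 3},
)

# Literal feature definitions used for the manifest's expected labels;
# evaluated by per-position enumeration, independently of the annotator's
# interval machinery.
_PRECEDENCE = {"exonic": 0, "splicing": 0, "ncRNA": 1, "utr5": 2, "utr3": 3,
               "intronic": 4, "upstream": 5, "downstream": 5, "intergenic": 6}
_ORDER = ("exonic", "splicing", "ncRNA", "utr5", "utr3", "intronic",
          "upstream", "downstream", "intergenic")
_FLANK = 1000
_SPLICE = 2


# ---------------------------------------------------------------------------
# Locus (genome + gene models)
# ---------------------------------------------------------------------------

@dataclass
class TranscriptTruth:
    transcript_id: str
    gene_id: str
    gene_name: str
    strand: str
    exons: tuple            # ((start, end, exon_id), ...) genomic order
    cds_segments: tuple     # ((start, end, frame), ...) genomic order
    coding: bool

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass
class SyntheticLocus:
    chrom: str
    genome: GenomeSequence
    gtf_records: list
    transcripts: list
    seed: int
    _feature_cache: dict = field(default_factory=dict, repr=False)

    @property
    def length(self) -> int:
        return self.genome.length(self.chrom)

    def write_fasta(self, path) -> None:
        write_fasta(self.genome, path)

    def write_gtf(self, path) -> None:
        write_gtf(self.gtf_records, path)

    # -- ground-truth feature/effect lookups (enumeration-based) ------------

    def expected_feature(self, pos: int) -> str:
        """Feature label at ``pos`` from the literal per-position definitions."""
        if pos not in self._feature_cache:
            self._feature_cache[pos] = _expected_feature(self, pos)
        return self._feature_cache[pos]

    def expected_effect(self, pos: int, ref: str, alt: str) -> str:
        """synonymous/nonsynonymous/'' by direct spliced-sequence translation."""
        return _expected_effect(self, pos, ref, alt)


def _transcript_position_sets(tx: TranscriptTruth) -> dict:
    exon_pos = set()
    for s, e, _ in tx.exons:
        exon_pos.update(range(s, e + 1))
    cds_pos = set()
    for s, e, _ in tx.cds_segments:
        cds_pos.update(range(s, e + 1))
    splice = set()
    for i, (s, e, _) in enumerate(tx.exons):
        if i > 0:
            splice.update(range(s - _SPLICE, s + _SPLICE))
        if i < len(tx.exons) - 1:
            splice.update(range(e - _SPLICE + 1, e + _SPLICE + 1))
    return {"exon": exon_pos, "cds": cds_pos, "splice": splice}


def _label_for_transcript(tx: TranscriptTruth, sets: dict, pos: int) -> str:
    if tx.start <= pos <= tx.end:
        if pos in sets["cds"]:
            return "exonic"
        if pos in sets["splice"]:
            return "splicing"
        if pos in sets["exon"]:
            if not tx.coding:
                return "ncRNA"
            lo = min(s for s, _, _ in tx.cds_segments)
            hi = max(e for _, e, _ in tx.cds_segments)
            if pos < lo:
                return "utr5" if tx.strand == "+" else "utr3"
            if pos > hi:
                return "utr3" if tx.strand == "+" else "utr5"
            return "exonic"
        return "intronic"
    upstream = (set(range(tx.start - _FLANK, tx.start)) if tx.strand == "+"
                else set(range(tx.end + 1, tx.end + _FLANK + 1)))
    downstream = (set(range(tx.end + 1, tx.end + _FLANK + 1)) if tx.strand == "+"
                  else set(range(tx.start - _FLANK, tx.start)))
    if pos in upstream:
        return "upstream"
    if pos in downstream:
        return "downstream"
    return "intergenic"


def _expected_feature(locus: SyntheticLocus, pos: int) -> str:
    labels = []
    for tx in locus.transcripts:
        lab = _label_for_transcript(tx, _transcript_position_sets(tx), pos)
        if lab != "intergenic":
            labels.append(lab)
    if not labels:
        return "intergenic"
    return min(labels, key=lambda l: (_PRECEDENCE[l], _ORDER.index(l)))


def _expected_effect(locus: SyntheticLocus, pos: int, ref: str, alt: str) -> str:
    seq = locus.genome.sequence(locus.chrom)
    for tx in sorted(locus.transcripts, key=lambda t: t.transcript_id):
        if not tx.coding:
            continue
        cds_pos = [p for s, e, _ in tx.cds_segments for p in range(s, e + 1)]
        if tx.strand == "-":
            cds_pos = cds_pos[::-1]
        if pos not in cds_pos:
            continue
        if len(cds_pos) % 3 != 0:
            continue
        bases = [seq[p - 1] if tx.strand == "+" else COMPLEMENT[seq[p - 1]]
                 for p in cds_pos]
        idx = cds_pos.index(pos)
        codon_i = idx // 3
        ref_codon = "".join(bases[codon_i * 3: codon_i * 3 + 3])
        edited = alt if tx.strand == "+" else COMPLEMENT[alt]
        mut = list(ref_codon)
        mut[idx % 3] = edited
        ref_aa = str(Seq(ref_codon).translate())
        alt_aa = str(Seq("".join(mut)).translate())
        return "synonymous" if ref_aa == alt_aa else "nonsynonymous"
    return ""


def generate_locus(seed: int, n_transcripts: int = 6, coding_fraction: float = 0.7,
                   chrom: str = "syn1") -> SyntheticLocus:
    """Generate a toy genome with gene models.

    Transcripts have 1-4 exons on either strand, are separated by >1.2 kb
    of intergenic sequence (so the 1-kb flanks have room), and coding
    transcripts carry an ATG...stop CDS with no internal stop codon and a
    length divisible by 3. Deterministic for a given seed.
    """
    if not 0 <= coding_fraction <= 1:
        raise DataError(f"coding_fraction must be within [0, 1], got {coding_fraction}")
    if n_transcripts < 1:
        raise DataError("n_transcripts must be >= 1")
    rng = np.random.default_rng(seed)

    layouts = []
    cursor = 1500
    for t in range(n_transcripts):
        n_exons = int(rng.integers(1, 5))
        exon_lens = [int(x) for x in rng.integers(90, 401, n_exons)]
        intron_lens = [int(x) for x in rng.integers(60, 301, max(n_exons - 1, 0))]
        strand = str(rng.choice(["+", "-"]))
        coding = bool(rng.random() < coding_fraction)
        exons = []
        p = cursor
        for i, el in enumerate(exon_lens):
            exons.append((p, p + el - 1))
            p += el
            if i < n_exons - 1:
                p += intron_lens[i]
        layouts.append({"exons": exons, "strand": strand, "coding": coding})
        cursor = p + int(rng.integers(1200, 2601))
    total_len = cursor + 1500

    genome_arr = rng.choice(list("ACGT"), size=total_len)
    seq = list("".join(genome_arr))

    transcripts = []
    gtf_records: list[GtfRecord] = []
    for t, lay in enumerate(layouts, start=1):
        gene_id = f"SYNG{t:06d}"
        tx_id = f"SYNT{t:06d}"
        gene_name = f"GENE{t}"
        strand = lay["strand"]
        exons = lay["exons"]
        biotype = "protein_coding" if lay["coding"] else "lincRNA"

        # exon ids numbered in transcription order
        order = exons if strand == "+" else exons[::-1]
        exon_ids = {}
        for j, (s, e) in enumerate(order, start=1):
            exon_ids[(s, e)] = f"SYNE{t:06d}.{j}"
        exon_tuples = tuple((s, e, exon_ids[(s, e)]) for s, e in exons)

        cds_tuples: tuple = ()
        if lay["coding"]:
            tx_positions: list[int] = []
            for s, e in order:
                rng_pos = range(s, e + 1) if strand == "+" else range(e, s - 1, -1)
                tx_positions.extend(rng_pos)
            L = len(tx_positions)
            a = int(rng.integers(15, 61))
            b = int(rng.integers(15, 61))
            if a + b > L - 9:
                a = min(a, (L - 9) // 2)
                b = min(b, L - 9 - a)
            cds_len = L - a - b
            cds_len -= cds_len % 3
            cds_positions = tx_positions[a:a + cds_len]
            n_internal = cds_len // 3 - 2
            codons = ["ATG"]
            codons += [str(rng.choice(NONSTOP_CODONS)) for _ in range(n_internal)]
            codons.append(str(rng.choice(STOP_CODONS)))
            cds_seq = "".join(codons)
            for i, p in enumerate(cds_positions):
                base = cds_seq[i]
                seq[p - 1] = base if strand == "+" else COMPLEMENT[base]
            lo, hi = min(cds_positions), max(cds_positions)
            genomic_segs = [(max(s, lo), min(e, hi)) for s, e in exons
                            if not (e < lo or s > hi)]
            seg_order = genomic_segs if strand == "+" else genomic_segs[::-1]
            frames = {}
            cum = 0
            for s, e in seg_order:
                frames[(s, e)] = (3 - (cum % 3)) % 3
                cum += e - s + 1
            cds_tuples = tuple((s, e, frames[(s, e)]) for s, e in genomic_segs)

        base_attrs = {"gene_id": gene_id, "gene_name": gene_name,
                      "gene_biotype": biotype}
        gtf_records.append(GtfRecord(chrom, "gene", exons[0][0], exons[-1][1],
                                     strand, None, dict(base_attrs)))
        tx_attrs = dict(base_attrs, transcript_id=tx_id)
        gtf_records.append(GtfRecord(chrom, "transcript", exons[0][0], exons[-1][1],
                                     strand, None, dict(tx_attrs)))
        for s, e, eid in exon_tuples:
            gtf_records.append(GtfRecord(chrom, "exon", s, e, strand, None,
                                         dict(tx_attrs, exon_id=eid)))
        for s, e, frame in cds_tuples:
            gtf_records.append(GtfRecord(chrom, "CDS", s, e, strand, frame,
                                         dict(tx_attrs)))

        transcripts.append(TranscriptTruth(
            transcript_id=tx_id, gene_id=gene_id, gene_name=gene_name,
            strand=strand, exons=exon_tuples, cds_segments=cds_tuples,
            coding=lay["coding"],
        ))

    genome = GenomeSequence({chrom: "".join(seq)})
    return SyntheticLocus(chrom=chrom, genome=genome, gtf_records=gtf_records,
                          transcripts=transcripts, seed=seed)


# ---------------------------------------------------------------------------
# Resource tables + repeats
# ---------------------------------------------------------------------------

@dataclass
class KbTruthSite:
    chrom: str
    pos: int
    dna_base: str
    rna_base: str
    memberships: tuple
    alu: bool
    evidence_class: str

    @property
    def key(self):
        return (self.chrom, self.pos, self.dna_base, self.rna_base)


@dataclass
class SyntheticResources:
    records_by_resource: dict
    repeats: list
    kb_truth: list
    seed: int

    @property
    def site_positions(self) -> set:
        return {t.pos for t in self.kb_truth}

    def write_tables(self, out_dir) -> dict:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for rid, recs in sorted(self.records_by_resource.items()):
            p = out_dir / f"resource_{rid}.tsv"
            write_resource_table(recs, p)
            paths[rid] = p
        return paths

    def write_repeats(self, path) -> None:
        write_repeats_bed(self.repeats, path)


def _resolve_request(req: Mapping) -> tuple[tuple, bool, str]:
    """Resolve a class request to (memberships, alu flag, class letter)."""
    from .knowledgebase import evidence_class_for_count

    letter = req.get("class_letter")
    memberships = tuple(req.get("memberships", ()))
    alu = req.get("alu")
    if memberships:
        alu = bool(alu)
        count = len(memberships) + (1 if alu else 0)
        implied = evidence_class_for_count(count)
        if letter and letter != implied:
            raise DataError(
                f"requested class {letter} but memberships {memberships} "
                f"with alu={alu} imply class {implied} (count {count})")
        return memberships, alu, implied
    if not letter:
        raise DataError("class request needs 'class_letter' or 'memberships'")
    if letter not in CLASS_COMPOSITIONS:
        raise DataError(f"unknown evidence class {letter!r}")
    memberships, alu = CLASS_COMPOSITIONS[letter]
    return memberships, alu, letter


def _pick_spaced_positions(rng, length: int, n: int, used: set,
                           spacing: int = 400, margin: int = 350) -> list[int]:
    chosen: list[int] = []
    attempts = 0
    while len(chosen) < n:
        attempts += 1
        if attempts > 20000:
            raise DataError("could not place requested sites; locus too small")
        cand = int(rng.integers(margin + 1, length - margin))
        if all(abs(cand - p) > spacing for p in used) and \
           all(abs(cand - p) > spacing for p in chosen):
            chosen.append(cand)
    return chosen


def generate_resources(seed: int, locus: SyntheticLocus,
                       class_requests: Sequence[Mapping] = DEFAULT_CLASS_MIX
                       ) -> SyntheticResources:
    """Write each requested site into exactly the resources its class needs.

    Alu-flagged sites get a ~300-bp Alu repeat interval placed over them;
    two non-Alu decoy repeats are added to exercise the Alu name filter.
    Sites are spaced >400 bp apart so a repeat never covers a neighbour.
    """
    rng = np.random.default_rng(seed)
    tissues = ("brain", "liver", "lymphoblastoid", "breast")
    resolved = []
    for req in class_requests:
        memberships, alu, letter = _resolve_request(req)
        for _ in range(int(req.get("n", 1))):
            resolved.append((memberships, alu, letter))

    used: set[int] = set()
    positions = _pick_spaced_positions(rng, locus.length, len(resolved), used)
    used.update(positions)

    records_by_resource: dict[str, list[ResourceRecord]] = {}
    repeats: list[RepeatInterval] = []
    kb_truth: list[KbTruthSite] = []
    for (memberships, alu, letter), pos in zip(resolved, positions):
        dna = locus.genome.base(locus.chrom, pos)
        if dna == "A":
            rna = "G"
        elif dna == "T":
            rna = "C"
        else:
            rna = str(rng.choice([b for b in "ACGT" if b != dna]))
        pubmed = str(int(rng.integers(10_000_000, 99_999_999)))
        for rid in memberships:
            records_by_resource.setdefault(rid, []).append(ResourceRecord(
                resource_id=rid, chrom=locus.chrom, pos=pos,
                dna_base=dna, rna_base=rna, strand="+",
                tissue_sources=(str(rng.choice(tissues)),),
                pubmed_ids=(pubmed,),
            ))
        if alu:
            offset = int(rng.integers(5, 41))
            start0 = max(0, pos - 1 - offset)
            repeats.append(RepeatInterval(
                chrom=locus.chrom, start=start0, end=min(start0 + 300, locus.length),
                repeat_name=str(rng.choice(["AluSx", "AluY", "AluJb"])),
                repeat_family="SINE/Alu",
            ))
        kb_truth.append(KbTruthSite(
            chrom=locus.chrom, pos=pos, dna_base=dna, rna_base=rna,
            memberships=memberships, alu=alu, evidence_class=letter,
        ))

    for pos in _pick_spaced_positions(rng, locus.length, 2, used):
        start0 = pos - 1
        repeats.append(RepeatInterval(
            chrom=locus.chrom, start=start0, end=min(start0 + 250, locus.length),
            repeat_name="L1MA4", repeat_family="LINE/L1",
        ))
    return SyntheticResources(records_by_resource=records_by_resource,
                              repeats=repeats, kb_truth=kb_truth, seed=seed)


# ---------------------------------------------------------------------------
# Paired DNA/RNA VCFs
# ---------------------------------------------------------------------------

@dataclass
class PlantedRdd:
    chrom: str
    pos: int
    ref: str
    alt: str
    edit_type: str
    expected_feature: str
    expected_effect: str
    known: bool = False

    @property
    def key(self):
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class FixtureManifest:
    """Ground truth for one generated fixture set (JSON-serialisable)."""

    seed: int
    planted_germline: list   # [(chrom, pos, ref, alt), ...]
    planted_rdd: list        # [PlantedRdd, ...]
    kb_truth: list           # [KbTruthSite, ...]

    def save(self, path) -> None:
        payload = {
            "seed": self.seed,
            "planted_germline": [list(g) for g in self.planted_germline],
            "planted_rdd": [asdict(r) for r in self.planted_rdd],
            "kb_truth": [asdict(t) for t in self.kb_truth],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "FixtureManifest":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            seed=payload["seed"],
            planted_germline=[tuple(g) for g in payload["planted_germline"]],
            planted_rdd=[PlantedRdd(**{**r, "expected_feature": r["expected_feature"]})
                         for r in payload["planted_rdd"]],
            kb_truth=[KbTruthSite(**{**t, "memberships": tuple(t["memberships"])})
                      for t in payload["kb_truth"]],
        )

    @property
    def expected_rdd_keys(self) -> set:
        return {r.key for r in self.planted_rdd}


@dataclass
class PairedVcfs:
    dna_records: list
    rna_records: list
    manifest: FixtureManifest

    def write(self, dna_path, rna_path) -> None:
        write_vcf(self.dna_records, dna_path)
        write_vcf(self.rna_records, rna_path)


def generate_paired_vcfs(seed: int, locus: SyntheticLocus,
                         n_germline: int = 6, n_rdd: int = 7,
                         known_sites: Sequence[KbTruthSite] = (),
                         atoi_fraction: float = 0.7,
                         exclude_positions: Iterable[int] = ()) -> PairedVcfs:
    """Paired DNA/RNA VCFs with planted germline variants and RDD sites.

    The DNA VCF holds the germline variants; the RNA VCF holds the same
    germline variants plus the planted RDD sites, so the RDD comparison
    must return exactly the planted set. ``known_sites`` re-uses
    knowledgebase sites as RDD plants (counted within ``n_rdd``); the rest
    are novel, biased ``atoi_fraction`` toward A-to-G / T-to-C.
    """
    if len(known_sites) > n_rdd:
        raise DataError("more known_sites than requested RDD sites")
    rng = np.random.default_rng(seed)
    chrom = locus.chrom
    seq = locus.genome

    used: set[int] = set(exclude_positions)
    used.update(t.pos for t in known_sites)

    def pick(filter_bases: str | None = None) -> int:
        attempts = 0
        while True:
            attempts += 1
            if attempts > 20000:
                raise DataError("no free positions left in the locus")
            cand = int(rng.integers(1, locus.length + 1))
            if cand in used:
                continue
            if filter_bases and seq.base(chrom, cand) not in filter_bases:
                continue
            used.add(cand)
            return cand

    germline = []
    for _ in range(n_germline):
        pos = pick()
        ref = seq.base(chrom, pos)
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        germline.append((chrom, pos, ref, alt))

    planted: list[PlantedRdd] = []
    for site in known_sites:
        planted.append(PlantedRdd(
            chrom=site.chrom, pos=site.pos, ref=site.dna_base, alt=site.rna_base,
            edit_type=f"{site.dna_base}-to-{site.rna_base}",
            expected_feature=locus.expected_feature(site.pos),
            expected_effect=locus.expected_effect(site.pos, site.dna_base,
                                                  site.rna_base),
            known=True,
        ))
    for _ in range(n_rdd - len(known_sites)):
        if rng.random() < atoi_fraction:
            pos = pick(filter_bases="AT")
            ref = seq.base(chrom, pos)
            alt = "G" if ref == "A" else "C"
        else:
            pos = pick()
            ref = seq.base(chrom, pos)
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        planted.append(PlantedRdd(
            chrom=chrom, pos=pos, ref=ref, alt=alt,
            edit_type=f"{ref}-to-{alt}",
            expected_feature=locus.expected_feature(pos),
            expected_effect=locus.expected_effect(pos, ref, alt),
            known=False,
        ))
    planted.sort(key=lambda r: r.key)

    dna_records = [VcfRecord(chrom=c, pos=p, id=None, ref_base=r, alt_base=a,
                             qual=60.0) for c, p, r, a in sorted(germline)]
    rna_entries = sorted(
        [(c, p, r, a) for c, p, r, a in germline] + [r.key for r in planted])
    rna_records = [VcfRecord(chrom=c, pos=p, id=None, ref_base=r, alt_base=a,
                             qual=60.0) for c, p, r, a in rna_entries]
    manifest = FixtureManifest(seed=seed, planted_germline=sorted(germline),
                               planted_rdd=planted, kb_truth=[])
    return PairedVcfs(dna_records=dna_records, rna_records=rna_records,
                      manifest=manifest)


# ---------------------------------------------------------------------------
# Full fixture set
# ---------------------------------------------------------------------------

def simulate(seed: int, out_dir, n_transcripts: int = 6,
             n_germline: int = 6, n_rdd: int = 8, n_known_rdd: int = 4,
             class_mix: Sequence[Mapping] = DEFAULT_CLASS_MIX
             ) -> tuple[FixtureManifest, dict]:
    """Generate and write a complete fixture set; returns (manifest, paths).

    Outputs under ``out_dir``: ``genome.fa``, ``genes.gtf``, ``repeats.bed``,
    one ``resource_<ID>.tsv`` per resource, ``dna.vcf``, ``rna.vcf`` and
    ``manifest.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sub = np.random.default_rng(seed).integers(0, 2**31, size=3)

    locus = generate_locus(int(sub[0]), n_transcripts=n_transcripts)
    resources = generate_resources(int(sub[1]), locus, class_mix)

    known = resources.kb_truth[:n_known_rdd]
    exclude = resources.site_positions - {t.pos for t in known}
    paired = generate_paired_vcfs(int(sub[2]), locus,
                                  n_germline=n_germline, n_rdd=n_rdd,
                                  known_sites=known,
                                  exclude_positions=exclude)
    manifest = FixtureManifest(
        seed=seed,
        planted_germline=paired.manifest.planted_germline,
        planted_rdd=paired.manifest.planted_rdd,
        kb_truth=resources.kb_truth,
    )

    paths = {
        "genome": out_dir / "genome.fa",
        "gtf": out_dir / "genes.gtf",
        "repeats": out_dir / "repeats.bed",
        "dna_vcf": out_dir / "dna.vcf",
        "rna_vcf": out_dir / "rna.vcf",
        "manifest": out_dir / "manifest.json",
    }
    locus.write_fasta(paths["genome"])
    locus.write_gtf(paths["gtf"])
    resources.write_repeats(paths["repeats"])
    paths["resources"] = resources.write_tables(out_dir)
    paired.write(paths["dna_vcf"], paths["rna_vcf"])
    manifest.save(paths["manifest"])
    return manifest, paths
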