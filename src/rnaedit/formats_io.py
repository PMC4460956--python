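"""Readers and writers for the standard formats the toolkit touches.

Coordinate conventions, fixed here once and converted at read time:

* VCF — 1-based positions (kept as-is).
* GTF — 1-based closed intervals (kept as-is).
* BED / RepeatMasker ``.out`` — normalised to 0-based half-open
  :class:`RepeatInterval`; a 1-based position ``p`` overlaps an interval
  iff ``start < p <= end`` (see :meth:`RepeatInterval.contains_position`).

Only single-base substitutions are ingested from VCF: RNA editing alters a
single nucleotide, so indels, multi-base and symbolic alleles are skipped
with a logged warning. Multiallelic records are split into one record per
alternative allele because every downstream comparison keys on a single
(chromosome, position, reference, alternative) tuple.

Chromosome labels are normalised by a ``chrom_policy`` flag shared by all
readers: ``"strip"`` (default) removes a ``chr`` prefix, ``"add"`` adds one,
``"none"`` leaves labels untouched.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
import pysam
from Bio import SeqIO

from .errors import (
    FastaFormatError,
    GtfFormatError,
    RepeatFormatError,
    ResourceFormatError,
    VcfFormatError,
)

logger = logging.getLogger(__name__)

BASES = "ACGT"

#: Columns required in an editing-resource TSV, in header order.
RESOURCE_COLUMNS = ("chrom", "pos", "in_dna", "in_rna", "strand", "source", "pubmed")


def normalize_chrom(name: str, policy: str = "strip") -> str:
    """Apply the chromosome-label policy (``strip``/``add``/``none``)."""
    if policy == "strip":
        if name.lower().startswith("chr") and len(name) > 3:
            return name[3:]
        return name
    if policy == "add":
        return name if name.lower().startswith("chr") else "chr" + name
    if policy == "none":
        return name
    raise ValueError(f"unknown chrom_policy {policy!r}")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

@dataclass
class VcfRecord:
    """One single-base substitution from a VCF file (1-based position)."""

    chrom: str
    pos: int
    id: str | None
    ref_base: str
    alt_base: str
    qual: float | None = None
    filter_field: str = "."
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise VcfFormatError(f"position must be >= 1, got {self.pos}")
        if self.ref_base == self.alt_base:
            raise VcfFormatError(
                f"{self.chrom}:{self.pos} REF equals ALT ({self.ref_base})"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_base, self.alt_base)


def _is_snv_allele(allele: str | None) -> bool:
    return allele is not None and len(allele) == 1 and allele.upper() in BASES


def read_vcf(path, chrom_policy: str = "strip") -> list[VcfRecord]:
    """Read site-level records from a VCF file.

    Multiallelic lines are split into one record per ALT; indels, symbolic
    and multi-base alleles are skipped with a warning. Genotype columns are
    ignored: the comparisons downstream are site-level.
    """
    path = os.fspath(path)
    try:
        vf = pysam.VariantFile(path)
    except (ValueError, OSError) as exc:
        raise VcfFormatError(f"{path}: not a parseable VCF ({exc})") from None
    records: list[VcfRecord] = []
    try:
        for rec in vf:
            if not _is_snv_allele(rec.ref):
                logger.warning(
                    "%s:%s REF %r is not a single base; skipped", rec.chrom, rec.pos, rec.ref
                )
                continue
            info = {}
            for k, v in rec.info.items():
                if v is True:
                    info[k] = True
                elif isinstance(v, tuple):
                    info[k] = ",".join(str(x) for x in v)
                else:
                    info[k] = str(v)
            filt = ";".join(rec.filter.keys()) or "."
            for alt in rec.alts or ():
                if not _is_snv_allele(alt):
                    logger.warning(
                        "%s:%s ALT %r is not a single-base substitution; skipped",
                        rec.chrom, rec.pos, alt,
                    )
                    continue
                if alt.upper() == rec.ref.upper():
                    logger.warning("%s:%s ALT equals REF; skipped", rec.chrom, rec.pos)
                    continue
                records.append(
                    VcfRecord(
                        chrom=normalize_chrom(rec.chrom, chrom_policy),
                        pos=rec.pos,
                        id=rec.id,
                        ref_base=rec.ref.upper(),
                        alt_base=alt.upper(),
                        qual=rec.qual,
                        filter_field=filt,
                        info=dict(info),
                    )
                )
    except (ValueError, OSError) as exc:
        raise VcfFormatError(f"{path}: malformed VCF body ({exc})") from None
    finally:
        vf.close()
    return records


def write_vcf(records: Iterable[VcfRecord], path) -> None:
    """Write records as a minimal valid VCF v4.2 file, in the given order."""
    records = list(records)
    header = pysam.VariantHeader()
    contigs: list[str] = []
    for r in records:
        if r.chrom not in contigs:
            contigs.append(r.chrom)
    for c in contigs:
        header.contigs.add(c)
    for r in records:
        for k, v in r.info.items():
            if k not in header.info:
                if v is True:
                    header.info.add(k, 0, "Flag", "flag")
                else:
                    header.info.add(k, 1, "String", "value")
        for name in r.filter_field.split(";"):
            if name not in (".", "", "PASS") and name not in header.filters:
                header.filters.add(name, None, None, "filter")
    with pysam.VariantFile(os.fspath(path), "w", header=header) as out:
        for r in records:
            rec = out.new_record(
                contig=r.chrom,
                start=r.pos - 1,
                stop=r.pos,
                alleles=(r.ref_base, r.alt_base),
                id=r.id,
                qual=r.qual,
            )
            for name in r.filter_field.split(";"):
                if name not in (".", ""):
                    rec.filter.add(name)
            for k, v in r.info.items():
                rec.info[k] = True if v is True else str(v)
            out.write(rec)


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

@dataclass
class GtfRecord:
    """One GTF feature line (1-based closed interval)."""

    seqname: str
    feature_kind: str
    start: int
    end: int
    strand: str
    frame: int | None
    attributes: dict

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise GtfFormatError(
                f"{self.seqname} {self.feature_kind}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise GtfFormatError(f"invalid strand {self.strand!r}")


_ATTR_RE = re.compile(r'(\w+)\s+(?:"([^"]*)"|([^";\s]+))\s*;?')


def _parse_attributes(text: str) -> dict:
    return {m.group(1): m.group(2) if m.group(2) is not None else m.group(3)
            for m in _ATTR_RE.finditer(text)}


def read_gtf(path, chrom_policy: str = "strip") -> list[GtfRecord]:
    """Read a 9-column GTF (Ensembl attribute dialect)."""
    path = os.fspath(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] != 9:
        raise GtfFormatError(f"{path}: expected 9 tab-separated columns, got {df.shape[1]}")
    records = []
    for row in df.itertuples(index=False):
        seqname, _source, feature, start, end, _score, strand, frame, attrs = row
        try:
            start_i, end_i = int(start), int(end)
        except ValueError:
            raise GtfFormatError(f"{path}: non-integer coordinates {start!r}/{end!r}") from None
        records.append(
            GtfRecord(
                seqname=normalize_chrom(seqname, chrom_policy),
                feature_kind=feature,
                start=start_i,
                end=end_i,
                strand=strand,
                frame=None if frame == "." else int(frame),
                attributes=_parse_attributes(attrs),
            )
        )
    return records


def write_gtf(records: Iterable[GtfRecord], path) -> None:
    """Serialise GTF records (used by the fixture generator)."""
    with open(os.fspath(path), "w") as fh:
        for r in records:
            attrs = " ".join(f'{k} "{v}";' for k, v in r.attributes.items())
            frame = "." if r.frame is None else str(r.frame)
            fh.write(
                f"{r.seqname}\trnaedit\t{r.feature_kind}\t{r.start}\t{r.end}\t.\t"
                f"{r.strand}\t{frame}\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# Repeats (BED / RepeatMasker .out)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepeatInterval:
    """A repeat annotation, 0-based half-open."""

    chrom: str
    start: int
    end: int
    repeat_name: str
    repeat_family: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise RepeatFormatError(
                f"{self.chrom}: empty interval [{self.start}, {self.end})"
            )

    def contains_position(self, pos: int) -> bool:
        """Whether a 1-based position overlaps this interval."""
        return self.start < pos <= self.end

    @property
    def is_alu(self) -> bool:
        return self.repeat_name.startswith("Alu")


def _looks_like_repeatmasker(fields: list[str]) -> bool:
    if len(fields) < 11:
        return False
    try:
        int(fields[0]); int(fields[5]); int(fields[6])
    except ValueError:
        return False
    return True


def read_repeat_intervals(path, chrom_policy: str = "strip") -> list[RepeatInterval]:
    """Read repeats from BED4+ or a RepeatMasker ``.out`` table.

    The dialect is auto-detected from the column signature; either way the
    result is 0-based half-open (RepeatMasker coordinates are 1-based closed
    and are shifted on read).
    """
    path = os.fspath(path)
    intervals: list[RepeatInterval] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    data = [ln for ln in lines if ln.strip() and not ln.startswith(("#", "track"))]
    # RepeatMasker .out files open with two header lines starting "SW"/"score".
    while data and data[0].lstrip().startswith(("SW", "score")):
        data.pop(0)
    for ln in data:
        fields = ln.split()
        if _looks_like_repeatmasker(fields):
            chrom, start, end = fields[4], int(fields[5]) - 1, int(fields[6])
            name = fields[9]
            family = fields[10] if len(fields) > 10 else ""
        elif len(fields) >= 4:
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError:
                raise RepeatFormatError(f"{path}: unrecognised repeat row {ln!r}") from None
            name = fields[3]
            family = fields[4] if len(fields) > 4 else ""
        else:
            raise RepeatFormatError(f"{path}: unrecognised repeat row {ln!r}")
        intervals.append(
            RepeatInterval(
                chrom=normalize_chrom(chrom, chrom_policy),
                start=start,
                end=end,
                repeat_name=name,
                repeat_family=family,
            )
        )
    return intervals


def write_repeats_bed(intervals: Iterable[RepeatInterval], path) -> None:
    with open(os.fspath(path), "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.repeat_name}\t{iv.repeat_family}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

class GenomeSequence:
    """Upper-cased per-chromosome nucleotide strings with 1-based access."""

    VALID = set("ACGTN")

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {c: s.upper() for c, s in sequences.items()}
        for chrom, seq in self._seqs.items():
            bad = set(seq) - self.VALID
            if bad:
                raise FastaFormatError(
                    f"{chrom}: invalid characters {sorted(bad)} in sequence"
                )

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def chroms(self) -> list[str]:
        return list(self._seqs)

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def fetch(self, chrom: str, pos: int, length: int = 1) -> str:
        """Return ``length`` bases starting at 1-based ``pos``."""
        if pos < 1 or pos + length - 1 > len(self._seqs[chrom]):
            raise IndexError(f"{chrom}:{pos}+{length} outside sequence")
        return self._seqs[chrom][pos - 1:pos - 1 + length]

    def base(self, chrom: str, pos: int) -> str:
        return self.fetch(chrom, pos, 1)

    def sequence(self, chrom: str) -> str:
        return self._seqs[chrom]


def read_fasta(path, chrom_policy: str = "strip") -> GenomeSequence:
    """Load a FASTA file, keyed by the first whitespace-delimited header token."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        name = normalize_chrom(rec.id, chrom_policy)
        if name in seqs:
            raise FastaFormatError(f"duplicate FASTA header {rec.id!r}")
        seqs[name] = str(rec.seq).upper()
    return GenomeSequence(seqs)


def write_fasta(genome: GenomeSequence, path, width: int = 60) -> None:
    with open(os.fspath(path), "w") as fh:
        for chrom in genome.chroms():
            fh.write(f">{chrom}\n")
            seq = genome.sequence(chrom)
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Editing-resource tables
# ---------------------------------------------------------------------------

@dataclass
class ResourceRecord:
    """One known editing site from a resource table, tagged with its resource."""

    resource_id: str
    chrom: str
    pos: int
    dna_base: str
    rna_base: str
    strand: str = "unknown"
    tissue_sources: tuple = ()
    pubmed_ids: tuple = ()

    def __post_init__(self) -> None:
        if self.dna_base == self.rna_base:
            raise ResourceFormatError(
                f"{self.chrom}:{self.pos} identical DNA and RNA bases"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.dna_base, self.rna_base)


def _split_list(value) -> tuple:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return ()
    return tuple(x.strip() for x in str(value).split(",") if x.strip())


def read_resource_table(path, resource_id: str, chrom_policy: str = "strip") -> list[ResourceRecord]:
    """Read an editing-site resource TSV.

    Expected header columns: ``chrom pos in_dna in_rna strand source pubmed``
    (``source`` and ``pubmed`` may hold comma-separated lists). Rows whose DNA
    and RNA base coincide are rejected with a warning.
    """
    path = os.fspath(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        return []
    missing = set(RESOURCE_COLUMNS) - set(df.columns)
    if missing:
        raise ResourceFormatError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        dna = str(row.in_dna).upper()
        rna = str(row.in_rna).upper()
        if dna not in BASES or rna not in BASES:
            logger.warning("%s: invalid bases %r/%r at %s:%s; row skipped",
                           resource_id, dna, rna, row.chrom, row.pos)
            continue
        if dna == rna:
            logger.warning("%s: identical DNA/RNA base at %s:%s; row skipped",
                           resource_id, row.chrom, row.pos)
            continue
        strand = row.strand if row.strand in ("+", "-") else "unknown"
        records.append(
            ResourceRecord(
                resource_id=resource_id,
                chrom=normalize_chrom(str(row.chrom), chrom_policy),
                pos=int(row.pos),
                dna_base=dna,
                rna_base=rna,
                strand=strand,
                tissue_sources=_split_list(row.source),
                pubmed_ids=_split_list(row.pubmed),
            )
        )
    return records


def write_resource_table(records: Iterable[ResourceRecord], path) -> None:
    with open(os.fspath(path), "w") as fh:
        fh.write("\t".join(RESOURCE_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.dna_base}\t{r.rna_base}\t"
                f"{r.strand if r.strand in ('+', '-') else '.'}\t"
                f"{','.join(r.tissue_sources)}\t{','.join(r.pubmed_ids)}\n"
            )
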