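"""Integration of RNA-editing-site resources into an evidence-graded knowledgebase.

Sites from the individual resources are merged on the exact key
``(chromosome, position, DNA base, RNA base)`` — not on strand — so the same
position edited to a different base stays a distinct site. Each integrated
site carries the set of resources that report it, and an *evidence level*
equal to the number of supporting resources plus one if the site lies in an
Alu repeat: 1 → E, 2 → D, 3 → C, 4 → B, ≥5 → A (A is the highest level).
Alu context can raise the level of a known site but can never create a site
on its own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .errors import DataError
from .formats_io import RepeatInterval, ResourceRecord

logger = logging.getLogger(__name__)

#: Resources eligible as evidence, in canonical order.
DEFAULT_RESOURCES = ("DARNED", "ENCODE", "RADAR", "BAHN", "LI")

EVIDENCE_CLASSES = ("A", "B", "C", "D", "E")

KB_COLUMNS = (
    "chrom", "pos", "dna_base", "rna_base", "strand", "memberships",
    "alu_name", "tissue_sources", "pubmed_ids", "evidence_count", "evidence_class",
)


@dataclass(frozen=True)
class ResourceRegistry:
    """The resources that count as evidence, plus the Alu bonus flag.

    The default registry follows the database tables (DARNED, ENCODE, RADAR,
    Bahn, Li); swap members to express other readings of the resource set.
    """

    resources: tuple = DEFAULT_RESOURCES
    alu_counts: bool = True

    def __post_init__(self) -> None:
        if len(set(self.resources)) != len(self.resources):
            raise ValueError("resource identifiers must be unique")

    def canonical_order(self, resource_ids: Iterable[str]) -> list[str]:
        """Registry members first (registry order), then the rest lexically."""
        ids = set(resource_ids)
        ordered = [r for r in self.resources if r in ids]
        ordered += sorted(ids - set(self.resources))
        return ordered


@dataclass
class IntegratedSite:
    """One merged knowledgebase entry."""

    chrom: str
    pos: int
    dna_base: str
    rna_base: str
    strand: str = "unknown"
    memberships: tuple = ()
    alu_name: str | None = None
    tissue_sources: tuple = ()
    pubmed_ids: tuple = ()

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.dna_base, self.rna_base)

    @property
    def data_references(self) -> tuple:
        """Resource names backing this site (Data reference column)."""
        return self.memberships


@dataclass(frozen=True)
class EvidenceAssignment:
    evidence_count: int
    class_letter: str


def evidence_class_for_count(count: int) -> str:
    """Map an evidence count to its class letter (counts above 5 clamp to A)."""
    if count < 1:
        raise ValueError("evidence count must be >= 1")
    return "EDCBA"[min(count, 5) - 1]


def assign_evidence_level(site: IntegratedSite,
                          registry: ResourceRegistry = ResourceRegistry()) -> EvidenceAssignment:
    """Grade a site by the number of registry resources reporting it.

    Alu overlap adds one to the count when the registry enables it, but a
    site with no resource membership is an error: Alu context alone is not
    evidence of editing.
    """
    if not site.memberships:
        raise DataError(f"site {site.key} has no resource memberships")
    eligible = [m for m in site.memberships if m in registry.resources]
    count = len(eligible)
    if registry.alu_counts and site.alu_name:
        count += 1
    if count < 1:
        raise DataError(
            f"site {site.key} has no membership in registered resources {registry.resources}"
        )
    return EvidenceAssignment(evidence_count=count, class_letter=evidence_class_for_count(count))


def build_alu_index(repeats: Iterable[RepeatInterval]) -> dict[str, IntervalTree]:
    """Per-chromosome interval trees over Alu repeats (0-based half-open)."""
    trees: dict[str, IntervalTree] = {}
    for iv in repeats:
        if iv.is_alu:
            trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv.repeat_name)
    return trees


def alu_name_at(trees: Mapping[str, IntervalTree], chrom: str, pos: int) -> str | None:
    """Name of an Alu repeat overlapping 1-based ``pos``, or None.

    The deterministic pick among overlaps is the lowest (start, name).
    """
    tree = trees.get(chrom)
    if not tree:
        return None
    hits = tree[pos - 1]  # [s, e) overlaps 1-based p iff s <= p-1 < e
    if not hits:
        return None
    return min((h.begin, h.data) for h in hits)[1]


class Knowledgebase:
    """Integrated editing sites keyed by (chrom, pos, DNA base, RNA base)."""

    def __init__(self, sites: Iterable[IntegratedSite] = (),
                 registry: ResourceRegistry = ResourceRegistry(),
                 raw_record_count: int = 0):
        self.registry = registry
        self.raw_record_count = raw_record_count
        self._sites: dict[tuple, IntegratedSite] = {}
        for s in sites:
            if s.key in self._sites:
                raise DataError(f"duplicate integrated site {s.key}")
            self._sites[s.key] = s

    def __len__(self) -> int:
        return len(self._sites)

    def __iter__(self):
        return iter(self._sites.values())

    def query(self, chrom: str, pos: int, dna_base: str, rna_base: str) -> IntegratedSite | None:
        """Exact-key lookup; None when absent."""
        return self._sites.get((chrom, pos, dna_base, rna_base))

    def evidence(self, site: IntegratedSite) -> EvidenceAssignment:
        return assign_evidence_level(site, self.registry)

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in EVIDENCE_CLASSES}
        for s in self:
            counts[self.evidence(s).class_letter] += 1
        return counts

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        """Persist as a sorted TSV with documented columns."""
        with open(path, "w") as fh:
            fh.write("\t".join(KB_COLUMNS) + "\n")
            for key in sorted(self._sites):
                s = self._sites[key]
                ev = self.evidence(s)
                fh.write("\t".join([
                    s.chrom, str(s.pos), s.dna_base, s.rna_base, s.strand,
                    ",".join(s.memberships),
                    s.alu_name or ".",
                    ",".join(s.tissue_sources) or ".",
                    ",".join(s.pubmed_ids) or ".",
                    str(ev.evidence_count), ev.class_letter,
                ]) + "\n")

    @classmethod
    def load(cls, path, registry: ResourceRegistry = ResourceRegistry()) -> "Knowledgebase":
        sites = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if tuple(header) != KB_COLUMNS:
                raise DataError(f"{path}: not a knowledgebase TSV (header {header})")
            for line in fh:
                f = line.rstrip("\n").split("\t")
                row = dict(zip(KB_COLUMNS, f))
                sites.append(IntegratedSite(
                    chrom=row["chrom"],
                    pos=int(row["pos"]),
                    dna_base=row["dna_base"],
                    rna_base=row["rna_base"],
                    strand=row["strand"],
                    memberships=tuple(row["memberships"].split(",")) if row["memberships"] else (),
                    alu_name=None if row["alu_name"] == "." else row["alu_name"],
                    tissue_sources=() if row["tissue_sources"] == "." else tuple(row["tissue_sources"].split(",")),
                    pubmed_ids=() if row["pubmed_ids"] == "." else tuple(row["pubmed_ids"].split(",")),
                ))
        return cls(sites, registry=registry)


def integrate_resources(resource_records: Mapping[str, Sequence[ResourceRecord]] | Iterable[ResourceRecord],
                        repeats: Iterable[RepeatInterval] = (),
                        registry: ResourceRegistry = ResourceRegistry()) -> Knowledgebase:
    """Merge per-resource site lists into a :class:`Knowledgebase`.

    Records sharing (chrom, pos, DNA base, RNA base) merge into one site whose
    memberships are the contributing resource ids. Tissue sources, PubMed ids
    and memberships are unions in canonical registry order, so integration is
    independent of the order resources are supplied in. Strand is decided by
    majority vote among resource records; ties (including all-unknown) give
    ``unknown``. A merged site is flagged with the name of any overlapping
    Alu repeat.
    """
    if isinstance(resource_records, Mapping):
        by_resource = {rid: list(recs) for rid, recs in resource_records.items()}
    else:
        by_resource = {}
        for rec in resource_records:
            by_resource.setdefault(rec.resource_id, []).append(rec)
    for rid, recs in by_resource.items():
        for rec in recs:
            if rec.resource_id != rid:
                raise DataError(
                    f"record {rec.key} tagged {rec.resource_id!r} supplied under {rid!r}")

    alu_trees = build_alu_index(repeats)
    merged: dict[tuple, dict] = {}
    raw_count = 0
    for rid in registry.canonical_order(by_resource):
        for rec in sorted(by_resource[rid], key=lambda r: r.key):
            raw_count += 1
            entry = merged.setdefault(rec.key, {
                "memberships": [], "tissues": [], "pubmeds": [], "strand_votes": [],
            })
            if rid not in entry["memberships"]:
                entry["memberships"].append(rid)
            for t in rec.tissue_sources:
                if t not in entry["tissues"]:
                    entry["tissues"].append(t)
            for p in rec.pubmed_ids:
                if p not in entry["pubmeds"]:
                    entry["pubmeds"].append(p)
            if rec.strand in ("+", "-"):
                entry["strand_votes"].append(rec.strand)

    sites = []
    for key in sorted(merged):
        chrom, pos, dna, rna = key
        entry = merged[key]
        plus = entry["strand_votes"].count("+")
        minus = entry["strand_votes"].count("-")
        strand = "+" if plus > minus else "-" if minus > plus else "unknown"
        sites.append(IntegratedSite(
            chrom=chrom, pos=pos, dna_base=dna, rna_base=rna,
            strand=strand,
            memberships=tuple(entry["memberships"]),
            alu_name=alu_name_at(alu_trees, chrom, pos),
            tissue_sources=tuple(entry["tissues"]),
            pubmed_ids=tuple(entry["pubmeds"]),
        ))
    return Knowledgebase(sites, registry=registry, raw_record_count=raw_count)
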