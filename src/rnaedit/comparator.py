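"""DNA-vs-RNA variant comparison and multi-sample known-site comparison.

The RDD (RNA-DNA difference) comparison takes paired variant calls from the
same individual: an RNA variant becomes an editing candidate iff no DNA
variant was called at the same position. Exclusion is by position alone —
a genomic variant explains an RNA mismatch regardless of allele notation.

Known-site comparison intersects/differences per-sample site sets by the
exact (chrom, pos, DNA base, RNA base) key, so the same position edited to
different bases counts as different sites.

Edit types are the 12 ordered base substitutions X-to-Y. For a minus-strand
site both bases are complemented before labelling, so a genomic T→C within
a minus-strand gene reports as A-to-G (the A-to-I signature).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import pandas as pd

from .errors import DataError
from .formats_io import VcfRecord

BASES = "ACGT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: The 12 possible edit-type labels, in fixed order.
EDIT_TYPES = tuple(f"{a}-to-{b}" for a in BASES for b in BASES if a != b)

SiteKey = tuple  # (chrom, pos, dna_base, rna_base)


def classify_edit_type(dna_base: str, rna_base: str, strand: str = "+") -> str:
    """Label a substitution; minus-strand bases are complemented first.

    Unknown strand is treated as plus (the label then reflects the genomic
    top strand).
    """
    dna, rna = dna_base.upper(), rna_base.upper()
    if dna not in BASES or rna not in BASES:
        raise DataError(f"invalid bases {dna_base!r}/{rna_base!r}")
    if dna == rna:
        raise DataError(f"DNA and RNA base identical ({dna})")
    if strand == "-":
        dna, rna = COMPLEMENT[dna], COMPLEMENT[rna]
    return f"{dna}-to-{rna}"


@dataclass(frozen=True)
class RddCandidate:
    """An RNA variant with no DNA variant at its position."""

    chrom: str
    pos: int
    dna_base: str     # reference base
    rna_base: str     # RNA alternative
    edit_type: str
    dna_status: str = "absent_in_dna"

    @property
    def key(self) -> SiteKey:
        return (self.chrom, self.pos, self.dna_base, self.rna_base)


def compare_rdd(dna_records: Iterable[VcfRecord],
                rna_records: Iterable[VcfRecord],
                min_qual: float | None = None) -> list[RddCandidate]:
    """RDD candidates: RNA variants at positions with no DNA variant.

    ``min_qual`` optionally drops RNA records below a QUAL threshold before
    the comparison (off by default).
    """
    dna_positions = {(r.chrom, r.pos) for r in dna_records}
    candidates = []
    seen = set()
    for r in rna_records:
        if min_qual is not None and (r.qual is None or r.qual < min_qual):
            continue
        if (r.chrom, r.pos) in dna_positions:
            continue
        key = r.key
        if key in seen:
            continue
        seen.add(key)
        candidates.append(RddCandidate(
            chrom=r.chrom, pos=r.pos, dna_base=r.ref_base, rna_base=r.alt_base,
            edit_type=classify_edit_type(r.ref_base, r.alt_base, "+"),
        ))
    return sorted(candidates, key=lambda c: c.key)


@dataclass
class PairwiseSets:
    intersection: frozenset
    only_a: frozenset
    only_b: frozenset


@dataclass
class SampleComparison:
    sample_names: tuple
    sites: dict                 # sample -> frozenset of SiteKey
    unique_sites: dict          # sample -> sites found in no other sample
    pairwise: dict              # (a, b) -> PairwiseSets for a < b in input order


def compare_known_sites(samples: Mapping[str, Iterable[SiteKey]]) -> SampleComparison:
    """Pairwise intersections/differences of per-sample editing-site sets."""
    names = tuple(samples)
    if len(names) < 2:
        raise DataError(
            "known-site comparison needs at least two samples; "
            "use annotation mode for a single sample")
    sites = {n: frozenset(map(tuple, samples[n])) for n in names}
    unique = {
        n: frozenset(sites[n] - frozenset().union(*(sites[m] for m in names if m != n)))
        for n in names
    }
    pairwise = {
        (a, b): PairwiseSets(
            intersection=sites[a] & sites[b],
            only_a=sites[a] - sites[b],
            only_b=sites[b] - sites[a],
        )
        for a, b in combinations(names, 2)
    }
    return SampleComparison(sample_names=names, sites=sites,
                            unique_sites=unique, pairwise=pairwise)


def pairwise_count_matrix(comparison: SampleComparison) -> pd.DataFrame:
    """Square matrix of |A∩B| with per-sample totals on the diagonal."""
    names = comparison.sample_names
    mat = pd.DataFrame(0, index=list(names), columns=list(names), dtype=int)
    for n in names:
        mat.loc[n, n] = len(comparison.sites[n])
    for (a, b), pair in comparison.pairwise.items():
        mat.loc[a, b] = mat.loc[b, a] = len(pair.intersection)
    return mat
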