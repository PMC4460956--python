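"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: per-position enumeration, literal
lookup tables, linear scans. Nothing imports the modules under test beyond
plain data containers.
"""

FLANK = 1000
SPLICE = 2

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

# Standard nuclear genetic code, written out literally.
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def codon_substitution_status(ref_codon, pos_in_codon, alt_base):
    """Oracle: translate-and-compare with the literal code table."""
    alt_codon = ref_codon[:pos_in_codon] + alt_base + ref_codon[pos_in_codon + 1:]
    return ("synonymous" if GENETIC_CODE[ref_codon] == GENETIC_CODE[alt_codon]
            else "nonsynonymous")


def evidence_letter(n_resources, alu):
    """Oracle: the A-E lookup written as a literal table."""
    count = n_resources + (1 if alu else 0)
    table = {1: "E", 2: "D", 3: "C", 4: "B"}
    return table.get(count, "A") if count >= 1 else None


class TxSpec:
    """Plain transcript description for the brute-force feature classifier."""

    def __init__(self, strand, exons, cds, coding=None):
        self.strand = strand
        self.exons = list(exons)          # [(start, end)], genomic order
        self.cds = list(cds)              # [(start, end)], genomic order
        self.coding = bool(cds) if coding is None else coding


def _per_transcript_positions(tx):
    """Explicit position sets for one transcript (pure enumeration)."""
    exon = set()
    for s, e in tx.exons:
        exon |= set(range(s, e + 1))
    cds = set()
    for s, e in tx.cds:
        cds |= set(range(s, e + 1))
    splice = set()
    for i, (s, e) in enumerate(tx.exons):
        if i > 0:                                    # junction before this exon
            splice |= set(range(s - SPLICE, s + SPLICE))
        if i < len(tx.exons) - 1:                    # junction after this exon
            splice |= set(range(e - SPLICE + 1, e + SPLICE + 1))
    start, end = tx.exons[0][0], tx.exons[-1][1]
    span = set(range(start, end + 1))
    before = set(range(start - FLANK, start))
    after = set(range(end + 1, end + FLANK + 1))
    upstream = before if tx.strand == "+" else after
    downstream = after if tx.strand == "+" else before
    return exon, cds, splice, span, upstream, downstream


def brute_force_feature(pos, transcripts):
    """Literal-definition classifier over plain transcript specs."""
    labels = []
    for tx in transcripts:
        exon, cds, splice, span, upstream, downstream = _per_transcript_positions(tx)
        if pos in span:
            if pos in cds:
                labels.append("exonic")
            elif pos in splice:
                labels.append("splicing")
            elif pos in exon:
                if not tx.coding:
                    labels.append("ncRNA")
                else:
                    lo = min(s for s, _ in tx.cds)
                    hi = max(e for _, e in tx.cds)
                    if pos < lo:
                        labels.append("utr5" if tx.strand == "+" else "utr3")
                    elif pos > hi:
                        labels.append("utr3" if tx.strand == "+" else "utr5")
                    else:
                        labels.append("exonic")
            else:
                labels.append("intronic")
        elif pos in upstream:
            labels.append("upstream")
        elif pos in downstream:
            labels.append("downstream")
    if not labels:
        return "intergenic"
    order = ["exonic", "splicing", "ncRNA", "utr5", "utr3", "intronic",
             "upstream", "downstream", "intergenic"]
    rank = {"exonic": 0, "splicing": 0, "ncRNA": 1, "utr5": 2, "utr3": 3,
            "intronic": 4, "upstream": 5, "downstream": 5}
    return min(labels, key=lambda l: (rank[l], order.index(l)))
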