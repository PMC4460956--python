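# Methods

## Scope and data model

`rnaedit` operates at the level of called variants: VCF files in, CSV tables
out. It does not align reads, call variants, or estimate editing levels from
read counts; those belong to the upstream pipeline. All internal positions
are 1-based (VCF/GTF convention); BED and RepeatMasker inputs are converted
to 0-based half-open intervals at read time with a single overlap rule
(1-based position *p* overlaps [start, end) iff start < p ≤ end), and repeat
intervals are the one type kept half-open, behind an explicit
`contains_position` helper. Chromosome labels are normalised by a shared
policy flag (strip/add/keep a `chr` prefix; default strips, since Ensembl
GTFs and UCSC-style tracks disagree).

Only single-base substitutions are ingested: RNA editing is by definition a
single-nucleotide alteration, so indels, multi-base and symbolic alleles are
skipped with a logged warning, and multiallelic VCF lines are split into one
record per alternative allele because every comparison keys on a single
(chrom, pos, ref, alt) tuple. Genotype and depth fields are ignored; the
comparisons are site-level. An optional minimum-QUAL filter exists on the
RDD comparison and the annotate command and is off by default.

## Knowledgebase and evidence levels

Resource tables are merged on the exact key (chromosome, position, DNA base,
RNA base). Strand deliberately stays out of the key; it is set by majority
vote among the contributing records, `unknown` on ties. Conflicting
reference bases at the same position are different keys and are never
merged. Tissue sources and PubMed ids are order-preserving unions; to make
integration independent of input order, resources are always iterated in a
canonical order (registry order, then lexical), so the union order is a
function of the data, not of the call.

The evidence number of a site is the count of registered resources reporting
it, plus one if the site lies inside a repeat whose name starts with `Alu`.
Classes map 1→E, 2→D, 3→C, 4→B, ≥5→A; counts above five (all five resources
plus Alu) clamp to A because the scheme defines exactly five classes. Alu
context can never create a site: grading a site with no resource membership
is an error. The default registry is (DARNED, ENCODE, RADAR, BAHN, LI); it is
a frozen dataclass, so alternative resource sets — e.g. swapping ENCODE for a
different publication-derived list — are expressible without code changes.
Both the raw record count and the merged site count are exposed, since the
two are easy to conflate when comparing against published totals.

## Genomic-feature classification

Transcript models are assembled from GTF `exon` and `CDS` features only.
UTRs are always derived from the CDS genomic extent (exonic positions
outside it, 5' or 3' side strand-aware) rather than from optional UTR
features — one code path, robust across GTF dialects. A transcript is
non-coding iff it has no CDS segments; the biotype attribute is carried but
advisory. A per-chromosome interval tree over transcript spans extended by
the 1-kb flank serves point queries.

Per-transcript rules, applied in order:

1. **exonic** — position overlaps a CDS base (wins even at a junction);
2. **splicing** — within 2 bp of an internal exon/intron boundary, on either
   side of the junction edge (intron positions `e+1, e+2` and exon positions
   `e-1, e` for a junction after exon end `e`, mirrored at exon starts);
   transcript outer ends are not junctions;
3. **ncRNA** — exonic in a non-coding transcript;
4. **utr5/utr3** — exonic, coding transcript, outside the CDS extent;
5. **intronic** — inside the span, not exonic;
6. **upstream/downstream** — within 1,000 bp beyond the TSS/TES
   (strand-aware); exactly 1,000 bp away still counts, 1,001 bp does not;
7. **intergenic** — otherwise.

Across transcripts the primary feature is chosen by the precedence
`exonic = splicing > ncRNA > utr5 > utr3 > intronic > upstream = downstream >
intergenic`, the conventional genic-annotation hierarchy. Equal-rank ties
(exonic vs splicing from different transcripts, upstream vs downstream)
break toward the label listed first, making the result independent of
transcript iteration order. Gene/ENSG/ENST columns are comma-joined sorted
lists over the transcripts whose span (or, for pure flank hits, whose flank)
contains the site; ENSE is filled only when the site lies in an exon. The
ncRNA column is `yes` when any span-overlapping transcript is non-coding.
One row is emitted per site, not per site×transcript.

## Coding effect

For a site inside a CDS, the spliced CDS sequence is rebuilt from the
reference genome (segments concatenated in genomic order, reverse-
complemented for minus-strand transcripts), the codon containing the site is
located by CDS offset, the edited base (complemented on the minus strand) is
substituted, and both codons are translated with the standard nuclear code
via Biopython. Identical amino acids → synonymous; anything else, including
stop gain/loss, → nonsynonymous. Sites outside every CDS, and transcripts
whose summed CDS length is not divisible by 3, return `not_applicable`
(reported as an empty column). If the genome base disagrees with the VCF
reference base, the genome wins and the mismatch is logged. When several
coding transcripts cover a site, the reported effect is the first applicable
one in transcript-id order — deterministic, and in the synthetic fixtures
transcripts do not overlap so the choice is moot.

By default the annotator emits rows only for sites found in the
knowledgebase (known-site annotation mode); `--keep-novel` keeps the rest
with empty evidence columns. Evidence-dependent columns (level, strand,
source, PubMed, Alu, data reference) come from the knowledgebase; feature,
coding effect and ncRNA are computed live from the gene models and genome.

## Comparisons

RDD detection excludes an RNA variant if **any** DNA variant was called at
its position, regardless of allele: a heterozygous genomic variant explains
an RNA mismatch however it is written. (Requiring an explicit
homozygous-reference DNA genotype would need genotype fields, which the
site-level model deliberately avoids.) Candidates are de-duplicated by key
and sorted. Known-site comparison across ≥2 samples uses exact allele keys;
`unique` sites are those present in no other sample, and every unordered
pair gets intersection and both differences, which satisfy
|A∩B| + |A\B| = |A| by construction. A single sample is an error pointing
at annotation mode.

Edit types are the 12 ordered substitutions `X-to-Y`. Minus-strand sites are
complemented before labelling (a genomic T→C in a minus-strand gene is
A-to-G, the A-to-I signature); unknown strand is treated as plus.

## Summaries

`summarize_rows` counts each row exactly once along one of eight dimensions
(genomic feature, chromosome, edit type, evidence class, gene, synonymous
status, ncRNA flag, sample), so totals always equal the row count; empty
values are pooled under `unannotated`. Categories are ordered by count
descending then lexically; the gene dimension is capped at the top 30 plus
an `other` bucket for plot readability. CSVs are the quantitative surface —
the bar-plot PNGs are rendered from the freshly written CSVs, never from
live state, so all quantitative tests target the CSVs.

## Synthetic fixtures

The generator is a pure function of an integer seed (NumPy `default_rng`
throughout; no global random state), so outputs are byte-identical per seed.

* **Locus**: by default six transcripts of 1–4 exons (exons 90–400 bp,
  introns 60–300 bp) on random strands, separated by 1.2–2.6 kb so 1-kb
  flanks and intergenic gaps are distinguishable, on a ~20–30 kb chromosome —
  enough structure to realise every feature class while keeping exhaustive
  position sweeps fast. 70% of transcripts are coding; their CDS starts with
  ATG, ends with a stop, contains no internal stop, and has length divisible
  by 3 (the stop codon is kept inside the CDS features; the annotator only
  requires divisibility by 3).
* **Resources**: each requested site is written into exactly the resources
  its target evidence class requires, using one canonical composition per
  class (A: DARNED+ENCODE+BAHN+RADAR+Alu; B: DARNED+RADAR+BAHN+Alu;
  C: DARNED+BAHN+RADAR; D: DARNED+RADAR; E: DARNED). Alu-flagged sites get a
  ~300-bp `Alu*` interval over them; non-Alu decoy repeats exercise the name
  filter. Sites are spaced >400 bp apart so a repeat never covers a
  neighbour. Inconsistent requests (a class letter contradicting an explicit
  membership list) are rejected.
* **Paired VCFs**: the DNA VCF holds germline variants; the RNA VCF holds the
  same germline variants plus planted RDD sites at disjoint positions, so
  the expected RDD output is exactly the planted set. Novel RDD sites are
  biased 70% toward A→G/T→C to echo A-to-I predominance (configurable). The
  manifest records each planted site's expected edit type, genomic feature
  and coding effect, computed by per-position enumeration and direct
  spliced-sequence translation — an independent path from the annotator's
  interval arithmetic.

What the fixtures do **not** emulate: sequencing error, coverage and allele
fraction, germline polymorphism density, overlapping genes, alternative
transcripts per gene, and real resource-export schemas (a single documented
TSV schema stands for all resources; adapters for real exports are an
extension point). Passing tests therefore demonstrate correctness of the
integration, grading, classification and comparison logic under clean
inputs, not robustness to noisy variant calls.

## Numerical and degenerate-input choices

* Evidence counts clamp at 5; grading an Alu-only or membership-less site
  raises.
* Strand votes tie → `unknown`; unknown strand prints as `.` and is treated
  as plus for edit-type labelling.
* Among overlapping Alu repeats the lowest (start, name) pair is reported.
* Header-only inputs yield empty collections, not errors; malformed rows
  either raise a format error (GTF column counts, start>end, bad BED) or are
  skipped with a logged warning (non-SNV VCF alleles, resource rows with
  identical bases), per the rule that readers never drop rows silently.
* Annotation CSVs always carry the fixed 17-column header, even when empty.

## Testing strategy

Every non-trivial operation is checked against an independent oracle built
the naive way: the evidence scheme against a literal lookup over all 62
membership/Alu combinations; the feature classifier against a per-position
enumeration classifier at every base of a multi-transcript locus; the codon
logic against a hard-coded genetic-code table over all 576 codon-position-
substitution cases, plus a plus/minus-strand mirror construction; the RDD
comparison against planted ground truth across 100 seeds; set identities by
brute-force set algebra (hypothesis-driven, derandomised). Whole-pipeline
determinism is asserted byte-for-byte on the CSV outputs.
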