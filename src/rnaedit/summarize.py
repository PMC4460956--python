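"""Executive-summary tables and bar plots over annotated rows.

Each summary counts every row exactly once along one dimension (genomic
feature, chromosome, edit type, evidence class, gene, synonymous status,
ncRNA flag, or sample), so counts always sum to the number of rows. CSVs
are the quantitative surface; the bar-plot images are rendered from the
CSVs and are presentation only.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .annotator import AnnotatedRow
from .comparator import classify_edit_type

DIMENSIONS = ("genomic_feature", "chromosome", "edit_type", "evidence_class",
              "gene", "syn_nonsyn", "ncrna", "sample")

#: Rows with an empty value along a dimension are counted under this label.
UNANNOTATED = "unannotated"

GENE_CAP = 30  # gene tables keep the top 30 categories plus "other"


@dataclass
class SummaryTable:
    dimension: str
    counts: list  # [(category, count), ...] counts descending, then lexical

    @property
    def total(self) -> int:
        return sum(c for _, c in self.counts)


def _category(row: AnnotatedRow, dimension: str) -> str:
    if dimension == "genomic_feature":
        value = row.genomic_feature
    elif dimension == "chromosome":
        value = row.chrom
    elif dimension == "edit_type":
        strand = row.strand if row.strand in ("+", "-") else "+"
        value = classify_edit_type(row.in_dna, row.in_rna, strand)
    elif dimension == "evidence_class":
        value = row.evidence_level
    elif dimension == "gene":
        value = row.gene
    elif dimension == "syn_nonsyn":
        value = row.syn_nonsyn
    elif dimension == "ncrna":
        value = row.noncoding_rna
    elif dimension == "sample":
        value = row.sample
    else:
        raise ValueError(f"unknown dimension {dimension!r}; valid: {DIMENSIONS}")
    return value or UNANNOTATED


def summarize_rows(rows: Iterable[AnnotatedRow], dimension: str,
                   gene_cap: int = GENE_CAP) -> SummaryTable:
    """Count rows along one dimension (zero-count categories omitted)."""
    if dimension not in DIMENSIONS:
        raise ValueError(f"unknown dimension {dimension!r}; valid: {DIMENSIONS}")
    counter = Counter(_category(r, dimension) for r in rows)
    ordered = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    if dimension == "gene" and len(ordered) > gene_cap:
        head, tail = ordered[:gene_cap], ordered[gene_cap:]
        ordered = head + [("other", sum(c for _, c in tail))]
    return SummaryTable(dimension=dimension, counts=ordered)


def write_summary_csv(table: SummaryTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("category,count\n")
        for cat, count in table.counts:
            fh.write(f"{cat},{count}\n")


def read_summary_csv(path) -> SummaryTable:
    df = pd.read_csv(path, dtype={"category": str, "count": int})
    dimension = Path(path).stem.replace("_summary", "")
    return SummaryTable(dimension=dimension,
                        counts=list(df.itertuples(index=False, name=None)))


def render_summary(tables: Sequence[SummaryTable], out_dir) -> list[Path]:
    """Write one ``<dimension>_summary.csv`` and one ``.png`` per table.

    The plot is drawn from the freshly written CSV, never from live state.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for table in tables:
        csv_path = out_dir / f"{table.dimension}_summary.csv"
        write_summary_csv(table, csv_path)
        written.append(csv_path)

        plotted = read_summary_csv(csv_path)
        fig, ax = plt.subplots(figsize=(max(4, 0.5 * len(plotted.counts)), 3.5))
        cats = [c for c, _ in plotted.counts]
        vals = [v for _, v in plotted.counts]
        ax.bar(range(len(cats)), vals, color="#4477aa")
        ax.set_xticks(range(len(cats)))
        ax.set_xticklabels(cats, rotation=60, ha="right", fontsize=7)
        ax.set_ylabel("sites")
        ax.set_title(f"RNA editing sites by {table.dimension.replace('_', ' ')}")
        fig.tight_layout()
        png_path = out_dir / f"{table.dimension}_summary.png"
        fig.savefig(png_path, dpi=100)
        plt.close(fig)
        written.append(png_path)
    return written
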