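"""Grouping circles by host-gene and classifying isoform relationships.

One gene can give rise to many circles. Pairs of circles from the same
host-gene are classified by the relationship of their boundaries:
``same_start``, ``same_end``, ``within`` (one strictly inside the
other), ``overlapping``, or ``non_overlapping`` (disjoint). The last
category is an addition for exhaustiveness — disjoint circles of one
gene do occur and would otherwise be unclassifiable; it is reported
separately so four-category totals stay comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .core import ExonAnnotation, GenomicInterval
from .io import CircleTable

__all__ = [
    "CATEGORIES",
    "HostGeneSummary",
    "assign_host_genes",
    "classify_circle_pair",
    "summarize_host_genes",
    "write_hostgene_outputs",
]

CATEGORIES = ("same_start", "same_end", "within", "overlapping", "non_overlapping")


def assign_host_genes(circles: CircleTable, annotation: ExonAnnotation) -> CircleTable:
    """Fill ``host_genes`` in place: a gene hosts a circle when at least
    one of its exons overlaps the circle interval. A circle may have 0,
    1 or several host-genes; multi-host circles contribute to each
    gene's summary independently."""
    for circle in circles:
        circle.host_genes = annotation.genes_overlapping(circle.interval)
    return circles


def classify_circle_pair(a: GenomicInterval, b: GenomicInterval) -> str:
    """Classify the relationship between two distinct circles of one gene.

    Precedence: same_start > same_end > within > overlapping >
    non_overlapping; containment that shares a boundary is reported by
    the shared boundary. Symmetric in its arguments; identical
    intervals are rejected (they would be one circle).
    """
    if a.chrom != b.chrom:
        raise ValueError("circle pair on different chromosomes")
    if (a.start, a.end) == (b.start, b.end):
        raise ValueError("identical circles are not a pair")
    if a.start == b.start:
        return "same_start"
    if a.end == b.end:
        return "same_end"
    if (a.start < b.start and b.end < a.end) or (b.start < a.start and a.end < b.end):
        return "within"
    if a.start < b.end and b.start < a.end:
        return "overlapping"
    return "non_overlapping"


@dataclass
class HostGeneSummary:
    gene_id: str
    n_circles: int
    categories: dict[str, int] = field(default_factory=lambda: {c: 0 for c in CATEGORIES})

    @property
    def is_single(self) -> bool:
        return self.n_circles == 1


def summarize_host_genes(circles: CircleTable) -> list[HostGeneSummary]:
    """Per-gene circle counts and pairwise relationship tallies.

    Requires host genes assigned. For a gene with n circles all
    n*(n-1)/2 pairs are classified, so category counts sum to that
    number; a single-circle gene has all counts zero.
    """
    by_gene: dict[str, list] = {}
    for circle in circles:
        for gene in circle.host_genes:
            by_gene.setdefault(gene, []).append(circle)

    summaries = []
    for gene in sorted(by_gene):
        members = by_gene[gene]
        s = HostGeneSummary(gene_id=gene, n_circles=len(members))
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                cat = classify_circle_pair(members[i].interval, members[j].interval)
                s.categories[cat] += 1
        summaries.append(s)
    return summaries


def write_hostgene_outputs(
    summaries: list[HostGeneSummary], prefix: str | Path
) -> tuple[Path, Path]:
    """Write ``<prefix>.hostgene_isoforms.txt`` and the single/multi
    proportion table ``<prefix>.hostgene_summary.txt``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    per_gene = prefix.parent / (prefix.name + ".hostgene_isoforms.txt")
    global_path = prefix.parent / (prefix.name + ".hostgene_summary.txt")

    rows = [
        {"gene_id": s.gene_id, "n_circles": s.n_circles, "is_single": str(s.is_single).lower(),
         **{c: s.categories[c] for c in CATEGORIES}}
        for s in summaries
    ]
    pd.DataFrame(rows, columns=["gene_id", "n_circles", "is_single", *CATEGORIES]).to_csv(
        per_gene, sep="\t", index=False
    )

    n_genes = len(summaries)
    n_multi = sum(1 for s in summaries if not s.is_single)
    pd.DataFrame(
        [
            {
                "n_host_genes": n_genes,
                "n_single": n_genes - n_multi,
                "n_multi": n_multi,
                "proportion_single": f"{(n_genes - n_multi) / n_genes:.4f}" if n_genes else "",
                "proportion_multi": f"{n_multi / n_genes:.4f}" if n_genes else "",
            }
        ]
    ).to_csv(global_path, sep="\t", index=False)
    return per_gene, global_path
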