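"""Alternative splicing within the same circle boundaries.

Two circular isoforms can share one back-splice junction and differ only
in an internal exon. Detection tools that look only at the junction
cannot see this; here the linear splice gaps of the circle's own reads
are collected, gaps that fully contain an annotated exon mark that exon
as skipped, and every read is then assigned to the inclusion or skipping
isoform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from .core import Circle, Exon, ExonAnnotation, GenomicInterval, IntronCall
from .extract import CircleReadSet

logger = logging.getLogger(__name__)

__all__ = [
    "SkippedExonCall",
    "infer_introns",
    "detect_skipped_exons",
    "assign_isoform_support",
    "write_skip_outputs",
]


@dataclass
class SkippedExonCall:
    """One skipped-exon event within a circle, with isoform support.

    ``n_total`` counts all distinct reads of the circle; reads that
    neither skip the exon nor align across its body (e.g. short
    junction-only fragments) are counted as ``n_uninformative``.
    """

    circle_id: str
    circle_interval: GenomicInterval
    exon: Exon
    intron: GenomicInterval
    skipping_reads: set[str]
    n_skip: int
    n_total: int
    n_uninformative: int = 0

    @property
    def proportion_skipping(self) -> float:
        return self.n_skip / self.n_total

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError("skipped-exon call with no reads")
        if self.n_skip != len(self.skipping_reads) or self.n_skip > self.n_total:
            raise ValueError("inconsistent skip counts")
        if not self.intron.contains(self.exon.interval):
            raise ValueError("skipped exon not contained in its intron")


def infer_introns(read_set: CircleReadSet) -> list[IntronCall]:
    """Collect the linear splicing events of one circle's reads.

    Every inter-segment gap of every alignment becomes an intron
    interval; identical intervals are merged and their supporting read
    names unioned. Gaps that cross the circle boundary are dropped with
    a warning — a splice out of the circle contradicts the back-splice.
    """
    boundary = read_set.circle.interval
    support: dict[tuple[int, int], set[str]] = {}
    for aln in read_set.alignments:
        for gap in aln.gaps():
            if gap.start < boundary.start or gap.end > boundary.end:
                logger.warning(
                    "circle %s: read %s has a gap [%d,%d) outside the circle; dropped",
                    read_set.circle.circle_id, aln.read_name, gap.start, gap.end,
                )
                continue
            support.setdefault((gap.start, gap.end), set()).add(aln.read_name)
    return [
        IntronCall(
            interval=GenomicInterval(boundary.chrom, s, e),
            supporting_reads=names,
        )
        for (s, e), names in sorted(support.items())
    ]


def detect_skipped_exons(
    introns: list[IntronCall],
    annotation: ExonAnnotation,
    circle: Circle,
) -> list[tuple[IntronCall, Exon]]:
    """Intersect intron intervals with annotated exons.

    A skipped-exon candidate is an annotated exon *fully contained* in
    an observed intron: a gap that merely abuts or partially overlaps an
    exon is ambiguous alignment, not skipping.
    """
    candidates: list[tuple[IntronCall, Exon]] = []
    for intron in introns:
        for exon in annotation.contained_in(intron.interval):
            candidates.append((intron, exon))
    return candidates


def assign_isoform_support(
    read_set: CircleReadSet,
    candidate: tuple[IntronCall, Exon],
) -> SkippedExonCall:
    """Assign each read of the circle to the skipping or inclusion isoform.

    A read skips the exon when any of its alignments carries a gap fully
    containing the exon. A read supports inclusion when a segment
    overlaps the exon body. Reads doing neither are uninformative but
    still count toward ``n_total``.
    """
    intron, exon = candidate
    names = read_set.read_names
    if not names:
        raise ValueError(f"circle {read_set.circle.circle_id}: empty read set")

    skipping: set[str] = set()
    covering: set[str] = set()
    for aln in read_set.alignments:
        for gap in aln.gaps():
            if gap.contains(exon.interval):
                skipping.add(aln.read_name)
        for seg in aln.segments:
            if seg.overlaps(exon.interval):
                covering.add(aln.read_name)
    uninformative = names - skipping - covering
    return SkippedExonCall(
        circle_id=read_set.circle.circle_id,
        circle_interval=read_set.circle.interval,
        exon=exon,
        intron=intron.interval,
        skipping_reads=skipping,
        n_skip=len(skipping),
        n_total=len(names),
        n_uninformative=len(uninformative),
    )


_TXT_HEADER = (
    "circle_id\tchrom\texon_start\texon_end\tgene_id\texon_number\t"
    "intron_start\tintron_end\tskipping_reads\tn_skip\tn_total\tn_uninformative\n"
)


def write_skip_outputs(
    calls: list[SkippedExonCall], prefix: str | Path
) -> tuple[Path, Path]:
    """Write ``<prefix>.skipped_exons.bed`` and ``<prefix>.skipped_exons.txt``.

    The BED12 file encodes, per call, the circle as the thick interval
    with blocks at the intron boundaries and at the skipped exon
    (positions relative to the circle start), score = round(100 x
    proportion skipping); it loads into any genome browser. The TSV
    carries exact genomic coordinates, the skipping read names and the
    absolute counts.
    """
    prefix = Path(prefix)
    bed_path = prefix.parent / (prefix.name + ".skipped_exons.bed")
    txt_path = prefix.parent / (prefix.name + ".skipped_exons.txt")
    prefix.parent.mkdir(parents=True, exist_ok=True)

    with open(bed_path, "w") as bed:
        for call in calls:
            c = call.circle_interval
            score = round(100 * call.proportion_skipping)
            # blocks: intron flanks inside the circle + the skipped exon
            block_ivs = sorted(
                {
                    (c.start, call.intron.start),
                    (call.exon.interval.start, call.exon.interval.end),
                    (call.intron.end, c.end),
                }
            )
            block_ivs = [(s, e) for s, e in block_ivs if e > s]
            sizes = ",".join(str(e - s) for s, e in block_ivs)
            starts = ",".join(str(s - c.start) for s, e in block_ivs)
            name = f"{call.circle_id}|skip_exon{call.exon.exon_number}"
            bed.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{name}\t{score}\t"
                f"{c.strand if c.strand != '.' else '+'}\t{c.start}\t{c.end}\t0\t"
                f"{len(block_ivs)}\t{sizes}\t{starts}\n"
            )
    with open(txt_path, "w") as txt:
        txt.write(_TXT_HEADER)
        for call in calls:
            e = call.exon
            txt.write(
                "\t".join(
                    [
                        call.circle_id,
                        e.interval.chrom,
                        str(e.interval.start),
                        str(e.interval.end),
                        e.gene_id,
                        str(e.exon_number),
                        str(call.intron.start),
                        str(call.intron.end),
                        ",".join(sorted(call.skipping_reads)),
                        str(call.n_skip),
                        str(call.n_total),
                        str(call.n_uninformative),
                    ]
                )
                + "\n"
            )
    return bed_path, txt_path
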