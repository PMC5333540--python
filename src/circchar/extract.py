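"""Split the global alignment file into per-circle alignment files.

A mixed SAM/BAM of chimeric (and possibly linear/unmapped) reads is hard
to inspect: when several circles or a linear transcript overlap, it is
unclear which reads belong to which circle. This stage writes one
coordinate-sorted, indexed BAM per circle containing exactly the records
whose read name is on the circle's supporting-read list AND whose
aligned span overlaps the circle interval — the positional filter is
what removes same-named multimappers aligned elsewhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import pysam

from .core import ChimericAlignment, Circle, GenomicInterval, circle_id_to_filename, cigar_to_segments
from .io import CircleTable

logger = logging.getLogger(__name__)

__all__ = ["CircleReadSet", "alignment_from_record", "extract_circle_reads"]


@dataclass
class CircleReadSet:
    """All alignment records assigned to one circle."""

    circle: Circle
    alignments: list[ChimericAlignment] = field(default_factory=list)
    file_path: Path | None = None

    @property
    def read_names(self) -> set[str]:
        return {a.read_name for a in self.alignments}

    @property
    def n_reads(self) -> int:
        return len(self.read_names)


def alignment_from_record(
    rec: pysam.AlignedSegment, min_deletion_gap: int = 30
) -> ChimericAlignment:
    """Convert a mapped SAM record into a :class:`ChimericAlignment`."""
    if rec.is_unmapped:
        raise ValueError(f"unmapped record {rec.query_name}")
    mate = 1 if rec.is_read1 else 2 if rec.is_read2 else 0
    strand = "-" if rec.is_reverse else "+"
    segments = cigar_to_segments(
        rec.reference_start,
        rec.cigarstring,
        chrom=rec.reference_name,
        strand=strand,
        min_deletion_gap=min_deletion_gap,
    )
    return ChimericAlignment(
        read_name=rec.query_name,
        mate=mate,
        segments=segments,
        is_supplementary=rec.is_supplementary,
    )


def _record_overlaps(rec: pysam.AlignedSegment, iv: GenomicInterval) -> bool:
    return (
        rec.reference_name == iv.chrom
        and rec.reference_start < iv.end
        and rec.reference_end is not None
        and rec.reference_end > iv.start
    )


def extract_circle_reads(
    alignment_path: str | Path,
    circles: CircleTable,
    out_dir: str | Path,
    sample: str = "sample",
    keep_secondary: bool = False,
    min_deletion_gap: int = 30,
) -> tuple[list[CircleReadSet], pd.DataFrame]:
    """Write one sorted, indexed BAM per circle and return the read sets.

    A record is assigned to a circle when its read name is in the
    circle's read-name list and its aligned span overlaps the circle
    interval. Unmapped records are always excluded; secondary records
    are excluded unless ``keep_secondary``. Supplementary records are
    kept — they carry the second arm of a chimeric alignment.

    Returns the per-circle read sets plus a summary table with columns
    ``circle_id``, ``n_records``, ``n_distinct_reads``, ``path``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not len(circles):
        raise ValueError("no circles to extract")

    name_to_circles: dict[str, list[Circle]] = {}
    for c in circles:
        for n in c.read_names:
            name_to_circles.setdefault(n, []).append(c)

    mode = "rb" if str(alignment_path).endswith(".bam") else "r"
    buckets: dict[str, list[pysam.AlignedSegment]] = {c.circle_id: [] for c in circles}
    with pysam.AlignmentFile(str(alignment_path), mode) as fh:
        header = fh.header.to_dict()
        for rec in fh.fetch(until_eof=True):
            if rec.is_unmapped:
                continue
            if rec.is_secondary and not keep_secondary:
                continue
            for circle in name_to_circles.get(rec.query_name, ()):
                if _record_overlaps(rec, circle.interval):
                    buckets[circle.circle_id].append(rec)

    read_sets: list[CircleReadSet] = []
    rows = []
    for circle in circles:
        recs = buckets[circle.circle_id]
        stem = f"{sample}_{circle_id_to_filename(circle.circle_id)}"
        bam_path = out_dir / f"{stem}.bam"
        unsorted = out_dir / f"{stem}.unsorted.bam"
        with pysam.AlignmentFile(str(unsorted), "wb", header=header) as out:
            for rec in recs:
                out.write(rec)
        pysam.sort("-o", str(bam_path), str(unsorted))
        unsorted.unlink()
        pysam.index(str(bam_path))
        if not recs:
            logger.warning("circle %s: no surviving alignment records", circle.circle_id)

        alignments = sorted(
            (alignment_from_record(r, min_deletion_gap) for r in recs),
            key=lambda a: a.start,
        )
        rs = CircleReadSet(circle=circle, alignments=alignments, file_path=bam_path)
        read_sets.append(rs)
        rows.append(
            {
                "circle_id": circle.circle_id,
                "n_records": len(recs),
                "n_distinct_reads": rs.n_reads,
                "path": str(bam_path),
            }
        )
    summary = pd.DataFrame(rows, columns=["circle_id", "n_records", "n_distinct_reads", "path"])
    return read_sets, summary
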