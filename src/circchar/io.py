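"""Readers for the three pipeline inputs.

Accepted formats:

* a two-column tab-separated circle table (circle id, comma-separated
  read names),
* the count table + STAR-style chimeric junction files written by
  back-splice detection (``CircRNACount`` plus one or more
  ``Chimeric.out.junction`` files, optionally the per-mate variants),
* a BED6 or BED12 exon annotation.

All 1-based sources are converted to 0-based half-open coordinates here,
at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .core import (
    Circle,
    Exon,
    ExonAnnotation,
    GenomicInterval,
    make_circle_id,
    parse_circle_id,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CircleTable",
    "JunctionRecord",
    "read_circle_table",
    "write_circle_table",
    "read_dcc_outputs",
    "read_junction_file",
    "read_exon_annotation",
]


@dataclass
class CircleTable:
    """The set of circRNA candidates for one sample."""

    circles: list[Circle]
    source: str = "custom_table"  # "custom_table" | "dcc"
    #: circles retained despite having no matched junction reads
    unsupported_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        ids = [c.circle_id for c in self.circles]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate circle ids in table")

    def __len__(self) -> int:
        return len(self.circles)

    def __iter__(self):
        return iter(self.circles)

    def by_id(self, circle_id: str) -> Circle:
        for c in self.circles:
            if c.circle_id == circle_id:
                return c
        raise KeyError(circle_id)


def read_circle_table(path: str | Path) -> CircleTable:
    """Parse the custom two-column circle table.

    Column 1 is the circle id (``chrom:start|end``), column 2 a
    comma-separated list of the names of reads spanning the back-splice
    junction. Duplicate read names within a line are deduplicated.
    """
    circles: list[Circle] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
                )
            try:
                chrom, start, end = parse_circle_id(parts[0])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            names = {n.strip() for n in parts[1].split(",") if n.strip()}
            if not names:
                raise ValueError(f"{path}:{lineno}: circle with no read names")
            circles.append(Circle.from_coords(chrom, start, end, names))
    return CircleTable(circles=circles, source="custom_table")


def write_circle_table(table: CircleTable, path: str | Path) -> Path:
    """Write a circle table in the two-column custom format (round-trips)."""
    path = Path(path)
    with open(path, "w") as fh:
        for c in table.circles:
            fh.write(f"{c.circle_id}\t{','.join(sorted(c.read_names))}\n")
    return path


@dataclass(frozen=True)
class JunctionRecord:
    """One line of a STAR-style chimeric junction file (0-based coords)."""

    donor_chrom: str
    donor_pos: int  # 0-based position of the junction on the donor side
    acceptor_chrom: str
    acceptor_pos: int
    read_name: str
    mate: int  # 1/2 when the file is mate-specific, else 0


def read_junction_file(path: str | Path, mate: int = 0) -> list[JunctionRecord]:
    """Parse a STAR-layout chimeric junction file.

    Columns: donor chrom, donor break (1-based), donor strand, acceptor
    chrom, acceptor break (1-based), acceptor strand, junction type,
    repeat lengths (2), read name, segment start + CIGAR (x2). ``mate``
    tags every record when the file is one of the per-mate junction
    files.
    """
    records: list[JunctionRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 10:
                raise ValueError(
                    f"{path}:{lineno}: junction line has {len(parts)} columns, expected >= 10"
                )
            records.append(
                JunctionRecord(
                    donor_chrom=parts[0],
                    donor_pos=int(parts[1]) - 1,
                    acceptor_chrom=parts[3],
                    acceptor_pos=int(parts[4]) - 1,
                    read_name=parts[9],
                    mate=mate,
                )
            )
    return records


def read_dcc_outputs(
    circrnacount_path: str | Path,
    chimeric_junction_paths: Sequence[str | Path],
    junction_mates: Sequence[int] | None = None,
    tolerance: int = 1,
) -> CircleTable:
    """Build a circle table from a back-splice count table plus junction files.

    Each row of the count table (chrom, start, end in the leading columns)
    becomes a circle; its read names are the read names of junction
    entries whose donor/acceptor coordinates match the circle boundaries
    within ``tolerance`` bases (after 1-based to 0-based conversion; the
    default +/-1 absorbs either off-by-one convention of the upstream
    caller). A back-splice junction has its donor at the circle's 3' end
    and its acceptor at the 5' start, so donor is matched against ``end``
    and acceptor against ``start``; the flipped orientation is accepted
    too. Circles with no matched read are kept but flagged in
    ``unsupported_ids``. A read matching several circles is assigned to
    all of them and logged.

    ``junction_mates`` optionally gives, per junction file, which mate it
    describes (0 = unknown/both); used downstream by fragment
    classification.
    """
    if not chimeric_junction_paths:
        raise ValueError("at least one chimeric junction file is required")
    if junction_mates is None:
        junction_mates = [0] * len(chimeric_junction_paths)
    if len(junction_mates) != len(chimeric_junction_paths):
        raise ValueError("junction_mates must parallel chimeric_junction_paths")

    junctions: list[JunctionRecord] = []
    for p, m in zip(chimeric_junction_paths, junction_mates):
        junctions.extend(read_junction_file(p, mate=m))
    if not junctions:
        raise ValueError("junction files contain no entries")

    circles: list[Circle] = []
    unsupported: set[str] = set()
    read_to_circles: dict[str, set[str]] = {}
    with open(circrnacount_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{circrnacount_path}:{lineno}: expected >= 3 columns"
                )
            if lineno == 1 and not parts[1].isdigit():
                continue  # header row
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            names: set[str] = set()
            for j in junctions:
                if j.donor_chrom != chrom or j.acceptor_chrom != chrom:
                    continue
                fwd = (
                    abs(j.donor_pos + 1 - end) <= tolerance
                    and abs(j.acceptor_pos - start) <= tolerance
                )
                rev = (
                    abs(j.acceptor_pos + 1 - end) <= tolerance
                    and abs(j.donor_pos - start) <= tolerance
                )
                if fwd or rev:
                    names.add(j.read_name)
            circle = Circle.from_coords(chrom, start, end, names)
            if not names:
                unsupported.add(circle.circle_id)
                logger.warning("circle %s has no matching junction reads", circle.circle_id)
            for n in names:
                read_to_circles.setdefault(n, set()).add(circle.circle_id)
            circles.append(circle)

    for name, ids in read_to_circles.items():
        if len(ids) > 1:
            logger.warning(
                "read %s matches %d circles (%s); kept in all",
                name, len(ids), ",".join(sorted(ids)),
            )
    return CircleTable(circles=circles, source="dcc", unsupported_ids=unsupported)


def _bed12_exons(parts: list[str], lineno: int, path: str | Path) -> list[tuple[GenomicInterval, str]]:
    chrom, start = parts[0], int(parts[1])
    strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "."
    name = parts[3] if len(parts) > 3 else f"feature_{lineno}"
    n_blocks = int(parts[9])
    sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
    starts = [int(x) for x in parts[11].rstrip(",").split(",")]
    if len(sizes) != n_blocks or len(starts) != n_blocks:
        raise ValueError(f"{path}:{lineno}: blockCount does not match block lists")
    return [
        (GenomicInterval(chrom, start + off, start + off + size, strand), name)
        for off, size in zip(starts, sizes)
    ]


def read_exon_annotation(path: str | Path) -> ExonAnnotation:
    """Read a BED6/BED12 exon annotation.

    BED12 blocks are expanded to exons. The BED name field is the gene
    id; BED6 lines sharing a name are grouped under one gene. Exon
    numbers are assigned per gene along the direction of transcription
    (genomic order, reversed for minus-strand genes).
    """
    raw: list[tuple[GenomicInterval, str]] = []
    with open(path) as fh:
        for lineno, line_raw in enumerate(fh, start=1):
            line = line_raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            try:
                if len(parts) >= 12:
                    raw.extend(_bed12_exons(parts, lineno, path))
                elif len(parts) >= 3:
                    chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                    name = parts[3] if len(parts) > 3 else f"feature_{lineno}"
                    strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "."
                    raw.append((GenomicInterval(chrom, start, end, strand), name))
                else:
                    raise ValueError("fewer than 3 columns")
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED line ({exc})") from exc

    by_gene: dict[str, list[GenomicInterval]] = {}
    for iv, gene in raw:
        by_gene.setdefault(gene, []).append(iv)

    exons: list[Exon] = []
    for gene, ivs in by_gene.items():
        ivs = sorted(ivs, key=lambda i: (i.chrom, i.start))
        minus = all(i.strand == "-" for i in ivs) and bool(ivs)
        n = len(ivs)
        for idx, iv in enumerate(ivs):
            number = n - idx if minus else idx + 1
            exons.append(Exon(interval=iv, gene_id=gene, exon_number=number))
    return ExonAnnotation(exons=exons)
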