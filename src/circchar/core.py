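"""Shared domain types and coordinate conventions.

Every stage of the pipeline speaks in the types defined here. All
coordinates are 0-based, half-open ([start, end)), everywhere: BED input
and output already uses this convention, and 1-based sources (SAM POS,
STAR chimeric-junction columns) are converted at the reader boundary.
A single convention removes off-by-one drift between stages.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "GenomicInterval",
    "Circle",
    "ChimericAlignment",
    "Exon",
    "ExonAnnotation",
    "IntronCall",
    "make_circle_id",
    "parse_circle_id",
    "circle_id_to_filename",
    "cigar_to_segments",
]

# Strand is carried through but never used for matching reads to circles;
# chimeric alignment strands are unreliable at the back-splice.
STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty/inverted interval: [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        """True if *other* lies fully within this interval (same chromosome)."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


def make_circle_id(chrom: str, start: int, end: int) -> str:
    """Canonical circle identifier ``chrom:start|end``.

    Deterministic and injective on valid (chrom, start, end) triples;
    becomes a safe filename after substituting ``:`` and ``|``.
    """
    if end <= start or start < 0:
        raise ValueError(f"invalid circle interval [{start}, {end})")
    return f"{chrom}:{start}|{end}"


_CIRCLE_ID_RE = re.compile(r"^(?P<chrom>.+):(?P<start>\d+)\|(?P<end>\d+)$")
# Tolerated alternative separators seen in the wild (chr:start-end, chr_start_end).
_CIRCLE_ID_ALT_RE = re.compile(r"^(?P<chrom>.+?)[:_](?P<start>\d+)[|_-](?P<end>\d+)$")


def parse_circle_id(circle_id: str) -> tuple[str, int, int]:
    """Parse a circle identifier back into (chrom, start, end)."""
    m = _CIRCLE_ID_RE.match(circle_id) or _CIRCLE_ID_ALT_RE.match(circle_id)
    if m is None:
        raise ValueError(f"unparsable circle id: {circle_id!r}")
    start, end = int(m["start"]), int(m["end"])
    if end <= start:
        raise ValueError(f"inverted circle id: {circle_id!r}")
    return m["chrom"], start, end


def circle_id_to_filename(circle_id: str) -> str:
    """Filesystem-safe version of a circle id (``:`` and ``|`` become ``_``)."""
    return circle_id.replace(":", "_").replace("|", "_")


@dataclass
class Circle:
    """A circRNA candidate: back-splice boundaries plus supporting read names."""

    circle_id: str
    interval: GenomicInterval
    read_names: set[str] = field(default_factory=set)
    host_genes: set[str] = field(default_factory=set)

    @classmethod
    def from_coords(
        cls, chrom: str, start: int, end: int, read_names: Iterable[str] = ()
    ) -> "Circle":
        return cls(
            circle_id=make_circle_id(chrom, start, end),
            interval=GenomicInterval(chrom, start, end),
            read_names=set(read_names),
        )


@dataclass
class ChimericAlignment:
    """The aligned blocks of one mate of one read.

    ``segments`` are the reference blocks after splitting the CIGAR on
    skip operations; gaps between consecutive segments are candidate
    introns. ``mate`` is 1, 2 or 0 (unpaired).
    """

    read_name: str
    mate: int
    segments: list[GenomicInterval]
    spans_backsplice: bool = False
    is_supplementary: bool = False

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("alignment with no segments")
        chroms = {s.chrom for s in self.segments}
        if len(chroms) != 1:
            raise ValueError("segments of one alignment span chromosomes")
        starts = [s.start for s in self.segments]
        if starts != sorted(starts):
            raise ValueError("segments not sorted by start")
        for a, b in zip(self.segments, self.segments[1:]):
            if b.start < a.end:
                raise ValueError("overlapping segments within one alignment")

    @property
    def chrom(self) -> str:
        return self.segments[0].chrom

    @property
    def start(self) -> int:
        return self.segments[0].start

    @property
    def end(self) -> int:
        return self.segments[-1].end

    def gaps(self) -> list[GenomicInterval]:
        """Inter-segment gaps (candidate introns) of this alignment."""
        out = []
        for a, b in zip(self.segments, self.segments[1:]):
            out.append(GenomicInterval(a.chrom, a.end, b.start, a.strand))
        return out


@dataclass(frozen=True)
class Exon:
    interval: GenomicInterval
    gene_id: str
    exon_number: int


@dataclass
class ExonAnnotation:
    """A flat exon annotation, sorted by (chrom, start).

    ``exon_number`` counts along the direction of transcription (reversed
    in genomic order for minus-strand genes).
    """

    exons: list[Exon]

    def __post_init__(self) -> None:
        self.exons = sorted(
            self.exons, key=lambda e: (e.interval.chrom, e.interval.start, e.interval.end)
        )

    def overlapping(self, region: GenomicInterval) -> list[Exon]:
        """All exons overlapping *region* by at least one base."""
        return [e for e in self.exons if e.interval.overlaps(region)]

    def contained_in(self, region: GenomicInterval) -> list[Exon]:
        """All exons fully contained in *region*."""
        return [e for e in self.exons if region.contains(e.interval)]

    def genes_overlapping(self, region: GenomicInterval) -> set[str]:
        return {e.gene_id for e in self.overlapping(region)}


@dataclass
class IntronCall:
    """A linear splice gap observed in circular reads, with its support."""

    interval: GenomicInterval
    supporting_reads: set[str]

    def __post_init__(self) -> None:
        if not self.supporting_reads:
            raise ValueError("IntronCall without supporting reads")


_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

# Reference-consuming CIGAR ops; N and (long) D split aligned blocks.
_REF_OPS = set("MDN=X")


def cigar_to_segments(
    ref_start: int,
    cigar: str,
    chrom: str = ".",
    strand: str = ".",
    min_deletion_gap: int = 30,
) -> list[GenomicInterval]:
    """Split a CIGAR string into reference-aligned blocks.

    Skip operations (N) always split blocks; deletions (D) split only when
    at least ``min_deletion_gap`` bases long — shorter deletions are
    alignment noise and are merged into the flanking block. Insertions,
    soft and hard clips consume no reference.

    Returns intervals in reference order; raises ``ValueError`` on a
    malformed CIGAR.
    """
    if not cigar or cigar == "*":
        raise ValueError(f"missing CIGAR: {cigar!r}")
    consumed = sum(len(m.group(0)) for m in _CIGAR_RE.finditer(cigar))
    if consumed != len(cigar):
        raise ValueError(f"malformed CIGAR: {cigar!r}")

    segments: list[tuple[int, int]] = []
    pos = ref_start
    block_start: int | None = None
    for m in _CIGAR_RE.finditer(cigar):
        n, op = int(m.group(1)), m.group(2)
        if op in ("M", "=", "X"):
            if block_start is None:
                block_start = pos
            pos += n
        elif op == "D":
            if n >= min_deletion_gap:
                if block_start is not None:
                    segments.append((block_start, pos))
                    block_start = None
                pos += n
            else:
                # short deletion: bridged, extends an open block but never
                # opens one
                pos += n
        elif op == "N":
            if block_start is not None:
                segments.append((block_start, pos))
                block_start = None
            pos += n
        # I, S, H, P consume no reference
    if block_start is not None:
        segments.append((block_start, pos))
    if not segments:
        raise ValueError(f"CIGAR aligns no reference bases: {cigar!r}")
    return [GenomicInterval(chrom, s, e, strand) for s, e in segments]
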