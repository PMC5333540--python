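"""Mate-pair evidence: single- vs double-breakpoint fragments.

A fragment whose two sequenced ends both span the back-splice junction
(a double-breakpoint fragment) is very unlikely to come from anything
but a circular molecule: trans-splicing or genomic rearrangement also
produce a chimeric junction, but only circularity lets both ends of one
fragment cross it. The catch is geometry — both ends can cross only if
the fragment is long enough to wrap the whole circle (or the mates
overlap across the junction), so the circle length must be weighed
against the library's expected fragment length. A circle no longer than
the fragment length that is nevertheless supported only by
single-breakpoint fragments is a suspect candidate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core import Circle, ExonAnnotation, GenomicInterval
from .extract import CircleReadSet
from .io import JunctionRecord

logger = logging.getLogger(__name__)

__all__ = [
    "FragmentSummary",
    "junction_spanning_from_alignments",
    "junction_spanning_from_junctions",
    "classify_fragments",
    "estimate_circle_length",
    "flag_suspect_circles",
    "write_mate_status",
]


@dataclass
class FragmentSummary:
    circle_id: str
    n_single: int
    n_double: int
    circle_length_bp: int = 0
    suspect_flag: bool = False

    @property
    def n_fragments(self) -> int:
        return self.n_single + self.n_double

    @property
    def double_fraction(self) -> float | None:
        if self.n_fragments == 0:
            return None
        return self.n_double / self.n_fragments


def junction_spanning_from_alignments(
    read_set: CircleReadSet, tolerance: int = 5
) -> dict[str, set[int]]:
    """Infer junction-spanning mates from split alignment records.

    A mate spans the back-splice when its records (primary plus
    supplementary) are split across the junction: one aligned segment
    ends at the circle's end and another starts at the circle's start
    (each within ``tolerance`` bases).
    """
    iv = read_set.circle.interval
    by_mate: dict[tuple[str, int], list] = {}
    for aln in read_set.alignments:
        by_mate.setdefault((aln.read_name, aln.mate), []).append(aln)
    spanning: dict[str, set[int]] = {}
    for (name, mate), alns in by_mate.items():
        segs = [s for a in alns for s in a.segments]
        ends_at_end = any(abs(s.end - iv.end) <= tolerance for s in segs)
        starts_at_start = any(abs(s.start - iv.start) <= tolerance for s in segs)
        if ends_at_end and starts_at_start:
            spanning.setdefault(name, set()).add(mate)
    return spanning


def junction_spanning_from_junctions(
    junctions: Iterable[JunctionRecord], circle: Circle, tolerance: int = 1
) -> dict[str, set[int]]:
    """Junction-spanning mates according to chimeric-junction records.

    Preferred evidence channel when the upstream detector's junction
    files are available: every record matching this circle's boundaries
    marks its (read, mate) as junction-spanning. Records from a
    non-mate-specific file carry mate 0, meaning "some mate".
    """
    iv = circle.interval
    spanning: dict[str, set[int]] = {}
    for j in junctions:
        if j.donor_chrom != iv.chrom or j.acceptor_chrom != iv.chrom:
            continue
        fwd = (
            abs(j.donor_pos + 1 - iv.end) <= tolerance
            and abs(j.acceptor_pos - iv.start) <= tolerance
        )
        rev = (
            abs(j.acceptor_pos + 1 - iv.end) <= tolerance
            and abs(j.donor_pos - iv.start) <= tolerance
        )
        if fwd or rev:
            spanning.setdefault(j.read_name, set()).add(j.mate)
    return spanning


def classify_fragments(
    read_set: CircleReadSet,
    junction_spanning: Mapping[str, set[int]] | None = None,
) -> FragmentSummary:
    """Count single- vs double-breakpoint fragments for one circle.

    Each distinct read name is one fragment. A fragment is *double*
    when both mates span the back-splice, *single* when exactly one does
    (unpaired reads are necessarily single). Read names with no
    junction-spanning mate at all should not be on the circle's list;
    they are excluded with a warning.

    ``junction_spanning`` maps read name to the set of junction-spanning
    mates (1/2, or 0 for "some unspecified mate"); when omitted it is
    derived from the split alignments themselves.
    """
    if junction_spanning is None:
        junction_spanning = junction_spanning_from_alignments(read_set)
    n_single = n_double = 0
    # fall back to the circle's read list when no alignments were extracted
    names = read_set.read_names or set(read_set.circle.read_names)
    for name in sorted(names):
        mates = junction_spanning.get(name, set())
        concrete = mates - {0}
        if not mates:
            logger.warning(
                "circle %s: read %s has no junction-spanning mate; excluded",
                read_set.circle.circle_id, name,
            )
            continue
        if len(concrete) >= 2:
            n_double += 1
        else:
            n_single += 1
    return FragmentSummary(
        circle_id=read_set.circle.circle_id, n_single=n_single, n_double=n_double
    )


def estimate_circle_length(
    circle: Circle,
    annotation: ExonAnnotation | None = None,
    covered_exons: Sequence | None = None,
) -> int:
    """Estimate the transcribed length of a circle in bases.

    The length is the summed length of covered annotated exons inside
    the circle interval (exons clipped at the boundaries). When
    ``covered_exons`` (rows from the coverage stage, with ``.exon`` and
    ``.n_reads``) is given, only exons with at least one read count;
    otherwise every overlapping annotated exon counts. With no
    annotation overlap at all the genomic span is the fallback.
    """
    iv = circle.interval

    def clipped(e: GenomicInterval) -> int:
        return max(0, min(e.end, iv.end) - max(e.start, iv.start))

    if covered_exons is not None:
        total = sum(
            clipped(row.exon.interval) for row in covered_exons if row.n_reads > 0
        )
        if total > 0:
            return total
    if annotation is not None:
        total = sum(clipped(e.interval) for e in annotation.overlapping(iv))
        if total > 0:
            return total
    return iv.length


def flag_suspect_circles(
    summary: FragmentSummary,
    expected_fragment_length: int,
    min_fragments: int = 2,
) -> bool:
    """Suspect-circle rule.

    A circle short enough to be wrapped by a typical library fragment
    (circle length <= expected fragment length) should show
    double-breakpoint fragments; when it is supported only by single-
    breakpoint fragments (and by at least ``min_fragments`` fragments,
    so the demand has any power) it is flagged. Circles longer than the
    fragment length cannot be expected to produce doubles, so they are
    never flagged.
    """
    if expected_fragment_length <= 0:
        raise ValueError("expected_fragment_length must be positive")
    return (
        summary.circle_length_bp <= expected_fragment_length
        and summary.n_double == 0
        and summary.n_fragments >= min_fragments
    )


def write_mate_status(
    summaries: Sequence[FragmentSummary], prefix: str | Path
) -> Path:
    """Write ``<prefix>.mate_status.txt`` (TSV, one row per circle)."""
    prefix = Path(prefix)
    path = prefix.parent / (prefix.name + ".mate_status.txt")
    prefix.parent.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "circle_id": s.circle_id,
            "n_single": s.n_single,
            "n_double": s.n_double,
            "n_fragments": s.n_fragments,
            "double_fraction": "" if s.double_fraction is None else f"{s.double_fraction:.4f}",
            "circle_length_bp": s.circle_length_bp,
            "suspect": str(s.suspect_flag).lower(),
        }
        for s in summaries
    ]
    pd.DataFrame(
        rows,
        columns=[
            "circle_id", "n_single", "n_double", "n_fragments",
            "double_fraction", "circle_length_bp", "suspect",
        ],
    ).to_csv(path, sep="\t", index=False)
    return path
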