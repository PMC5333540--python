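"""Synthetic circRNA data with known truth.

Generates toy chromosomes, BED annotations, circle tables, STAR-layout
chimeric-junction files and SAM alignments for back-spliced transcripts,
so that every pipeline stage is testable without any real sequencing
data.

The fragment model mirrors a random-fragmentation library prep: each
sequenced fragment is cut at a uniformly random position on the
circularized transcript, and a mate spans the back-splice junction
exactly when its linearized coordinates cross the junction (with a
minimum overhang on both sides, as an aligner would require). Reads
longer than the circularized transcript are capped at one full rotation
— the physical rolling-circle case. There is no sequencing-error model:
none of the downstream procedures use base qualities or mismatches, and
coverage noise enters only through the random fragment positions.

Back-splice-spanning mates are emitted as a primary plus a supplementary
SAM record with soft-clips, together with matching entries in per-mate
junction TSVs, so both evidence channels of the fragment analysis are
exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import Circle, GenomicInterval, make_circle_id

__all__ = [
    "SimTruth",
    "TruthCircle",
    "SimOutput",
    "make_exon_skip_example",
    "simulate_circles",
    "make_false_positive_fixture",
    "mate_spans_junction",
    "double_fraction_oracle",
]

MIN_OVERHANG = 10  # bases a junction-crossing mate must have on each side


@dataclass
class TruthCircle:
    """Ground truth for one simulated circle."""

    circle_id: str
    interval: GenomicInterval
    transcript_length: int  # inclusive-isoform transcribed length
    skip_fraction: float = 0.0
    skipped_exon: GenomicInterval | None = None
    listed_reads: set[str] = field(default_factory=set)
    fragment_class: dict[str, str] = field(default_factory=dict)  # name -> single|double
    skipping_reads: set[str] = field(default_factory=set)  # listed reads from skipped isoform
    is_false_positive: bool = False


@dataclass
class SimTruth:
    circles: dict[str, TruthCircle] = field(default_factory=dict)


@dataclass
class SimOutput:
    """File paths of one simulated dataset plus its truth."""

    sam_path: Path
    circle_table_path: Path
    annotation_path: Path
    count_path: Path | None
    junction_paths: list[Path]
    truth: SimTruth


# ---------------------------------------------------------------------------
# geometry helpers


def mate_spans_junction(start: int, length: int, transcript_length: int) -> bool:
    """Does a mate at linearized position *start* cross the back-splice?

    The mate covers transcript positions [start, start + length) on the
    circularized (wrapping) coordinate; it spans the junction when it
    wraps with at least ``MIN_OVERHANG`` bases on both sides.
    """
    part1 = transcript_length - start
    part2 = start + length - transcript_length
    return part1 >= MIN_OVERHANG and part2 >= MIN_OVERHANG


def double_fraction_oracle(
    transcript_length: int, fragment_length: int, read_length: int
) -> tuple[float, float]:
    """Enumerate all cut positions; return P(double) and P(>=1 mate spans).

    Brute-force companion to the simulator: for every integer cut
    position the two mates' junction crossings are evaluated directly.
    """
    T = transcript_length
    r = min(read_length, T)
    n_double = n_any = 0
    for p in range(T):
        m1 = mate_spans_junction(p, r, T)
        s2 = (p + fragment_length - r) % T
        m2 = mate_spans_junction(s2, r, T)
        if m1 and m2:
            n_double += 1
        if m1 or m2:
            n_any += 1
    return n_double / T, n_any / T


def _chain_blocks(chain: list[tuple[int, int]], s: int, e: int) -> list[tuple[int, int]]:
    """Map transcript interval [s, e) through an exon chain to genomic blocks."""
    blocks = []
    offset = 0
    for gs, ge in chain:
        n = ge - gs
        lo, hi = max(s, offset), min(e, offset + n)
        if hi > lo:
            blocks.append((gs + (lo - offset), gs + (hi - offset)))
        offset += n
    return blocks


def _blocks_to_cigar(blocks: list[tuple[int, int]]) -> tuple[int, str, int]:
    """(pos, cigar of M/N ops, query length) for a list of genomic blocks."""
    cigar = []
    qlen = 0
    for i, (s, e) in enumerate(blocks):
        if i > 0:
            gap = s - blocks[i - 1][1]
            if gap > 0:
                cigar.append(f"{gap}N")
        cigar.append(f"{e - s}M")
        qlen += e - s
    return blocks[0][0], "".join(cigar), qlen


# ---------------------------------------------------------------------------
# SAM assembly


class _SamBuilder:
    def __init__(self) -> None:
        self.records: list[tuple[str, int, str, int, str, str]] = []
        self.chrom_max: dict[str, int] = {}

    def add_mate(
        self,
        name: str,
        mate: int,  # 0 unpaired, 1, 2
        chrom: str,
        chain: list[tuple[int, int]],
        tstart: int,
        length: int,
    ) -> None:
        """Emit the SAM record(s) of one mate on a circular exon chain.

        ``tstart`` is the linearized transcript start; a wrapping mate
        becomes a primary record (the part containing the read start)
        plus a supplementary record, with complementary soft-clips.
        """
        T = sum(e - s for s, e in chain)
        length = min(length, T)
        tstart %= T
        parts: list[tuple[int, int]]
        if tstart + length <= T:
            parts = [(tstart, tstart + length)]
        else:
            parts = [(tstart, T), (0, tstart + length - T)]
            # an aligner will not map a junction arm shorter than its
            # minimum overhang; such an arm stays unaligned (clipped)
            parts = [p for p in parts if p[1] - p[0] >= MIN_OVERHANG] or [parts[0]]

        base_flag = 0 if mate == 0 else (0x1 | (0x40 if mate == 1 else 0x80))
        part_q = []
        total_q = 0
        rendered = []
        for s, e in parts:
            blocks = _chain_blocks(chain, s, e)
            pos, cigar, qlen = _blocks_to_cigar(blocks)
            rendered.append((pos, cigar, qlen))
            part_q.append(qlen)
            total_q += qlen
        offset = 0
        for i, (pos, cigar, qlen) in enumerate(rendered):
            pre, post = offset, total_q - offset - qlen
            full = (f"{pre}S" if pre else "") + cigar + (f"{post}S" if post else "")
            flag = base_flag | (0x800 if i > 0 else 0)
            self.records.append((name, flag, chrom, pos, full, "A" * total_q))
            offset += qlen
        end = max(b[1] for s, e in parts for b in _chain_blocks(chain, s, e))
        self.chrom_max[chrom] = max(self.chrom_max.get(chrom, 0), end)

    def add_gapped_read(
        self, name: str, chrom: str, pos: int, cigar: str, mate: int = 0
    ) -> None:
        """Emit a single record from an explicit (pos, CIGAR) pair."""
        import re

        qlen = sum(
            int(n) for n, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar) if op in "MIS=X"
        )
        ref_span = sum(
            int(n) for n, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar) if op in "MDN=X"
        )
        flag = 0 if mate == 0 else (0x1 | (0x40 if mate == 1 else 0x80))
        self.records.append((name, flag, chrom, pos, cigar, "A" * qlen))
        self.chrom_max[chrom] = max(self.chrom_max.get(chrom, 0), pos + ref_span)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:unsorted\n")
            for chrom in sorted(self.chrom_max):
                fh.write(f"@SQ\tSN:{chrom}\tLN:{self.chrom_max[chrom] + 1000}\n")
            for name, flag, chrom, pos, cigar, seq in self.records:
                fh.write(
                    f"{name}\t{flag}\t{chrom}\t{pos + 1}\t60\t{cigar}\t*\t0\t0\t{seq}\t*\n"
                )
        return path


def _write_junctions(
    entries: dict[int, list[tuple[str, int, int, str]]], out_dir: Path, stem: str
) -> list[Path]:
    """Write per-mate STAR-layout junction TSVs.

    ``entries`` maps mate (1/2/0) to (chrom, circle_start, circle_end,
    read_name) tuples; positions are converted to the 1-based STAR
    convention (donor = last base of the circle, acceptor = first).
    """
    paths = []
    for mate, rows in sorted(entries.items()):
        suffix = {1: "mate1.", 2: "mate2.", 0: ""}[mate]
        path = out_dir / f"{stem}.{suffix}Chimeric.out.junction"
        with open(path, "w") as fh:
            for chrom, start, end, name in rows:
                fh.write(
                    "\t".join(
                        [
                            chrom, str(end), "+", chrom, str(start + 1), "+",
                            "0", "-1", "-1", name, str(end - 20), "20M130S",
                            str(start + 1), "20S130M",
                        ]
                    )
                    + "\n"
                )
        paths.append(path)
    return paths


def _write_circle_table(circles: list[Circle], path: Path) -> Path:
    with open(path, "w") as fh:
        for c in circles:
            fh.write(f"{c.circle_id}\t{','.join(sorted(c.read_names))}\n")
    return path


def _write_count_table(circles: list[Circle], path: Path) -> Path:
    with open(path, "w") as fh:
        fh.write("Chr\tStart\tEnd\tStrand\tsim\n")
        for c in circles:
            fh.write(
                f"{c.interval.chrom}\t{c.interval.start}\t{c.interval.end}\t+\t"
                f"{len(c.read_names)}\n"
            )
    return path


# ---------------------------------------------------------------------------
# the worked five-read example


def make_exon_skip_example(out_dir: str | Path) -> SimOutput:
    """The canonical two-isoform worked example.

    A toy chromosome carries one gene with five 100 bp exons at
    100-200, 300-400, 500-600, 700-800 and 900-1000; one circle spans
    exons 2-5 (300-1000) and is supported by five junction-spanning
    reads whose splice gaps realize four distinct introns — between
    exons 2-3, 3-4, 4-5 and 2-4 — with exactly two reads carrying the
    2->4 gap that skips exon 3.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chrom = "chrT"
    circle = Circle.from_coords(chrom, 300, 1000, [f"r{i}" for i in range(1, 6)])

    sam = _SamBuilder()
    reads = [
        ("r1", 300, "100M100N100M100N100M"),  # exons 2,3,4
        ("r2", 500, "100M100N100M100N100M"),  # exons 3,4,5
        ("r3", 300, "100M100N100M"),          # exons 2,3
        ("r4", 300, "100M300N100M"),          # exons 2,4  (skips exon 3)
        ("r5", 300, "100M300N100M100N100M"),  # exons 2,4,5 (skips exon 3)
    ]
    for name, pos, cigar in reads:
        sam.add_gapped_read(name, chrom, pos, cigar)
    sam.chrom_max[chrom] = max(sam.chrom_max[chrom], 1100)
    sam_path = sam.write(out_dir / "example.sam")

    # BED12 annotation: one gene, five 100 bp exons
    ann_path = out_dir / "annotation.bed"
    with open(ann_path, "w") as fh:
        sizes = ",".join(["100"] * 5)
        starts = ",".join(str(100 + 200 * i - 100) for i in range(5))
        fh.write(
            f"{chrom}\t100\t1000\tgeneA\t0\t+\t100\t1000\t0\t5\t{sizes}\t{starts}\n"
        )

    table_path = _write_circle_table([circle], out_dir / "circles.tsv")
    count_path = _write_count_table([circle], out_dir / "CircRNACount")
    junction_paths = _write_junctions(
        {0: [(chrom, 300, 1000, name) for name, _, _ in reads]}, out_dir, "example"
    )

    truth = SimTruth(
        circles={
            circle.circle_id: TruthCircle(
                circle_id=circle.circle_id,
                interval=circle.interval,
                transcript_length=400,  # four covered 100 bp exons
                skip_fraction=2 / 5,
                skipped_exon=GenomicInterval(chrom, 500, 600),
                listed_reads=set(circle.read_names),
                skipping_reads={"r4", "r5"},
                fragment_class={name: "single" for name, _, _ in reads},
            )
        }
    )
    return SimOutput(
        sam_path=sam_path,
        circle_table_path=table_path,
        annotation_path=ann_path,
        count_path=count_path,
        junction_paths=junction_paths,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# random simulations


def _simulate_circle_fragments(
    rng: np.random.Generator,
    sam: _SamBuilder,
    junctions: dict[int, list],
    truth: TruthCircle,
    chrom: str,
    inclusive_chain: list[tuple[int, int]],
    skipped_chain: list[tuple[int, int]] | None,
    fragment_length: int,
    read_length: int,
    skip_fraction: float,
    n_listed: int,
    prefix: str,
    max_attempts_factor: int = 200,
) -> None:
    """Draw fragments until *n_listed* junction-spanning fragments exist."""
    iv = truth.interval
    listed = 0
    attempts = 0
    j = 0
    max_attempts = max_attempts_factor * n_listed
    while listed < n_listed and attempts < max_attempts:
        attempts += 1
        j += 1
        name = f"{prefix}_f{j}"
        skipped = skipped_chain is not None and rng.random() < skip_fraction
        chain = skipped_chain if skipped else inclusive_chain
        T = sum(e - s for s, e in chain)
        r = min(read_length, T)
        p = int(rng.integers(0, T))
        s2 = (p + fragment_length - r) % T
        m1 = mate_spans_junction(p, r, T)
        m2 = mate_spans_junction(s2, r, T)
        sam.add_mate(name, 1, chrom, chain, p, r)
        sam.add_mate(name, 2, chrom, chain, s2, r)
        if not (m1 or m2):
            continue
        listed += 1
        truth.listed_reads.add(name)
        truth.fragment_class[name] = "double" if (m1 and m2) else "single"
        if skipped:
            truth.skipping_reads.add(name)
        if m1:
            junctions.setdefault(1, []).append((chrom, iv.start, iv.end, name))
        if m2:
            junctions.setdefault(2, []).append((chrom, iv.start, iv.end, name))


def simulate_circles(
    n_circles: int,
    length_grid: list[int],
    fragment_length: int = 350,
    read_length: int = 150,
    skip_fraction: float = 0.0,
    n_fragments_per_circle: int = 50,
    seed: int = 1,
    out_dir: str | Path = ".",
) -> SimOutput:
    """Simulate circles with random-fragmentation paired-end reads.

    Circle transcribed lengths cycle through ``length_grid``. With
    ``skip_fraction`` zero each circle is one exon equal to its genomic
    span; otherwise each circle has three exons (the middle one roughly
    a third of the transcript, flanked by 100 bp introns) and each
    fragment derives from the exon-skipping isoform with probability
    ``skip_fraction``. ``n_fragments_per_circle`` counts
    junction-spanning (listed) fragments; non-spanning fragments are
    also written to the SAM, as they would be present in a real
    alignment file. Deterministic for a given seed.
    """
    if read_length >= fragment_length:
        raise ValueError("read_length must be smaller than fragment_length")
    if min(length_grid) <= 0:
        raise ValueError("circle lengths must be positive")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    chrom = "chrS"
    spacing = max(length_grid) + 3000

    sam = _SamBuilder()
    junction_entries: dict[int, list] = {1: [], 2: []}
    circles: list[Circle] = []
    truth = SimTruth()
    ann_lines: list[str] = []

    for i in range(n_circles):
        L = length_grid[i % len(length_grid)]
        g0 = 1000 + i * spacing
        gene = f"gene{i}"
        if skip_fraction > 0:
            m = max(MIN_OVERHANG * 2, round(L / 3))
            a = (L - m) // 2
            b = L - m - a
            if min(a, b) < MIN_OVERHANG * 2:
                raise ValueError(f"circle length {L} too short for a 3-exon structure")
            e1 = (g0, g0 + a)
            mid = (g0 + a + 100, g0 + a + 100 + m)
            e2 = (g0 + a + 100 + m + 100, g0 + a + 100 + m + 100 + b)
            inclusive = [e1, mid, e2]
            skipped = [e1, e2]
            iv = GenomicInterval(chrom, e1[0], e2[1])
            for num, (gs, ge) in enumerate(inclusive, start=1):
                ann_lines.append(f"{chrom}\t{gs}\t{ge}\t{gene}\t0\t+")
            skipped_exon = GenomicInterval(chrom, mid[0], mid[1])
        else:
            inclusive = [(g0, g0 + L)]
            skipped = None
            iv = GenomicInterval(chrom, g0, g0 + L)
            ann_lines.append(f"{chrom}\t{g0}\t{g0 + L}\t{gene}\t0\t+")
            skipped_exon = None

        tc = TruthCircle(
            circle_id=make_circle_id(chrom, iv.start, iv.end),
            interval=iv,
            transcript_length=L,
            skip_fraction=skip_fraction,
            skipped_exon=skipped_exon,
        )
        _simulate_circle_fragments(
            rng, sam, junction_entries, tc, chrom, inclusive, skipped,
            fragment_length, read_length, skip_fraction,
            n_fragments_per_circle, prefix=f"c{i}",
        )
        truth.circles[tc.circle_id] = tc
        circles.append(
            Circle(circle_id=tc.circle_id, interval=iv, read_names=set(tc.listed_reads))
        )

    sam_path = sam.write(out_dir / "sim.sam")
    ann_path = out_dir / "annotation.bed"
    ann_path.write_text("\n".join(ann_lines) + "\n")
    table_path = _write_circle_table(circles, out_dir / "circles.tsv")
    count_path = _write_count_table(circles, out_dir / "CircRNACount")
    junction_paths = _write_junctions(junction_entries, out_dir, "sim")
    return SimOutput(
        sam_path=sam_path,
        circle_table_path=table_path,
        annotation_path=ann_path,
        count_path=count_path,
        junction_paths=junction_paths,
        truth=truth,
    )


def make_false_positive_fixture(
    seed: int = 1,
    out_dir: str | Path = ".",
    n_fp: int = 22,
    n_true: int = 64,
    fp_length: int = 300,
    true_length: int = 650,
    fragment_length: int = 350,
    read_length: int = 150,
    n_fragments_per_circle: int = 60,
) -> SimOutput:
    """Short false-positive 'circles' mixed with genuine circles.

    The false positives emulate trans-splice-like junctions: every
    fragment has exactly one chimeric mate (single-breakpoint only) with
    a thin anchor on the circle's 3' side, and the linear mate falls on
    the 5' side only — so the coverage profile is heavily one-sided
    around the junction. Their length is at most the fragment length,
    so the suspect rule applies. Genuine circles are simulated with the
    ordinary circular fragment model and give junction-balanced
    profiles.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    chrom = "chrF"
    spacing = max(fp_length, true_length) + 3000

    sam = _SamBuilder()
    junction_entries: dict[int, list] = {1: [], 2: []}
    circles: list[Circle] = []
    truth = SimTruth()
    ann_lines: list[str] = []

    for i in range(n_fp + n_true):
        is_fp = i < n_fp
        L = fp_length if is_fp else true_length
        g0 = 1000 + i * spacing
        iv = GenomicInterval(chrom, g0, g0 + L)
        chain = [(g0, g0 + L)]
        ann_lines.append(f"{chrom}\t{g0}\t{g0 + L}\tgene{i}\t0\t+")
        tc = TruthCircle(
            circle_id=make_circle_id(chrom, g0, g0 + L),
            interval=iv,
            transcript_length=L,
            is_false_positive=is_fp,
        )
        if is_fp:
            # every fragment: one chimeric mate whose 3'-side anchor is a
            # typical aligner minimum junction overhang, the other mate
            # linear on the 5' half only
            anchor = 15
            r = min(read_length, L)
            for j in range(n_fragments_per_circle):
                name = f"fp{i}_f{j}"
                sam.add_mate(name, 1, chrom, chain, L - anchor, r)
                lin_max = max(1, L // 2 - r)
                lin = int(rng.integers(0, lin_max))
                sam.add_mate(name, 2, chrom, chain, lin, min(r, L // 2))
                tc.listed_reads.add(name)
                tc.fragment_class[name] = "single"
                junction_entries[1].append((chrom, iv.start, iv.end, name))
        else:
            _simulate_circle_fragments(
                rng, sam, junction_entries, tc, chrom, chain, None,
                fragment_length, read_length, 0.0,
                n_fragments_per_circle, prefix=f"t{i}",
            )
        truth.circles[tc.circle_id] = tc
        circles.append(
            Circle(circle_id=tc.circle_id, interval=iv, read_names=set(tc.listed_reads))
        )

    sam_path = sam.write(out_dir / "fp.sam")
    ann_path = out_dir / "annotation.bed"
    ann_path.write_text("\n".join(ann_lines) + "\n")
    table_path = _write_circle_table(circles, out_dir / "circles.tsv")
    count_path = _write_count_table(circles, out_dir / "CircRNACount")
    junction_paths = _write_junctions(junction_entries, out_dir, "fp")
    return SimOutput(
        sam_path=sam_path,
        circle_table_path=table_path,
        annotation_path=ann_path,
        count_path=count_path,
        junction_paths=junction_paths,
        truth=truth,
    )
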