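"""Exon-wise and position-wise read coverage of each circle.

A genuine circle shows even coverage around its back-splice junction;
an unbalanced junction (high on one side, low on the other) hints at a
non-circular origin. This stage computes, per circle, a per-exon
coverage table and a per-base profile along the transcribed (exonic)
coordinate, which downstream clustering and plotting consume.

Depth counts alignment segments (each mate separately), not fragments.
Bases of the genomic span that fall in no covered exon are excluded
from the transcribed coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .core import Exon, ExonAnnotation, GenomicInterval, circle_id_to_filename
from .extract import CircleReadSet

__all__ = [
    "ExonCoverageRow",
    "CoverageProfile",
    "exonwise_coverage",
    "positionwise_coverage",
    "render_profile_plot",
    "write_exon_counts",
    "write_coverage_bed",
    "write_profile",
]


@dataclass
class ExonCoverageRow:
    circle_id: str
    exon: Exon
    exon_length_bp: int
    n_reads: int
    mean_depth: float
    fraction_covered: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_covered <= 1.0:
            raise ValueError("fraction_covered outside [0, 1]")


@dataclass
class CoverageProfile:
    """Per-base depth along the transcribed coordinate of one circle.

    Arrays are parallel, one entry per transcribed base, ordered 5'->3'
    in genomic orientation; ``rel_pos_circle`` spans [0, 1] and is
    non-decreasing.
    """

    circle_id: str
    exon_number: np.ndarray
    rel_pos_circle: np.ndarray
    rel_pos_exon: np.ndarray
    depth: np.ndarray
    circle_length_bp: int

    def __len__(self) -> int:
        return len(self.depth)


def _depth_array(read_set: CircleReadSet) -> np.ndarray:
    """Per-base segment pileup over the circle's genomic span."""
    iv = read_set.circle.interval
    depth = np.zeros(iv.length, dtype=np.int64)
    for aln in read_set.alignments:
        for seg in aln.segments:
            lo = max(seg.start, iv.start) - iv.start
            hi = min(seg.end, iv.end) - iv.start
            if hi > lo:
                depth[lo:hi] += 1
    return depth


def _clip(e: GenomicInterval, iv: GenomicInterval) -> tuple[int, int]:
    return max(e.start, iv.start), min(e.end, iv.end)


def exonwise_coverage(
    read_set: CircleReadSet, annotation: ExonAnnotation
) -> list[ExonCoverageRow]:
    """Coverage statistics for every annotated exon overlapping the circle.

    Exons are clipped at the circle boundaries. ``n_reads`` counts
    distinct read names with at least one base of segment overlap;
    ``mean_depth`` and ``fraction_covered`` are per-base statistics.
    A circle with no annotation overlap gets a single pseudo-exon equal
    to its genomic span.
    """
    circle = read_set.circle
    iv = circle.interval
    exons = annotation.overlapping(iv)
    if not exons:
        exons = [Exon(interval=iv, gene_id=circle.circle_id, exon_number=1)]
    depth = _depth_array(read_set)

    rows = []
    for exon in sorted(exons, key=lambda e: (e.interval.start, e.interval.end)):
        lo, hi = _clip(exon.interval, iv)
        sub = depth[lo - iv.start : hi - iv.start]
        exon_iv = exon.interval
        names = {
            a.read_name
            for a in read_set.alignments
            for s in a.segments
            if s.overlaps(exon_iv)
        }
        rows.append(
            ExonCoverageRow(
                circle_id=circle.circle_id,
                exon=exon,
                exon_length_bp=exon_iv.length,
                n_reads=len(names),
                mean_depth=float(sub.mean()) if len(sub) else 0.0,
                fraction_covered=float((sub > 0).mean()) if len(sub) else 0.0,
            )
        )
    return rows


def positionwise_coverage(
    read_set: CircleReadSet, covered_exons: Sequence[ExonCoverageRow]
) -> CoverageProfile:
    """Per-base profile along the concatenation of covered exons.

    The transcribed coordinate concatenates, in genomic order, the
    exons with at least one overlapping read (all exons when the read
    set is empty, so an all-zero profile is still produced). Relative
    positions are computed against the transcribed circle length and
    the exon length.
    """
    circle = read_set.circle
    iv = circle.interval
    depth = _depth_array(read_set)

    use = [r for r in covered_exons if r.n_reads > 0] or list(covered_exons)
    use = sorted(use, key=lambda r: (r.exon.interval.start, r.exon.interval.end))

    exon_number: list[int] = []
    rel_exon: list[float] = []
    depths: list[int] = []
    for row in use:
        lo, hi = _clip(row.exon.interval, iv)
        n = hi - lo
        if n <= 0:
            continue
        exon_number.extend([row.exon.exon_number] * n)
        rel_exon.extend((np.arange(n) / max(n - 1, 1)).tolist())
        depths.extend(depth[lo - iv.start : hi - iv.start].tolist())

    L = len(depths)
    rel_circle = np.arange(L) / max(L - 1, 1)
    return CoverageProfile(
        circle_id=circle.circle_id,
        exon_number=np.asarray(exon_number, dtype=np.int64),
        rel_pos_circle=rel_circle,
        rel_pos_exon=np.asarray(rel_exon, dtype=float),
        depth=np.asarray(depths, dtype=np.int64),
        circle_length_bp=L,
    )


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or len(y) == 0:
        return y.astype(float)
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(y.astype(float), pad, mode="edge")
    out = np.convolve(padded, kernel, mode="same")[pad : pad + len(y)]
    return out


def render_profile_plot(
    profile: CoverageProfile, out_path: str | Path, window: int | None = None
) -> Path:
    """Save a smoothed coverage-profile plot, exons as coloured segments.

    Smoothing is a centred rolling mean with window
    max(3, circle_length / 50) bases unless given. Pure side effect:
    the profile itself is never altered.
    """
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    if len(profile) == 0:
        raise ValueError("cannot plot an empty profile")
    if window is None:
        window = max(3, profile.circle_length_bp // 50)
    smoothed = _smooth(profile.depth, window)

    fig, ax = plt.subplots(figsize=(6, 3))
    cmap = plt.get_cmap("tab10")
    for k, num in enumerate(sorted(set(profile.exon_number.tolist()))):
        mask = profile.exon_number == num
        ax.fill_between(
            profile.rel_pos_circle[mask],
            smoothed[mask],
            color=cmap(k % 10),
            alpha=0.7,
            label=f"exon {num}",
        )
    ax.set_xlabel("relative position in circle")
    ax.set_ylabel("coverage")
    ax.set_title(profile.circle_id)
    ax.legend(fontsize=6, ncol=4)
    fig.tight_layout()
    fig.savefig(out_path, dpi=100)
    plt.close(fig)
    return out_path


def write_exon_counts(
    rows: Sequence[ExonCoverageRow], prefix: str | Path
) -> Path:
    """Write ``<prefix>.exon_counts.txt`` (one row per circle x exon)."""
    prefix = Path(prefix)
    path = prefix.parent / (prefix.name + ".exon_counts.txt")
    prefix.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "circle_id": r.circle_id,
                "chrom": r.exon.interval.chrom,
                "exon_start": r.exon.interval.start,
                "exon_end": r.exon.interval.end,
                "gene_id": r.exon.gene_id,
                "exon_number": r.exon.exon_number,
                "exon_length_bp": r.exon_length_bp,
                "n_reads": r.n_reads,
                "mean_depth": f"{r.mean_depth:.4f}",
                "fraction_covered": f"{r.fraction_covered:.4f}",
            }
            for r in rows
        ],
        columns=[
            "circle_id", "chrom", "exon_start", "exon_end", "gene_id",
            "exon_number", "exon_length_bp", "n_reads", "mean_depth",
            "fraction_covered",
        ],
    ).to_csv(path, sep="\t", index=False)
    return path


def write_coverage_bed(
    per_circle_rows: dict[str, Sequence[ExonCoverageRow]], prefix: str | Path
) -> Path:
    """BED12, one line per circle, covered exons as blocks (browser-loadable)."""
    prefix = Path(prefix)
    path = prefix.parent / (prefix.name + ".coverage.bed")
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for circle_id, rows in per_circle_rows.items():
            covered = [r for r in rows if r.n_reads > 0]
            if not covered:
                continue
            chrom = covered[0].exon.interval.chrom
            blocks = sorted(
                {
                    (r.exon.interval.start, r.exon.interval.end)
                    for r in covered
                }
            )
            start = blocks[0][0]
            end = blocks[-1][1]
            sizes = ",".join(str(e - s) for s, e in blocks)
            offsets = ",".join(str(s - start) for s, e in blocks)
            fh.write(
                f"{chrom}\t{start}\t{end}\t{circle_id}\t0\t+\t{start}\t{end}\t0\t"
                f"{len(blocks)}\t{sizes}\t{offsets}\n"
            )
    return path


def write_profile(profile: CoverageProfile, out_dir: str | Path) -> Path:
    """Write ``<circle_id>.coverage_profile.txt`` into *out_dir*."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{circle_id_to_filename(profile.circle_id)}.coverage_profile.txt"
    pd.DataFrame(
        {
            "exon_number": profile.exon_number,
            "rel_pos_circle": np.round(profile.rel_pos_circle, 6),
            "rel_pos_exon": np.round(profile.rel_pos_exon, 6),
            "coverage": profile.depth,
        }
    ).to_csv(path, sep="\t", index=False)
    return path
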