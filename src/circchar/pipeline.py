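"""End-to-end orchestration of the characterization stages.

The stages after read extraction (exon skipping, mate-pair analysis,
host-gene isoforms, coverage) are independent of one another and can be
skipped individually; clustering consumes the coverage profiles and
therefore requires the coverage step. A manifest JSON records the
package version, all parameters, the seed and the status of every step.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .clustering import (
    assign_length_group,
    cluster_group,
    summarize_clusters,
    write_cluster_outputs,
)
from .coverage import (
    exonwise_coverage,
    positionwise_coverage,
    render_profile_plot,
    write_coverage_bed,
    write_exon_counts,
    write_profile,
)
from .extract import extract_circle_reads
from .fragments import (
    classify_fragments,
    estimate_circle_length,
    flag_suspect_circles,
    junction_spanning_from_junctions,
    write_mate_status,
)
from .hostgenes import assign_host_genes, summarize_host_genes, write_hostgene_outputs
from .io import read_circle_table, read_dcc_outputs, read_exon_annotation, read_junction_file
from .skipping import assign_isoform_support, detect_skipped_exons, infer_introns, write_skip_outputs

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "STEP_NAMES"]

STEP_NAMES = ("skipped_exons", "mate_pairs", "isoforms", "coverage", "clustering")


@dataclass
class PipelineConfig:
    alignment: str | Path
    annotation: str | Path
    out_dir: str | Path
    expected_fragment_length: int
    sample: str = "sample"
    circle_table: str | Path | None = None
    dcc_count: str | Path | None = None
    dcc_junctions: list[str | Path] = field(default_factory=list)
    junction_mates: list[int] | None = None
    skip_steps: tuple[str, ...] = ()
    seed: int = 42
    n_bins: int = 100
    min_fragments: int = 2
    make_plots: bool = False


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run extraction plus all requested stages; return the manifest."""
    unknown = set(cfg.skip_steps) - set(STEP_NAMES)
    if unknown:
        raise ValueError(f"unknown step name(s) in skip list: {sorted(unknown)}")
    if cfg.circle_table is None and cfg.dcc_count is None:
        raise ValueError("either a circle table or a count table + junction files is required")
    if cfg.dcc_count is not None and not cfg.dcc_junctions:
        raise ValueError("a count table requires at least one chimeric junction file")
    run = [s for s in STEP_NAMES if s not in cfg.skip_steps]
    if "clustering" in run and "coverage" not in run:
        raise ValueError("clustering requires the coverage step; do not skip coverage")
    if cfg.expected_fragment_length <= 0:
        raise ValueError("expected_fragment_length must be positive")

    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prefix = out_dir / cfg.sample
    t0 = time.time()

    if cfg.circle_table is not None:
        circles = read_circle_table(cfg.circle_table)
    else:
        circles = read_dcc_outputs(
            cfg.dcc_count, cfg.dcc_junctions, junction_mates=cfg.junction_mates
        )
    annotation = read_exon_annotation(cfg.annotation)

    read_sets, extract_summary = extract_circle_reads(
        cfg.alignment, circles, out_dir / "circle_bams", sample=cfg.sample
    )
    extract_summary.to_csv(out_dir / f"{cfg.sample}.extraction_summary.txt", sep="\t", index=False)
    status: dict[str, str] = {"extract": "done"}
    logger.info("extracted %d circles in %.1f s", len(read_sets), time.time() - t0)

    # coverage feeds both mate_pairs (circle length) and clustering
    per_circle_rows: dict[str, list] = {}
    profiles = []
    if "coverage" in run:
        profile_dir = out_dir / "coverage_profiles"
        for rs in read_sets:
            rows = exonwise_coverage(rs, annotation)
            per_circle_rows[rs.circle.circle_id] = rows
            profile = positionwise_coverage(rs, rows)
            profiles.append(profile)
            write_profile(profile, profile_dir)
            if cfg.make_plots and len(profile) and profile.depth.max() > 0:
                render_profile_plot(
                    profile, out_dir / "coverage_plots" / f"{rs.file_path.stem}.png"
                )
        write_exon_counts(
            [r for rows in per_circle_rows.values() for r in rows], prefix
        )
        write_coverage_bed(per_circle_rows, prefix)
        status["coverage"] = "done"
    else:
        status["coverage"] = "skipped"

    if "skipped_exons" in run:
        calls = []
        for rs in read_sets:
            if not rs.alignments:
                continue
            introns = infer_introns(rs)
            for cand in detect_skipped_exons(introns, annotation, rs.circle):
                calls.append(assign_isoform_support(rs, cand))
        write_skip_outputs(calls, prefix)
        status["skipped_exons"] = "done"
    else:
        status["skipped_exons"] = "skipped"

    lengths: dict[str, int] = {}
    for rs in read_sets:
        lengths[rs.circle.circle_id] = estimate_circle_length(
            rs.circle, annotation, per_circle_rows.get(rs.circle.circle_id)
        )

    if "mate_pairs" in run:
        junctions = []
        for idx, path in enumerate(cfg.dcc_junctions):
            mate = cfg.junction_mates[idx] if cfg.junction_mates else 0
            junctions.extend(read_junction_file(path, mate=mate))
        summaries = []
        for rs in read_sets:
            spanning = (
                junction_spanning_from_junctions(junctions, rs.circle)
                if junctions
                else None
            )
            s = classify_fragments(rs, spanning)
            s.circle_length_bp = lengths[rs.circle.circle_id]
            s.suspect_flag = flag_suspect_circles(
                s, cfg.expected_fragment_length, min_fragments=cfg.min_fragments
            )
            summaries.append(s)
        write_mate_status(summaries, prefix)
        status["mate_pairs"] = "done"
    else:
        status["mate_pairs"] = "skipped"

    if "isoforms" in run:
        assign_host_genes(circles, annotation)
        write_hostgene_outputs(summarize_host_genes(circles), prefix)
        status["isoforms"] = "done"
    else:
        status["isoforms"] = "skipped"

    if "clustering" in run:
        by_group: dict[str, list] = {"all": list(profiles)}
        for p in profiles:
            if len(p) == 0:
                continue
            by_group.setdefault(assign_length_group(p.circle_length_bp), []).append(p)
        cluster_sets = []
        cluster_summaries = []
        for group in ("all", "small", "medium", "long"):
            members = by_group.get(group, [])
            if not members:
                continue
            cs = cluster_group(members, group=group, n_bins=cfg.n_bins, seed=cfg.seed)
            cluster_sets.append(cs)
            cluster_summaries.extend(summarize_clusters(cs, lengths))
        write_cluster_outputs(cluster_sets, cluster_summaries, lengths, prefix)
        status["clustering"] = "done"
    else:
        status["clustering"] = "skipped"

    manifest = {
        "version": __version__,
        "sample": cfg.sample,
        "parameters": {
            "alignment": str(cfg.alignment),
            "annotation": str(cfg.annotation),
            "circle_table": str(cfg.circle_table) if cfg.circle_table else None,
            "dcc_count": str(cfg.dcc_count) if cfg.dcc_count else None,
            "dcc_junctions": [str(p) for p in cfg.dcc_junctions],
            "expected_fragment_length": cfg.expected_fragment_length,
            "n_bins": cfg.n_bins,
            "min_fragments": cfg.min_fragments,
        },
        "seed": cfg.seed,
        "n_circles": len(circles),
        "steps": status,
        "runtime_s": round(time.time() - t0, 2),
    }
    with open(out_dir / f"{cfg.sample}.manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
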