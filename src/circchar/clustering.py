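"""Length grouping and coverage-profile clustering.

All per-circle profiles are rescaled to a common number of bins,
normalized in amplitude, and clustered by K-means under the correlation
distance d(x, y) = 1 - Pearson(x, y). Clustering is run on all circles
together and, to keep it from merely grouping circles by length, also
within length groups: small (< 500 bp), medium (500-1,000 bp), long
(>= 1,000 bp). The number of clusters follows a fixed piecewise rule of
the group size: no clustering for up to two circles, 2 clusters for
3-9, 4 for 10-100, round(n / 20) capped at 10 beyond that. Clusters
whose mean profile is heavily one-sided around the back-splice junction
are flagged — an unbalanced junction suggests a non-circular origin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coverage import CoverageProfile

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterSet",
    "ClusterSummary",
    "assign_length_group",
    "choose_cluster_count",
    "normalize_profiles",
    "kmeans_correlation",
    "summarize_clusters",
    "cluster_group",
    "write_cluster_outputs",
]

LENGTH_GROUPS = ("small", "medium", "long")


def assign_length_group(circle_length_bp: int) -> str:
    """small: < 500 bp; medium: 500-1,000 bp; long: >= 1,000 bp."""
    if circle_length_bp <= 0:
        raise ValueError("circle length must be positive")
    if circle_length_bp < 500:
        return "small"
    if circle_length_bp < 1000:
        return "medium"
    return "long"


def _round_half_away(x: float) -> int:
    import math

    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def choose_cluster_count(n_circles: int) -> int | None:
    """Cluster count as a piecewise function of the group size.

    None (no clustering) for n <= 2; 2 for 3 <= n <= 9; 4 for
    10 <= n <= 100; round(n / 20), half away from zero, capped at 10,
    for n > 100 (applied as printed, even just above 100 where it gives
    5).
    """
    if n_circles < 1:
        raise ValueError("need at least one circle")
    if n_circles <= 2:
        return None
    if n_circles <= 9:
        return 2
    if n_circles <= 100:
        return 4
    return min(10, _round_half_away(n_circles / 20))


def normalize_profiles(
    profiles: Sequence[CoverageProfile], n_bins: int = 100
) -> tuple[np.ndarray, list[str]]:
    """Resample profiles onto a common relative-position grid.

    Each profile is linearly interpolated onto ``n_bins`` equally spaced
    positions in [0, 1] (normalizing by circle length) and scaled to a
    maximum of 1. All-zero profiles cannot be normalized and are
    excluded with a warning.

    Returns the (n_circles x n_bins) matrix and the matching circle ids.
    """
    if n_bins < 10:
        raise ValueError("n_bins must be at least 10")
    grid = np.linspace(0.0, 1.0, n_bins)
    rows = []
    ids = []
    for p in profiles:
        if len(p) == 0 or p.depth.max() == 0:
            logger.warning("circle %s: all-zero profile excluded from clustering", p.circle_id)
            continue
        y = np.interp(grid, p.rel_pos_circle, p.depth.astype(float))
        rows.append(y / y.max())
        ids.append(p.circle_id)
    if not rows:
        return np.empty((0, n_bins)), []
    return np.vstack(rows), ids


def _corr_dist(matrix: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Pairwise correlation distance 1 - Pearson(rows, centroids)."""

    def standardize(m: np.ndarray) -> np.ndarray:
        c = m - m.mean(axis=1, keepdims=True)
        n = np.linalg.norm(c, axis=1, keepdims=True)
        n[n == 0] = 1.0
        return c / n

    return 1.0 - standardize(matrix) @ standardize(centroids).T


def kmeans_correlation(
    matrix: np.ndarray,
    k: int,
    seed: int = 42,
    n_restarts: int = 10,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """K-means under centred-Pearson correlation distance.

    Centroids are per-cluster mean profiles; assignment minimizes
    1 - Pearson(profile, centroid). The best of ``n_restarts`` random
    initializations (by total within-cluster distance) is returned;
    deterministic for a given seed. Zero-variance rows have no defined
    correlation and are rejected upstream.

    Returns (labels in 0..k-1, centroids k x n_bins).
    """
    n = matrix.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds number of profiles ({n})")
    variances = matrix.var(axis=1)
    if np.any(variances == 0):
        raise ValueError("zero-variance profile rows; exclude them before clustering")

    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for _ in range(n_restarts):
        centroids = matrix[rng.choice(n, size=k, replace=False)].copy()
        labels = np.zeros(n, dtype=int)
        for _it in range(max_iter):
            dist = _corr_dist(matrix, centroids)
            new_labels = dist.argmin(axis=1)
            # empty-cluster repair: give it the worst-fitting point
            for c in range(k):
                if not np.any(new_labels == c):
                    worst = dist[np.arange(n), new_labels].argmax()
                    new_labels[worst] = c
            if np.array_equal(new_labels, labels) and _it > 0:
                break
            labels = new_labels
            for c in range(k):
                centroids[c] = matrix[labels == c].mean(axis=0)
        total = float(_corr_dist(matrix, centroids)[np.arange(n), labels].sum())
        if best is None or total < best[0]:
            best = (total, labels.copy(), centroids.copy())
    assert best is not None
    return best[1], best[2]


@dataclass
class ClusterSet:
    """One clustering run over one length group (or all circles)."""

    group: str  # small | medium | long | all
    circle_ids: list[str]
    profiles: np.ndarray  # n_circles x n_bins, normalized
    k: int | None
    assignments: np.ndarray | None  # labels 1..k, parallel to circle_ids
    centroids: np.ndarray | None
    seed: int

    @property
    def n_circles(self) -> int:
        return len(self.circle_ids)


@dataclass
class ClusterSummary:
    group: str
    cluster: int
    n_members: int
    median_length_bp: float
    mean_profile: np.ndarray
    unbalanced: bool


def cluster_group(
    profiles: Sequence[CoverageProfile],
    group: str = "all",
    n_bins: int = 100,
    seed: int = 42,
    n_restarts: int = 10,
) -> ClusterSet:
    """Normalize a set of profiles and cluster them (k from the size rule)."""
    matrix, ids = normalize_profiles(profiles, n_bins=n_bins)
    # constant profiles have no correlation structure; drop them
    if matrix.shape[0]:
        keep = matrix.var(axis=1) > 0
        for cid, ok in zip(ids, keep):
            if not ok:
                logger.warning("circle %s: constant profile excluded from clustering", cid)
        matrix = matrix[keep]
        ids = [cid for cid, ok in zip(ids, keep) if ok]
    k = choose_cluster_count(matrix.shape[0]) if matrix.shape[0] >= 1 else None
    if k is None:
        return ClusterSet(group, ids, matrix, None, None, None, seed)
    labels, centroids = kmeans_correlation(matrix, k, seed=seed, n_restarts=n_restarts)
    return ClusterSet(group, ids, matrix, k, labels + 1, centroids, seed)


def summarize_clusters(
    cluster_set: ClusterSet,
    lengths: Mapping[str, int],
    unbalance_factor: float = 3.0,
    edge_fraction: float = 0.10,
) -> list[ClusterSummary]:
    """Per-cluster mean profile, member count, median circle length.

    A cluster is flagged *unbalanced* when the mean coverage of the
    first ``edge_fraction`` of bins differs from the last by more than
    ``unbalance_factor`` — coverage piled on one side of the back-splice
    junction only.
    """
    if cluster_set.k is None or cluster_set.assignments is None:
        return []
    out = []
    n_edge = max(1, int(round(edge_fraction * cluster_set.profiles.shape[1])))
    for c in range(1, cluster_set.k + 1):
        mask = cluster_set.assignments == c
        members = [cid for cid, m in zip(cluster_set.circle_ids, mask) if m]
        mean_profile = cluster_set.profiles[mask].mean(axis=0)
        head = float(mean_profile[:n_edge].mean())
        tail = float(mean_profile[-n_edge:].mean())
        lo, hi = min(head, tail), max(head, tail)
        unbalanced = hi > unbalance_factor * max(lo, 1e-9)
        member_lengths = [lengths[cid] for cid in members if cid in lengths]
        out.append(
            ClusterSummary(
                group=cluster_set.group,
                cluster=c,
                n_members=int(mask.sum()),
                median_length_bp=float(np.median(member_lengths)) if member_lengths else float("nan"),
                mean_profile=mean_profile,
                unbalanced=unbalanced,
            )
        )
    return out


def write_cluster_outputs(
    cluster_sets: Sequence[ClusterSet],
    summaries: Sequence[ClusterSummary],
    lengths: Mapping[str, int],
    prefix: str | Path,
) -> tuple[Path, Path]:
    """Write cluster assignments and per-cluster mean profiles as TSV."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    assign_path = prefix.parent / (prefix.name + ".cluster_assignments.txt")
    mean_path = prefix.parent / (prefix.name + ".cluster_profiles.txt")

    rows = []
    for cs in cluster_sets:
        for i, cid in enumerate(cs.circle_ids):
            rows.append(
                {
                    "circle_id": cid,
                    "group": cs.group,
                    "cluster": int(cs.assignments[i]) if cs.assignments is not None else "",
                    "circle_length_bp": lengths.get(cid, ""),
                }
            )
    pd.DataFrame(rows, columns=["circle_id", "group", "cluster", "circle_length_bp"]).to_csv(
        assign_path, sep="\t", index=False
    )

    mrows = []
    for s in summaries:
        mrows.append(
            {
                "group": s.group,
                "cluster": s.cluster,
                "n_members": s.n_members,
                "median_length_bp": s.median_length_bp,
                "unbalanced": str(s.unbalanced).lower(),
                "mean_profile": ",".join(f"{v:.4f}" for v in s.mean_profile),
            }
        )
    pd.DataFrame(
        mrows,
        columns=["group", "cluster", "n_members", "median_length_bp", "unbalanced", "mean_profile"],
    ).to_csv(mean_path, sep="\t", index=False)
    return assign_path, mean_path
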