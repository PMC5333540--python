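"""Length groups, cluster-count rule, correlation k-means."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from circchar.clustering import (
    ClusterSet,
    assign_length_group,
    choose_cluster_count,
    kmeans_correlation,
    normalize_profiles,
    summarize_clusters,
)
from circchar.coverage import CoverageProfile


class TestLengthGroups:
    @pytest.mark.parametrize(
        "length,group",
        [(1, "small"), (499, "small"), (500, "medium"), (750, "medium"),
         (999, "medium"), (1000, "long"), (5000, "long")],
    )
    def test_boundaries(self, length, group):
        assert assign_length_group(length) == group

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            assign_length_group(0)


class TestClusterCountRule:
    @pytest.mark.parametrize(
        "n,k",
        [(1, None), (2, None), (3, 2), (7, 2), (9, 2), (10, 4), (50, 4),
         (100, 4), (101, 5), (110, 6), (120, 6), (150, 8), (199, 10),
         (200, 10), (300, 10), (5000, 10)],
    )
    def test_piecewise_rule(self, n, k):
        assert choose_cluster_count(n) == k

    def test_below_one_rejected(self):
        with pytest.raises(ValueError):
            choose_cluster_count(0)

    @given(n=st.integers(1, 5000))
    @settings(max_examples=300, deadline=None)
    def test_total_and_capped(self, n):
        k = choose_cluster_count(n)
        assert k is None or 2 <= k <= 10


def _profile(depths, circle_id="c"):
    depths = np.asarray(depths)
    n = len(depths)
    return CoverageProfile(
        circle_id=circle_id,
        exon_number=np.ones(n, dtype=int),
        rel_pos_circle=np.arange(n) / max(n - 1, 1),
        rel_pos_exon=np.arange(n) / max(n - 1, 1),
        depth=depths,
        circle_length_bp=n,
    )


class TestNormalize:
    def test_common_length(self):
        m, ids = normalize_profiles(
            [_profile(np.ones(200), "a"), _profile(np.ones(2000), "b")], n_bins=50
        )
        assert m.shape == (2, 50)
        assert ids == ["a", "b"]

    def test_constant_profile_becomes_ones(self):
        m, _ = normalize_profiles([_profile(np.full(300, 7))], n_bins=20)
        assert np.allclose(m[0], 1.0)

    def test_ramp_matches_interpolation_oracle(self):
        n = 777
        ramp = np.arange(n)
        m, _ = normalize_profiles([_profile(ramp)], n_bins=100)
        grid = np.linspace(0, 1, 100)
        oracle = np.interp(grid, np.arange(n) / (n - 1), ramp / ramp.max())
        assert np.allclose(m[0], oracle)

    def test_all_zero_profile_excluded(self, caplog):
        with caplog.at_level("WARNING"):
            m, ids = normalize_profiles([_profile(np.zeros(50), "z")], n_bins=20)
        assert m.shape[0] == 0 and ids == []


def _two_families(n_per=10, n_bins=60, noise=0.05, seed=0):
    rng = np.random.default_rng(seed)
    x = np.linspace(0, 1, n_bins)
    bell = np.exp(-((x - 0.5) ** 2) / 0.02)
    spike = np.exp(-(x**2) / 0.01) + np.exp(-((x - 1) ** 2) / 0.01)
    rows, labels = [], []
    for i in range(n_per):
        rows.append(bell + noise * rng.random(n_bins))
        labels.append(0)
        rows.append(spike + noise * rng.random(n_bins))
        labels.append(1)
    m = np.vstack(rows)
    return m / m.max(axis=1, keepdims=True), np.array(labels)


class TestKmeansCorrelation:
    def test_recovers_two_families_perfectly(self):
        m, truth = _two_families()
        labels, centroids = kmeans_correlation(m, k=2, seed=1)
        assert adjusted_rand_score(truth, labels) == 1.0
        assert centroids.shape == (2, m.shape[1])

    def test_k_equals_n_zero_distance(self):
        rng = np.random.default_rng(4)
        m = rng.random((5, 30))
        labels, centroids = kmeans_correlation(m, k=5, seed=2)
        assert sorted(labels) == [0, 1, 2, 3, 4]
        from circchar.clustering import _corr_dist

        total = _corr_dist(m, centroids)[np.arange(5), labels].sum()
        assert total == pytest.approx(0.0, abs=1e-9)

    def test_duplicated_rows_share_label(self):
        m, _ = _two_families(n_per=4)
        m = np.vstack([m, m[0], m[0]])
        labels, _ = kmeans_correlation(m, k=2, seed=3)
        assert labels[0] == labels[-1] == labels[-2]

    def test_row_order_invariance_up_to_relabeling(self):
        m, _ = _two_families(n_per=6, seed=5)
        labels_a, _ = kmeans_correlation(m, k=2, seed=7)
        perm = np.random.default_rng(0).permutation(m.shape[0])
        labels_b, _ = kmeans_correlation(m[perm], k=2, seed=7)
        assert adjusted_rand_score(labels_a[perm], labels_b) == 1.0

    def test_k_larger_than_rows_rejected(self):
        with pytest.raises(ValueError):
            kmeans_correlation(np.random.default_rng(0).random((3, 10)), k=4)

    def test_zero_variance_row_rejected(self):
        m = np.vstack([np.ones(10), np.random.default_rng(0).random(10)])
        with pytest.raises(ValueError, match="zero-variance"):
            kmeans_correlation(m, k=2)


class TestSummaries:
    def test_identical_profiles_mean_and_median_length(self):
        row = np.linspace(0.2, 1.0, 40)
        m = np.vstack([row] * 3)
        cs = ClusterSet(
            group="small", circle_ids=["a", "b", "c"], profiles=m, k=1,
            assignments=np.array([1, 1, 1]), centroids=m[:1], seed=0,
        )
        out = summarize_clusters(cs, {"a": 500, "b": 560, "c": 600})
        assert len(out) == 1
        assert np.allclose(out[0].mean_profile, row)
        assert out[0].median_length_bp == 560

    def test_unbalanced_flag(self):
        n = 50
        onesided = np.concatenate([np.full(25, 1.0), np.full(25, 0.05)])
        bell = np.exp(-((np.linspace(0, 1, n) - 0.5) ** 2) / 0.05)
        m = np.vstack([onesided, bell])
        cs = ClusterSet(
            group="all", circle_ids=["fp", "ok"], profiles=m, k=2,
            assignments=np.array([1, 2]), centroids=m, seed=0,
        )
        out = summarize_clusters(cs, {"fp": 300, "ok": 300})
        assert out[0].unbalanced is True
        assert out[1].unbalanced is False

    def test_fp_fixture_cluster_is_flagged_unbalanced(self, tmp_path):
        """One-sided trans-splice-like circles land in a flagged cluster."""
        from circchar.coverage import exonwise_coverage, positionwise_coverage
        from circchar.extract import extract_circle_reads
        from circchar.io import read_circle_table, read_exon_annotation
        from circchar.simulate import make_false_positive_fixture

        out = make_false_positive_fixture(
            seed=2, out_dir=tmp_path, n_fp=6, n_true=12, n_fragments_per_circle=30
        )
        circles = read_circle_table(out.circle_table_path)
        annotation = read_exon_annotation(out.annotation_path)
        read_sets, _ = extract_circle_reads(out.sam_path, circles, tmp_path / "bams")
        profiles = [
            positionwise_coverage(rs, exonwise_coverage(rs, annotation))
            for rs in read_sets
        ]
        matrix, ids = normalize_profiles(profiles)
        labels, centroids = kmeans_correlation(matrix, k=2, seed=2)
        cs = ClusterSet("all", ids, matrix, 2, labels + 1, centroids, seed=2)
        lengths = {cid: out.truth.circles[cid].transcript_length for cid in ids}
        flags = {}
        for summary in summarize_clusters(cs, lengths):
            members = [
                cid for cid, lab in zip(ids, labels + 1) if lab == summary.cluster
            ]
            is_fp_cluster = all(
                out.truth.circles[cid].is_false_positive for cid in members
            )
            flags[is_fp_cluster] = summary.unbalanced
        assert flags[True] is True      # the all-FP cluster is unbalanced
        assert flags[False] is False    # the genuine cluster is not
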