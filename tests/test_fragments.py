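"""Single- vs double-breakpoint fragments and the suspect-circle rule."""

import numpy as np
import pytest

from circchar.core import Circle, GenomicInterval
from circchar.extract import CircleReadSet, extract_circle_reads
from circchar.fragments import (
    FragmentSummary,
    classify_fragments,
    estimate_circle_length,
    flag_suspect_circles,
    junction_spanning_from_alignments,
    junction_spanning_from_junctions,
    write_mate_status,
)
from circchar.io import read_circle_table, read_exon_annotation, read_junction_file
from circchar.simulate import double_fraction_oracle, simulate_circles


def _read_set(names, start=0, end=500):
    circle = Circle.from_coords("chrX", start, end, set(names))
    return CircleReadSet(circle=circle, alignments=[])


class TestClassifyFragments:
    def test_both_mates_spanning_is_double(self):
        s = classify_fragments(_read_set(["f1"]), {"f1": {1, 2}})
        assert (s.n_double, s.n_single) == (1, 0)

    def test_one_mate_spanning_is_single(self):
        s = classify_fragments(_read_set(["f1"]), {"f1": {1}})
        assert (s.n_double, s.n_single) == (0, 1)

    def test_unpaired_read_counts_single(self):
        s = classify_fragments(_read_set(["f1"]), {"f1": {0}})
        assert (s.n_double, s.n_single) == (0, 1)

    def test_empty_read_set(self):
        s = classify_fragments(_read_set([]), {})
        assert s.n_fragments == 0
        assert s.double_fraction is None

    def test_unsupported_read_excluded_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            s = classify_fragments(_read_set(["f1", "f2"]), {"f1": {1, 2}})
        assert s.n_fragments == 1
        assert any("no junction-spanning mate" in r.message for r in caplog.records)

    def test_counting_conservation(self):
        spanning = {f"f{i}": ({1, 2} if i % 3 == 0 else {1}) for i in range(30)}
        s = classify_fragments(_read_set(list(spanning)), spanning)
        assert s.n_single + s.n_double == 30


class TestCircleLength:
    def test_worked_example_covered_exons_sum_400(
        self, skip_example_read_sets, skip_example_annotation
    ):
        from circchar.coverage import exonwise_coverage

        rs = skip_example_read_sets[0][0]
        rows = exonwise_coverage(rs, skip_example_annotation)
        assert estimate_circle_length(rs.circle, skip_example_annotation, rows) == 400

    def test_fallback_is_genomic_span(self):
        circle = Circle.from_coords("chrZ", 100, 800, {"r"})
        assert estimate_circle_length(circle) == 700

    def test_single_exon(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chrZ\t200\t350\tg\t0\t+\n")
        ann = read_exon_annotation(p)
        circle = Circle.from_coords("chrZ", 100, 800, {"r"})
        assert estimate_circle_length(circle, ann) == 150


class TestSuspectRule:
    @pytest.mark.parametrize(
        "length,n_single,n_double,expected",
        [
            (300, 5, 0, True),    # short, only singles -> suspect
            (300, 2, 3, False),   # doubles present
            (2000, 5, 0, False),  # fragment cannot wrap the circle
            (300, 1, 0, False),   # below min_fragments: no power
        ],
    )
    def test_rule(self, length, n_single, n_double, expected):
        s = FragmentSummary("c", n_single, n_double, circle_length_bp=length)
        assert flag_suspect_circles(s, expected_fragment_length=350) is expected

    def test_invalid_fragment_length(self):
        s = FragmentSummary("c", 1, 0, circle_length_bp=100)
        with pytest.raises(ValueError):
            flag_suspect_circles(s, expected_fragment_length=0)


@pytest.fixture(scope="module")
def noiseless_sim(tmp_path_factory):
    d = tmp_path_factory.mktemp("fragsim")
    out = simulate_circles(
        n_circles=6, length_grid=[250, 600, 1200], n_fragments_per_circle=25,
        seed=9, out_dir=d,
    )
    circles = read_circle_table(out.circle_table_path)
    read_sets, _ = extract_circle_reads(out.sam_path, circles, d / "bams")
    return out, read_sets


class TestTruthRecovery:
    def test_junction_file_channel_recovers_truth_exactly(self, noiseless_sim):
        out, read_sets = noiseless_sim
        junctions = [
            j
            for path, mate in zip(out.junction_paths, (1, 2))
            for j in read_junction_file(path, mate=mate)
        ]
        for rs in read_sets:
            spanning = junction_spanning_from_junctions(junctions, rs.circle)
            s = classify_fragments(rs, spanning)
            truth = out.truth.circles[rs.circle.circle_id]
            expect_double = sum(1 for v in truth.fragment_class.values() if v == "double")
            assert s.n_double == expect_double
            assert s.n_fragments == len(truth.fragment_class)

    def test_alignment_channel_agrees_with_truth(self, noiseless_sim):
        out, read_sets = noiseless_sim
        for rs in read_sets:
            s = classify_fragments(rs, junction_spanning_from_alignments(rs))
            truth = out.truth.circles[rs.circle.circle_id]
            expect_double = sum(1 for v in truth.fragment_class.values() if v == "double")
            assert s.n_double == expect_double

    def test_truth_classes_match_enumeration_oracle(self, noiseless_sim):
        """Simulated double fractions track the all-cut-positions enumeration."""
        out, _ = noiseless_sim
        for truth in out.truth.circles.values():
            p_double, p_any = double_fraction_oracle(
                truth.transcript_length, fragment_length=350, read_length=150
            )
            expected = p_double / p_any if p_any else 0.0
            n = len(truth.fragment_class)
            observed = (
                sum(1 for v in truth.fragment_class.values() if v == "double") / n
            )
            # binomial tolerance at n=25
            assert abs(observed - expected) <= 4 * np.sqrt(
                max(expected * (1 - expected), 0.01) / n
            )


def test_write_mate_status(tmp_path):
    s = FragmentSummary("c1", 3, 1, circle_length_bp=400, suspect_flag=False)
    path = write_mate_status([s], tmp_path / "x")
    lines = path.read_text().splitlines()
    assert lines[0].startswith("circle_id")
    assert lines[1].split("\t") == ["c1", "3", "1", "4", "0.2500", "400", "false"]
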