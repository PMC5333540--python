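"""Exon-skipping detection within circle boundaries."""

import numpy as np
import pytest
from scipy import stats

from circchar.core import Circle, Exon, GenomicInterval, IntronCall
from circchar.extract import CircleReadSet, extract_circle_reads
from circchar.io import read_circle_table, read_exon_annotation
from circchar.simulate import simulate_circles
from circchar.skipping import (
    assign_isoform_support,
    detect_skipped_exons,
    infer_introns,
    write_skip_outputs,
)


@pytest.fixture(scope="module")
def worked_example_calls(skip_example_read_sets, skip_example_annotation):
    read_sets, _ = skip_example_read_sets
    rs = read_sets[0]
    introns = infer_introns(rs)
    candidates = detect_skipped_exons(introns, skip_example_annotation, rs.circle)
    return rs, introns, candidates


class TestWorkedExample:
    def test_four_distinct_introns(self, worked_example_calls):
        _, introns, _ = worked_example_calls
        got = {(i.interval.start, i.interval.end) for i in introns}
        assert got == {(400, 500), (600, 700), (800, 900), (400, 700)}

    def test_single_candidate_is_exon3(self, worked_example_calls):
        _, _, candidates = worked_example_calls
        assert len(candidates) == 1
        intron, exon = candidates[0]
        assert (exon.interval.start, exon.interval.end) == (500, 600)
        assert exon.exon_number == 3
        assert (intron.interval.start, intron.interval.end) == (400, 700)

    def test_two_of_five_reads_skip(self, worked_example_calls):
        rs, _, candidates = worked_example_calls
        call = assign_isoform_support(rs, candidates[0])
        assert call.n_skip == 2
        assert call.n_total == 5
        assert call.proportion_skipping == pytest.approx(0.4)
        assert call.skipping_reads == {"r4", "r5"}
        assert call.n_uninformative == 0

    def test_outputs_contain_counts_and_invariants(self, worked_example_calls, tmp_path):
        rs, _, candidates = worked_example_calls
        call = assign_isoform_support(rs, candidates[0])
        bed, txt = write_skip_outputs([call], tmp_path / "ex")
        lines = txt.read_text().splitlines()
        assert len(lines) == 2
        fields = lines[1].split("\t")
        assert fields[9] == "2" and fields[10] == "5"
        bed_fields = bed.read_text().split("\t")
        assert bed_fields[4] == "40"  # round(100 * 0.4)
        # containment invariants on every output row
        assert call.intron.contains(call.exon.interval)
        assert call.circle_interval.contains(call.intron)

    def test_empty_calls_write_header_only(self, tmp_path):
        bed, txt = write_skip_outputs([], tmp_path / "none")
        assert bed.read_text() == ""
        assert len(txt.read_text().splitlines()) == 1


def _toy_read_set(alignments, start=0, end=1000):
    circle = Circle.from_coords("chrX", start, end, {a.read_name for a in alignments})
    from circchar.core import ChimericAlignment

    return CircleReadSet(circle=circle, alignments=alignments)


def _aln(name, segs, mate=0):
    from circchar.core import ChimericAlignment

    return ChimericAlignment(
        read_name=name,
        mate=mate,
        segments=[GenomicInterval("chrX", s, e) for s, e in segs],
    )


class TestInferIntrons:
    def test_gapless_reads_yield_no_introns(self):
        rs = _toy_read_set([_aln("a", [(10, 100)]), _aln("b", [(200, 400)])])
        assert infer_introns(rs) == []

    def test_identical_gaps_merge_support(self):
        rs = _toy_read_set(
            [_aln("a", [(10, 100), (200, 300)]), _aln("b", [(50, 100), (200, 250)])]
        )
        introns = infer_introns(rs)
        assert len(introns) == 1
        assert introns[0].supporting_reads == {"a", "b"}

    def test_gap_crossing_circle_boundary_dropped(self, caplog):
        rs = _toy_read_set([_aln("a", [(10, 100), (1100, 1200)])], start=0, end=1000)
        with caplog.at_level("WARNING"):
            introns = infer_introns(rs)
        assert introns == []
        assert any("outside the circle" in r.message for r in caplog.records)


class TestDetectSkippedExons:
    def _annotation(self, exons):
        from circchar.core import ExonAnnotation

        return ExonAnnotation(
            exons=[
                Exon(GenomicInterval("chrX", s, e), "g", i + 1)
                for i, (s, e) in enumerate(exons)
            ]
        )

    def test_partial_overlap_is_not_a_candidate(self):
        intron = IntronCall(GenomicInterval("chrX", 100, 300), {"a"})
        ann = self._annotation([(250, 400)])  # half-overlaps the intron
        circle = Circle.from_coords("chrX", 0, 1000, {"a"})
        assert detect_skipped_exons([intron], ann, circle) == []

    def test_contained_exon_is_a_candidate(self):
        intron = IntronCall(GenomicInterval("chrX", 100, 300), {"a"})
        ann = self._annotation([(150, 250)])
        circle = Circle.from_coords("chrX", 0, 1000, {"a"})
        out = detect_skipped_exons([intron], ann, circle)
        assert len(out) == 1

    def test_no_contained_exon_empty(self):
        intron = IntronCall(GenomicInterval("chrX", 100, 300), {"a"})
        ann = self._annotation([(500, 600)])
        circle = Circle.from_coords("chrX", 0, 1000, {"a"})
        assert detect_skipped_exons([intron], ann, circle) == []


def _measure_skip_proportion(tmp_path, skip_fraction, seed, n_reads=200):
    out = simulate_circles(
        n_circles=1,
        length_grid=[300],
        fragment_length=350,
        read_length=250,
        skip_fraction=skip_fraction,
        n_fragments_per_circle=n_reads,
        seed=seed,
        out_dir=tmp_path,
    )
    circles = read_circle_table(out.circle_table_path)
    annotation = read_exon_annotation(out.annotation_path)
    read_sets, _ = extract_circle_reads(out.sam_path, circles, tmp_path / "bams")
    rs = read_sets[0]
    candidates = detect_skipped_exons(infer_introns(rs), annotation, rs.circle)
    truth = next(iter(out.truth.circles.values()))
    # exactly one skipped-exon candidate: the middle exon
    mids = {(e.interval.start, e.interval.end) for _, e in candidates}
    assert (truth.skipped_exon.start, truth.skipped_exon.end) in mids
    call = next(
        assign_isoform_support(rs, c)
        for c in candidates
        if c[1].interval.start == truth.skipped_exon.start
    )
    return call, truth


def test_simulated_proportion_within_binomial_interval(tmp_path):
    """At n = 200 reads the estimate sits in the exact binomial 99% band."""
    call, truth = _measure_skip_proportion(tmp_path, skip_fraction=0.3, seed=5)
    lo, hi = stats.binom.interval(0.99, call.n_total, 0.3)
    assert lo <= call.n_skip <= hi
    assert call.skipping_reads == truth.skipping_reads
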