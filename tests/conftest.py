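import pytest

from circchar.extract import extract_circle_reads
from circchar.io import read_circle_table, read_exon_annotation
from circchar.simulate import make_exon_skip_example


@pytest.fixture(scope="session")
def skip_example(tmp_path_factory):
    """The five-read, two-isoform worked example dataset."""
    d = tmp_path_factory.mktemp("skip_example")
    return make_exon_skip_example(d)


@pytest.fixture(scope="session")
def skip_example_read_sets(skip_example, tmp_path_factory):
    """Per-circle read sets extracted from the worked example."""
    d = tmp_path_factory.mktemp("skip_example_bams")
    circles = read_circle_table(skip_example.circle_table_path)
    read_sets, summary = extract_circle_reads(
        skip_example.sam_path, circles, d, sample="ex"
    )
    return read_sets, summary


@pytest.fixture(scope="session")
def skip_example_annotation(skip_example):
    return read_exon_annotation(skip_example.annotation_path)
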