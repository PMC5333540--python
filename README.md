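# circchar

Characterization of circular RNA candidates from RNA-seq alignments.

Circular RNAs (circRNAs) arise from back-splicing: a downstream 5′
splice site is joined to an upstream 3′ splice site, producing a
circular transcript. Detection tools find the diagnostic back-splice
junction reads, but stop there — they say nothing about the internal
structure of the circle, whether two isoforms share one junction, or
whether a junction is even likely to come from a circle at all.
`circchar` starts where detection ends. Given

1. a SAM/BAM file of chimerically mapped reads (it may also contain
   linear and unmapped reads),
2. either a two-column circle table (`circleID<TAB>read1,read2,...`) or
   a detector's count table plus STAR-layout chimeric-junction files, and
3. a BED6/BED12 exon annotation,

it produces, per circle:

- **one sorted, indexed BAM** holding exactly the reads that support
  that circle (filtered by read name *and* positional overlap, so
  same-named multimappers elsewhere are excluded);
- **alternatively spliced exons within the circle boundaries**: all
  linear splice gaps of the circle's reads are collected; an annotated
  exon fully contained in a gap is called skipped, and every read is
  assigned to the skipping or inclusion isoform, giving
  n_skip / n_total;
- **single- vs double-breakpoint fragment counts**: a fragment whose
  two mates both span the back-splice can only come from a circular
  molecule, and this is only geometrically possible when the circle
  length ≤ the library fragment length; short circles supported *only*
  by single-breakpoint fragments are flagged as suspect;
- **host-gene isoform summaries**: circles grouped per gene, with every
  pair classified as same-start, same-end, within, overlapping or
  non-overlapping;
- **exon-wise and position-wise coverage profiles**, and
- **coverage-profile clusters**: profiles are length-normalized to a
  common grid and clustered with K-means under correlation distance
  d(x, y) = 1 − r(x, y), on all circles and within length groups
  (small < 500 bp, medium 500–1,000 bp, long ≥ 1,000 bp); clusters with
  a one-sided ("junction-unbalanced") mean profile point at likely
  false-positive candidates.

A synthetic-data module (`circchar.simulate`) generates toy chromosomes,
annotations and chimeric paired-end alignments with known truth, so the
whole pipeline runs and is tested without any real sequencing data.

## Worked example

`examples/01_exon_skipping.py` builds a toy circle over exons 2–5 of a
five-exon gene, supported by five junction-spanning reads, two of which
splice directly from exon 2 to exon 4:

```
circle chrT:300|1000: 4 distinct introns
  intron [400, 500)  supported by ['r1', 'r3']
  intron [400, 700)  supported by ['r4', 'r5']
  intron [600, 700)  supported by ['r1', 'r2']
  intron [800, 900)  supported by ['r2', 'r5']
skipped exon 3 [500, 600): 2 of 5 reads skip it (proportion 0.40)
```

The four gaps are the introns between exons 2–3, 3–4, 4–5 and 2–4; only
the 2–4 gap fully contains an annotated exon, so exon 3 is called
skipped, and the 2/5 proportion is the relative support of the
exon-skipping circular isoform sharing the same back-splice junction.
`examples/02_fragment_evidence.py` and
`examples/03_false_positive_screening.py` demonstrate the
double-breakpoint geometry and the false-positive screen the same way.

## Command line

```bash
circchar run --bam reads.bam --circles circles.tsv --annotation exons.bed \
    --sample mysample --out results/ --fragment-length 350 \
    [--dcc-count CircRNACount --dcc-junctions mate1.junction,mate2.junction] \
    [--skip-steps clustering] [--seed 42] [--bins 100] [--plots]
```

Steps (`skipped_exons`, `mate_pairs`, `isoforms`, `coverage`,
`clustering`) can be skipped individually; clustering requires coverage.
A manifest JSON records the version, parameters, seed and per-step
status; re-running with the same configuration reproduces all tabular
outputs byte for byte.

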