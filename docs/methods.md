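# Methods

## Scope and model

`circchar` characterizes circRNA candidates *after* mapping and
back-splice detection. Its unit of analysis is a **circle**: a genomic
interval (chrom, start, end), identified as `chrom:start|end`, plus the
names of the reads spanning its back-splice junction. All internal
coordinates are 0-based half-open; 1-based sources (SAM POS, STAR
chimeric-junction columns) are converted at the reader boundary so no
off-by-one arithmetic leaks between stages. Strand is carried through
but never used to match reads to circles — chimeric alignments at a
back-splice do not carry reliable strand information, and nothing in
the downstream procedures needs it.

## Per-circle read extraction

A record enters a circle's BAM when its read name is on the circle's
list **and** its aligned span overlaps the circle interval. The
positional condition is what removes same-named multimappers aligned
elsewhere. Unmapped records are dropped; secondary records are dropped
by default (configurable); supplementary records are kept because they
carry the second arm of a chimeric alignment. Output BAMs are
coordinate-sorted and indexed.

## Alternative splicing within circle boundaries

Aligned blocks are obtained by splitting each CIGAR on skip (`N`)
operations; deletions shorter than 30 bp (configurable) are treated as
alignment noise and bridged, longer deletions split blocks like `N`.
Every inter-block gap inside the circle is an observed intron; gaps
crossing a circle boundary contradict the back-splice and are dropped
with a warning. An annotated exon **fully contained** in an intron is a
skipped-exon candidate — containment, not mere overlap, because a gap
that only clips an exon edge is ambiguous alignment rather than
skipping. Each read is then assigned to the skipping isoform (it
carries a gap containing the exon), the inclusion isoform (a block
overlaps the exon body), or neither; the reported proportion is
n_skip / n_total over all distinct reads, with the uninformative count
reported separately since short junction-only fragments cannot always
be assigned.

## Mate-pair (fragment) evidence

Each distinct read name is one fragment. A mate "spans the back-splice"
when (preferred) a chimeric-junction record for this circle names it,
or when its split alignment covers both the region ending at the
circle's end and the region starting at the circle's start (±5 bp).
Fragments with both mates spanning are *double-breakpoint* — strong
evidence of circularity; one spanning mate is *single* (inconclusive);
unpaired reads are necessarily single. The transcribed circle length is
the summed length of covered annotated exons clipped to the circle
(genomic span as fallback). The suspect rule: a circle is flagged iff
circle length ≤ expected fragment length, no double-breakpoint fragment
was observed, and at least `min_fragments` (default 2, below which the
demand has no power) fragments exist. The expected fragment length is
library-dependent and therefore a required user parameter with no
default inference.

## Host-gene isoforms

A gene hosts a circle when one of its exons overlaps the circle
interval; circles may have zero, one or several host genes, and
multi-host circles count in each gene's summary. Every non-identical
pair of circles of one gene receives exactly one category with
precedence same_start > same_end > within > overlapping >
non_overlapping; containment sharing a boundary is reported by the
shared boundary. `non_overlapping` is an added fifth category for
disjoint pairs (which do occur) so the classification is total; it is
tallied separately so four-category totals remain comparable.

## Coverage profiles

Depth counts alignment segments (each mate separately); fragment-level
depth is deliberately not used. The transcribed coordinate of a circle
concatenates its covered annotated exons in genomic order (a pseudo-exon
equal to the genomic span when no annotation overlaps); bases outside
covered exons are excluded. Per exon the table reports read count
(≥ 1 bp overlap), mean per-base depth and fraction of bases covered;
per base the profile reports exon number, relative position in circle
and in exon (both spanning [0, 1] inclusive), and depth. Exon-wise mean
depth equals the mean of position-wise depths over that exon's bases by
construction, and the profile is checked in the tests against a direct
per-base pileup loop. Plot smoothing is a centred rolling mean with
window max(3, circle_length/50) bases — presentation only, never fed
back into any computation.

## Profile clustering

Profiles are linearly interpolated onto `n_bins` (default 100) equally
spaced relative positions and scaled to maximum 1; all-zero and
constant profiles have no correlation structure and are excluded with a
warning. K-means uses the centred-Pearson correlation distance
d(x, y) = 1 − r(x, y) with per-cluster mean centroids, empty-cluster
repair (the worst-fitting point is reassigned), 10 random restarts
scored by total within-cluster distance, and a fixed default seed (42)
exposed as a parameter. The distance choice is part of the method, so
the K-means is implemented here rather than delegated to a library that
only supports Euclidean distance. The cluster count is a piecewise
function of group size: ≤ 2 circles — no clustering; 3–9 — 2; 10–100 —
4; above 100 — round(n/20), half away from zero (so the rule is stable
across platforms at, e.g., n = 110), capped at 10 and applied exactly
as stated even just above 100 where it yields 5. Clustering runs on all
circles and within length groups (small < 500 bp, medium 500–1,000 bp,
long ≥ 1,000 bp), because the all-circles clustering mostly recovers
length. A cluster is flagged *junction-unbalanced* when the mean
coverage of the first 10% of bins and of the last 10% differ by more
than a factor of 3 (both configurable); flagged clusters are surfaced
for the user's eye, never removed automatically.

## Synthetic data

The simulator emulates a random-fragmentation library: each fragment is
cut at a uniformly random integer position on the circularized
transcript; mate 1 is the first `read_length` bases, mate 2 the last;
a mate spans the back-splice exactly when its linearized coordinates
wrap the junction with ≥ 10 bases on each side (an aligner's minimum
overhang; shorter arms are soft-clipped rather than emitted, as a real
aligner would). Reads longer than the transcript are capped at one full
rotation — the physical rolling-circle case, which is represented but
not separately quantified. Spanning mates are written as a primary plus
a supplementary SAM record with complementary soft-clips, together with
per-mate STAR-layout junction TSVs and a count table, so both evidence
channels of the fragment analysis and both input paths of the readers
are exercised. There is no sequencing-error model: no downstream
procedure uses base qualities or mismatches, and coverage noise enters
only through random fragment positions. Consequences for
interpretation: passing tests demonstrate the correctness of the
interval logic, the counting and the geometry under ideal alignments —
they say nothing about robustness to mis-mapping, soft-clip ambiguity
at real junctions, or annotation errors, which real data would add.

Default study conditions, chosen once: fragment length 350 bp and read
length 150 bp for fragment-geometry simulations; the skip-recovery
setting uses three-exon circles (inclusive transcript 300 bp, middle
exon ~L/3, 100 bp introns) with 250 bp reads — read lengths of this
order are what make long-read circRNA libraries informative, and at
250 bp every junction-spanning read covers the middle exon's flanks, so
the estimated proportion is the plain binomial proportion and recovery
is tested against the exact binomial interval. The false-positive
fixture emulates trans-splice-like junctions: every fragment has
exactly one chimeric mate with a 15 bp far-side anchor (a typical
minimum junction overhang) and a linear mate on the near side only,
giving one-sided coverage and single-breakpoint-only support; it is
mixed with genuine circles of medium length so the separation under
clustering is shape-driven, not length-driven.

## Numerical and degenerate-input choices

- `double_fraction` is undefined (reported as missing) for circles with
  zero classified fragments.
- Reads on a circle's list with no junction-spanning mate should not be
  there; they are excluded from fragment counting with a warning.
- DCC-style junction matching uses a ±1 bp tolerance after coordinate
  conversion (configurable) because upstream tools differ in whether
  positions are 0- or 1-based; a read matching several circles is kept
  in all of them and logged rather than silently dropped.
- Ties in k-means restarts resolve to the first-best restart;
  determinism is guaranteed by seeding every random draw.
- Problem sizes in the test suite (up to 50 simulated circles, 200
  fragments per circle, 20 seeds per recovery experiment) are chosen so
  the binomial/enumeration oracles are decisive while the whole suite
  runs in seconds.

## Known limitations

- Only annotated exons can be called skipped; novel exons and intron
  retention are out of scope.
- No transcript-model reconstruction: the transcribed length is an
  exon-coverage estimate, not an assembled isoform.
- Rolling-circle amplification is represented in simulation but not
  detected or quantified.
- The statistical question "does this host-gene produce more circles
  than average" is left to the user; the package only tabulates.
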