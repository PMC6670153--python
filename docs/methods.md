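# Methods

## Coordinate model

All internal coordinates are 0-based half-open on the forward genomic
strand, matching BED. Region tables may declare rows as `0-half-open` or
`1-closed`; 1-closed rows are converted at the boundary (`start ← start −
1`) and the conversion is self-inverse. Strand labels are always genomic;
sense-to-gene annotations are derived from a region's declared host-gene
strand. For a minus-strand host gene the Roman module labels I, II, …
run in gene sense, i.e. against genomic coordinates (a
`label_orientation="genomic"` switch restores plain genomic labelling).

## Prevalence counting

Inputs are pre-called hotspot intervals, not signal tracks; no peak
calling or thresholding happens here. The overlap rule is ≥ 1 bp: a
hotspot spanning a module boundary counts in every module it touches,
and several hotspots of one cell type in one module count once. This is
the most inclusive deterministic rule consistent with counting "cell
types with at least one hotspot per module"; it is declared, since
visual counting on a genome browser cannot resolve the boundary case.
Counts are not width-normalized, and the truncated last module reports
its true width. Counting is exact (verified against a per-base
brute-force oracle on randomized instances) and invariant to track
order; adding tracks or widening hotspots can only increase counts.

## Initiator scanning

The initiator element is modelled as a 7-column position frequency
matrix with consensus YYANWYY and the +1 base (an A) at offset 2. The
shipped matrix is a canonical initiator profile written for this
package; promoter-prediction servers keep their matrices private, so the
matrix is a configurable input (`load_pwm`) and counts on real sequence
are only comparable after calibrating to whatever matrix produced the
reference numbers. Scores use max-ratio normalization — the product of
per-position probabilities divided by the product of column maxima — so
the consensus scores exactly 1.0 and a cutoff of 0.99 has an absolute
meaning independent of motif width; log-odds scoring is deliberately not
the default. Rows are smoothed with pseudocount 0.01. An `N` residue
scores its column's minimum probability (conservative). Both strands are
scanned by default; minus-strand hits are scored on the reverse
complement and their +1 position mapped back to forward coordinates. All
windows at or above the cutoff are reported without merging.

## TSS profiling

CAGE-HMM predictions arrive as stranded BED6 intervals, possibly wider
than 1 bp; each is reduced to its 5′ end in transcription sense (start
for `+`, end − 1 for `−`) before module assignment — a fixed, declared
rule, since wide predictions rarely straddle 2.5-kb boundaries but the
assignment must be deterministic. Counts are totals over cell types with
no cross-cell-type deduplication (bar-chart semantics); a `dedupe`
switch collapses identical (position, strand) calls when a per-site view
is wanted. Column sums over modules plus the outside tally always equal
the number of loaded predictions.

## EST consensus

Scoring is fixed at match +1, mismatch −1, gap −2 with free end gaps —
standard defaults for fragments of one transcript, declared because no
single convention exists. The pairwise aligner is an overlap-mode
dynamic program; traceback tie-breaks are diagonal > up > left, and
among equal-scoring end cells the one aligning the most of both
sequences wins, making every output deterministic. The multiple
alignment is center-star: the center maximizes summed pairwise scores
(first on ties), others merge under "once a gap, always a gap", with
leading gap runs right-aligned against the center start so staggered
fragments tile correctly; projecting any row against the center
reproduces its optimal pairwise score. Consensus calling drops columns
with non-gap depth < 2, calls the majority residue when its support
among non-gap rows is ≥ 0.5 and unique, and writes N otherwise.
Minus-strand ESTs are reverse-complemented into transcript orientation
before alignment. Transcript matching is Smith–Waterman local alignment
under the same scheme, ties broken by input order; identity counts
matching columns over all aligned columns, so N calls score as
mismatches.

## In-silico PCR

Sequence matching only: no melting-temperature or efficiency model (the
wet-lab annealing temperature is deliberately not represented).
Mismatches are allowed uniformly along a primer except the 3′-terminal
base, which must pair exactly (polymerase extension realism); the
default is zero mismatches. Template `N` never matches. Products pair a
forward-strand forward-primer site with a downstream reverse-strand
reverse-primer site, footprints non-overlapping, up to a default maximum
of 5,000 bp to suppress spurious distant pairings.

## Synthetic data generator

The generator emulates the statistical structure of the public inputs
the analysis consumes, at the study's scale:

- genome: 25 kb of i.i.d. bases at GC 0.41 (host gene on the minus
  strand), with one planted antisense promoter at position 1,500 — five
  consensus-maximal initiator instances spaced 10 bp apart, centers
  recorded as truth;
- hotspot tracks: 124 DNase and 51 H3K4me3 cell types; background
  hotspots as a homogeneous point process (1 per 10 kb per cell type for
  DNase, one tenth of that for H3K4me3, since the promoter mark is
  sparse away from promoters), lengths normal(200, 60) resampled until
  ≥ 50 bp (resampling, not clamping, avoids piling mass at the minimum);
  each promoter receives one hotspot per cell type with probability 0.8,
  centered with normal(0, 100) jitter;
- CAGE: 35 cell types, Poisson(0.6) predictions per promoter per cell
  type at the promoter ± normal(0, 25) on the promoter strand, plus
  uniformly placed false predictions at 0.15 per 10 kb with random
  strand — yielding a few tens of promoter-proximal calls and ~a dozen
  scattered ones over the region, the shape of per-region CAGE tallies;
- ESTs: a hidden 600-nt lncRNA transcribed from the antisense promoter;
  eight ESTs as random subintervals (lengths normal(350, 80), min 50)
  with i.i.d. substitutions at 1 %, plus an optional decoy fraction on
  the host-gene strand.

Each output family draws from its own random stream keyed by (seed,
stream index), so outputs are bit-reproducible and adding an output
never perturbs existing ones. The truth record (promoter positions,
initiator centers, lncRNA coordinates and sequence) suffices to score
every downstream stage without re-reading the configuration.

What the generator does **not** emulate: mappability artifacts,
correlated cell-type batteries (cell types are i.i.d.), signal-strength
variation within hotspots, spliced ESTs, sequencing indels, and CAGE
tag-count weighting. Passing the planted-signal tests therefore shows
the pipeline's arithmetic and ranking behaviour is correct under the
assumed generative model, not that the biological signal in real tracks
has these properties.

## Stand-in reference tables

The per-cell-type supplementary tables behind the published worked
examples are spreadsheets not redistributed here. The shipped
`synthetic_*` tables are deterministic stand-ins (fixed build seed,
regenerable via `analysis/00_build_reference_standins.py`) constructed
to carry the published aggregates — region sizes (24.8-kb intron, 0.8 /
4.2 / 2.1-kb breakpoint subregions, 10-kb promoter control, 25-kb
gene-free control), the 53 = 28 + 25 EST census with the eight selected
antisense accessions, intron modules VI and X above 80 of 124 DNase cell
types, and exactly 1 of 51 H3K4me3 cell types in the gene-free control —
while their per-cell-type and per-base detail is synthetic. Tests
recompute the aggregates through the real pipeline; they validate the
arithmetic, not the original measurements. Real-track counts (e.g.
initiator totals on the actual hg19 sequences, or stranded CAGE totals)
require the external sequences and tracks plus matrix calibration, and
are intentionally out of the offline test surface.

## Problem sizes and numerical choices

The acceptance script and test suite use the default scenario (25 kb,
10 modules, 175 simulated tracks) across 100 seeds for planted-signal
rates, 200 randomized instances per brute-force-oracle comparison
(alignment oracles enumerate monotone matchings, so those instances stay
at ≤ 8 nt), and single fixed-seed runs for the transcript chain — sizes
chosen so every check is exact or tightly bounded while the whole suite
runs in well under a minute of compute per stage. Floating-point window
scores are compared to oracles at relative tolerance 1e-10, and
cutoff-threshold tests pick cutoffs at midpoints between attained score
values so no comparison sits on a floating-point boundary.

## Known limitations

- Center-star alignment is a 2-approximation; for ESTs that barely
  overlap the chosen center, relative placement of their non-overlapping
  extensions is conventional, and consensus quality degrades at
  low-depth columns (N calls count against identity).
- The promoter-like flag (DNase and H3K4me3 prevalence both ≥ half
  their cell-type totals by default) is a labelled heuristic
  convenience, not a calibrated classifier.
- No liftover, no remote data access, no spliced alignment, no HMM TSS
  calling from raw CAGE tags: the package consumes processed intervals,
  as the upstream analyses did.
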