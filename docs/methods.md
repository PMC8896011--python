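# Methods

`teenrich` implements a repeat-centric analysis stack for finding and
characterising DNA-binding proteins that target transposable elements (TEs),
with LINE-1 (L1) as the element of interest.  This note describes the models
and procedures, the parameters that matter, what the synthetic-data
generator does and does not emulate, and the numerical choices made where
the design was open.

## TE-class enrichment with a shuffled null

ChIP-seq peak sets are screened for TE-class enrichment by comparing the
number of peaks overlapping each RepeatMasker class against the same count
after randomly relocating the peaks.

**Shuffle model.**  Each peak keeps its length and is relocated by drawing a
chromosome with probability proportional to chromosome length, then a start
uniform over positions where the interval fits.  Draws landing in a
blacklist, or (by default) on a previously placed shuffled interval, are
rejected and retried up to `max_tries = 1000` times, after which the
interval is dropped and the drop is recorded; a dropped interval's shuffle
count is rescaled by `n_peaks / n_placed` so expectations stay comparable.
Ten independent shuffles are averaged into the expected count (averaging and
pooling have the same expectation; averaging keeps per-shuffle counts
inspectable).  Per-shuffle RNG streams are spawned as
`default_rng([seed, experiment, shuffle])`, so a 10-shuffle run is a prefix
of a 100-shuffle run.

**Statistic.**  For each experiment × class cell,

    log2 ratio = log2((observed + ε) / (expected + ε)),   ε = 1 peak

The pseudocount ε handles zero expectations symmetrically: a cell with
`observed = expected = 0` scores exactly 0.  Overlap means ≥1 shared bp
(`bedtools intersect -u` semantics); a peak may count toward several classes
but at most once per class.  An experiment is called *enriched* for a class
when `(observed+ε)/(expected+ε) > 2`, *single-class* when exactly one class
passes.  Raising the fold threshold can only remove labels (monotonicity, a
tested property).

**Calibration and power.**  The log2 ratio of a null peak set has standard
deviation ≈ CV/ln 2, where CV = √((1−p)/(n·p)) for n peaks and effective
per-peak hit probability p (p grows with both class coverage and peak
width, since a w-bp peak hits an L-bp element with probability proportional
to L+w−1 per element).  For the ±0.5 calibration band to hold in ≥95% of
200-peak screens, every tested class needs p ≳ 0.3.  The calibration
scenario therefore uses a 1 Mb genome with LINE ≈ 26% coverage (the
subfamily ladder), three decoy classes at 10% coverage built from 200-bp
elements, and 600-bp peaks.  Smaller or sparser classes would need more
peaks for the same band — a real constraint of the statistic, not of this
implementation.

## Motif discovery: ZOOPS EM

A single motif of fixed width (default 13) is fit to a set of sequences
under the "zero or one occurrence per sequence" model: with prior γ a
sequence carries one site at a position/strand uniform over its valid
windows (windows containing N are excluded); otherwise it is pure
background.  The background is the order-0 letter composition of the input
(floored at 1e-4 per letter so log-odds stay finite on degenerate inputs).

E-step: posterior over (position, strand, no-site) per sequence, computed in
log space.  M-step: position frequency matrix from posterior-weighted counts
plus background-proportional Dirichlet pseudocounts (total 0.1), and
γ = mean total site posterior.  The EM objective (log-likelihood plus the
Dirichlet log-prior) is non-decreasing per iteration — asserted in tests;
the raw likelihood alone is not guaranteed monotone under MAP updates.
Convergence: relative objective change < 1e-6; default cap 200 iterations.

Two refinements beyond the basic EM are required for reliable recovery:

* **Phase shifts.**  Periodic motifs (e.g. a telomere-like
  `TTAGGGTTAGGGT`) trap EM in a register shifted by one or two columns,
  which explains almost as much data.  After the best of `n_starts` seeded
  restarts (each initialised from a random input subsequence at letter
  probability 0.5), EM is re-run from ±1- and ±2-column shifts of the
  matrix (vacated columns filled with background) and the best objective
  kept, iterating until no shift improves.
* **Orientation.**  Under two-strand search a motif and its reverse
  complement have identical likelihood.  The fitted matrix is oriented so
  that the majority of posterior-mode site calls lie on the forward strand.

The result object carries the matrix, γ, the objective trace, a convergence
flag and per-sequence site calls (posterior-mode position/strand or none).

## PWM scanning with exact p-values

Scores are base-2 log-odds against an order-0 background, discretised to
integer multiples of `1/granularity` bits (default granularity 1000).  The
exact null distribution of the integer total score is computed by
convolving the four-point column distributions — the same dynamic programme
FIMO uses — giving an exact p-value `P(score ≥ s)` for every attainable
score; tests verify it against exhaustive enumeration of all 4^W words for
widths 4–8 to 1e-12.

Scanning reports every window on either strand with `p < threshold`
(default 5e-6), skipping windows containing N, with forward-strand
coordinates; a palindromic exact tie reports the + strand only.  A
threshold ≥ 1 disables filtering and reports every window.  By default the
background is re-estimated from the scanned sequence; `background="motif"`
keeps the motif's training background.  The latter matters near the cutoff:
a 13-mer with two mismatches to a sharp consensus has exact
p = 742/4^13 ≈ 1.1e-5 under the uniform null, only ~2× above the 5e-6
cutoff, so composition wobble in a re-estimated background can move such
borderline words across the threshold.  The subfamily-specificity scenario
therefore scans under the motif's own (uniform) background.

Occurrences are binned by L1 subfamily by assigning each to the overlapping
annotation with the largest overlap (leftmost on ties); occurrences outside
every annotation go to an `unassigned` bin.

## Consensus-coordinate binding profiles

Peak/read sequences are aligned to an L1 consensus with exact affine-gap
Smith–Waterman at near-minimal penalties — match +1, mismatch 1, gap open
1, gap extend 1, minimum reported score 1; a gap of length g costs
`open + g·extend`.  These permissive parameters deliberately tolerate the
20–30% divergence of old genomic L1 copies.  Read-mapper seeding heuristics
are not reproduced: at consensus scale (~6 kb) the full dynamic programme
is affordable and strictly more sensitive, and both query strands are
scored (ties report +).  Tie-breaking among co-optimal cells: smallest
reference start, then fewest gaps, then smallest reference end, with a
diagonal-preferring traceback.  The DP fill is a numba kernel; a pure-Python
full-DP oracle in the test-suite checks scores exactly.

Per-position depth counts alignments covering a position through M/=/X/D
CIGAR operations (deletions span the reference, insertions do not).  The
profile reports `ratio[i] = (chip[i]+ε) / (s·input[i]+ε)` with ε = 1 and
`s` = total chip aligned bases / total input aligned bases, i.e. the input
is depth-scaled to the ChIP library before the ratio.

## Coverage meta-profiles and mappability

Profile matrices use the mean as the bin statistic; missing values
(windows truncated by chromosome ends) are NaN and excluded from means.
*Anchor mode* takes `[midpoint−flank, midpoint+flank)` around each anchor
(motif occurrences ± 1 kb by default; midpoint chosen for symmetry);
*scaled mode* linearly interpolates each region's per-base signal onto a
common length (full-length L1 → 5 kb by default) — values, not mass, are
interpolated, so a constant region stays constant whatever its length.
Rows of minus-strand features are flipped to read 5′→3′.  Default bin size
50 bp.  Heatmap row ordering by descending mean is presentation-only;
matrices carry stable row identifiers.

Theoretical mappability at k (default 100, matching 100-bp sequencing) is
`1 / (occurrence count of the k-mer starting at each position, counting
both strands)`: 1 marks globally unique sequence, 1/2 a two-copy repeat.
The final k−1 positions of a chromosome repeat the last defined value.  A
self-reverse-complementary k-mer counts its own reverse-strand occurrence;
at k = 100 this is vanishingly rare.

Coverage from alignment records counts M/=/X/D as covered and excludes N
(spliced gaps are not coverage); `unique_only` keeps records whose mapping
quality proxy marks them unique, `all_primary` keeps primary records
regardless; `normalize_1x` rescales to genome-wide mean depth 1.

## Expression and indel quantification

Fragment counting uses union semantics: a paired-end fragment counts once
toward a region when ≥1 of its records overlaps it by ≥1
reference-consuming bp; with `unique_only` (default) fragments containing
any multi-mapping record are excluded.  The library size is the number of
counted-eligible fragments — including fragments assigned to no region —
and `fpm = count·1e6/library_size`, `fpkm = fpm·1e3/length`.  Read-through
transcription is quantified over 1-kb windows immediately 3′ of each
element ( `[end, end+1000)` on +, `[start−1000, start)` on −), clipped at
chromosome bounds and flagged when they overlap another element.

CRISPR disruption is read off a cDNA-coordinate profile:
`ratio[i] = indel-bearing depth / total depth`, where a record is
indel-bearing iff its CIGAR contains an I or D operation; uncovered
positions are NaN.  A guide site is called *disrupted* when the mean
treated ratio within ±20 bp is ≥ 0.10 while the control mean there is
< 0.02.  The thresholds are configurable; the defaults separate planted
30% editing from sequencing-scale noise by more than an order of magnitude
in the synthetic libraries, and real editing efficiencies below ~10% would
need the threshold lowered.

## Synthetic data: what it emulates, and what it does not

`make_genome` builds an i.i.d.-background genome carrying planted L1 copies
on an age ladder: each subfamily has a divergence (substitutions per site
from a shared ~6-kb consensus, transitions:transversions 2:1), full-length
and 5′-truncated copies (L1 truncation is 5′-biased, so the 3′ end is
kept), random strand, and non-overlapping placement.  The consensus carries
ORF1 at [900, 1900), ORF2 at [1990, 5810) and two 13-mer binding cores
inside ORF2 (near its 5′ and 3′ ends).  Per subfamily each core is forced
exactly intact or exactly ablated — two fixed substitutions in the core,
chosen because a two-mismatch word falls just above the 5e-6 scan cutoff
while one mismatch stays below it — so site-level ground truth is exact.
Decoy TE classes (SINE/LTR/DNA) contribute annotation-only intervals.
Divergence is substitution-only: planted elements have no indels, keeping
consensus-coordinate truth exact.

`make_chip_experiment` centres a chosen fraction of peaks (with ±w/4
jitter) on distinct intact sites of one motif — requesting more signal
peaks than intact sites is an error — and scatters the rest uniformly; the
ChIP track is a Gaussian bump (amplitude 9, σ = w/4) per peak over a unit
baseline, the input track is flat.  `make_rnaseq_library` samples paired
100-bp-read fragments from weighted gene models; any record covering a
guide site (with ≥1 bp on each side) carries a 1–5-bp insertion or
deletion with the planted probability, so the guide-site indel ratio is an
unbiased estimate of that probability; L1 elements are silent unless a
read-through weight adds their 1-kb downstream windows as weak sources.

Deliberately not emulated: sequencing error, fragment-size and GC biases,
chromatin-matched nulls, indel divergence within elements, multi-copy
nested repeats, and real subfamily phylogeny.  Passing the planted-truth
suite therefore shows the *procedures* are correct and calibrated under
clean conditions; it does not certify performance on real libraries, where
mappability, composition bias and annotation error dominate.

All generators, the shuffler and the EM are deterministic functions of
their seed (numpy `default_rng` with explicit spawn keys); byte-identical
reproduction is itself a tested property.

## Validation scenario sizes

The scenarios in `teenrich.validation` (run by the test-suite and by
`scripts/acceptance.py`) use: 100 null-screen replicates of 200 peaks on a
1 Mb genome; 10 cohort seeds × 20 experiments × 200 peaks on a 4 Mb genome
with ~200 intact sites (5 planted binders at signal fraction 0.9); 1000
random interval fixtures against the all-pairs oracle; 100 random
alignment instances (60-bp query × 500-bp reference) against the
pure-Python DP oracle; exhaustive word enumeration at widths 4–8; 20
discovery seeds of 200 sequences × 60 bp; and 10 indel seeds of 4000
fragments over a 3-kb cDNA.  These sizes keep the whole suite at a few
minutes on one CPU while leaving the statistical margins comfortable.
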