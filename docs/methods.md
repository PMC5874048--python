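# Methods

## The statistic

The pipeline quantifies transcriptional read-through: RNA signal that
accumulates downstream of a transcript's 3' end (TES) when RNAPII fails to
terminate, as happens when the 5'→3' "torpedo" exonuclease XRN2 is
catalytically inactive. For each analyzed transcript the procedure is:

1. Anchor at the TES, defined as the coordinate one past the last
   transcribed base in transcription direction (span end on +, span start
   on −; internal coordinates are 0-based half-open throughout, converted
   from GTF at the I/O boundary).
2. Sum strand-specific per-base signal in K contiguous genomic windows of
   W nt placed directly downstream of the TES (window k covers distances
   [(k−1)W, kW)), and in the terminal reference window — the last W nt of
   the transcript's genomic span.
3. Normalize each downstream window by the terminal-window signal. The
   ratio cancels expression level and sequencing depth, so gene-body
   levels of different conditions overlay and only termination differences
   remain.
4. Aggregate across transcripts into a meta-gene curve per
   condition/replicate, and contrast conditions per window with a
   bootstrap confidence interval.

Defaults: W = 250 nt, K = 20 (5 kb downstream). Analyzed transcripts are
the highly expressed (TPM strictly > 10), spliced (≥ 2 exons) ones; both
rules are configurable. Windows are genomic (they ignore the exon
structure of other isoforms), matching the windowed-density reading of
the statistic; transcripts whose span is shorter than W, or whose windows
would leave the chromosome, are flagged invalid rather than silently
truncated.

## Transcript selection

TPM is computed from per-base exonic coverage: rate_t = exonic signal /
exonic length, scaled so rates sum to 10^6. This diverges from count-based
TPM only by the constant relating signal units to fragments, which cancels
in the normalization; it keeps the pipeline self-contained on coverage
input. The threshold comparison is strict (> 10), so a transcript at
exactly the threshold is excluded.

Because the downstream windows must measure the anchored transcript's own
read-through, a clearance filter (on by default) drops transcripts with
another same-strand transcript overlapping the `clearance` nt (default
K·W) downstream of their TES. Signal is strand-specific, so opposite-strand
neighbors are ignored; isoforms of the same gene sharing the identical TES
are also ignored. Whether the original analysis applied such a guard is
not documented; it is configurable for that reason.

Every transcript is accounted for in the audit table with its first
failing rule (`expression` → `monoexonic` → `clearance`); at the profile
stage a `terminal-floor` reason marks transcripts whose terminal signal
falls below ε (default 1.0 signal unit), which would otherwise produce
unstable ratios. ε must be > 0; raising it trades transcripts for ratio
stability.

## Aggregation modes

Two readings of "aggregate across transcripts" are shipped:

- `mean_of_ratios` (default): per window, the arithmetic mean (and SD) of
  the per-transcript normalized values — an averaged-densities reading.
- `pooled_ratio`: per window, summed raw window signal across transcripts
  divided by summed terminal signal — a cumulative-signal reading.
  Invariant to transcript duplication, dominated by highly covered
  transcripts.

On the toy example with terminal signals (100, 300) and window-1 signals
(100, 0) the modes give 0.5 and 0.25 respectively; both are tagged in the
output. Replicate curves are reported individually and as an
across-replicate mean. The condition contrast resamples transcripts with
replacement within each condition (1000 bootstrap draws, percentile 95%
CI, seeded); no parametric distributional claim is made.

## The synthetic-data generator

The generator emulates the statistical structure of a stranded (dUTP)
RNA-seq study of termination: triplicate conditions, strand-specific
exonic coverage of spliced transcripts, and condition-dependent
read-through decaying downstream of the TES. Expected per-base coverage is

    c_t                          on exonic positions of transcript t,
    α·c_t·exp(−d/λ)              at distance d ∈ [0, D_max) downstream of
                                 t's TES on t's strand,
    β                            elsewhere,

with realized values drawn per-base Poisson. α ∈ [0,1] is the read-through
fraction (the condition knob: ~0.05 for competent termination, large for a
termination-deficient state), λ the decay length scale (default 1000 nt),
D_max the maximal extent (default 5000 nt), and c_t per-transcript
expression drawn log-normally (log-mean 3, log-sd 1, i.e. median ≈ 20
read-bases/base). Exponential decay is the simplest monotone model of a
downstream signal that dies off, and it admits an exact oracle.

Generator design choices: exon lengths U(300, 1200) nt so the terminal
250-nt genomic window always lies inside the 3'-terminal exon (the
terminal reference then equals gene-body level in expectation — no 3'
bias is modeled); introns U(100, 500) nt; transcripts packed left-to-right
with inter-span gaps ≥ 6000 nt (≥ both the default clearance of 5 kb and
D_max) so downstream windows never hit neighboring transcription; K·W
margins at the chromosome ends so no window leaves the chromosome. All
randomness flows from one seed; identical parameters and seed give
byte-identical output files.

The analytic oracle for the noiseless normalized value of window k is

    α·(λ/W)·exp(−(k−1)W/λ)·(1 − exp(−W/λ)),

independent of c_t (terminal sum c_t·W cancels). The discrete per-base sum
differs from this continuous form by < 0.5% for λ ≥ 500 at W = 250
(validated by brute-force summation in the tests); at α = 0.5, λ = 1000 the
window-1 value is 0.4424 (continuous) vs 0.4426 (discrete). Inverting the
window-1 formula yields the estimator α̂ = mean₁ / [(λ/W)(1 − e^(−W/λ))],
which recovers α to well under 5% relative error at 200 transcripts with
c_t ≳ 20/base.

What passing synthetic tests do not show about real data: the generator
has no overdispersion (pure Poisson), no 3' coverage bias, no antisense or
overlapping transcription, no splice-junction reads, and uniform exonic
coverage; real libraries violate all of these to some degree. The tests
establish correctness of the computation, not robustness to every
real-data artifact.

## Coverage representation and the BAM adapter

Coverage is held as sorted non-overlapping runs per (chrom, strand) with
prefix sums, so interval sums are exact per-base sums (no binning or
interpolation) in O(log R + runs overlapped). bedGraph pairs (0-based
half-open, one file per strand) are the canonical exchange format; the
writer emits values that round-trip bit-exactly.

The optional BAM adapter counts fragments, not reads: each properly
paired fragment adds +1 over the union of both mates' aligned blocks
(N/intron gaps excluded), so mate overlap is counted once and signal is
proportional to cDNA fragments. Under the dUTP protocol the second cDNA
strand is destroyed, so read 2 carries the transcript strand
(`dutp-reverse`); secondary, supplementary and duplicate-flagged reads are
skipped. No mapping-quality filtering or deduplication beyond flags is
attempted.

## Pipeline determinism and numerics

The expression filter is applied per condition on replicate-pooled
coverage; profiles are computed per replicate for the retained set. All
stage outputs are TSVs whose floats round-trip exactly, so running
`quantify` → `metagene` → `compare` as separate commands is byte-identical
to `run-all`, and reruns with the same config and seed are byte-identical.
The run manifest records input checksums, per-stage exclusion tallies, the
seed and the package version. Config files are YAML; relative paths
resolve against the config file's directory, so simulated bundles are
relocatable.

Problem sizes used in the shipped checks — 200 transcripts, triplicates,
4 Mb chromosome, 10 recovery repetitions — are the package's desk-scale
rendering of the emulated study design and run in seconds.
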