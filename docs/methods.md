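# Methods

## Signal model and normalization

Tiling-array ChIP signal is represented per probe (50 bp probes every
100 bp in the synthetic design; any non-overlapping grid is accepted).
Chip and control channels are combined as log2(chip/control) and the
genome-wide mean is subtracted, so every normalized track averages exactly
zero; channels already on a log2 scale are combined by subtraction.  The
centering mean is unweighted over probes — probes are uniform length in
the designs handled here, so base-pair weighting would change nothing; the
choice is recorded because either convention is defensible.  Missing
probes in one channel are a hard error, not imputed.

Z-scores use the population (n) standard deviation, computed jointly over
all chromosomes, ignoring NaN (empty bins).  A constant vector raises
rather than returning silent zeros.

## Domain calling

**Bins.** Each chromosome is tiled into `bin_size` = 200 bp bins stepped
by 100 bp, covering [0, chromosome length) with a trailing partial bin.
A probe contributes to every bin containing its midpoint; empty bins carry
NaN and are excluded from z statistics.

**Enrichment and bin-level differential calls.** Bins with z strictly
beyond the cutoff (z > 2 enrichment/H3K27me3 gain, z < −3 loss, "strictly"
matching the published wording) are unioned; neighbouring intervals merge
when the gap (next start − previous end) is ≤ 200 bp.  H3K27me3 gains keep
only regions of length > 500 bp (strictly greater, i.e. ≥ 501 on integer
coordinates).

**Broad blocks (H3K9me2).** The published H3K9me2 domains came from an
external broad-block algorithm whose internals are out of scope here; this
package provides a transparent stand-in.  Single-track form
(`call_blocks`): probes with z strictly beyond the cutoff (default 0.5,
permissive enough to capture the weak pre-marking of Class I genes) seed
blocks; runs of up to 2 failing probes are bridged; blocks spanning fewer
than 4 probes are dropped.  Differential form
(`call_differential_blocks`), used for the mutant-vs-wild-type H3K9me2
cutoffs 0.75/0.8: detection runs on a 5-probe moving average of the probe
differences (the weakest real effect, a Class I gene moving from half- to
full-strength H3K9me2, is only ≈ 1.8 noise SD per probe, so unsmoothed
thresholding is too ragged), requiring ≥ 6 supported probes.  Each
detected block's boundaries are then refit on the *unsmoothed* differences
as the maximum-scoring contiguous segment of
(value − baseline) − lift/2, where baseline is the genome-wide median and
lift the block's median height — the maximum-likelihood extent of a step
of that height, which undoes the ±2-probe smear that smoothing adds.
Blocks whose refined probes do not average above the z cutoff are
discarded, and boundaries extend to the midpoints of the flanking
inter-probe gaps (a called domain plausibly reaches halfway to the next
probe).  All of these block parameters are this package's own documented
choices; the published z cutoffs are applied unchanged.

**Permutation FDR.** FDR = (mean region count over permutations of the
signal) / (observed count), with the first track's values permuted within
each chromosome.  The default null is a random *shuffle*: the domain
callers key on spatial clustering of high values, and shuffling destroys
exactly that while preserving the value distribution.  A circular
*rotation* variant is also provided, but note that rotation moves a
contiguous signal block without destroying it, so rotated tracks yield
roughly the observed count again and the resulting "FDR" is ≈ 1 whenever
real contiguous signal exists — rotation answers position-anchored
questions, not "more domains than chance".  Because the permuted values
retain the real signal's heavy tail, the shuffle null is conservative on
fixtures where planted signal occupies a sizeable genome fraction (the
scattered high values occasionally recluster); reported FDRs on the dense
synthetic fixture should be read with that in mind.  A call set with zero
observed regions reports FDR 0 with an explicit `zero_observed` flag and
is never counted as significant.

## Gene assignment and classification

A gene joins a region set when its total overlap with the *union* of
regions reaches 150 bp.  Summing over the union was chosen (and is
configurable to single-region mode) because several sub-150 bp overlaps
jointly covering a nucleosome's worth of DNA are the same biological
signal; the published wording does not distinguish the two.  Class I =
gaining ∩ wild-type H3K9me2 genes; Class II = gaining ∩ wild-type
H3K27me3 genes; genes in both wild-type sets appear in both classes and
are tallied separately as dual — the source analysis never addresses the
intersection.  Printed percentages round half-up to one decimal, matching
printed-value parity (100·515/6592 = 7.812 → 7.8).

## Metagene profiles

Bodies are rescaled onto 20 equal-fraction bins (the source figures show
scaled TSS→TTS bodies without stating a bin count); flanks are binned at
150 bp over 3 kb by default.  Probes, reads and cytosines are assigned to
the bin containing their midpoint — one bin per observation, no double
counting.  Minus-strand genes are flipped so bin 0 is always 5′-most.
Genes shorter than one body bin are skipped with a warning rather than
clipped.  Profiles average over genes ignoring NaN and may be smoothed
with a centered moving average (default window 5 bins, truncated at the
edges; the source says "moving average" without a window).  Bins with zero
contributors stay NaN even after smoothing.  Because tracks are already
log2-scale, the "log2 ratio" of two profiles is their per-bin difference
by default; building profiles with `linearize=True` (mean of 2^x, then
log2) gives the ratio-of-linear-means reading, and the mode is recorded in
the profile.  Methylation profiles pool counts — Σ methylated / Σ total
per bin, not a per-site average: sites (0/1) and (2/2) give 2/3, not 0.5.
Read-density profiles count read midpoints per bin, normalized per kb of
bin and per million total reads.

## Expression and sequence statistics

RPKM = count / (length/10³) / (library/10⁶).  Zero-RPKM elements are
removed before boxplot comparisons (the published boxplot rule) rather
than pseudocounted; the removal count is reported.  Group comparisons use
the two-tailed Wilcoxon rank-sum test: exact enumeration of all C(n+m, n)
labelings when n+m ≤ 12 without ties (two-tailed p doubles the smaller
tail, capped at 1), otherwise a normal approximation with tie correction
and 0.5 continuity correction; a fully tied pooled sample gives p = 1.
Single-element genotype changes use an exact conditional two-proportion
test (the element's combined reads split binomially by library-size
ratio) — a documented stand-in, since no test is named in the source and
the design has no replicates.  Boxplot summaries use linear-interpolation
("type 7") quartiles with whiskers at the most extreme points within
1.5 × IQR.  "C+G density" is ambiguous between base composition and
CpG-site density; both are computed, and CpG-dinucleotide density (CG
dinucleotides per non-N window) is the default for gain-vs-stable
transposon comparisons because the proposed mechanism concerns unmethylated
CpG sites.  N bases are excluded from numerators and denominators.

## Synthetic epigenome

The generator emulates a two-mark × three-genotype tiling study of a small
plant-like genome.  Defaults define the standard study conditions:
3 chromosomes × 200 kb, 120 genes (1–2.5 kb) and 40 transposons
(0.8–2 kb) placed without overlap behind ≥ 300 bp flanks, probe grid
50 bp/100 bp, additive Gaussian noise SD 0.3 on the log2 scale,
enrichment 1.5 log2 units.  Class structure: 25 % of genes are Polycomb
targets of which 60 % convert (Class II), 15 % are Class I (half-strength
H3K9me2 in wild type — the "lower levels" pre-marking — at factor 0.5,
configurable), 50 % of transposons gain H3K27me3 in met1; ibm1 gains are
planted at 20 % of plain genes, a separate truth field since ibm1 targets
a distinct gene set.  Planted intervals are the element's own span, so
truth is exact to the base pair.  Effect sizes are not stated numerically
in the source; these defaults were fixed once such that calling at the
published thresholds recovers the planted truth (Jaccard ≥ 0.9, ≥ 95 %
label recovery) at the stated noise, and they stay fixed across all tests.

Sequences: AT-rich background; K27-gaining transposons are built with a
high CpG-dinucleotide rate (0.20) and stable ones low (0.02), encoding the
CpG-density difference of gaining transposons.  Paralogy is emulated by
copying a 300 bp core between pairs of Class II genes with 20 % point
mutation, annotated as dispersed repeats; tandem repeats are planted in
half the Class I genes.  Methylomes are binomial per-cytosine tables at
coverage 10 with contexts derived from the sequence (CG/CHG/CHH on both
strands): wild type has gene-body CG methylation (0.7) and all-context
transposon methylation (0.8); met1 zeroes CG everywhere and elevates CHG
(0.6) in Class I/II gene bodies.  Expression uses a Poisson–Gamma
(negative binomial, dispersion 0.2) tier model — silent (0), low (5),
moderate (100) reads — with non-silent draws floored at one read so the
planted silent set is exactly the zero-count set; Class II and stable
Polycomb targets are silent in both genotypes, K27-gaining transposons are
lowly expressed in wild type and reactivated in met1.  Small RNAs
concentrate on Class I genes and triple in met1.

What the generator does **not** emulate: hybridization physics and
probe-sequence bias, replicate structure, nucleosome positioning, partial
or boundary-shifted mark changes (planted effects fill whole elements),
and genome-scale repeat complexity.  Passing tests therefore demonstrate
the correctness of the analysis logic under the stated signal model, not
performance on real arrays.

## Numerical and degenerate-input choices

Identical mutant/wild-type tracks (zero-variance difference) return an
empty call with a warning, not an exception.  Ties at exactly
z = cutoff are excluded (strict inequality).  Probe/bin assignment uses
half-open intervals throughout (BED/bedGraph 0-based half-open on disk;
GFF3 1-based closed).  Fixture bundles are byte-identical for identical
spec+seed (per-stage seeds derive from the spec seed), and pipeline
reports are byte-identical for identical config+seed.

## Known limitations

Recovery Jaccard ≈ 0.91–0.93 rather than 1.0 at the standard noise: the
residual is boundary quantization on the 100 bp probe grid plus ~1 probe
of step-fit uncertainty at the weak Class I edges.  The z < −3 loss cutoff
is deliberately stringent; on the dense synthetic fixture the loss caller
recovers most but not all Class II H3K27me3 losses, consistent with the
source's own description of its cutoffs as conservative.  The permutation
FDR is conservative on dense fixtures (see above).  The block caller is a
stand-in, not a re-derivation of the published block algorithm.
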