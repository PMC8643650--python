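# Methods

## Run-kinetics model

The simulator treats each (channel, pore) as an alternating renewal process:
a vacancy gap followed by a read. Residence time is `length / speed` with
`speed` = 450 bases/s by default. Vacancy gaps are exponential with mean
`mean_vacancy / loading_factor` (default 2 s at 1 molar equivalent, ME):
loading more library shortens the wait for a molecule to dock. Channels die
with an exponential lifetime of hazard `channel_death_hazard ×
loading_factor` (default 0.03/h at 1 ME) — the simplest mechanism that
produces both the observed decay of active channels over a 48 h run and the
faster decay at higher loading. Why higher loading accelerates channel death
is not mechanistically settled; the hazard × ME coupling is a modeling
choice, not a claim. Read lengths are log-normal parameterized by median and
log-sd (default 0.35), truncated at 50 bp, matching the right skew of real
short-library length distributions without asserting their exact shape.
Q-scores are normal(10, 1.5) with pass threshold 7, the usual convention;
one pore per channel by default with multi-pore channels behind
`pores_per_channel`.

Two deterministic limits make the engine exactly checkable: with fixed
vacancy V, fixed length L and immortal channels, each channel produces
exactly `floor(T / (L/speed + V))` reads, every computed vacancy gap equals
V and every residence equals L/speed. The expected yield ratio between two
libraries is `(V + R_long) / (V + R_short)` with R the mean residence time
(mean log-normal length over speed); seeded simulations land within ~10% of
this closed form.

What the simulator does *not* model: signal-level squiggles, basecall error
beyond barcode substitutions, pore blocking/unblocking dynamics, mux scans,
or any attempt to reproduce a particular instrument run's absolute yield.

## Kinetics statistics

All statistics operate on the per-read summary table. A read contributes to
cumulative yield at its *end* time (a read is sequenced when it finishes).
Channel lifetime is the end time of the channel's last read; channels with
no reads are absent. Vacancy gaps are computed only between consecutive
reads of the *same pore within the same channel*; overlapping reads within a
pore are invalid input. Activity rasters mark a five-minute window (default)
for a channel if any part of a read overlaps it. "Relative reads per
channel" divides total reads by the device channel count (512 MinION-like,
126 Flongle-like), the reading that makes cross-device comparison
meaningful. MAPQ is `round(-10 log10 p)` capped at 60; the length-stratified
analysis defaults to 100 bp strata from 100 bp to 1 kb and reports per
stratum the unaligned / perfect-MAPQ(60) / suboptimal fractions, which sum
to 1. Time is seconds throughout; minutes only at presentation.

## Binning, filtering, normalization

Bins are equal-expected-mass cuts of a per-window unique-read weight track:
bins are allocated to chromosomes proportionally to total weight
(largest-remainder rounding, minimum one), then boundaries are placed where
cumulative weight crosses multiples of the per-bin target, never splitting a
window or crossing a chromosome. On a uniform track over 3 Gbp, 5,000 bins
are exactly 600 kb and 20,000 bins 150 kb. A uniform-track constructor
stands in when no mappability track is available, so the synthetic pipeline
needs no reference genome; computing real mappability tracks from sequence
is out of scope. Coordinates are 0-based half-open everywhere and a read
belongs to the bin containing its leftmost mapped base.

Alignment filtering mirrors `samtools view -q 20 -F 0x904`: MAPQ ≥ 20
(inclusive) and none of unmapped/secondary/supplementary. Normalization
divides counts by their mean; with GC correction enabled, a lowess fit
(span 0.3) of mean-normalized count against bin GC is divided out
multiplicatively before a final rescale so the ratio mean is exactly 1.
GC correction requires at least 100 informative bins and is off unless GC
fractions are supplied; plain mean normalization is scale-invariant.

## Circular binary segmentation

For a segment of n bins, every arc (i..j] of the circularized profile is
compared against its complement with a pooled-variance two-sample t
statistic; the maximal arc defines the candidate change-points. The
five-contiguous-bin transition rule gates the call: if the maximal arc spans
fewer than `min_width` = 5 bins, or would leave a flanking piece shorter
than 5 bins, no transition is called in that segment. Otherwise the split is
accepted when a within-segment permutation test on the max statistic gives
p < alpha, and the recursion continues into the resulting pieces (up to
three, when the arc is interior). Chromosome labels are hard breaks:
segmentation runs per chromosome.

Defaults alpha = 0.01 and n_perm = 1000 follow common CBS practice; both are
exposed. Numerical choices: ties in the max statistic (relative tolerance
1e-9) break to the lexicographically smallest (i, j); a segment with zero
pooled variance but unequal means scores +inf; the permutation decision
short-circuits in two directions — sequentially, once enough permuted maxima
exceed the observed value that p ≥ alpha is guaranteed, and via a
conservative Bonferroni bound on the t tail (accept without permuting when
`n² · 2 · P(T_{n-2} > t_obs)` < alpha/10). Neither shortcut changes the
decision except on measure-zero boundaries; together they keep multi-seed
end-to-end analyses in minutes. Permutations are vectorized in batches and
driven by one seeded generator, so a fixed seed reproduces the segmentation
exactly. An exhaustive O(n²) scan (`exhaustive_best_split`) is kept as an
independent oracle for the fast path. Profiles shorter than `2·min_width`
return a single segment with a warning. No undo-splits heuristics or
alternative segmenters are provided.

## Absolute copy number

Segment ratios are scaled to integers by grid search for the multiplier m
over (0.5, 8.0] in steps of 0.05 (Ginkgo-lineage convention, configurable)
minimizing the bin-count-weighted squared distance of r_s·m to the nearest
integers; ties break to the smallest m. The flat-profile degeneracy (all
ratios 1: every integer m fits exactly) is flagged `ploidy_unresolvable`;
by default the diploid scale m = 2 is then reported — the sensible prior
for a normal karyotype — while `diploid_default=False` preserves the raw
smallest-grid-point tie-break. Subclonal and allele-specific states are out
of scope; copy numbers are non-negative integers.

Downsampling draws a multivariate hypergeometric subsample of the bin
counts, exactly equivalent in distribution to subsampling reads without
replacement, summing exactly to the target. Breakpoint accounting treats
chromosome starts as non-boundaries; a called boundary with no true
transition within ±2 bins (default) is spurious, a true transition with no
called boundary within tolerance is missed.

## Demultiplexing

Reads are assigned to the nearest barcode by Hamming distance over the
barcode-length window at the read 5' end (configurable offset), accepting
the assignment only when it is unique and within `max_dist` = 4 mismatches.
Since the five standard 24-nt barcodes are pairwise ≥ 10 apart (computed
minimum 15), floor((10−1)/2) = 4 guarantees no substitution pattern of ≤ 4
errors can reach a wrong barcode — verified by exhaustive enumeration of all
1- and 2-error corruptions. Substitution errors only; indel-tolerant
matching and signal-space barcode calling are out of scope.

## The standard complex-karyotype truth

Parameter-recovery experiments use a fixed 5,000-bin genome (20 chromosomes
of 250 bins) with a deterministic event list: 1,500 bins (30%) deleted to
CN 1 and 500 bins (10%) gained to CN 4 over a diploid background, mixing
whole-chromosome, arm-level and interstitial events (smallest 30 bins),
with 19 interior transitions. Bin counts are multinomial with probability
proportional to purity-diluted copy number, optionally warped by a
quadratic GC bias peaking at 45% GC. At 2M total reads (400 reads/bin) the
full pipeline recovers every transition within ±1 bin and 100% of bin-level
integer copy numbers in typical seeds; replicate profiles at 4M reads
correlate at r ≈ 0.993 and a 600k replicate against 4M at r ≈ 0.976.

Because the multinomial model is clean — no GC bias unless requested, no
mappability artifacts, no overdispersion, purity 1 — the pipeline remains
accurate down to 250k reads (50 reads/bin) on this truth: the permutation
test's false-split rate does not depend on depth, so spurious segments do
not become more frequent at 250k here, unlike on real data where coverage
biases dominate at low depth. Passing these tests therefore demonstrates
correctness of the machinery under the stated noise model, not robustness
to every artifact of real sequencing.

## Problem sizes used in tests

Simulated runs use 4–64 channels and 0.5–4 h durations (the kinetics are
per-channel, so device-scale channel counts add nothing but time);
recovery experiments use 20 seeds × {2M, 1M, 500k, 250k} reads on the
5,000-bin truth; concordance uses 10 seed pairs; the CBS oracle comparison
uses 50 instances of n ≤ 120. These sizes are the package's choice of
statistically sufficient defaults.
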