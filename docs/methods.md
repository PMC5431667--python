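# Methods

## Signal model and scope

A cohort is a set of subjects, each with three logR tracks (time points
t₁–t₃) aligned to one ordered autosomal marker map. The package models logR
as baseline 0 plus iid Gaussian per-probe noise, with copy-number segments
adding a constant shift over a contiguous marker run. Sex chromosomes are
removed before any analysis. B-allele frequencies, mosaic fractions and
genotype calls are out of scope.

## Synthetic cohorts

The generator (`longcnv.sim`) emulates a 50k-density array: inter-marker
spacing uniform on [0.5, 1.5] × 50 kb (strictly increasing positions,
default 10 chromosomes × 120 markers), per-track Gaussian noise (default
sd 0.15 logR), and planted CNVs with shifts −0.6 (loss) and +0.45 (gain) —
typical Illumina one-copy magnitudes, chosen to clear the ±0.35 call filter
with margin at the default noise. Per subject the default design plants
14 constant, 5 de-novo-(0,1,1) and 8 de-novo-(0,0,1) CNVs of 5–10 markers,
matching the study design's per-subject averages (14 constant, 13 de novo,
with roughly twice as many events in the second interval as the first);
10% of planted CNVs are gains, mirroring the strong excess of deletions in
SNP-array CNV calls. CNVs are placed non-overlapping with ≥ 10 background
markers between events; the genomic layout is drawn once per seed and
replicated across subjects, so truth lists differ only by subject id.
Optional features: a long-period sinusoidal "genomic wave" in marker index
(stands in for GC-correlated waves without needing a reference genome) and
isolated ±1.0 spikes at a configurable rate to exercise outlier removal.
One master seed drives everything; per-sample noise streams are derived
sub-streams, so cohorts are bit-reproducible.

What the simulator does **not** emulate: real probe-density variation,
locus-dependent noise, wave structure tied to actual GC content, partial
(mosaic) shifts, or correlated batch artifacts. Passing the recovery tests
therefore demonstrates correctness of the algorithms under the stated noise
model, not calling performance on real arrays.

## Quality control

* **dLRS** — median |logR_{i+1} − logR_i| within chromosomes, divided by √2.
  For iid noise this estimates 0.6745 σ (the median-based robust scale);
  it is shift-invariant and scales linearly. Cohort outliers are flagged by
  the Tukey rule dLRS > Q3 + 1.5·IQR (no flags and a warning below 4
  samples, where quartiles are meaningless).
* **Wave metric** — absolute Pearson correlation between per-window
  (default 1 Mb) median logR and a windowed composition covariate (true GC
  content if supplied, the simulator's wave covariate otherwise); 0 is
  returned for zero-variance inputs, missing below 3 windows.
* **PCA batch check** — principal components of the sample×marker matrix
  (markers mean-centered, components truncated to rank) with the mean
  silhouette on PC1–PC2 per labeling factor (time point, subject) as the
  quantitative stand-in for visual inspection; |silhouette| ≲ 0.2 means no
  clustering.

## Segmentation

Each track is segmented per chromosome under the *maximum pairwise segment
p-value* criterion with defaults p ≤ 0.005, ≥ 2 markers per segment,
outlier removal on, and CNV calls filtered at segment mean < −0.35 or
> +0.35.

Design of the optimizer (each step was chosen after measuring the
alternative's failure on simulated tracks):

1. **Outlier masking.** Hampel-style: a marker is masked when its residual
   from the window-5 running median (excluding the center) exceeds
   3 × the chromosome-wide robust spread of residuals (MAD × 1.4826) and
   neither neighbor lies within that tolerance of its value. Masked markers
   are excluded from all statistics but spanned by segment coordinates
   (attached to the left segment). A *windowed* MAD is deliberately not
   used: five residuals cannot estimate scale, and wherever a few neighbors
   agree by chance it collapses, masking ~8% of genuine markers in
   simulation; the chromosome-wide spread reduces false masking to < 1%
   while still catching planted ±1.0 spikes.
2. **Candidate breakpoints** by recursive binary splitting on the
   within-segment sum of squares, unconditionally down to the minimum
   segment size (ties broken leftmost). A top-down *stopping* rule (test
   only the best split of the chromosome) is provably blind to a short CNV
   inside a long chromosome — the two halves have nearly equal means — so no
   test is applied during splitting.
3. **Merge-pruning to a fixed point.** Adjacent segments are joined worst
   pair first while any pairwise p exceeds the threshold. The pairwise test
   is a Welch-type two-sample test in which both segments carry the
   *track-wide* robust noise variance (median |successive difference| /
   (0.6745·√2), squared) with correspondingly large degrees of freedom:
   per-probe logR noise is homoscedastic along a track — a copy-number
   change shifts the mean, not the variance — and the empirical variance of
   a 2–5-marker segment is so unstable that genuine boundaries with z ≈ 11
   were assessed as insignificant under segment-local Welch df. Zero-
   variance pairs (noise-free data) short-circuit to exact mean equality,
   up to float round-off. Worst-first ordering makes the accepted breakpoint
   set monotone in the threshold: lowering `max_pairwise_p` only extends the
   merge sequence.
4. **Selection adjustment.** The per-pair threshold is
   `max_pairwise_p / (n−1)` for a chromosome of n markers. Surviving
   boundaries are the extremes among ~n candidates; without the adjustment
   ~15% of pure-noise chromosomes (200 markers, sd 0.15) retain a spurious
   split at the nominal 0.005. With it, ≥ 9/10 pure-noise seeds yield a
   single segment while planted ±0.45–0.6 shifts (z ≳ 6) are untouched.
5. **Boundary refinement and re-splitting.** After the merge fixed point,
   each boundary is re-optimized to the SSE minimum between its flanking
   segments (greedy splitting can straddle a true edge inside an
   unsplittable fragment), and each segment is re-tested with a CBS-style
   best sub-interval scan (most aberrant interval vs the rest, mid length
   capped at 100 markers) at the same threshold — worst-first merging is
   path dependent and can swallow two nearby CNVs together with the gap
   between them, a configuration no single split exposes. Refine/re-split
   and merge alternate to a fixed point (≤ 5 rounds).

Calls take half-open base-pair coordinates [first marker position, last
marker position + 1); lengths are end − start; ids are assigned in genome
order. On 20 fixed small instances (≤ 12 markers) the returned partition
satisfies the pairwise acceptance rule and lies within 5% of the SSE
optimum found by exhaustive enumeration over all accepted partitions.

## Temporal classification

Within a subject, same-state same-chromosome calls are grouped by single
linkage under reciprocal overlap ≥ 0.5 (both intervals must cover each
other to half their length; the threshold is exposed because no published
convention exists for cross-time-point CNV identity). Trajectories take the
union of member intervals — conservative for coverage accounting — and the
OR of time-point presence. Classification is the exact pattern table
(constant (1,1,1); de novo (0,1,1)/(0,0,1); all other non-empty patterns
inconsistent, with (1,0,1) additionally flagged as a "resurrection"
diagnostic since the accumulation model predicts it should not occur).
Inconsistent trajectories stay in the outputs but are excluded from all
headline statistics.

Coverage at time t is the per-chromosome union of intervals of
constant/de novo trajectories present at any time ≤ t — cumulative by
construction, hence monotone. The per-class coverage statistic is median
length × count. The de novo proportion comparison is an exact two-sided
binomial test (sum of outcome probabilities ≤ the observed one) of one
cohort's de novo count against the other cohort's proportion as the null.
Reported ratios are rounded half away from zero at the printed precision.

## Annotation and enrichment

Interval–feature overlap is any-shared-base (configurable minimum overlap in
bp), computed by a per-chromosome sweep over start-sorted inputs and
verified against an all-pairs oracle. The Venn partition over up to four
gene sets counts each member of the union in exactly one exclusive region.
QTL trait-class enrichment counts, per class, CNVs overlapping ≥ 1 QTL of
the class (once per class regardless of multiplicity) and tests the de novo
count against the constant-group proportion (exact binomial, continuity
floor 0.5/n on degenerate null proportions). Gene-set enrichment reports
C (category size), O (observed), E = C·k/N, R = O/E, the hypergeometric
upper tail P(X ≥ O), and Benjamini–Hochberg adjusted p-values across
categories; with O = 0 the convention is R = 0, rawP = 1.

## qPCR validation

Relative quantity uses efficiency-corrected ΔΔCq against a pooled
first-time-point control and the geometric mean of two normalizer genes
(replicate Cq values averaged before exponentiation; per-assay efficiencies
are inputs, default 2.0, as copy-stable normalizers are assumed). Status at
t₂/t₃ is the RQ ratio to t₁ with inclusive cut-offs 0.75 (loss) and 1.25
(gain) — this package's defaults, as no published thresholds exist — and
agreement with array predictions is the percentage of matching
(assay, sample, time point) status pairs, i.e. direction-of-change
agreement.

## Problem sizes and determinism

Default verification cohorts are 8 subjects × 3 time points on 10
chromosomes × 120 markers (1,200 autosomal markers, 27 planted CNVs per
subject) — large enough that every temporal class, both states, and
multi-CNV chromosomes occur, small enough for exhaustive property checks.
The recovery benchmark averages 10 seeds; the acceptance script uses 3
seeds derived from its `--seed`. All randomness flows from explicit seeds;
identical configurations give byte-identical outputs.

## Known limitations

* The pairwise-test noise model assumes homoscedastic per-probe noise per
  track; strongly locus-dependent noise would weaken both the variance
  floor and the selection adjustment.
* Matching by reciprocal overlap with single linkage can chain distinct
  events through an intermediate call; at the default threshold this did
  not occur in simulation but is possible in principle.
* Gains at +0.45 with 5 markers sit ≈ 1.5 noise-sd above the +0.35 filter:
  a few percent of such gain–time-point observations fall under the filter
  by chance and are recorded as missed time points. This is a property of
  the fixed call threshold, not of the segmentation.
* Enrichment treats gene sets as flat collections (no ontology graph
  propagation) and assumes the analyzed genes are drawn from the stated
  reference universe.
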