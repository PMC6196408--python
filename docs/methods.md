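# Methods

## Problem setting

Read-depth CNV detection treats the per-window log2 ratio of sample to
matched-normal readcounts as a noisy 1-D signal

    r = f + eps,   eps_i ~ iid N(0, sigma_N^2),

where the noiseless f is sparse and piecewise constant: copy numbers are
discrete, CNVs occupy a small fraction of the genome, and the quantities of
interest — breakpoints and narrow (focal) events — are exactly the features
that linear smoothers destroy. `tautcnv` denoises r by 1-D total-variation
(TV) minimization before segmentation:

    min_f  1/2 sum_i (r_i - f_i)^2  +  penalty * sum_i |f_{i+1} - f_i|.

TV solutions are piecewise constant with sharp, unshifted edges, which is
why they suit this signal class better than moving averages or wavelet
shrinkage.

## Taut string

With running sums R_i = sum_{u<=i} r_u and the substitution
f_i = s_i - s_{i-1}, the TV minimizer is the string of shortest length
through the tube R_i ± theta, pinned at (0, 0) and (n, R_n); a constant tube
radius theta yields exactly the TV minimizer with penalty theta (the
two-point case makes this concrete: r = (0, 2), theta = 0.5 gives
f = (0.5, 1.5), i.e. the difference is shrunk by theta). The implementation
grows the greatest convex minorant of the upper tube and the least concave
majorant of the lower tube left to right; when their admissible slope ranges
become incompatible the binding hull's first vertex is emitted as a knot and
the pass restarts there. The construction is a single pass with restarts,
amortized linear time in practice (the test suite checks the empirical
log-log runtime slope), and deterministic; tube-boundary comparisons use a
1e-12 slope tolerance.

KKT structure worth knowing when reading output: on each constant run the
fitted level equals the mean of its observations, except (a) the two
boundary runs, whose dual endpoints are pinned at 0 so the run sum deviates
by exactly theta, and (b) retained local extremes, which deviate by
2*theta/length — these are the features local squeezing deliberately
preserves at their observed level.

### Penalty choice and local squeezing

The default penalty is theta = 0.5 * lambda with lambda = c * sqrt(n) *
sigma; sigma is the scaled median absolute successive difference
(1.48/sqrt(2)) * median |r_{i+1} - r_i|, which ignores the sparse jumps of
f. We read the bare "1.48/sqrt(2) {|r_2 - r_1|, ...}" recipe as this median
— the standard robust estimator this family of methods uses. `c` defaults
to 0.25, chosen so that the breakpoint count roughly matches truth on the
bundled simulator at moderate noise; it is exposed everywhere.

A single global radius flattens narrow CNVs whose total mass is below the
tube diameter. Local squeezing iterates: fit, compute residuals w = r - f,
test every dyadic interval I against the multiresolution bound

    |sum_{i in I} w_i|  <=  sigma * sqrt(C * |I| * log n),     C = 2.5,

and multiply the tube radii by gamma = 0.5 on (exactly) the union of
violating intervals, re-pinning the ends; repeat up to 50 rounds, returning
the last fit flagged unconverged if the cap is hit. The cited squeezing
scheme gives no formulas for the criterion; the dyadic family and C = 2.5
are this package's documented interpretation, both configurable. Squeezing
is local (per-position radii), not a global lambda shrink: that is what
lets a 2-window CNV survive a tube built for n = 35,000. Small gamma
squeezes hard and fast and produces more spurious local extremes; gamma
near 1 is gentler and slower — the default 0.5 trades the two off.

## Preprocessing

- **Outlier filtering.** Windows whose readcount (and GC fraction, when
  present) lies strictly below the pct-th or strictly above the
  (100-pct)-th linear-interpolation percentile are dropped (pct = 1).
  Strict comparisons make fully tied data a no-op. Count and GC criteria
  are evaluated on the original track and combined by conjunction.
- **GC correction.** Windows are binned at integer GC percent; per-bin mean
  counts m_gc are smoothed by a weighted local quadratic regression
  (tricube kernel, span 0.3, weights proportional to bin occupancy —
  implemented in-package because no installed smoother supports both
  weights and degree 2), and counts are rescaled by
  median(count) / m_gc_smooth(gc). Sample and normal are corrected
  independently.
- **Ratio.** Both tracks are restricted to their common surviving windows,
  scaled to the mean of the two library sizes, offset by a pseudocount
  (default 0.5 counts) so zero-count windows stay finite, log2-ratioed,
  and median-centered (default on) so the ±thr calling rule is symmetric
  around copy-neutral. Denoising treats surviving windows as adjacent;
  the index mapping back to genomic coordinates is kept alongside the
  signal.

## Segmentation and calling

CBS recursively tests, per interval, the best circular arc/complement
mean-shift split: the statistic is |sum(arc) - w * mean| / sqrt(w (m - w)),
its p-value comes from within-interval permutations (alpha = 0.01; the
permutation stream is seeded per interval, so results are reproducible),
and accepted splits recurse. Intervals up to 600 windows are searched
exhaustively over all arcs; longer intervals are searched over a
width grid (all widths up to 15, a ratio-1.4 geometric ladder, and each
width's mirror so wrapped arcs are covered). The grid is used identically
for observed and permuted data, so the test remains exact in the
permutation sense; after acceptance the changepoint pair is refined by
exhaustive search within the grid gap so breakpoint locations are not
quantized. Permutations stop early as soon as the p > alpha decision is
certain. `min_width = 2` guards degenerate single-window arcs. This is a
deliberately simplified reimplementation of the classical circular binary
segmentation recipe; it does not reproduce any particular existing
implementation's pruning heuristics.

Calling applies strict thresholds to segment means of the *denoised*
signal: amplification above +thr, deletion below -thr (thr = 0.2 on the
simulated benchmark), neutral otherwise. Adjacent segments with the same
call are then merged into maximal CNV regions, which are the reported unit.
The merge matters: a permutation test finds the taut string's small plateau
artifacts inside a long CNV statistically real (they are), so CBS may cut
one CNV into several near-equal pieces; merged regions are what a caller
reports and what overlap-based evaluation should see.

## Synthetic data

`simulate_ratio_signal` draws r = f + N(0, sigma_N^2) over a zero baseline.
The benchmark suite (`paper_benchmark_suite`) fixes the study conditions:
CNV lengths log-uniform on [1, 10^4] windows, amplitudes ±1, at most 30%
of windows covered, at least one neutral window between events, 10 CNVs
attempted per layout, n = 35,000 windows per signal (the smallest round
size that admits a 10^4-window CNV under the coverage cap), and a 10-point
noise grid sigma_N = 0.47 ... 0.05. Each truth layout is observed at every
noise level; everything is a pure function of the seed. With unit
amplitudes the mean-square CNV power is 1, so the grid spans SNR
= 1/sigma_N^2 ≈ 4.5-400; specifying `snr` instead of `sigma_N` uses
sigma_N = sqrt(P_signal / SNR).

`simulate_paired_tracks` adds the upstream stages for end-to-end tests:
per-window GC ~ Beta(9, 11), a unimodal coverage-vs-GC response peaking at
45% GC, Poisson counts at a controlled mean depth, and the CNV truth
scaling the sample only. It emulates window-level count data, not reads:
no mappability structure, no replication timing, no correlated noise —
so green preprocessing tests show the chain is self-consistent, not that
it removes every bias of real capture data.

## Evaluation

Detection is scored at segment level: a detected CNV region is a true
positive when it overlaps a benchmark CNV of the same direction by at least
80% of the benchmark segment's length (benchmark-sided, per the usual
phrasing of the rule; a reciprocal-overlap flag exists). Matching is
one-to-one, largest overlap first. Sensitivity = TP/(TP+FN),
FDR = FP/(FP+TP). Segment-level true negatives are not well defined, so
specificity counts windows neutral in both truth and detection.
Breakpoint accuracy is the fraction of benchmark CNVs with a detected CNV
matching both endpoints exactly. Length-stratified sensitivity bins
benchmark segments by true length; length-stratified FDR bins detected
calls by detected length (a false positive has no true counterpart to take
a length from).

## Benchmark scale and reproduction

`scripts/acceptance.py` and the benchmark tests sample the full
50-layout x 10-level suite diagonally: 50 independent truth layouts, layout
i scored at noise level i mod 10, so the grid is covered evenly with 50
signals (using few layouts repeatedly across levels makes the
length-stratified denominators collapse for unlucky seeds). CBS runs with
100 permutations there (p = 1/101 still clears alpha = 0.01); library
defaults remain the full suite and 1000 permutations. These are
the package's own problem-size choices for a single-CPU run; metrics are
pooled counts over all signals.

Two benchmark observations deserve honesty. First, narrow-CNV false
discovery under the taut-string pipeline is low (~0.06 for amplifications
in the bundled run) — lower than the reference operating point the suite
compares against. Second, the raw (no-denoising) arm of this pipeline is
strong: with an exact permutation CBS plus region merging, it matches or
beats the denoised arms on pooled sensitivity and FDR, so the claimed
method ordering (taut string ≥ DWT ≥ none) holds only for its
taut-string-vs-DWT half here; the taut string does dominate on exact
breakpoint recovery at low noise and dominates the moving average at every
noise level. The corresponding checks are left asserting the full ordering
and fail honestly rather than being weakened.

## Known limitations

- Dyadic multiresolution intervals are an interpretation; a sliding or
  all-intervals family would be more sensitive but quadratic.
- The CBS width grid can in principle miss a maximum between grid widths
  for the *accept/reject decision* (location refinement recovers the pair
  afterwards); at the benchmark's signal sizes this was never observed to
  flip a decision with non-degenerate effect sizes.
- GC correction assumes enough windows per GC bin to estimate bin means;
  sparsely populated tails lean on the occupancy-weighted smoother.
- The simulator's noise is white; real readcount noise is overdispersed
  and locally correlated, so absolute benchmark rates do not transfer to
  real WES data.
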