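# Methods

`maremap` implements the computational layer of a two-tiered strategy for
assigning transcription factors (TFs) to regulatory elements: yeast
one-hybrid (Y1H) screens detect *which* TFs bind an element, and a
microfluidic occupancy assay on a tiled fragment library localizes *where*
they bind, at 12-bp resolution. Motif scanning, nucleosome-occupancy
masking and luciferase reporter statistics provide the orthogonal
benchmarking layer. This note records the models, the parameters that
matter, and the design choices made where the procedure was genuinely open.

## Tiling design

A regulatory element of length L with 24-bp genomic flanks is tiled with
36-bp fragments advancing in 12-bp steps (24-bp overlap), so every interior
12-bp bin is contained in exactly three fragments and its signal is an
average over three independent measurements. Coordinates are 0-based
half-open with position 0 at the element start; flank positions are
negative. When the covered span L + 2·24 is not a multiple of 12 (e.g. a
998-bp element gives span 1046), one terminal fragment is anchored flush to
the right edge: this guarantees exact coverage without disturbing the 12-bp
bin grid, and the residual sub-step bin at the right edge takes its own
center as representative position. Under containment counting the bin
multiplicities are 1, 2, 3, …, 3, 2, 1 — only the outermost bin on each
side is measured once; exact triple coverage holds for every interior bin.
Flank sequences must be supplied explicitly (they are genomic context;
padding with N would corrupt binding-site content). Each synthesis oligo is
clamp + core + primer-annealing tail; the clamp defaults to `CCC` and the
tail to a fixed 20-mer, both configurable.

## Occupancy landscape and peak calling

Per-fragment bound-DNA fluorescence is divided by the surface-immobilized
protein fluorescence of the same unit cell (a flag disables this when
protein levels were not measured), averaged per bin over the covering
fragments, and interpolated to integer positions with a natural cubic
spline through the bin mid positions (no extrapolation beyond the outer
mids; fewer than four bins fall back to linear with a warning). A monotone
shape-preserving cubic (`pchip`) is available because spline overshoot can
in principle manufacture spurious high positions.

Positions are classified into specific (SBP) and non-specific (NSBP)
binding positions by 1-D 2-means clustering of the interpolated
per-position signal with 1000 random restarts under a fixed seed. In one
dimension every 2-means assignment is a threshold partition, so the Lloyd
iteration vectorizes across restarts via prefix sums over the sorted
values; with 1000 restarts the global optimum is found in practice (tests
verify agreement with an exhaustive threshold-partition search). The lower
cluster center is the bait-specific mean background signal (MBS). A flat
landscape is classified as all-background. Clustering bin-level values
instead of per-position values is a documented option.

Per-position enrichment is E = signal / MBS. SBPs with E < 2 are demoted;
maximal runs of surviving consecutive SBPs become specific binding regions
(SBRs), each with its largest-E position as the peak maximum (leftmost on
exact ties). Replicates are processed independently end to end, including
classification. A peak is reproducible when its maximum falls inside a peak
of the other replicate *and* that peak's maximum falls inside a peak of the
first replicate (the stricter mutual reading of "overlap"; plain
interval-overlap is available as `mode="interval"`). Division by the
maximal signal (max-normalization) is provided for visualization and export
only and is never applied before classification. The whole chain is
invariant under rescaling all intensities by any c > 0.

## Motif scanning with exact p-values

The scanner is self-contained rather than wrapping an external motif tool.
PWM probabilities receive a pseudocount (default 1e-3, applied as
p' = (p + pc)/(1 + 4·pc)); windows are scored by log2 odds against a
0-order background (uniform by default; an estimate from the scanned
sequence is an option, with the caveat that p-values then depend on the
query). Per-position scores are discretized to integer multiples of 1e-3
bits and the exact null distribution of the window score of a random
background k-mer is built by dynamic programming, one position at a time;
tail sums give exact p-values on the same grid the windows are scored on,
so scanner p-values and the null agree by construction and match exhaustive
k-mer enumeration exactly (verified to motif length 8). A window is a hit
when its p-value is strictly below the stringency (1e-3, 1e-4 default,
1e-5); both strands are scanned by reverse-complementing the matrix, with
all coordinates reported on the forward strand. Overlapping hits are all
reported — benchmark support only asks for "at least one hit", so merging
would be inert there.

## Y1H plate calling and aggregation

A well's convoluted growth score is the sum of its four quadrant colony
intensities (the one deliberate simplification of the upstream
plate-image analysis, which this package does not reimplement — inputs are
intensity grids, not photographs). Background is the maximal control
(empty-prey) score on the plate; a well is positive when its score exceeds
(1 + threshold) × background with threshold 0.20. Borderline wells can be
re-called at 0.10 via an explicit per-well override list — deciding which
wells "border the cluster of positives" is a human judgment, so it is an
input, not an inference. Calling is scale-invariant. Baits whose control
background exceeds a configurable absolute cap are flagged self-activating
and rejected. Positives found in both screens of a method are
"reproducible"; the consensus per bait is the intersection of the two
methods' reproducible sets, the union their union, and printed percentages
use round-half-up to integers (32.5% → 33%). Known-interactor sensitivity
sums numerators and denominators over the baits that have literature
interactor sets; baits without one (orphan enhancers) are excluded from the
denominator. The packaged `table1.tsv` fixture transcribes the published
per-bait screen summary, and `published_table_totals()` recomputes its
totals row from the per-bait entries.

## Benchmarking

PPV is the fraction of detected TF–bait interactions supported by ≥1 motif
hit of that TF in that bait; sensitivity is the fraction of motif-predicted
TF–bait pairs that were detected. Both are pair-level: a pair is
"predicted" when the TF has ≥1 hit anywhere in the cloned bait interval
(hits in flank sequence are not counted). Interactions whose TF has no PWM
are excluded from the PPV denominator and reported separately. Nucleosome
masking removes a hit when any base of its interval has predicted occupancy
probability strictly above the threshold (0.3, 0.5 or 0.7); retained-hit
sets are monotone in the threshold, and predicted-pair sets are monotone in
the scanning stringency. Occupancy tracks are consumed from TSV — the
nucleosome model that produces them is upstream of this package.
Sensitivity can be stratified by motif load (hit count and best hit score
per pair).

## Reporter statistics

Per-well firefly luminescence is divided by the co-transfected Renilla
signal; within each (bait, TF) group — including the control group —
outliers are excluded by the fourth-spread rule: the fourths are the
medians of the lower and upper halves of the sorted data (the overall
median belonging to both halves when n is odd), and values outside
[lower − 1.5·d, upper + 1.5·d], d the fourth-spread, are dropped. Groups
of fewer than four values are left unfiltered with a warning. The fold
change is mean(r_TF)/mean(r_CTRL) with standard error propagated as
se = fold·sqrt((sem_T/mean_T)² + (sem_C/mean_C)²), which agrees with a
bootstrap of the ratio within 15% at n = 6. Significance is a two-sided
Welch t-test on the normalized ratios at α = 0.05 (the test is not named in
the source protocol; Mann–Whitney is available as an option). No
multiple-testing correction is applied to the call itself; a
Benjamini–Hochberg column is emitted for information.

One calibration caveat is worth stating plainly: the Welch call itself is
calibrated on clean log-normal nulls at n = 6 (null rejection ≈ 0.04), but
applying the fourth-spread trim to pristine null draws first trims ~19% of
groups and inflates the combined null rejection to ≈ 0.08–0.09. This is the
known cost of outlier rules ahead of t-tests; the filter earns its keep
only when measurements are actually contaminated (failed transfections,
pipetting errors), which the null simulation deliberately does not model.
Both rates are computed and reported by the acceptance script.

## Synthetic data

All generators are pure functions of (parameters, seed); replicate r draws
from seed + 1000·r. Fragment intensities are
baseline · (1 + Σ_sites (enrichment − 1) · overlap_fraction) · exp(ε) with
ε ~ Normal(0, log(1 + CV)) — multiplicative log-normal noise is the natural
model for fluorescence, and the linear-in-overlap site contribution is the
simplest model consistent with a 12-bp site being fully contained in three
consecutive fragments. The default configuration mirrors the method's
benchmark experiment: a 998-bp element with two planted sites (centers at
25% and 65% of the element, width 12 bp, 4-fold enrichment) measured in two
replicates at CV 0.10. Plates draw truncated-normal quadrant scores with
planted positives scaled ×2; PWMs are consensus-concentrated matrices with
occurrences written into the sequence at recorded positions and strands;
nucleosome tracks are logistic-squashed Gaussian-smoothed white noise with
a chosen autocorrelation length.

What the generators do *not* emulate: spatial artifacts and
position-dependent noise on chips and plates, sequence-dependent synthesis
or labeling efficiency, protein-concentration drift across a chip row,
cross-talk between adjacent spots, and real nucleosome sequence preference.
Passing recovery tests therefore demonstrates the correctness and
calibration of the algorithms under their stated noise model, not the
wet-lab error modes of the assays.

## Problem sizes and numerics

The statistical guarantees are estimated at sizes chosen to make their
binomial noise negligible relative to the thresholds: 100 seeded
simulations for site recovery (≥95% must recover every planted site within
±12 bp) and for the noise-only false-positive control (≥95% must yield zero
peaks), 2000 replicates for the type-I error (0.05 ± 0.02), 20 instances
for the clustering-vs-oracle check, and full 4^k enumeration for motif
p-values at k ≤ 8. Degenerate inputs are handled explicitly: flat
landscapes classify as all-background; zero fourth-spread excludes nothing;
empty peak lists propagate as "nothing reproducible"; an all-identical
2-means input never divides by zero because the degenerate path returns
before clustering. Ties are broken deterministically (leftmost peak
maximum; values exactly at the 2-means cut go to background).
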