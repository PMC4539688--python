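# Methods

## Scope and data flow

hicdelta detects differential interactions (DIs) between biological
conditions in Hi-C data. The stages are: restriction-digest genome model →
chimeric-read splitting and pair QC → bin-pair counting → abundance
filtering → offset-based normalization → quasi-negative-binomial GLM
testing → consolidation. Each stage is an importable module; the CLI and
`pipeline.run_pipeline` only orchestrate.

## Genome model

An enzyme is a palindromic recognition site plus the 5′-side cut offset
*p*; the overhang is `len(site) − 2p` and must be non-negative (5′ overhang
or blunt). Fill-in plus blunt ligation writes
`site[:p+L] + site[p:]` across a junction — the **ligation signature**
(HindIII: AAGCTAGCTT). The paper-facing conventions that the literature
leaves open are fixed as follows:

* a "cut position" is the **centre** of the recognition occurrence — the
  blunt position after fill-in; symmetric and enzyme-agnostic;
* overlapping occurrences all count (step-1 scan); occurrences containing
  N are skipped;
* fragments are non-overlapping half-open intervals between centre cuts
  (some pipelines let fragments overlap by the overhang; we do not);
* bin boundaries are nominal multiples of the bin width moved to the
  nearest cut, ties going to the larger coordinate; boundaries that
  collide after rounding drop the empty bin;
* coordinates are 0-based half-open internally, 1-based inclusive in
  reports.

## Read-pair processing

Reads containing the signature are split at its centre; the 5′ segment is
the informative one (the mate locates the 3′ partner), and on simulated
junction-spanning reads the pre-split 5′ segment relocates its true origin
at least as often as placing the full-length read (tested property).

The inferred sequencing-fragment size of a pair is the sum of each read's
distance to the nearest cut in its own direction (chromosome end if none).
Filters run in a fixed order so the tallies partition the removals and are
reproducible: (1) unmapped or MAPQ < 10; (2) duplicate flag (honoured, not
recomputed); (3) inferred size strictly above 600 bp (non-specific
cleavage); (4) intra-chromosomal inward pairs with 5′-to-5′ gap < 1 kbp
(dangling ends); (5) outward pairs with gap < 25 kbp (self-circles).
Same-strand and inter-chromosomal pairs are exempt from the orientation
filters. The gap is the 5′-to-5′ distance, not the insert extremes.
Technical replicates are pooled by appending to one HDF5 pair store.

## Counting and abundance

Counts are sparse: only observed bin pairs are materialized; the universe
sizes (possible intra/inter pairs) are carried so that implicit zeros can
enter order statistics analytically. Marginal counts treat each read
singly (a diagonal pair contributes 2 to its bin), so marginals sum to
twice the pair count and proxy genomic coverage for CNV work.

The filter statistic is the average log2 CPM with a library-size-scaled
prior (default 2) added to the counts and twice the scaled prior added to
the library sizes. This is finite at zero counts and monotone in every
count; it is only *approximately* invariant under common rescaling of
counts and depths — exact invariance is impossible for any nonzero prior —
and the tests assert near-invariance at realistic counts.

## Filtering

* **direct** (default, fold 5): threshold = median abundance of the FULL
  inter-chromosomal universe (implicit zeros included, via an analytic
  pooled median) + log2(fold). Inter-chromosomal contacts are mostly
  non-specific ligation, so this median estimates the non-specific rate.
* **trend**: loess of abundance on log10 distance over intra-chromosomal
  pairs; keep pairs above their fitted value; inter pairs fall back to the
  direct threshold. Degenerate (all-equal) distances fall back to the mean
  with a warning.
* **peak**: enrichment = pixel abundance − max over square rings at
  Chebyshev radius 1..r (pixel excluded; truncated at block edges and at
  the diagonal for intra blocks), computed with summed-area tables and
  verified against an exhaustive scan. The ring geometry and threshold are
  parameters; donut/quadrant decompositions are out of scope.

## Normalization

All methods return per-(bin pair, library) offsets on the natural-log
scale: log library size plus an adjustment that is mean-centred across
libraries per bin pair (offsets are only identified up to a per-pair
constant). Counts are never altered. M/A diagnostics are in log2; ln 2
converts at the boundary.

* **loess**: per library, M (log2 CPM minus the per-pair across-library
  mean) is smoothed against average abundance A with plain (non-robust)
  lowess plus one twicing pass (refit of the residuals), which roughly
  halves the smoothing bias; the fitted curve is the adjustment. After
  normalization the refitted M-vs-A trend is flat for every library pair.
  Span default 0.3, prior 2, tricube weights — the low-count adaptations
  are our choices and are stated here rather than inherited.
* **scaling**: one factor per library from a doubly trimmed mean
  (trim 30 % in M, 5 % in A) of *prior-free* M values with zero counts
  excluded — prior-free so a pure scaling bias is recovered exactly —
  anchored to geometric mean 1. The trimming makes it robust to a
  minority of genuine DIs.
* **CNV**: the covariate for bin *b* is the library-size-adjusted log2
  ratio of its marginal counts between a library and the reference.
  Because copy-number changes are regional, the covariate is first
  denoised with a 5-bin running median along each chromosome
  (`smooth_bins=5`; set 1 to disable). Each bin pair carries the ordered
  covariate pair and its own log2-FC as response; a hand-written
  kNN/tricube local-*linear* surface (span 0.1 of the data, ≥ 30
  neighbours) fitted at the data points is the CNV bias. With > 2
  libraries each library is smoothed against the reference and the
  adjustments re-centred. No installed package offers 2-D loess
  prediction, hence the in-house smoother; it is exercised against
  spike-in recovery rather than a reference implementation.
* **iterative correction**: symmetric Sinkhorn-style balancing — rows and
  columns repeatedly divided by relative coverage until the CV of nonzero
  row sums < tol (default 1e-6, ≤ 50 iterations), optionally excluding the
  lowest-coverage fraction of bins first. Provided as a diagnostic /
  alternative; not chained into GLM offsets by default.

## Dispersion estimation and testing

GLMs are fitted per bin pair by vectorized damped Fisher scoring (step
halving on deviance increase; relative-deviance tolerance 1e-8, 100
iterations, non-converged pairs flagged and returned at the last iterate).
With an intercept-only design and equal offsets the score equation is
solved exactly by the mean, which the tests assert; at φ = 0 the fits
match an independent Poisson GLM implementation.

The NB dispersion trend maximizes the **Cox–Reid adjusted profile
likelihood** (NB log-likelihood minus half the log-determinant of the
Fisher information) summed within ~20 equal-occupancy abundance bins, over
a log-spaced φ grid with quadratic interpolation between grid points,
then smooths log φ against abundance by lowess and interpolates per bin
pair (clamped at the range ends). Estimation requires residual df ≥ 1.

QL dispersions: raw σ²_b = deviance at the trended φ divided by the
residual df. Under the model raw values are trend × F(df, d₀); the trend
is a plain local mean of log raw values with the log-F mean bias removed,
and d₀ comes from matching the spread of the log residuals to the
theoretical log-F spread. In robust mode (default) the residuals are
winsorized at the (5 %, 10 %) tails and matched against *winsorized*
theoretical moments computed by quadrature — a plain winsorized match
would understate the spread and report an infinite prior. Exact-zero
deviances are floored at 10⁻³ × the median positive value for the log
scale only; the squeeze uses the unfloored raw values:
σ²_post = (d₀·trend + df·raw)/(d₀ + df).

The QL F-test computes the deviance drop between the full fit and a fit
on the design projected onto the contrast's null space, divides by the
contrast df and σ²_post, and refers to F(q, df + d₀) (χ² when d₀ = ∞).
log2 fold changes are reported for 1-df contrasts. BH adjustment is the
standard step-up (delegated to statsmodels; an independent implementation
serves as the test oracle). Two deliberate choices: deviance-based rather
than Pearson raw dispersions (small-count stability), and robust EB on by
default.

Calibration was verified two ways: analytically trivial cases, and
null-simulation uniformity — the p-value KS test against uniform passes
(KS p ≈ 0.3–0.7 across seeds) at the same level as an independent
reference QL implementation run on identical counts, which also matches
our detections bin-pair-for-bin-pair when given identical offsets.

## Consolidation

Clustering links two bin pairs when both anchor-interval gaps are ≤
`max_gap` (Chebyshev adjacency within a chromosome pair), closed
transitively; ids are deterministic (sorted first member) and the
implementation is verified against brute-force graph components. Nesting
maps a small bin pair to the parent whose bins contain its anchor
midpoints. Evidence is pooled flat — a parent collects its own p-value
(if tested) plus all nested children's — and combined with Simes' method
(min over i of n·p₍ᵢ₎/i); BH across parents gives one FDR per event.
Clustering is applied to all retained pairs by default (clustering only
pre-selected significant pairs is available by subsetting first). Plaid
plots raster read pairs into pixel boxes, linear colour scale in count
divided by library size, with a 45°-rotated variant for near-diagonal
views.

## Synthetic data and benchmark

`simulate_counts` builds a two-chromosome interaction space (70 bins each
by default ⇒ 9,870 fully materialized bin pairs) with log-uniform baseline
mean counts — intra-chromosomal in [5, 500] per million read pairs,
inter-chromosomal in [0.1, 2] to emulate non-specific ligation — so the
filter and normalization see realistic structure. 10 % of intra pairs are
spiked at fold 4 in the second group (half up, half down); counts are NB
with dispersion φ = 0.05 (BCV ≈ 22 %) at library size 10⁶, 2 groups × 2
replicates, 5 benchmark iterations; all constants live in one `SimParams`
block and every draw derives from a single seed.

The benchmark chain is: direct filter (fold 5) → normalization → trended
dispersion → QL F-test → BH at the nominal FDR. For the *benchmark*
normalization we use trimmed scaling, matching the principle used on real
data of choosing the method for the biases actually present: the
simulation has no trended bias, and fitting a loess trend to
bias-free data absorbs part of the asymmetric DI signal at the abundance
extremes (up-spiked pairs dominate the top of the abundance range),
costing power and shifting the observed FDR upward. The null-calibration
check, where no DIs exist, runs the full loess chain.

The comparator is an exact two-sided binomial test of y₁ in y₁+y₂ trials
at p₀ = N₁/(N₁+N₂) per bin pair (minlike two-sided p, verified against
pmf enumeration), plus the ad-hoc workaround that intersects detections
over every between-group library pairing. On the default design the QL
pipeline's observed FDR stays at or below nominal while both binomial
variants exceed it substantially, and the QL pipeline detects at least as
many true DIs as the intersection workaround — the directional behaviour
the method is designed to show. Observed FDR is false detections over
max(1, detections), averaged over iterations with standard errors.

`simulate_chimeric_reads` joins the filled-in end of one restriction
fragment to the start of another (reconstituting the signature), samples
a read across the junction at a uniform offset, and records the 5′
origin; it drives the split-vs-naive alignment property test.

`apply_cnv` spikes a regional copy gain by scaling each bin pair by
fold^(anchors inside the region) — one-anchor pairs ×fold, both-anchor
×fold² — which is how interaction counts respond to the product of anchor
copy numbers and produces the coherent marginal bias the CNV offsets
model. (Doubling only both-anchor pairs, an alternative design, yields a
weak bin-heterogeneous marginal signal that no marginal-covariate method
can fully separate.)

## What the simulations do and do not show

The generator reproduces overdispersed replicate counts, a distance-free
abundance landscape, non-specific inter-chromosomal background, spiked
DIs, trended and CNV biases, and junction-spanning reads. It does not
emulate distance-dependent contact decay within the spiked benchmark
(the trend filter is tested on separately constructed decaying fields),
domain/compartment structure, mappability or GC variation, duplicate
reads, or real aligner behaviour (alignment itself is out of scope;
duplicate flags are honoured, not computed). Passing benchmarks therefore
demonstrate correctness of counting, filtering, normalization and the
inference machinery under the stated count model — not robustness to
every artifact of real libraries.

## Problem sizes and numerical choices

Default test-suite and acceptance problem sizes — ~10⁴ bin pairs, 4
libraries, 5 benchmark iterations, 50×50 balancing matrices — were chosen
as the smallest sizes at which the statistical properties under test
(trend recovery within ±0.01 of φ, KS uniformity, FDR within 2 MC
standard errors) are measurable above Monte-Carlo noise; the full suite
runs in well under a minute of compute. Degenerate inputs (all-zero
matrices, empty pair lists, missing inter-chromosomal pairs, zero
residual df) raise informative errors rather than returning NaNs; ties in
boundary rounding and canonical ordering are broken deterministically so
reruns are byte-identical.

## Known limitations

* Multi-enzyme digests, non-palindromic and 3′-overhang enzymes are
  rejected.
* The CNV surface assumes two-library contrasts (or library-vs-reference
  loops); it has no joint multi-library model.
* The QL machinery needs replication (residual df ≥ 1); single-replicate
  designs cannot be tested.
* Fragment-resolution counting, donut peak calling, TAD calling and
  interactive visualization are out of scope.
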