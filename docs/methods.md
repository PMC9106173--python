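# Methods

## Signal model and barcode construction

A trial is a uniformly sampled univariate signal: the angular velocity of
one foot around the medio-lateral axis (deg/s, 100 Hz by default). The
0-dimensional sublevel-set persistence barcode records, as the threshold α
sweeps upward, the birth of a connected component of {t : f(t) ≤ α} at each
local minimum and its death when it merges with an older component at a
local maximum (elder rule). The implementation is a union-find sweep over
the plateau-collapsed samples sorted by value. Choices the definition
leaves open are resolved as follows:

- **Plateaus.** Runs of equal consecutive samples are collapsed to a single
  extremum at the run's first index, making the extrema sequence strictly
  alternating (which the min/max pairing requires). The barcode depends
  only on the sequence of extrema values, so it is invariant under time
  reversal and index dilation.
- **Boundaries.** The first/last samples are kept as extrema, but boundary
  maxima never kill components (they cannot bridge two components);
  boundary minima do create components. This follows from the sweep itself
  rather than from a special case.
- **Elder-rule ties.** When two components born at the same level merge,
  the one whose representative minimum has the smaller time index survives.
  Any consistent rule yields the same multiset of bar lengths; this one
  makes outputs deterministic.
- **Degenerate inputs.** Signals shorter than 2 samples are rejected; a
  constant signal has a single degenerate minimum and a single infinite
  bar. Equal-valued minima and maxima cannot create zero-length bars: a
  merging component's birth is always strictly below the merge level.

Bar levels stay in signal units (deg/s) and are never normalised, because
the bar-to-bar and bar-to-diagonal costs operate on raw levels.

Trimming removes the k longest bars (the infinite bar counts as longest);
ties break by length descending, then birth ascending, then birth time
index — again purely for determinism.

## Step counting

The trim count k is the number of gait cycles in the trial. For a
single-foot signal one cycle corresponds to one long-bar pair, so "steps"
here means that foot's cycles; a metadata step count, when present,
overrides the estimate (and a config switch can force either source).

The automatic estimate uses the mean-centered, lag-0-normalised
autocorrelation function: the first local ACF maximum at a lag of at least
`min_cycle_s` (default 0.4 s — shorter gait cycles are not physiological)
whose ACF value exceeds `acf_floor` (default 0.2 — suppresses spurious
ripples; the method is a heuristic and the thresholds are package choices)
gives the cycle duration; k = round(duration / cycle duration), floored at
1, the rounding absorbing an incomplete final step. Signals with no
qualifying peak (e.g. heavily disordered gait, white noise) raise a
step-count failure; the pipeline excludes such trials with a warning
naming them.

## Bottleneck distance

Barcodes are compared with the bottleneck distance, with both barcodes
augmented by zero-length diagonal bars so bijections always exist. Bars
with infinite death can only be matched to each other (the cost of mixing
finite and infinite deaths is infinite), so barcodes with different
infinite-bar counts are at distance +∞ — returned as a value with a
warning rather than raised, since trimmed pipelines never produce it.

The solver is exact: the optimum is a member of the candidate set
{all pairwise bar costs} ∪ {all half-lengths (death − birth)/2}; a binary
search over the sorted candidates finds the smallest radius r whose
threshold graph admits a perfect matching, decided by Hopcroft–Karp-style
maximum bipartite matching on the standard (m₁+m₂)×(m₁+m₂) diagonal-slot
reduction. Infinite bars are matched among themselves by sorted births,
which is optimal for points on a line. Feasibility uses a ≤ r + 1e−12
slack to guard against representation error at the optimum. Cohort
barcodes have tens of bars, so exactness costs about a millisecond per
pair; the O(n²) distance matrix can be cached on disk keyed by a digest of
the barcodes.

The suite checks the solver against an exhaustive enumeration oracle and
verifies the stability bound d(B(f), B(f+η)) ≤ sup|η| empirically.

## Embedding

The trial-by-trial distance matrix is embedded with UMAP using the
precomputed-metric mode (the dissimilarity is never recomputed from
coordinates). Defaults: n_neighbors = 45 (global structure), min_dist =
0.3, 2 components. Because the optimisation is stochastic, the seed is a
mandatory part of the configuration (default 0) and is recorded in the
provenance log; fixed-seed runs are bit-identical. n_neighbors is capped
at n − 1 for cohorts smaller than the default, with a logged warning.
Absolute embedded coordinates carry no meaning; only relative structure
does. Note that the underlying UMAP implementation is not exactly
equivariant under permutation of the input rows (optimisation order
consumes randomness); group-level structure, which is all the features
read, is preserved, and the tests check that form.

## Group features

For groups defined by metadata (never by clustering the embedding):

- Sil(Cᵢ, Cⱼ): mean over x ∈ Cᵢ of (b − a)/max(a, b), with a the mean
  plain Euclidean distance from x to its |Cᵢ|−1 group-mates and b the mean
  distance from x to Cⱼ. Asymmetric; in [−1, 1]. Undefined for singleton
  Cᵢ — a singleton raises rather than returning 0; the experiment tables
  mark such cells unavailable (NaN) instead.
- MSD(Cᵢ): mean squared distance over the |Cᵢ|(|Cᵢ|−1)/2 unordered
  distinct pairs. The normalisation 2/(n(n−1)) identifies the sum as
  running over unordered pairs; the ordered reading would halve nothing
  and double nothing coherently, so the unordered mean is implemented.
- SD(Cᵢ): maximum squared pairwise distance; 0 for singletons.

The three experiment tables are: healthy-vs-patient (one row), EDSS
thresholds i ∈ {0, 2, 2.5, 3, 3.5, 4, 4.5, 5, 5.5, 6} partitioning into
{EDSS ≤ i} vs {EDSS > i} with both silhouette orientations (healthy
subjects carry EDSS 0), and the per-subject longitudinal table comparing
the M0 and M6 session groups. A config switch can compute the features
directly on the bottleneck matrix instead of the embedding for sensitivity
analysis; the embedded-space computation is the standard one.

## Synthetic cohorts

The generator emulates the four-extrema topology of one gait cycle: a
post-heel-strike dip A (−100 deg/s), the foot-flat plateau B (+10), a
deeper pre-toe-off dip C (−280), and the swing plateau D (+350), at
fractions (0.07, 0.28, 0.55, 0.78) of a 1.2 s cycle. Values are monotone
cubic (PCHIP) between anchors, so a noise-free trial has exactly the
anchor extrema: its barcode has one long bar per cycle (pair (C, D), one
infinite) and one medium bar per cycle (pair (A, B)). Anchor levels and
cycle duration are in the range of healthy adult foot angular-velocity
recordings.

Severity is modelled as band-limited oscillation noise (6 random-phase
sinusoids in 4–12 Hz; baseline amplitude 6 deg/s for everyone plus
16 deg/s per severity unit) and timing jitter (1.5% of cycle duration per
severity unit) — exactly the small-bar signature the trimmed-barcode
distance is designed to read. Patient severities are spread evenly over
[1, 4] and mapped to EDSS half-steps; walking velocity decreases linearly
with severity for the velocity-difference baseline metric. Asymmetry
multiplies the left-foot oscillation amplitude for chosen
(subject, session) pairs; longitudinal drift adds severity at M6 for
chosen subjects. Per-trial seeds derive from the cohort seed and the
trial's design coordinates, so generation is deterministic and
order-independent.

What the generator does **not** emulate: real stride-to-stride waveform
variability, double-support timing, U-turns and segmentation artifacts,
sensor drift, or any biomechanical coupling between feet. Passing the
planted-structure tests therefore shows that the pipeline recovers
oscillation-amplitude structure it is designed for, not that it validates
clinically on real cohorts.

## Problem sizes and determinism

The test suite and the acceptance script run cohorts of 8 subjects
(32 trials, single session) for the separation experiment and 7 subjects
(56 trials, two sessions) for the longitudinal experiment, 5 cycles per
trial, chosen as the smallest designs in which all four planted effects
(separation, drift, asymmetry, outlier) are simultaneously identifiable;
planted effect sizes (drift +2.5 severity, left-foot factor 3.5, outlier
gain 2.5) are set clearly above the within-group variation. Oracle and
stability checks use 200 barcode pairs and 100 random-walk signals. All
randomness flows from explicit seeds; the pipeline is a pure function of
(input digests, config, seed) and records all three in its provenance log.

## Known limitations

- The ACF step counter degrades on severely disordered gait (by design it
  then fails loudly; metadata counts are preferred whenever available).
- Exact bottleneck matching scales roughly with the fourth power of the
  bar count per pair; signals with thousands of extrema would need the
  geometric approximations the package deliberately avoids.
- UMAP coordinates, and hence the numeric feature values, depend on the
  seed; conclusions should rest on seed-stable orderings and signs, which
  is what the tests assert.
- Inputs are assumed to be pre-segmented straight-walk signals; no
  proprietary IMU formats, turn detection, or higher-dimensional homology.
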