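# Methods

This note documents the models, estimators and design choices behind
`emmap`, and what the synthetic-data experiments do and do not demonstrate.

## The multilevel map

A recording of duration `NEMr` (default 1024 ms at 1000 Hz) is tiled by a
dyadic hierarchy: level *l* consists of `NEMr / (Nss·2^(l−1))` half-open
windows of length `Nss·2^(l−1)` ms, with `Nss` = 64 ms, giving five levels of
16/8/4/2/1 cells.  Windows are `[start, end)` in ms, so the two children of
a cell tile it exactly — no sample is shared or skipped.  Cells are
addressed 1-based as (level, index).  Each measure is evaluated
independently on the samples of each window; a cell where the measure fails
is marked missing (NaN) with the reason logged, never silently zeroed.

## Entropy estimators

**Approximate entropy.**  `ApEn(m, r, N) = Φ^m(r) − Φ^{m+1}(r)` with
`Φ^q(r)` the mean over all `N−q+1` templates of the log fraction of
templates within Chebyshev distance `r` (comparison `d ≤ r`, self-matches
included, so every count is positive and the logarithm is defined).  Natural
logarithms throughout; units are nats.

**Fuzzy entropy.**  Templates are first de-meaned ("baseline removed");
similarity of a pair is `exp(−d^n / r)` with Chebyshev `d`; `φ^q` averages
pairwise similarity with self-pairs excluded, over templates `i = 1..N−q`
(the last available template is dropped, a literal reading of the
finite-set estimator); `FuzEn = ln φ^m − ln φ^{m+1}`.  If `φ^{m+1}`
underflows to exactly zero — every pair far apart on the scale of `r` — a
degenerate-similarity error is raised and the map layer records the cell as
missing, rather than reporting an infinite entropy.

**Tolerance scope.**  The defaults follow the operating point used for
eye-movement analysis: `m = 2`, `r = 0.2·SD` for ApEn and `n = 2,
r = 0.075·SD` for FuzEn, where SD is the *population* standard deviation
(÷N; the convention is fixed for reproducibility and is numerically
indistinguishable from ÷(N−1) at N = 1024) of the **whole parent series**,
not of the individual 64-ms segment.  This matters: a series-wide tolerance
makes segment entropies comparable across the map, because saccadic
velocities dominate the SD and thus set one common scale.  A per-segment
scope (`r_scope="segment"`) is available for sensitivity analysis.
`fuzen_param_sweep` reproduces the (n, r) selection diagnostic: FuzEn over a
grid of (n, r) on a collection of series, tabulating the across-series SD;
the operating point is conventionally taken where that SD starts to
decrease only slowly.

Two estimator facts worth knowing:

- ApEn is *not* guaranteed non-negative at small N (its two template
  averages run over different index sets); Gaussian series shorter than ~64
  samples go negative a few percent of the time.  All map segments are
  ≥ 64 samples, where we observe no negative values.
- FuzEn scale behaviour follows from `μ = exp(−d^n/r)`: scaling the data by
  c requires scaling `r` by `c^n` (not c) to leave the value unchanged.
  With the SD-proportional tolerance used here this is immaterial in
  practice, since `r` tracks the data scale.
- Because the similarity kernel with `n = 2` is effectively Gaussian with
  width `√r`, FuzEn at the default tolerance is dominated by the closest
  template pairs; its per-cell values are noticeably noisier than ApEn's on
  64-sample segments.

## Largest Lyapunov exponent

State space is reconstructed by delay embedding with `M = N − (m−1)τ`
vectors.  The lag τ is the first *prominent* minimum of the lagged mutual
information (equal-width histogram estimate, 16 bins): the raw MI curve of
short series jitters on its plateau, so the curve is smoothed with a
3-point moving average and a dip must have prominence ≥ 10% of the curve
range (`scipy.signal.find_peaks`) to count.  With this rule the classic
quarter-period result for a sinusoid verifies numerically (τ = 25 for a
100-sample period).  If the lag-1 MI is already at the small-sample noise
floor (white noise: no dependence to exploit), or no prominent dip exists,
the MI-minimising lag is returned with a fallback flag.

The dimension m is chosen by the Kennel false-nearest-neighbours test
(distance-ratio threshold 15, size criterion 2 series SDs, convergence at
< 1% false neighbours); pairs separated only at rounding level (exactly
periodic data) are counted as true neighbours, since the ratio test on them
compares rounding noise.  Stochastic data never converges and is flagged.

Divergence is tracked from each reference vector's nearest neighbour
(Euclidean metric), excluding temporally close vectors (Theiler-style
window, default `m·τ` samples — without it, adjacent samples on the same
trajectory segment dominate the neighbour search).  Two estimators:

- `paper_average` (default): `λ = mean_j ln(d_j(i)/d_j(0)) / (iΔt)` at a
  fixed horizon `i = follow_steps` (default 10 samples).  Faithful to the
  defining divergence relation, but sensitive to the choice of i.
- `rosenstein_slope`: least-squares slope of `⟨ln d_j(i)⟩` against `iΔt`
  over `i = 1..follow_steps` — the small-data algorithm, more robust, used
  for calibration.  On the fully chaotic logistic map (analytic exponent
  ln 2) it recovers λ within a few percent at N = 2000.

Pairs with zero initial separation are skipped; if all are degenerate an
error is raised.  λ is reported in units of 1/Δt (1/s for 1000 Hz data);
positive values mean divergence, negative convergence.

**Embedding granularity.**  (m, τ) are estimated once per 1024-sample
series and reused for every segment of that series: 64-sample segments are
too short for reliable FNN/MI.  Segments where the selected embedding
leaves too few state vectors (fewer than max(10, follow_steps+2)) or no
neighbour candidate outside the exclusion window fall back to a fixed
(m = 2, τ = 1); if even that is infeasible the cell is missing.

## Normalization and feature vectors

Before feature assembly every map level is min-max rescaled to [0, 1], per
measure, per level, pooled across all series of the dataset — fitted on the
whole dataset *before* cross-validation splitting, replicating the original
processing order.  This leaks distributional information across folds; a
fold-safe variant (min-max refitted on each training fold,
`fold_safe_normalization=True`) is provided as the leakage-free
alternative.  Per-measure (rather than joint) rescaling is used so each
measure's dynamic range is fully exploited.

A feature specification selects 1–3 *contiguous* levels from 1–4 and a
non-empty subset of the three measures.  For class c (the c-th segment at
the finest selected level lX) the feature vector holds the normalized cell
(lX, c) and, for each coarser selected level, the ancestor cell whose
window contains that segment — for every selected measure, giving
|levels|·|measures| features.  Rows with any missing feature are dropped
and counted.  The class count is `Ncl = NEMr/(Nss·2^(lX−1))`; note the
widely printed form of this rule is ambiguous about operator precedence and
is implemented to match its enumerated values (16, 8, 4, 2).

## Classification

kNN with Euclidean distance and uniform majority vote, evaluated by
leave-one-group-out cross-validation where a group is one
participant-session (all of a session's recordings are held out together,
so accuracy measures transfer to unseen sessions).  Per-class accuracies
are pooled over folds by default; per-fold averaging is available by flag.

**Tie-breaking.**  Vote ties are frequent whenever k is not much larger
than the class count (k = 15 with 16 classes ties on most queries), and any
index-based rule then biases per-class accuracies — breaking ties toward
the lowest class index inflates class 1 several-fold under label
permutation.  Ties are therefore broken toward the vote-tied class with the
smaller summed neighbour distance, which is deterministic and symmetric
across class indices on uninformative features; exact distance ties (a
measure-zero event for continuous features) fall back to the lowest class
index.  With this rule, label-permuted data scores at the 1/Ncl chance
level, per class, within binomial bounds.

## Synthetic saccadic signals

The generator emulates a 1024 ms "jumping point" trial at 1000 Hz in the
velocity domain with three consecutive events:

| component | model | defaults |
|---|---|---|
| saccadic latency | truncated-normal duration | mean 170 ms, SD 25, bounds [100, 250] |
| latency dynamics | fixational tremor + weakly unstable AR(1) | tremor SD 15 deg/s; AR a = 1.002, innovation SD 1.5 |
| saccade | raised-cosine velocity pulse | duration U(30, 80) ms; peak from a saturating main-sequence relation (≤ ~520 deg/s) |
| fixation | tremor + AR(1) low-pass drift + Poisson microsaccades | tremor SD 15 deg/s; drift SD 3; 1.5 microsaccades/s, peaks U(8, 25) deg/s |
| sensor noise | i.i.d. Gaussian, everywhere | SD 1 deg/s |

Two modelling choices carry the scientific content:

- **Micro-movement placement.**  Tremor/drift/microsaccades are fixational
  phenomena: they are present while the eye holds a target — during the
  latency period (old target) and the final fixation (new target) — and
  suppressed during the ballistic saccade.  Consequently the saccade window
  is a large, *smooth* pulse with only small sensor noise, and both
  entropies attain their map minima there, while latency and fixation show
  similar, higher entropy.  (With stationary white noise everywhere this
  signature inverts for FuzEn: additive noise keeps increment
  unpredictability constant while the tolerance is series-wide.)
- **Latency instability.**  The weakly unstable AR(1) component makes
  nearby latency-period trajectories genuinely diverge, producing the
  positive Lyapunov exponents associated with pre-saccadic programming.

Seeding: each series' RNG derives from
`SeedSequence(master_seed, spawn_key=(participant, session, point))`, so a
single integer reproduces any subset of a dataset bit-identically.

**What the generator does not model:** smooth pursuit, binocular disparity,
blinks/artefacts, position-dependent (main-sequence direction) effects,
tracker-specific noise spectra, or any participant-level individuality
beyond independent draws — consequently, passing tests demonstrate that the
pipeline recovers the event structure it is pointed at, not that it attains
any particular accuracy on real oculographic recordings, whose between- and
within-subject variability is far richer.

## Problem sizes and numerical choices

- Map-signature experiments use batches of 100 series (10 participants × 2
  sessions × 5 points) and 10 independent batches; the study-scale geometry
  (24 × 2 × 29 with four excluded sessions = 1276 series) is exercised for
  dataset arithmetic.
- Entropy implementations are verified against plain-loop transcriptions of
  the defining equations to 1e−12 on series up to N = 256.
- Two-point differentiation of positions is the forward difference
  `(x_{i+1} − x_i)/Δt` (length N−1); a central-difference stencil is
  available.
- A constant series has SD 0 and hence no usable SD-proportional
  tolerance; since both entropies equal 0 for *any* positive tolerance
  there, the map layer substitutes a unit tolerance instead of failing.
- Min-max normalization of an all-equal value population raises a
  degenerate-range error and the affected cells are flagged missing, never
  divided by zero.
- All randomness is NumPy `default_rng`; no global seeding.

## Known limitations

- FuzEn on 64-sample segments is min-distance dominated (see above): its
  level-1 cells are noisy, and single-series maps occasionally place the
  FuzEn minimum outside the saccade window even when the averaged map is
  clean.
- The `paper_average` LLE at a fixed horizon conflates noise-driven and
  dynamical divergence; on stochastic segments it is positive by
  construction.  Sign and magnitude comparisons across segments are
  meaningful, absolute values are estimator-specific.
- Leave-one-session-out folds assume session labels are exchangeable;
  with the dataset-wide ("paper") normalization the reported accuracies
  include a small optimistic bias relative to the fold-safe variant.
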