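# Methods

This note documents the models and numerical choices behind
`stridetrends`: what each component assumes, which parameters matter, what
the synthetic-data generator does and does not emulate, and where the
design was genuinely open.

## Signal model

A per-trial gait parameter (stride time ST in seconds, stride length SL in
meters) is modelled as

    y_i = T_i + e_i,     i = 1..N (stride number),

with `T` a continuous piecewise-linear trend and `e` stationary,
short-amplitude noise. Stride speed is SS_i = SL_i/ST_i exactly. The
package's central claim-testing machinery asks whether the apparent
persistence of `y` comes from `T` or from `e`.

## Trend extraction (adaptive regression splines)

The trend is fitted as f(x) = β₀ + Σ βₘ hₘ(x) with hinge basis functions
max(0, x−t) / max(0, t−x), x the stride index, in two phases:

* **Forward pass.** Candidate knots are every interior abscissa (boundary
  knots duplicate the global line and make the design singular). At each
  step the reflected pair with the largest SSE reduction is appended and
  all coefficients re-estimated by least squares; the search is implemented
  by orthogonalizing candidate columns against the current design's Q
  factor, which gives the exact pair-wise SSE reduction without refitting
  per candidate. Ties are broken toward the smaller knot (determinism).
  Iteration stops when the R² gain drops below `stop_threshold`
  (default 1e-3) or the term budget is reached.
* **Backward pruning.** Terms are deleted one at a time (smallest SSE
  increase first) down to the intercept; the model minimizing
  GCV(λ) = SSE/[1 − M/N]² with M = r + cK is returned, ties toward fewer
  terms, c = 2 (the customary knot penalty for additive models), r the
  design rank, K the distinct-knot count. Models with M ≥ N get infinite
  GCV. Lone terms with coefficient below 1e-12 of the response scale are
  dropped afterwards.

Only the additive, order-1 (no interaction) variant exists: for a single
predictor, products of hinges would introduce quadratic pieces and are out
of scope.

**Term budget.** `max_terms` defaults to 43 basis functions (21 knots).
A 5-minute trial of ~250 strides with mean segment duration ~23 strides
carries ~11 knots, i.e. 23 basis functions; a budget of 21 would make the
typical trial unrepresentable, so the default allows roughly twice the
expected knot count. For very short series the GCV prune, not the budget,
is the effective regularizer.

## Scaling estimators

* **DFA-n.** The mean-centred series is integrated; the profile is split
  into non-overlapping forward boxes of size n (remainder discarded, one
  polynomial per box, matching the single-sum definition of the
  fluctuation function); α is the least-squares slope of log F(n) vs
  log n. Box sizes are geometrically spaced integers with ratio 2^(1/8)
  from max(4, 2(order+1)) to N/4, the whole grid being used for the slope.
  This grid was fixed by requiring the estimator to reproduce published
  median exponents for windowed FBM ensembles (0.53/0.82 at k = 40 and
  0.43/0.76 at k = 260 for H = 0.40/0.75, DFA1); it matches the
  conventional defaults of the widely used WFDB implementation.
* **Madogram.** For a path Y, V(l) = Σ|Y_{i+l} − Y_i| / (2(N−l)) at lags
  1 and 2 gives D̂ = 2 − log₂[V(2)/V(1)] and α = 2 − D̂. O(N), no tuning
  parameters, exact (α = 1) for affine paths.
* **Conventions.** DFA consumes noise-like series and integrates
  internally. The madogram consumes paths: bounded gait/noise series are
  cumulatively summed (after mean-centring) first, while FBM simulation
  paths are used directly. In window sweeps over FBM, DFA runs on
  within-window increments and the madogram on the window path — the only
  pairing under which both estimate the same H, consistent with the
  published medians above.
* Constant input has no defined exponent and raises
  (`ConstantSeriesError`) rather than returning NaN, so pipeline failures
  are loud.

## FBM / fGn simulation

Fractional Gaussian noise is synthesised by Davies–Harte circulant
embedding (exact covariance; eigenvalues via FFT) with an exact Hosking
recursion fallback should the embedding produce negative eigenvalues.
Paths start at 0, so a length-L path carries L−1 increments. Determinism
is per numpy `default_rng(seed)`.

## Synthetic gait trials

The generator reproduces summary statistics, not biomechanics:

| parameter | default | meaning |
|---|---|---|
| `n_strides` | 250 | ~5 min of treadmill walking |
| `treadmill_speed` | 1.25 m/s | belt speed; mean_sl = speed × mean_st |
| `duration_rate` | 0.043 | exponential rate of normalized segment durations (mean ≈ 23 strides, min 2 after rounding) |
| `slope_scale_st/sl` | 1.2e-3 / 1.5e-3 | Cauchy scale of normalized slopes |
| `slope_location_st/sl` | 8e-4 / 6e-4 | Cauchy location |
| `trend_correlation` | 0.79 | target Pearson correlation of the ST/SL trends |
| `residual_hurst` | 0.48 | Hurst exponent of the fGn residuals |
| `residual_cv` | 0.006 | residual std / mean |
| `max_segment_change` | 0.03 | cap on a segment's total relative trend change |
| `trend_reversion` | 0.5 | fraction of the level deviation pulled back per segment |

ST and SL trends share knot times (their coupling is strong and their
duration distributions indistinguishable in real data) and their slope
draws are coupled through a Gaussian copula. Mapping the copula to the
heavy-tailed Cauchy marginal attenuates the correlation, so the copula
correlation is offset by +0.09 (calibrated once against the ground-truth
trends) to realize the nominal `trend_correlation`. Slope draws are
truncated at ±20 scale units (a raw Cauchy draw has no moments and would
occasionally destroy a trial).

**Why the cap and the reversion exist.** Independent truncated-Cauchy
slopes over ~23-stride segments would let single segments move the trend
by tens of percent and the location parameter alone would drift it ~20%
per trial — while real trials show total coefficients of variation of only
1.6–1.8%. Real slope and duration cannot be independent: long segments
must be nearly flat. The generator encodes this by capping each segment's
total relative change at `max_segment_change` and adding a mean-reverting
pull of `trend_reversion` × (level deviation) per segment — a minimal
model of the tight control walkers exert. With the defaults, total ST/SL
COV lands at ≈ 1.8% and the generated trials are recoverable by the trend
fitter: on the ground-truth channel the pipeline recovers the duration
rate to ~13%, the Cauchy slope scale to ~15%, the trend correlation to
±0.01 and the residual exponent to ±0.03 (the tolerances asserted in the
test suite are wider).

What the generator does **not** emulate: gait biomechanics, left/right
asymmetries, treadmill transients at trial start, slope–duration
dependence beyond the cap, or any speed dependence of the statistics.
Tests passing on these trials show the pipeline recovers the statistical
structure it is pointed at; they do not validate physiological claims
about real walkers.

Residual CVs for real data are unknown (published values are totals over
trend + noise); 0.006 was chosen so the totals match and is the value
recovery tolerances were verified at.

## Surrogates

Phase randomization operates on the rFFT: DC is never rotated (mean
preserved) and for even lengths the Nyquist bin is fixed (real output).
Independent surrogates replace phases with iid uniform draws;
cross-correlated surrogates add one shared uniform phase field to both
spectra, preserving each amplitude spectrum and the cross-spectrum. No
amplitude adjustment (AAFT/IAAFT) is applied, so marginal distributions
are Gaussianized — a documented limitation. Composite ensembles add
independent permutations of the residuals to the fixed trend; the
permutation conserves the residual multiset exactly.

## Speed control quantities

TSC is implemented without a square root, exactly as the defining sum
Σ(vᵢ − ⟨SS⟩)²/(N⟨SS⟩²); an RMS variant is available via `sqrt=True`
because published renderings of the formula are ambiguous. ⟨SS⟩ is the
trial-mean measured stride speed, not the nominal belt speed.
Coefficients of variation use the sample standard deviation (N−1).

## Group statistics

All hypothesis tests delegate to scipy/statsmodels: Shapiro–Wilk
normality, Kruskal–Wallis or one-way ANOVA (selected by normality unless
forced) with Tukey HSD post hocs, pairwise two-sample KS and
Anderson–Darling, and left-sided one-sample t/Wilcoxon tests against 0.5
for anti-persistence. Significance is fixed at 0.05; no multiplicity
correction is layered on top of Tukey. Groups with fewer than 3 values
are skipped per test with a NaN row rather than an error.

## Degenerate inputs and tie-breaks (summary)

* Duplicate abscissae: rejected before fitting.
* Constant response: intercept-only model, no segments.
* Segments of fewer than 2 counted strides (adjacent knots): dropped — a
  one-stride piece has no slope.
* Shared segment boundaries belong to the left segment; the first segment
  owns its left endpoint (strides are counted exactly once).
* Equal SSE reductions in the forward pass: smaller knot wins.
* Equal GCV in pruning: fewer terms win.
* Exponential fit: rate is 1/mean (the MLE); Cauchy fit: scipy MLE seeded
  with median and half-IQR (generic starting values diverge on
  heavy-tailed samples). Goodness of fit defaults to KS; a Monte-Carlo
  Anderson–Darling variant is provided because the two can disagree on
  tail behaviour.

## Problem sizes used in the checked results

The estimator-bias study in `scripts/acceptance.py` uses 500 paths of
length 260 (the published ensemble size); the equivalent test-suite checks
use 200 paths, where the medians are stable to ~0.01. Pipeline recovery
tests use 50 trials of 250 strides. These sizes were chosen as the
smallest at which the reported medians/means are stable against the seed.
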