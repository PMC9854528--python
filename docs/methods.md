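# Methods

## Measurements and conventions

All series are frame-indexed at 30 fps; one second is 30 measurements, and a
window of *n* frames spans *n*/30 s (a 19-frame window ≈ 633 ms, reported as
≈ 630 ms; 17 frames ≈ 567 ms ≈ 570 ms).  Pitch is undefined at voiceless or
undetected frames; such cells are NaN in memory and the literal token `NA` in
the tab-separated files.  SubRip timestamps convert to frames by
`floor(seconds × fps)`, and subtitle intervals are half-open `[start, end)` so
adjacent subtitles never share a frame.  Segment ids are
`<episode>-<subtitle index zero-padded to 4>`.

Eyebrow height is the distance between the centroid of the ten brow landmarks
(indices 17–26 of the standard 68-point annotation) and the centroid of four
nose landmarks ({27, 31, 33, 35}), divided by the outer-eye-corner distance
({36, 45}).  The ratio is invariant under translation, rotation and uniform
scaling of the landmark set; the index sets and the normalizer are
configurable (`GeometryConfig`), and because all measurements are z-scored per
speaker downstream, the analysis is insensitive to the normalizer choice.
Head angles come from the same landmarks: lateral = signed rotation of the
inter-ocular axis about the camera's depth axis, sagittal = signed elevation
of the bridge-to-chin axis out of the frontal plane (positive = pitched up,
chin toward the camera); both are reported in degrees and are zero for a
frontal symmetric face.

Per-speaker standardization uses the sample SD (ddof = 1); missing values
pass through untouched and are excluded from the moments.

## Windows and the raise scope

Within each segment the eyebrow peak is the frame of maximal standardized
eyebrow height, ties broken to the earliest frame (deterministic and
order-independent).  The analysis window copies eyebrow and pitch to
positions −60 … +60 around the peak; positions outside the segment stay
missing ("up to 60 values per side").  Windows from segments shorter than the
default fitting span are kept but flagged.

The raise scope asks at which positions eyebrow heights are elevated.  At
every position a two-sided Mann-Whitney U test compares the values at that
position against the pooled values over all positions and windows; p-values
are Holm-corrected (α = 0.05 by default; both are parameters).  The reported
`significant_positions` are the corrected-significant positions whose rank
direction is *elevated* (common-language effect size > ½).  The direction
filter matters: with a strong raise, positions far from the peak are
significantly *lower* than the pooled distribution, and a raw two-sided
significant set would absurdly include them in the "scope of the raise".
Full corrected p-values and directions are returned alongside.  Because the
test is rank-based, the result is invariant under monotone transformations of
the eyebrow scale.

## The sinusoid model and its fitting

Pre-peak fits use positions −(n−1) … 0 and post-peak fits positions
0 … n−1, both including the peak (the mirrored inclusion is a convention;
nothing downstream depends on the shared point).  Time is measured in
seconds from the first fitted position, t = (pos − pos₀)/30.  Seconds —
rather than frames — as the unit of *f* keeps the fitted frequencies
(typically 0.2–1.2 cycles/s) in the regime of sub-cycle to full-cycle
excursions over a ~0.6 s window, matching how pitch excursions look at this
time scale.

Missing pitch is linearly interpolated over the **whole 121-position window**
before the fitted region is sliced out, so a voiceless run at a region edge
is bridged from its real neighbors on both sides; only runs touching the
window's own boundary fall back to nearest-value extension.  A region is
fitted only if at least 75% of its positions were observed before
interpolation; otherwise the fit is skip-marked with a reason (never an
exception), and skipped rows are preserved in the fit tables.

The least-squares problem is solved by **variable projection**: for fixed f
the model y = I + A sin(2πft + φπ) is linear in (I, a, b) with
a = A cos φπ, b = A sin φπ, so each candidate f costs one 3×3 linear solve
and the search is one-dimensional in f.  The profile SSE(f) is evaluated on a
dense geometric grid of 64 points over f ∈ [0.05, 5] cycles/s (plus the
conventional starts 0.3, 0.6, 1.0, 1.6, 2.4); every local minimum is refined
by bounded Brent iteration (xatol 1e-11, ≤ 500 evaluations).  This dominates
a multi-start scheme in 4 parameters: the linear subproblem is exact in
(I, A, φ), so phase starts are unnecessary and the optimum found is at least
as good at a fraction of the cost.

Amplitude is bounded at 5× the data range.  Without the bound, windows whose
interpolated contour is nearly linear admit degenerate solutions with f at
the lower bound and arbitrarily large A (the sine is locally linear with
slope ∝ A·f); such leverage points would dominate the downstream regression.
An essentially exact fit (SSE ≤ 1e-10 × SST) is exempt from the bound,
because a genuinely shallow crest sampled over a fraction of a cycle can have
A above 5× the observed range, and an exact interpolant is unambiguous
evidence for it — this keeps noiseless parameter recovery exact.  Constant
input returns A = 0, I = mean, with frequency/phase unidentifiable by
convention.

Fitted parameters are canonicalized to A ≥ 0, f > 0, φ ∈ [0, 2) using
sin(x + π) = −sin(x) and periodicity; canonicalization never moves the curve
(checked to 1e-10).  Goodness of fit is r² = 1 − SSE/SST on the fitted
(interpolated) values; SST = 0 raises rather than returning a fictitious r².

## Mixed models

Brow-peak magnitude is regressed on the sine parameters with a random
intercept per speaker, REML-estimated via statsmodels MixedLM (optimizer
fallback chain powell → lbfgs → cg → nm, since small-sample gradient paths
can hit singular intermediate matrices).  By default all four parameters
(I, A, f, φ) of a region enter the model and all are reported; a predictor
subset flag reproduces displays restricted to significant terms.  The
combined model joins pre fits at size 19 with post fits at size 17 (inner
join on segments) and uses {A, f, φ}_pre ∪ {A, f}_post.

Degrees of freedom are Satterthwaite-approximated.  statsmodels does not
provide these, so the package computes them directly from the closed-form
restricted likelihood of the random-intercept model (block-diagonal V
inverted by Sherman–Morrison): df_j = 2·var_j² / (g_jᵀ W g_j), with g_j the
finite-difference gradient of the coefficient's variance in
θ = (σ², τ) and W the inverse observed information of the REML criterion
(central differences; one-sided at the τ ≥ 0 boundary, with a residual-df
fallback when the information matrix degenerates at τ = 0).  The
implementation is validated against R's lmerTest in the test suite
(estimates and SEs to ~1e-4, df to 1%).

Window-size selection refits each candidate by ML and minimizes
AIC = −2ℓ + 2(p + 2), ties to the smallest size.  Because different window
sizes skip different segments, AIC values are only comparable on a common
response: the per-size selection models are therefore restricted to segments
fittable at *every* candidate size.  The full criterion table is returned so
users can apply other rules.

Positional summary curves are OLS fits on a full cubic B-spline basis of
size k (default k = 30 pooled, k = 10 for the low/high split at the 1.5-SD
peak threshold; boundary values go to the high set).  Bands are pointwise
95% intervals for the mean curve.  At k equal to the number of positions the
basis spans all functions on the grid and the smooth interpolates the
per-position means; prediction variances that round to tiny negatives in
this near-singular regime are clipped to zero.

## The synthetic generator

`synthetic.generate_dataset` emulates the structure the analysis assumes, not
acoustic reality: five speakers × 150 segments by default, segment lengths
normal around 68 frames (≈ 2.28 s, SD 25, floor 40), with an eyebrow series
per segment consisting of a Gaussian bump (SD 6 frames, so the elevated
region spans roughly ±2 SD ≈ the ±9–12 frames scale of real raises) plus
AR(1) noise (ρ = 0.5, innovation SD 0.1, stationary start).  The bump height
is

    h = β₀ + Σ β_x·x + u_speaker + ε,  u ~ N(0, 0.3²), ε ~ N(0, 0.6²)

with coupling defaults β₀ = 0.213, β_φpre = 0.238, β_Apost = 0.162,
β_fpost = 0.387 and zero elsewhere — effect sizes of the order observed in
conversational data — and noise SDs chosen to give realistic t-statistics at
n ≈ 750 (variance components are not observable from published tables, so
these are declared assumptions).  Pitch follows the pre-peak sinusoid over
positions −18 … 0 and the post-peak sinusoid over 0 … 16, each on the fitting
step's own clock; the post baseline I_post is solved so both sines pass
through the same value at the peak (exact continuity — a smoothing blend
would break exact two-sided parameter recovery, which is a test invariant).
Outside the coupled windows pitch is a bounded random walk (step SD 0.1,
clipped to ±3), and voiceless gaps are geometric runs (mean 4 frames)
started with per-frame probability 0.05 (stationary missing fraction
≈ 17%).  All randomness flows from a single `numpy.random.default_rng(seed)`;
datasets are bit-for-bit reproducible from (config, seed).

**What passing tests do and do not show.**  The generator's pitch is exactly
sinusoidal inside the coupled windows, its brow raises are exactly Gaussian,
and couplings are exactly linear; real contours are none of these.  Recovery
results therefore validate the *pipeline machinery* (windowing, fitting,
inference), not the adequacy of the sinusoid model for real speech.  Two
pipeline-induced biases are worth knowing about, both present in any analysis
of this shape and visible with the generator because truth is known:

1. *Errors-in-variables attenuation.*  Fitted sine parameters on windows with
   interpolated gaps are noisy measurements of the generative parameters —
   the amplitude error in particular is heavy-tailed, because short shallow
   arcs make (A, f, φ) jointly ill-conditioned.  Regression coefficients on
   fitted parameters are therefore attenuated relative to the generative
   coupling, and their Wald intervals under-cover.  The estimator-level
   recovery tests (3 SE, 95%-interval coverage, mean-bias bounds) accordingly
   run on the generator's true parameters and latent peak heights, which
   isolates the mixed-model machinery; the full-pipeline route is checked on
   the frequency coefficient, whose measurement error is bounded and mild.
2. *Peak-selection bias.*  The observed peak height is the maximum of a noisy
   series, which is upward-biased by more for flat (low-h) segments than for
   peaked ones; this slightly compresses all slopes even with perfect
   predictors.

## Numerical and degenerate-input choices

- Peak ties → earliest frame.  All-missing eyebrow segments are dropped from
  windowing (with a count in the audit log); an all-missing pitch dataset
  completes with every fit skip-marked and models reporting "no model".
- Interpolation needs ≥ 1 observed value (a single value extends to a
  constant); an all-missing series is an error.
- fit_sine requires ≥ 5 strictly increasing time points.
- Zero normalizing landmark distance, collinear head axes, constant z-score
  groups, single-speaker mixed models, rank-deficient designs and empty
  pre/post joins all raise typed errors named in `avprosody.errors`.
- Pipeline runs are pure functions of (inputs, config, seed); every bundle is
  stamped with a config hash, and the audit log records record counts
  surviving each stage.

## Problem sizes

The default test and acceptance runs use the generator's native scale
(5 × 150 = 750 segments, ≈ 52k frames); multi-seed coverage checks use 20
replicates at that size, and window-size-selection simulations use 400
segments with a reduced size grid.  These sizes give stable estimates
(Monte-Carlo SE of recovered coefficients ≈ 0.01–0.03) while keeping a full
suite run in the low minutes on a single CPU.

## Known limitations

- Only the analysis pipeline is covered: face detection, landmark estimation
  and pitch extraction are upstream and consumed as tables.
- One sinusoid per region: no multi-cycle pitch modeling, declination
  removal, or harmonic terms.
- Random intercepts only; no random slopes or Bayesian estimation.
- The raise-scope reference distribution (position vs. pooled) and the Holm
  correction are one defensible operationalization of "higher than the
  mean"; alternatives (e.g., vs. a fixed baseline set) would shift the run's
  edges by a few frames.
- The supplementary-data reproduction path (`reproduce`) requires the
  original per-segment window tables, which are not bundled; it is exercised
  on synthetic stand-ins in the test suite.
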