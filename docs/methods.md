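# Methods

## The assay and its observables

The package models a flow-chamber thrombosis assay: anticoagulated
whole blood, platelets labeled with DiOC6, perfused over immobilized
collagen in a microfluidic channel at a wall shear stress of
15 dyn/cm² with 1.67-Hz pulsatility, imaged by fluorescence microscopy
every 35 s for 10 min (18 frames).  Shear and pulse frequency are
carried as metadata; no hemodynamics is simulated.

Two per-frame metrics summarize the field:

- **TFI**, total fluorescent intensity: the background-subtracted,
  zero-clipped pixel sum over the region of interest.  Fluorescence is
  proportional to labeled platelet mass, so TFI tracks total
  accumulation including vertical growth.
- **TAC**, total area covered: the number of pixels at or above a
  global threshold, scaled to µm².  TAC tracks lateral spread.

Conventions, used everywhere: 0-based (row, col) pixel coordinates,
half-open ROIs, flow along image columns, channel width along rows,
t = 0 at the first acquired frame.  Whether acquisition began exactly
with perfusion onset is an acquisition detail the analysis cannot
recover; all lag times are relative to the first frame.

## Kinetic model and lag time

Accumulation traces are fitted with a quadratic, y = A t² + B t + C,
by ordinary least squares.  The **lag time** is the real root of the
fitted quadratic on the ascending branch, i.e. the root t* with
2 A t* + B > 0 (for A > 0, (−B + √(B² − 4AC)) / 2A).  Edge cases are
reported through an explicit quality flag rather than errors:

- discriminant ≤ 0 (double root / no real root): the vertex −B/2A,
  flagged `vertex_degenerate`;
- A < 0: the smaller (rising) root, flagged `concave`;
- A = 0: linear fallback −C/B;
- selected root negative or beyond the last sample: flagged
  `out_of_range`, value still returned.

The root is solved against zero; traces are background-subtracted
before fitting, so "signal crosses zero" and "signal leaves baseline"
coincide.

### Numerical design

The normal equations are solved in centered/scaled time
u = (t − mean)/sd and mapped back; the discriminant is computed from
the scaled coefficients (disc_t = disc_u / s²), which is free of the
catastrophic cancellation B² − 4AC suffers for near-double roots far
from t = 0.  Root pairs use the stable −(B + sign(B)√disc)/2 form.

Two thresholds route a fit to the degenerate (vertex) branch:

- a relative floor, disc ≤ 1e−9 · (B² + |4AC|), absorbing round-off in
  exact fits;
- a statistical floor, disc ≤ 2 · SD(disc), with SD(disc) from the
  delta method on the OLS coefficient covariance.  A noisy sample of a
  pure shifted parabola has true discriminant 0; without this rule the
  spurious √disc excursion biases the root upward by tens of seconds
  at realistic noise.

### Fit window

The quadratic describes the curve only after nucleation, so fitting
the flat pre-nucleation baseline would bias every coefficient.  Two
mechanisms address this:

1. `fit_quadratic` by default drops samples up to the last sample at
   or below baseline (0 after background subtraction).  On a noiseless
   synthetic trace the surviving samples lie exactly on a(t − τ)², so
   the fit — and hence the lag — is exact to round-off.
2. `estimate_lag` then iterates to self-consistency: fit, take the
   lag, restart the window there, repeat until the window is stable
   (cycle-detected, ≤ 50 iterations, never fewer than 4 samples).
   The window is extended *below* the current lag by √(rmse/A) — the
   distance at which the model's misfit to the flat baseline,
   A(τ − t)², reaches the estimated noise — because those samples
   anchor the vertex at negligible model error.  The extension is
   self-calibrating: it vanishes as rmse → 0, so noiseless exactness
   is preserved, while at 5 % noise it roughly halves the median lag
   error (to ~20–30 s, under the one-frame interval of 35 s).

The **rapid-phase slope** is the OLS line slope over all samples with
t ≥ lag.  The window is anchored to the lag estimate because the
assays report the post-onset linear segment without defining its
bounds; with fewer than two qualifying samples the slope is NaN, never
a silent zero.  **Maximum accumulation** is the largest observed
value.  Both metrics (TFI and TAC) are fitted independently.

## Segmentation, tracking, spatial selection

Default background is the median of the first frame in the ROI (the
first frame predates significant adhesion); default threshold is
Otsu's method computed once on the final frame and applied to all
frames, keeping TAC comparable across time.  Both accept fixed
overrides — tracking validation uses background + 1 on noiseless
stacks, where Otsu can sit above a dim thrombus's pixels when blob
brightnesses span a wide range.

Thrombi are 8-connected components of the thresholded mask;
components under 4 px are discarded as single-pixel noise.  Tracks
link components frame-to-frame by maximal pixel overlap, ties broken
by nearest centroid; unmatched components start new tracks; a track
ends when nothing overlaps it.  On a merge the component attaches to
the larger-overlap predecessor; on a split the larger-overlap
component keeps the track.  Per member frame, pixel area, µm² area,
background-subtracted integrated intensity and intensity-weighted
centroid are recorded.

Only tracks whose mean centroid row falls in the **vertical middle
third** of the channel — rows [floor(H/3), H − floor(H/3)), boundary
row included — are selected for per-thrombus kinetics, controlling for
the lower shear near the channel walls.  The synthetic frame plays the
role of the mid-channel viewing region (midway along the flow path);
for real data a column-range ROI option restricts the along-flow
extent.

## Group statistics

Endpoints are summarized as mean ± SE (sample SD over √n).  Two-sample
comparisons use Student's pooled-variance t (not Welch — matching the
named test in the assay literature; at the equal group sizes used here
the two coincide), two-sided p.  The summary-statistic form pools the
SDs implied by the printed SEs and reduces, at equal n, to
t = Δmean / √(se₁² + se₂²).  Zero pooled variance is flagged: t = 0,
p = 1 at equal means, infinite t otherwise.

The repeated-measures comparison is a two-way mixed-design ANOVA
implemented directly from sums of squares: group (between subjects)
tested against subjects-within-group; time and group × time (within)
tested against time × subjects-within-group.  Balanced designs only
(every subject at every timepoint; group sizes may differ); no
sphericity correction is applied — with the two-timebin analyses used
for trace endpoints sphericity is moot.  The implementation agrees
with pingouin's `mixed_anova` to 1e−9 and with a hand-computed
2×2×2 decomposition exactly (test-suite cross-checks).  Timepoint
binning is configurable and defaults to per-frame.

Effect summaries report the difference and fold-ratio of group means;
one-decimal rounding is presentation-only and never enters stored
values.  No multiple-testing correction is applied.

## Tail bleeding

Bleeding after tail-tip amputation occurs in start/stop cycles.  The
endpoint is the cumulative sum of episode durations truncated at the
1200-s (20-min) observation cap — truncation is idempotent — and blood
loss is the pre/post body-weight difference in grams (the amputated
tip is weighed with the animal, so the difference is blood).  No
mass-to-volume conversion is applied; none is standard.

## Synthetic data generator

The generator emulates the fluorescent observable only: each simulated
thrombus nucleates at τ and then carries total fluorescence
a·(t − τ)² (the quadratic growth the fit assumes) spread over an
isotropic 2-D Gaussian blob truncated at 3σ, with
σ = max(1 px, r·(t − τ)) capped so the support stays in frame, on a
flat background (default 100 counts) with additive Gaussian camera
noise clipped at zero (default SD 2), quantized to 16-bit by
largest-remainder rounding, which preserves each frame's total to one
count (plain rounding loses several percent of a dim blob's tail
pixels).  Default geometry: 120 × 160 px at 1 µm/px, frames at 0, 35,
…, 595 s.  A single integer seed drives one `numpy` generator; draws
occur in frame order, noise after blobs, so runs are bit-reproducible.

Ground truth (every τ, growth coefficient, center, overlap flag)
serializes to JSON and round-trips losslessly; parse errors name the
offending field.

What the generator does *not* emulate: photobleaching, drift, uneven
illumination, embolization (thrombi never shrink or detach),
non-Gaussian camera noise, and departures from quadratic growth.
Passing tests therefore demonstrate correctness of the estimators
under the model's own assumptions, not robustness to every real-data
pathology; the quantification entry points accept real TIFF stacks
with per-frame timestamp sidecars for instrument data.

## Pipeline and problem sizes

The `full` pipeline simulates two groups of 4 channels (matching the
reference design of four animals per group), 3 thrombi per channel,
control nucleation ~73 s and the comparison group shifted +57 s (the
published effect size) with 12-s between-channel jitter; quantifies;
fits; and compares, writing per-stage CSV/JSON plus a SHA-256 manifest
so identical config + seed give byte-identical outputs.  Validation
suites use 50 noiseless (τ, a) combinations, 100 noisy replicates at
5 % of trace maximum, 20 random 3-thrombus layouts, and 1000-replicate
null calibration at n = 4 per group — sizes chosen so the whole chain
re-runs in seconds while keeping binomial/median estimates stable.

## Known limitations

- The lag estimator assumes a single dominant onset per trace;
  multi-wave accumulation yields a compromise lag.
- Overlap tracking has no motion model; it assumes thrombi are
  stationary (valid for adherent thrombi, not embolizing ones).
- The ANOVA rejects unbalanced designs rather than imputing.
- `out_of_range` lags are reported with their flag, not censored;
  downstream group statistics include them unless the caller filters.
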