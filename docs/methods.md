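# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `nemaphene`, in the order data flows through the package.

## Synthetic worm model

The worm is a tapered tube around a centerline built from cumulative turning
angles over 768 equal arc-length steps, so total arc length equals
`body_length` exactly and the 13 equidistant posture points land on vertices.
The tangent angle is the sum of three terms:

* **Heading** — a constant; the body extends tail-ward of the nose, and the
  width-weighted centroid (the centroid of the analytic body plan) is placed
  on the trajectory `x₀ + v·t·ĥ`, so translation speed is exact by
  construction and undulation contributes zero net centroid drift.
* **Head bend** — a circular arc over the first 2/12 of arc length: the
  tangent ramps linearly from +θ to −θ. Because the chord of a circular arc
  is parallel to its midpoint tangent, the two anterior chords of the
  13-point polyline differ in direction by exactly θ, i.e. the analytic first
  supplementary angle equals `head_bend_angle` with no fitting. An earlier
  design concentrated the bend at a point; that was abandoned because the
  medial axis of a corner cuts it (by up to ~12% of the angle), so even a
  perfect skeleton-based measurement could not recover the nominal value.
  The bounded-curvature arc keeps the medial axis on the centerline.
  `head_bend_frequency > 0` makes θ oscillate sinusoidally (for testing the
  maximal-extension statistic).
* **Undulation** — a traveling sine in the tangent angle (default amplitude
  30°, wavelength 0.65 body lengths, 0.3 Hz), smoothly ramped in *after* the
  anterior sixth so it cannot contaminate the head statistic.

The default worm is a 1 mm adult with 35 µm mid-body half-width tapering to
zero at both tips (`half_width(u) = w_max·sin(πu)^0.5`); the analytic plan
area `L·∫2·hw(u)du` is recorded in the ground truth. Defaults follow the
assay: 500 ms frame interval, 240 frames (2 min), 16-bit images with
background 100, foreground 500. Pixel calibration is not fixed by the assay
description; the default 5 µm/px is an ordinary dissecting-scope scale and is
configurable.

Rendering follows "pixel is foreground iff its distance to the centerline is
at most the local half-width", implemented as a union of disks stamped along
a densely resampled centerline on a 4× supersampled grid, block-averaged to
grayscale coverage. The renderer's own mask (`coverage ≥ 0.5`) is exactly
what midpoint thresholding of the noiseless image recovers. One seeded
`numpy` generator per dataset; ground-truth sidecars are computed from the
analytic form (or high-resolution numerical evaluation of it), never from
rendered pixels.

## Posture pipeline

1. **Segmentation** — Otsu split, then the final threshold is the midpoint of
   the two class *medians* (robust to noise, and exact on noiseless renders);
   polarity is auto-detected by taking the minority class as the worm. Holes
   filled, largest connected component kept, area bounds enforced.
2. **Skeleton and pruning** — `skimage` skeletonization; the skeleton pixel
   graph (8-connected, √2 diagonal weights) is pruned to its longest
   endpoint-to-endpoint geodesic. No endpoints ⇒ the posture is coiled and
   the frame is rejected with a `CoiledWormError`.
3. **Smoothing and subpixel refinement** — the path is smoothed with a local
   Gaussian (σ = 1.5 samples) rather than a smoothing spline: a global spline
   residual budget preferentially flattens the *localized* anterior bend
   (a 30° bend read back as < 15°) because the head dip is cheap in summed
   residual. Each vertex is then moved to the intensity-weighted transverse
   centroid of the normalized worm profile (3 iterations); weights below 0.25
   are zeroed so clipped noise tails outside the worm cannot tug the
   centroid. Both ends are extended along their terminal tangents to the
   half-coverage crossing of the grayscale image — "from the tip of the
   nose" means the true tip, which skeletons stop short of by about a
   half-width.
4. **13 points and the angle** — points at arc lengths {0, L/12, …, L} by
   linear interpolation on the 400-vertex midline; the first supplementary
   angle is `atan2`-based and reported as an unsigned magnitude (a signed
   image-frame variant exists but is *not* a dorsoventral label — the image
   alone cannot identify the dorsal side).
5. **Head assignment** — the end that leads the centroid motion is the nose
   (orientation first made consistent across frames by endpoint proximity).
   Below 2 px of net motion the label is `unassigned` unless a user override
   is given. Reversing frame order swaps the labels, as it must.
6. **Summary statistic** — the maximum |angle| over valid frames in the
   analysis window (default 15–60 s, configurable), i.e. the maximal
   head-swing extension. Per-frame failures are recorded and skipped.

Measured accuracy on synthetic worms at 5 µm/px with noise at 10% of
contrast: mean |error| ≈ 1.6–1.8° across 10–60° bends (a small attenuation
growing with θ remains, from smoothing and residual medial-axis bias), and a
straight-worm null below 1°.

## Locomotion

Centroid per frame from the segmented mask; average speed is path length over
adjacent valid-frame pairs divided by their summed time. This is "activity"
speed: a worm bending in place scores nonzero. Undulation-induced centroid
wobble is part of the measurement (no smoothing by default); it recovers
20–100 µm/s within ~1% on synthetic movies because the generator pins the
body centroid to the trajectory.

## Puncta

Profiles are sampled at 0.5 px steps with `width` perpendicular offsets
averaged (default 3 px; width-averaging attenuates peaks whose PSF σ is
comparable to the width — use width 1 when absolute heights matter).
Detection: local maxima above median + 3·σ̂, where σ̂ is the scaled median
absolute successive difference of the profile decimated back to 1 px spacing
(decimation stops interpolation correlation from shrinking σ̂; at k = 3 the
false-positive rate on pure noise is well under 1 per 300 samples). Minimum
separation is enforced; closer peaks merge with a warning.

Measurement: the background is the local 10th percentile (configurable) of a
*median-filtered* profile (15 px window) — narrow puncta cannot lift a wide
median, while filtering keeps the low percentile from chasing noise minima,
whose −1.28σ bias would otherwise inflate every net. The peak grey is the
apex of a quadratic fit around the local maximum with the parabola's known
Gaussian-width attenuation divided out (the scale-free curvature/apex ratio
identifies the width): exact for a clean Gaussian punctum of any width,
unbiased under noise, where a raw max of noisy samples is extreme-value
biased upward. `net = peak_grey − background` exactly; nets double under a
2× gain and ignore additive offsets. Pooling across images is refused when
metadata sidecars declare different exposure/gain/pinhole settings.

## Evoked currents

Traces are uniform grids (validated to 1 ppm) with ≥ 20 ms pre-stimulus
baseline. Kinetics in the generator are
`k(t) = e^(−t/τd) − e^(−t/τr)` rescaled to unit peak (τr = 0 ⇒ pure
monoexponential), so "amplitude" is the analytic peak deviation and the
analytic charge is `A·(τd − τr)/k(t_peak)` (= `A·τd` for monoexponential).
Inward currents deflect negative (clamp at −60 mV).

* **Baseline**: mean over [onset − 20 ms, onset).
* **Amplitude**: max |I − baseline| in [onset, onset + 50 ms]; a window-edge
  peak is flagged, and responses below 5× the baseline noise sd are flagged
  sub-threshold (no t½/charge reported).
* **t½**: time from the peak to the first crossing of 50% of the signed peak
  deviation. The crossing is located on a median-3 + boxcar-3 filtered
  deviation with linear interpolation — a raw first-passage rule is ~6%
  early under 2% noise — and the boxcar's known exponential-rescaling shift
  `τ·ln((e^x + 1 + e^(−x))/3)`, `x = dt/τ` (τ inferred from the measured
  t½), is subtracted. Closed forms at 2.9 kHz agree to ≤ 0.004 ms noiseless;
  under 2% amplitude noise: bias +0.3%, sd 4.2% over 100 replicates.
* **Charge**: |trapezoidal ∫(I − baseline)| from onset to the first time the
  deviation stays below 5% of amplitude for ≥ 2 ms, capped at 200 ms (all
  three are config keys; the historical software's rule is not documented).
  For a monoexponential the truncated integral is `0.95·A·τ`, and it
  converges to `A·τ` as the cutoff → 0.
* **Normalization**: `(I − baseline)/signed peak deviation`; the measured
  peak sample is exactly 1.

## Statistics

Long-format tables (`group,id,value`). s.e.m. uses the n−1 sample sd. The
default unpaired test is Welch's (coincides with pooled for balanced
equal-variance data; pooled available). One-way ANOVA is the standard
between/within decomposition. Dunnett's many-to-one comparison computes
`tᵢ = (x̄ᵢ − x̄₀)/√(s²(1/nᵢ + 1/n₀))` with the variance pooled over all
groups, and the familywise adjusted p as the Monte-Carlo tail probability of
`max|t*|` under the joint null (default 10⁵ draws, seeded and exactly
reproducible; the correlation enters through the shared control draw and the
shared χ² variance). Adjusted p-values are floored at the parametric raw p
so `adjusted ≥ raw` holds exactly, not merely in expectation; with a single
treatment the procedure reduces to the pooled two-sample test within
Monte-Carlo error. Calibration over 2000 null simulations puts the t-test
and ANOVA rejection rates at 0.05 ± 0.015 and the Dunnett familywise error
inside [0.035, 0.065]. No additional correction is applied across different
metrics.

## Problem sizes in tests and the acceptance script

The demonstration problem sizes are deliberately small — a few frames per
movie, 12 movies for angle recovery, 12 frames per speed movie, 2000 null
simulations with 10⁴ Dunnett draws — chosen so the whole battery re-runs in
about a minute while keeping Monte-Carlo error well inside the tolerances
quoted above. Generator defaults keep the full assay conditions (240 frames
at 500 ms).

## What the synthetic data does and does not show

The generators emulate the *geometry and noise* of the assays: single worms
on clean backgrounds, Gaussian puncta on flat backgrounds, exponential
synaptic kinetics with white noise. They do not emulate plate debris,
touching/overlapping animals, omega turns and coils (coils are detected and
rejected, not resolved), photobleaching, uneven illumination, structured
backgrounds, stimulus artifacts, or series-resistance errors. Passing the
recovery tests therefore demonstrates correctness of the estimators under
the stated model, not robustness to every pathology of real recordings; the
per-frame failure flags and config keys are the intended handles for real
data.

## Known limitations

* The first angle attenuates slightly (≈ 2° at a 60° bend) at coarse pixel
  scales; higher magnification reduces it.
* Head assignment needs net forward motion; a stationary worm requires a
  user override.
* Dorsoventral sign of the bend is not identified (image-frame sign only).
* The Dunnett procedure assumes a common within-group variance (classical
  Dunnett); no unequal-variance variant is provided.
* Charge integrals of slowly decaying responses that never re-reach baseline
  are reported to the cap and flagged.
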