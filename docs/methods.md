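# Methods

## Scene model

A synthetic scene is conditioned on a `MaskTriple` of three co-registered
binary masks: `M_tissue` (soft tissue), `M_device` (dense metallic tools)
and `M_lumen` (contrast-agent-filled vessel lumens, constrained to lie
inside the tissue). `make_mask_triple` draws the tissue region as one
simply-connected random spline blob, lumens as thick random polylines
clipped to the tissue, and devices as bars/discs placed anywhere.

The background renderer is procedural by design: band-limited value-noise
texture, per-region intensity offsets and a light Gaussian blur. Under the
default *attenuation* polarity denser structures are darker
(device ≈ 40–55, lumen ≈ 110, tissue ≈ 165, free background ≈ 225 on the
8-bit scale), which matches raw-attenuation imagery; `display-inverted`
flips the scale for the clinical bright-metal convention. The renderer makes
no claim to anatomical realism — its contract is only that region mean
intensities are correctly ordered and mask-consistent, which is what the
compositing, labelling and tracking layers actually consume.

Imaging noise is injected in a fixed order — Poisson photon resampling,
additive zero-mean Gaussian, pepper — because physical photon noise
precedes electronic read noise, and dead pixels are a sensor property.
Poisson noise is parameterized by a photon-count scale `s` (pixel treated as
`Poisson(v·s)/s`; larger `s` → less relative noise; default disabled), since
no standard parameterization on 8-bit data exists. A fully disabled
`NoiseSpec` is the bit-exact identity.

## Shape synthesis and sprite extraction

Liquid-device silhouettes are periodic B-spline blobs: `n` control points
sampled sector-wise in angle (θᵢ uniform within the i-th of n equal sectors,
guaranteeing angular monotonicity and hence a star-shaped polygon) and
uniformly in radius within `[l_min, l_max]`; the closed sequence (first
point appended) is fit with a periodic, smoothing-free (s = 0) cubic spline
and resampled at `N_interp` uniform parameter values `u_k = k/(N_interp−1)`.
Cubic degree is the standard interpolating choice; defaults `n = 10`,
`N_interp = 200` give smooth blobs at the tens-of-pixels scale used here.
Interpolation (not approximation) is a tested contract: the curve passes
through every control point to < 1e-6 px. Rare self-intersecting resamplings
are redrawn with an incremented seed and recorded in provenance.

Soft-device sprites are extracted from clean-background captures by Otsu
thresholding (foreground = intensities ≤ threshold, inclusive because on
bimodal integer images the Otsu value coincides with the lower class),
largest-connected-component selection (ties → first in row-major order),
rotation of the major axis to horizontal (skipped for near-isotropic
components, eccentricity < 0.1, whose major axis is undefined) and tight
cropping.

## Compositing and auto-annotation

Each placed instance draws a contrast multiplier ρ ~ U(ρ_low, ρ_high); the
per-pixel target is v_t = clip(ρ·v_b, v_min, v_max). A single scalar
α = Σ(v_t − v_r) / Σ(v_b − v_r), clipped to [0, 1], blends
v = α·v_b + (1−α)·v_r inside the mask. This form makes the blended region's
mean equal the target mean (v_t = v_r ⇒ α = 0, raw sprite; v_t = v_b ⇒
α = 1, invisible) and therefore gives direct control over minimum contrast.
A `verbatim` mode evaluates the alternative numerator Σ(v_t − v_b) for
audit; it is not the default because that numerator is negative whenever the
device darkens the scene, and after clipping would discard ρ entirely. α is
scalar per instance, not per pixel.

Placement is biased into lumens when present (devices travel in
contrast-filled vessels), else into tissue. Occlusion is modelled by
placing an instance beneath `M_device`: occluded pixels revert to the
original rendering and the emitted polygon traces only the visible region.
When the occluder splits the visible pixels, the largest connected component
defines both the stored mask and the polygon (keeping the one-polygon-per-
row label schema). Instances with visible fraction below
`min_visible_fraction` (default 0.1) are rendered but unlabelled. Polygons
are traced at sub-pixel level (0.5 iso-contour) and normalized to [0, 1];
re-rasterizing them reproduces the stored masks with IoU ≥ 0.99 — the only
lossy step in the labelling path.

Defaults ρ ∈ [0.5, 0.9], target height h = 24 px, height jitter ±20 %, free
rotation, occlusion probability 0.3: low-contrast, small, arbitrarily
oriented devices, the regime the tracker must survive.

## Dataset layer

Labels use the one-row-per-instance text format `class x1 y1 x2 y2 …` with
coordinates normalized by frame width/height at 6-decimal precision; reads
invert writes and malformed rows fail with their line number. Frames are
tiled into an `n_cols × n_rows` grid (default 5 × 5 = 25 patches in global
search mode) with pairwise overlap ≥ 10 % of the patch extent; integer
strides are grown until the overlap bound holds and the last row/column is
clamped to the frame edge, so coverage is exact. Train/validation splits are
deterministic shuffled partitions at 20:1 (synthetic) or 10:1 (real).

## Tracking

The tracker alternates two modes. GLOBAL: the full frame is tiled, the
detector runs per patch, detections are lifted to frame coordinates and
cross-patch duplicates merged greedily at box IoU ≥ 0.5 keeping the highest
confidence. LOCAL: the detector sees only a crop around the predicted
position (side = max(4 × object size, 96 px)). GLOBAL is used for
initialization and recovery; LOCAL is the primary mode.

Detections pass five gates: (1) confidence ≥ threshold; (2) geometric
consistency — rotation-agnostic min/max bbox dimensions within range;
(3) temporal continuity — distance to the Kalman prediction ≤ `max_step`,
widened by ×(1 + 0.5·misses) while coasting so recovery remains possible;
(4) anatomical plausibility — distance to a lumen centreline, when one is
supplied (a distance threshold, the simplest plausible reading);
(5) history — when the 10-frame success rate falls below `min_history_rate`
the confidence threshold escalates ×1.5 (capped at 0.95), demanding stronger
evidence while the track is unreliable. Among survivors the detection
nearest the prediction wins.

The filter is constant-velocity over [x, y, vx, vy] with white-acceleration
process noise (spectral density q = 0.5 px²/frame³ — devices move a few
px/frame at ≤ 30 f.p.s., so accelerations are small) and isotropic
measurement noise R = r/confidence with r = 1 px²: the adaptivity is that
low-confidence detections pull the state less. Updates use the Joseph form,
keeping the covariance symmetric positive-semidefinite (tested over
thousands of random steps). Without a measurement the filter coasts and
`frames_since_detection` increments; after `max_coast_frames` (default 15,
≈ 0.5 s at 30 f.p.s.) the tracker reverts to GLOBAL search, and after twice
that budget the track is dropped entirely and re-confirmation starts over.

Track birth uses two-frame confirmation: a track starts only when
statically-gated detections on consecutive frames lie within `max_step` of
each other, the confirming pair chosen by smallest displacement (ties by
confidence). Spatially independent clutter essentially never wins this test,
whereas a most-confident-single-detection bootstrap is routinely captured by
a lucky false positive. On confirmation the pair's first frame is
retroactively marked localized.

Reporting distinguishes two ratios. `detection_lsr` counts only frames with
an accepted detection. `lsr` additionally counts frames the filter bridged
by in-window coasting — the gap-interpolation role of the Kalman filter —
and is the headline localization success ratio; positions are NaN before
initialization and RMSE is computed over frames with an estimate.

## Synthetic sequences and the mock detector

`make_sequence` renders a single device along a piecewise-linear waypoint
path at constant speed with a fixed per-sequence ρ (temporal coherence), and
hides it beneath `M_device` during scripted occlusion windows.
`mock_detector` wraps the ground truth in the detector interface with
scripted degradation: per-frame dropout (probability `fn_rate`), Gaussian
position jitter, and Poisson-distributed clutter placed uniformly over the
frame — deliberately unbiased toward the target so that the temporal gate,
not luck, must reject it. Detections are pre-drawn per frame from the seed,
so the stream is identical regardless of crop query pattern. The stress
condition used throughout (300 frames, fn = 0.2, 0.1 clutter/frame, 1-px
jitter) reflects a tracker that misses one frame in five under degraded
image quality.

What the mock does **not** emulate: confidence statistics of a trained
network, correlated misses (real detectors fail in bursts near occluders),
shape-dependent localization bias, or appearance drift. Passing the
integration tests therefore demonstrates the correctness and robustness of
the gating/filtering/interpolation logic under the stated noise model, not
end-to-end performance on clinical video.

## Metrics

AP is the raw Riemann sum over the precision–recall curve traced at each
distinct confidence threshold — no 11-point or 101-point interpolation —
and is verified exactly (1e-12) against a brute-force threshold-enumeration
oracle. Matching is greedy by descending confidence (ties → higher IoU),
each ground truth consumable once, and requires IoU **strictly** greater
than the threshold, applied uniformly at all ten mAP50:95 thresholds
{0.50, …, 0.95}. With no ground truth AP is undefined and raises rather
than returning 0. Masks and boxes are scored separately (mAP(M), mAP(B));
an ROI-classification variant scores regions by their maximum contained
confidence. Michelson contrast and the MAD noise estimator
(σ̂ = 1.4826·median|v − median v|) follow the standard definitions; the
1.4826 constant is hard-coded (not scipy's higher-precision equivalent) so
the estimate-to-MAD ratio is exactly the documented value. Note the MAD
estimator's known bias under heavy contamination: at 25 % extreme
salt-pepper outliers the estimate inflates to ≈ 1.43 σ (analytic value,
verified in tests) — bounded, unlike the sample standard deviation, but not
unbiased.

## Numerical choices and edge cases

- Images are 8-bit, 0-based coordinates, x = column, y = row; all blending
  is computed in float64 and rounded once at the end.
- IoU of two empty regions is 1.0 by convention.
- Histogram equalization passes constant frames through unchanged
  (degenerate histogram) and rescales non-constant output to span [0, 255].
- Tiling strides round down; patch extents grow until the minimum-overlap
  bound is met exactly, so the 25-patch default holds for any frame ≥ the
  grid size.
- `blend` interprets the position as the sprite mask's bounding-box centre,
  so scripted paths, emitted labels and detector outputs agree on where an
  instance *is* without a systematic offset.
- Degenerate blends (Σ(v_b − v_r) = 0 over the mask) raise rather than
  divide by zero; compose_scene retries such placements elsewhere.

## Problem sizes

Default test and acceptance scales: 256×256–384×256 scenes, 60–300-frame
sequences, 100-sample label sweeps, 1,000-seed spline sweeps, 200 random AP
instances. These sizes give stable statistics for every contract checked
while keeping the full suite near five seconds; all quantities are computed
fresh at run time from seeds.

## Known limitations

- The procedural renderer covers mask-consistency and intensity ordering
  only; no tissue texture realism, beam hardening, or scatter.
- Single-target tracking per sequence (the data model supports multiple
  instances per scene; the tracking loop maintains one track).
- No physics in the liquid-shape model — spline blobs are a geometric, not
  ferrofluidic, family.
- The centreline gate expects a polyline supplied by the caller; no
  centreline extraction from `M_lumen` is provided.
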