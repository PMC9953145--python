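# Methods

This note records the models, estimators, defaults and numerical conventions
behind `fadf`, and what the synthetic validation does and does not establish
about real data.

## Measurement model

A session is a series of paired green/red fundus frames at minutes
t = 0, 5, …, 30 post-injection, with t = 0 the pre-injection baseline. The
green channel carries a semi-permeable detection dextran, the red channel a
high-molecular-weight reference dextran that does not cross the blood–retina
barrier. Per frame and channel, vessels are segmented (below) and the median
fluorescence intensity is taken inside (`MFI_in`) and outside (`MFI_out`) the
vessel mask over the analyzed field of view. Defining
`R(t) = MFI_out(t) / MFI_in(t)`:

- `VL(t) = R(t) / R(0)` (Vascular Leakage, per channel),
- `LI(t) = VL_green(t) / VL_red(t)` (Leakage Index),
- `LI(30)` = the Leakage Index at the final protocol time point.

Two normalization choices were genuinely open and are worth stating:

- *Quotient, not difference.* "Relative to time zero" is implemented as
  `R(t)/R(0)` rather than `R(t) − R(0)`: the quotient is dimensionless,
  invariant to rescaling a whole channel, and exactly 1 at baseline. A
  difference mode (`vl_mode="difference"`) is retained for sensitivity
  analysis.
- *Quotient of channels for LI.* `LI = VL_green / VL_red` is the only form
  with exact drift cancellation: a gain `c(t)` applied to both channels of a
  frame pair multiplies `MFI_in` and `MFI_out` equally, cancels within each
  `R(t)`, and hence leaves `LI` unchanged to floating-point round-off. The
  test suite asserts this end-to-end at 1e−10 relative tolerance.

Median vs mean MFI: the median is the default (robust to bright specks and
clipped pixels); the mean is selectable (`mfi_statistic="mean"`). Masks are
recomputed per time point and channel; no image registration is performed
anywhere. A fixed-mask sensitivity mode can be had by passing
`mask_mode="shared_green"`.

## Noise estimation

Thresholds are phrased in units of the noise SD above the background level,
so both must be estimated per frame. The default estimator
(`method="mad_background"`):

1. Histogram the field pixels (512 bins). Pixels lying exactly at the range
   extremes are excluded from the peak search first — clipping piles at 0 or
   at the bit-depth ceiling otherwise masquerade as the background peak. The
   smoothed argmax gives a crude mode.
2. A center-free initial scale `s0` is taken from the inter-quantile spread
   of the pixels at or below the field median (20th–80th percentile of that
   subsample, divided by the corresponding Gaussian factor 1.0283).
3. The background level is refined as the median of pixels within
   `mode ± 2·s0` — a symmetric window, so the estimate is an unbiased center
   of the background peak with sub-bin accuracy.
4. `sd = 1.4826 × median(background_level − x)` over pixels *strictly below*
   the background level. The lower flank of the background peak contains no
   vessel signal, so this is unbiased for any bright-tail area fraction
   (for a Gaussian background the median lower-flank deviation is 0.674 σ,
   and 1.4826 ≈ 1/0.674).

On pure-noise and phantom frames the estimate is within ~2 % of truth; the
tests bound it at ±6 % (pure noise) and ±10 % (phantom). A `sample_sd`
method (mean/SD over a user-supplied background region) is available, and a
constant image returns `sd = 0` with a degenerate flag and a warning.

Both the background level and the SD scale linearly under a positive gain, so
the segmentation mask is scale-invariant (tested exactly for power-of-two
gains, where float arithmetic introduces no rounding).

## Segmentation

Vessel pixels satisfy `intensity > background_level + k·sd`; `k = 4` by
default for leakage analysis (legal range 3–5, warning outside), `k = 2` for
caliber (range 1–3). Optional Gaussian pre-smoothing is off by default.
Cleanup removes connected objects below 10 px and fills holes below 25 px —
sizes quoted at 512×512 and scaled with image area, chosen to suppress salt
noise without deleting capillaries; both are configurable and can be disabled
(`cleanup=False`), which is also the configuration under which the
k-monotonicity invariant `vessel(k₂) ⊆ vessel(k₁), k₂ > k₁` holds exactly.
The extravascular mask is the field of view minus the vessels, so the two
compartments always partition the field; an optional n-pixel guard ring
around vessels (`boundary_exclusion_px`, default 0) can be carved out of the
EVS. Per-channel masks are the default; union and green-derived shared-mask
modes exist for sensitivity checks.

## Caliber

The chain is: local contrast adjustment → fine filter → k·σ segmentation →
skeletonization → skeletal diameter.

- *Local contrast adjustment*: each pixel is rescaled by the min/max over a
  sliding window (default 255 px). The window must exceed the typical
  inter-vessel spacing so that essentially every window sees both background
  and vessel signal and the background normalizes to a consistent low band;
  windows with zero range map to 0.5 by convention. The per-session pipeline
  clamps the window to the frame size for small images.
- *Fine filter*: 3×3 median, removing impulse noise (and, with the contrast
  step, 1-px bright rims from chromatic aberration at vessel walls — the
  tests show such rims change the measured bar caliber by ≤ 1 px).
- *Noise reference*: the caliber threshold uses the noise of the first
  post-injection image of the session (t = 5), not the baseline.
- *Skeleton*: Lee's thinning (`skimage.morphology.skeletonize(method="lee")`),
  which yields 1-px-wide skeletons with no 2×2 all-true block; the default
  Zhang method occasionally violates that on branching trees, and the medial
  axis transform is 2 px wide on even-width shapes.
- *Skeletal diameter*: `2 × EDT` (Euclidean distance transform) at each
  skeleton pixel; per-object caliber is the median (mean selectable) over the
  object's skeleton pixels, the image summary the median over all skeleton
  pixels. Rasterization makes an axis-aligned bar of odd width w read w+1
  and oblique bars read within ±1 px — the resolution floor of the method.
  Units are pixels; an optional `um_per_px` factor converts summaries.

Longitudinal caliber tables compare pooled per-session distributions
(median, quartiles, min/max); individual vessels are deliberately not
tracked across sessions.

## Phantom

The phantom exists so that every downstream stage has ground truth.

- *Geometry*: a stylized radial tree — a central disc, six trunks, two
  children per segment with jittered angles, widths decaying geometrically
  per level (default root 8 px, decay 0.6, four levels at 512²; vessel area
  ≈ 5–10 % of the circular field, comparable to a fundus frame). It is not
  an anatomically realistic retina; all downstream math needs only two
  labeled compartments at realistic area fractions. Segment endpoints,
  nominal widths and raster lengths are recorded per level.
- *Kinetics*: the two-compartment linear model
  `c_in' = −k_clear·c_in`, `c_ev' = k_perm·(c_in − c_ev)`, solved in closed
  form with the `expm1` formulation (numerically stable through the
  `k_perm = k_clear` limit, where `c_ev = c0·k_perm·t·e^(−k_perm·t)`). It is
  the smallest model producing the observed dynamics: extravascular rise to
  a peak and decline for the detection dye, flatness for the reference. The
  defaults `k_perm = 0.2/min`, `k_clear = 0.05/min` put the extravascular
  peak near 9 minutes.
- *Rendering*: pixel = `drift(t) · clouding(t, x) · (baseline + gain·signal)`
  + Gaussian noise (Poisson selectable), where signal is `c_in` on vessel
  pixels and `evs_dilution · c_ev` outside. Defaults: baseline 100, gain
  1900 (20× vessel/background contrast at t = 0), noise SD 25, 16-bit
  clipping with a warning. Two deliberate modeling choices:
  - the multiplicative artifacts scale the *whole* signal including the
    baseline, since they model detector gain and optical transmission — this
    makes the renderer's drift exactly the disturbance the Leakage Index
    cancels;
  - `evs_dilution` (default 0.3) down-weights the rendered extravascular
    signal for the dilution of leaked dye into tissue volume. Without it the
    model's `c_ev` overtakes `c_in` late in the session whenever clearance is
    present, making the surround brighter than the vessels — contrary to the
    persistent inside/outside separation seen in vivo. The analytic
    expectation used by the oracle tests is
    `R(t) = (baseline + gain·evs_dilution·c_ev) / (baseline + gain·c_in)`.
- *Extravascular uniformity*: leaked dye is spatially uniform within the EVS
  (diffuse, not focal, leakage); no diffusion kernel is simulated.

What the phantom does *not* emulate: optic-disc anatomy and capillary
plexuses, partial-volume vessel edges, spatially correlated speckle, eye
motion between frames, and focal lesions. Passing tests therefore establish
the correctness of the estimators and statistics under the stated imaging
model, not performance on pathological in vivo data.

### The zero-permeability calibration

With a fluorescent background offset and a *cleared* detection dye, the
out/in ratio of the detection channel rises even at zero permeability: the
outside MFI stays at baseline while the inside MFI decays, so `LI(30) > 1`
without any leakage. This is a property of background-contaminated ratio
measurements, not of the code. Calibration experiments that require
`LI(30) = 1` at `k_perm = 0` — the permeability sweep and the null-leak
distribution checks — therefore use `k_clear = 0` for the detection tracer
(static intravascular signal). The paired sweep (same noise seeds across
permeability values) at 512², noise at half the background level, recovers
the permeability ordering exactly and calibrates to 1 ± 0.002 at zero
permeability.

## Problem sizes and numerical conventions

Validation runs use 512×512 phantoms (full-resolution 1536×1636 sessions are
supported by configuration); the permeability sweep uses 5 noise seeds per
value and the reference-flatness check 50 seeds. The shrinking-caliber
longitudinal phantom uses roots 8/7/6 px with decay 0.8 over three levels:
with heavier decay the pooled median sits on the thinnest generation, where
rasterized diameters quantize to a few discrete values and adjacent root
calibers tie. Ties in `R(0)` (zero baseline ratio), empty vessel masks at
measurement time, mismatched time grids, and a missing 30-min endpoint are
all hard errors except the last, which falls back to the latest available
time point with a warning. All randomness flows from explicit seeds; renders
are bit-reproducible.

## Known limitations

- The threshold segmentation has no vesselness model; very low-contrast
  capillaries below `k·σ` are assigned to the EVS, which slightly dilutes
  `MFI_out`. The ratiometric normalization removes the static part of this
  bias.
- Skeletal diameters are quantized by rasterization (±1 px); sub-pixel
  caliber changes are not resolvable.
- The two-compartment model has no back-flux saturation or binding; it is a
  small-signal description adequate for ordering permeabilities, not for
  absolute permeability estimation.
- Sessions are analyzed independently; motion between time points is handled
  only implicitly by re-segmenting each frame.
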