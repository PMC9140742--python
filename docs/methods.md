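# Methods

`pupilkit` estimates pupil diameter, in pixels, from short sequences of RGB
eye images taken with consumer cameras. Two segmentation pipelines cover the
two lighting regimes in which such images are taken, a Hough-circle baseline
provides a comparison method, and a synthetic scene generator provides
ground-truthed fixtures. This note records the models, the parameters that
matter, the numerical conventions, and the design choices that were genuinely
open.

## The two imaging regimes

In dark-eyed subjects the iris and pupil are nearly the same color, so a
single global grayscale threshold cannot separate them.

**Outdoor sunlight.** Strong ambient light raises overall exposure;
the pupil remains the darkest region in the *red* channel, but with low
contrast against the iris. The CCLPF pipeline (color-component low-pass
filtering) works on the red channel's local means.

**Indoor flash photography.** An axial flash produces the red-eye reflex:
the pupil images as a saturated dark red, while the sclera is near-gray and
the iris sits in between. In HSV space the pupil is the unique
highest-saturation region, and the PRSSM pipeline (saturation-based
recognition) segments it there.

## CCLPF: the outdoor pipeline

Per frame, at the 333 x 250 working resolution:

1. **Exposure enhancement.** Every channel is multiplied by 3 (clipped to
   [0, 255]), stretching the small pupil–iris red gap.
2. **Mean matrix.** The 3 x 3 unit-stride sliding mean of the red channel —
   a (H−2) x (W−2) real-valued grid (82,088 entries at working resolution).
3. **Dark interval.** The matrix is flattened row-major and a 5000-entry
   window is taken starting at the global minimum — the darkest (pupil)
   stretch. By default the window is then ordered ascending (see *Dark
   interval ordering* below).
4. **Running-minimum smoothing.** The prefix-minimum filter applied backward
   (suffix minimum) clamps upward noise spikes, leaving a non-decreasing
   curve from the global minimum. On an ascending-ordered window it is the
   identity.
5. **Component threshold.** The curve is scanned from its lowest value; the
   first consecutive difference greater than 5 marks the transition out of
   the pupil's value band. The value before the jump is the upper limit; if
   no jump exists the last element is used. The extraction threshold is the
   mean of {lower, upper, (lower+upper)/2}, algebraically the midpoint
   (lower+upper)/2.
6. **Mask and measurement.** Mean cells below the threshold mark their 3 x 3
   window centers on a blank canvas; a 10 x 10 morphological opening removes
   speckle (in particular the specular highlight); the largest 8-connected
   contour's bounding box gives the diameter as max(width, height); the
   rule-of-thumb temporal correction (tolerance 10 px) replaces any frame
   that jumps more than the tolerance from the previous accepted value.

### Dark interval ordering

Taking the window forward in raster order and suffix-min smoothing it
exposes only the running minima of the raster tail: the jump scan then sees
a handful of coarsely spaced record values, and wherever the ~15-row window
ends mid-pupil the scan stalls partway up the pupil's radial ramp. On the
synthetic fixtures this under-segments the pupil by 2x the intended error
budget. Ordering the window ascending instead exposes the window's full
value continuum — pupil interior, boundary blend, iris — so the >5 jump
criterion responds to genuine value gaps, and the no-jump fallback (upper =
window maximum) correctly places the threshold midway between the pupil
minimum and the bright surround. Both orderings are implemented
(`CclpfConfig.sort_interval`); ascending is the default.

Consequence of the midpoint rule worth knowing: the threshold sits halfway
between the *darkest pupil value* and the upper limit, so the mask is a
level set inside the pupil's radial shading ramp, cutting slightly inside
the rim. Together with the window-center mask convention (one pixel of rim
erosion per side by construction) the pipeline carries a structural ~−3 px
diameter bias on clean scenes — visible in the noise-free tests and well
inside the 25 px outdoor error budget.

## PRSSM: the indoor pipeline

Per frame:

1. **HSV conversion** to the 8-bit convention (hue 0–180 half-degrees,
   saturation/value 0–255).
2. **Adaptive saturation threshold.** Starting at 255 the saturation cut
   descends in steps of 5. At each step the mask is all pixels with
   saturation ≥ the cut; with P_n the mask pixel count and S the image pixel
   count, the pixel growth ratio is G_n = (P_n − P_{n−1}) / S. Because the
   mask is a superlevel set, P_n is non-decreasing and every G_n ≥ 0. The
   ratio rises while the sweep eats into the pupil's saturation cluster and
   first *declines* (strict <, first n ≥ 2) once the cluster is exhausted;
   that step's cut is the threshold. If no decline occurs by 0 the cut with
   maximal growth is returned and flagged in the trace.
3. **Mask and measurement** as in CCLPF, with temporal tolerance 5 px (the
   indoor pipeline is the more stable of the two).

The hue and value bands are fixed at their full ranges ([0, 180], [0, 255]);
only saturation is adaptive.

### Band direction

The saturation band is read as *high saturation is pupil* (foreground =
S ≥ t, with t descending). This is the only direction under which mask
counts are monotone, growth ratios are non-negative, and "first decline" is
well defined; the opposite reading produces negative ratios and no coherent
stopping rule.

## Hough-circle baseline

The comparison method grayscales a single channel (default grayscale for
full-RGB input is the blue-weighted formula 0.299 R + 0.701 B, i.e. the
standard luma formula with the green weight reassigned to blue), equalizes
its histogram (8-bit CDF mapping), Gaussian-blurs (5 x 5), extracts Canny
edges (defaults 50/150), and votes circles with the circular Hough
transform; the strongest detection's diameter is 2r. A per-channel sweep
over Canny lower thresholds 10..70 in steps of 5 (upper = 2 x lower) across
R, G, B, H, S, V records the first parameterization that detects a circle
on each channel. Parameters the method description leaves open are fixed as
documented defaults: radius search 10–120 px in steps of 4, minimum peak
separation of half the image height, and an accumulator vote threshold of
0.35 of the circle circumference (below which a frame counts as "no
detection"). No temporal correction is applied — the baseline has none — so
its corrected series equals its raw series. On eye scenes the dominant
circular edge is the iris/sclera boundary, so the baseline tends to report
the iris diameter; this is its characteristic failure mode against the two
pupil pipelines.

## Synthetic scenes

`synth.render_eye` draws a sclera field with concentric iris and pupil
disks (anti-aliased 1-px boundaries), multiplicative radial shading inside
the pupil, an optional specular highlight, optional optical blur, and an
additive Gaussian noise field. `synth.generate_sequence` renders an
80-frame sequence whose true diameters follow an exponential constriction
d(t) = 45 + 45·exp(−t/20) px (90 → 45 px, time constant a quarter of the
sequence), with ≤2 px per-frame center jitter and a fresh noise draw per
frame, all derived from one seed.

Defaults, and why:

- **Palettes.** Indoor: sclera (228,225,220), iris (110,90,72), pupil
  (75,22,18) — 8-bit saturations 9 / 88 / 194, realizing the pupil > iris >
  sclera saturation ordering with ≥30-unit margins. The pupil triple keeps
  its value channel high enough that saturation noise (amplified by 255/V
  per intensity unit) stays within the sweep's 5-unit steps, and its red
  channel below 85 so the 3x-enhanced red (225) does not clip — the outdoor
  pipeline must remain functional on indoor scenes for the cross-regime
  comparison. Outdoor: sclera (210,200,195), iris (85,67,54), pupil
  (64,48,40) — red ordering pupil < iris < sclera with a deliberately small
  21-unit pupil–iris gap (the low-contrast sunlight regime); after the 3x
  enhancement the iris red clips to ~225–255, far above any component
  threshold, so the red mask never leaks into the iris.
- **Pupil shading** (depth 0.35, power 6): the pupil color is scaled by
  1 − 0.35·(1 − (ρ/r)^6), darkest at center. Real pupils image darker at
  the center than at the rim, and the outdoor pipeline *requires* a radial
  ramp: on a perfectly flat pupil its threshold (the midpoint of the dark
  band) either equals the band (empty mask, noise-free) or bisects the
  noise distribution (speckle). The shading is multiplicative, so HSV
  saturation — the indoor pipeline's statistic — is unchanged by it.
- **Noise** (sd 5, correlation length 250 px, shared across channels): a
  Gaussian random field added equally to R, G and B, i.e. smooth luminance
  drift. Smartphone imaging pipelines denoise aggressively; the residual
  variation in real frames is low-frequency illumination/shading drift, not
  white sensor noise. Both pipelines presuppose exactly this: i.i.d. pixel
  noise at sd 5 makes every threshold mask a ~50%-density speckle that the
  10 x 10 opening annihilates, and channel-independent noise widens the
  pupil's saturation cluster (via the 255/V amplification) beyond the
  sweep's step. White and per-channel noise remain available
  (`noise_corr=0`, `noise_shared=False`) for studying exactly that
  breakdown.
- **Highlight** (radius 3 px, offset (+4, −4)): small enough that the
  10 x 10 opening removes its artifacts — the noise-removal mechanism the
  geometry tests exercise.
- **Optical blur** (`optics_blur`, default 0): Gaussian point-spread applied
  to the clean scene. Off by default: ≥1 px of blur widens the saturation
  blend ring at the pupil rim enough to bias the indoor pipeline ~−5 px.
  The noise-free end-to-end tests enable it (1.2 px), because without any
  blur the clean shading ramp's integer quantization leaves artificial >5
  value gaps that stop the threshold scan — a corner case real optics never
  produce.

What the generator does **not** emulate: eyelids, lashes, partial
occlusion, gaze direction, motion blur, compression artifacts, or the
texture of a real iris. Passing the fixture tests therefore shows that the
pipelines implement their specifications and track a constricting pupil
under smooth illumination drift — not that they are robust to everything a
clinical video contains.

## Numerical conventions

- Rounding: nearest integer, ties away from zero, once at the end of each
  per-pixel formula.
- Resize: area averaging for downscale, bilinear for upscale.
- HSV: hue halved into [0, 180]; saturation 0 where max = 0.
- Mean matrices are real-valued (no premature integer truncation); the
  threshold comparisons operate on reals.
- Global-minimum ties in the dark interval: first occurrence in raster
  order. A window truncated by the end of the flattened matrix is processed
  as-is with a warning.
- The 10 x 10 structuring element is anchored at cell (5, 5); connectivity
  is 8-way for components and contours.
- Diameters are integer pixel counts (no sub-pixel fitting); the bounding
  box of the largest-area contour supplies max(width, height).
- Temporal correction compares each raw value against the previous
  *accepted* value, so a single bad frame cannot drag the series. The flip
  side, visible in stress tests: if the series freezes while the true
  diameter keeps moving, the rule cannot re-acquire it. Keeping per-frame
  raw jitter below the tolerance is what the study conditions provide.
- Frame-level pipeline failures record diameter 0 and a flag; they never
  abort a sequence.

## Known limitations

- Both pipelines assume exactly one pupil-like region; there is no
  multi-candidate disambiguation beyond largest-contour selection.
- The component threshold's midpoint rule under-segments shaded pupils by
  design (see above); the outdoor pipeline is the sloppier of the two, as
  its 25 px error budget reflects.
- The adaptive saturation sweep's strict first-decline rule can stop one
  step early when the saturation histogram is locally non-monotone; the
  5 px temporal tolerance absorbs the resulting single-frame dips.
- The Hough baseline reports the iris, not the pupil, on most eye scenes;
  it is included as the comparison method, not as a usable pupillometer.
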