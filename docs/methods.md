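# Methods

This note documents the models and procedures implemented in
`shadowpipe`, the parameter defaults and why they were chosen, what the
synthetic scene generator does and does not emulate, and the numerical
decisions made where the design was genuinely open.

## Flat-fielding

Each pixel is corrected as `corrected = (raw − offset) · gain` with
`gain = avg / calib`. `avg` is the pixel's temporal mean over the video
(or segment). `calib`, the calibration frame, is the mean of the pixel's
ascending-sorted temporal values at 1-based ranks
`ceil(lo·T)+1 … ceil(hi·T)` for a window `(lo, hi] = (0.80, 0.90]` over
`T` frames — a robust estimate of the bright background that excludes
both transient dark objects (below the 80th percentile) and transient
bright noise (top decile). The window is configurable; `(0.8, 1.0]`
reproduces a plain top-quintile mean, and `(0, 1)` degenerates to the
temporal mean. The offset default is 0 — the dark level of the sensor —
and may be supplied as a scalar or a dark frame.

Two gain conventions are provided:

- **Per-pixel `avg` (default).** The correction acts on *temporal*
  deviations of each pixel from its own bright-background estimate. A
  perfectly static video is a fixed point (to float tolerance), the
  correction is scale-equivariant before clipping, and a segmented run
  with segment length equal to the video length is bit-identical to a
  whole-video run. These identities anchor the test suite.
- **`uniform_background=True`.** The gain targets the scalar mean
  brightness (`mean(avg) / calib`), driving every background pixel
  toward one level. This is the standard flat-field normalization that
  also removes *static* illumination gradients; on a static
  0.6→1.0 linear gradient it reduces the background coefficient of
  variation by far more than 10×. The two conventions coincide only when
  the illumination is already uniform; both are exposed because the
  per-pixel form has the clean algebraic contract while the uniform form
  is what "make the background flat" usually means.

For backgrounds that oscillate (independently drifting layers, camera
vibration), the video is split into segments of 10 frames, each with its
own `avg` and `calib` (a trailing remainder shorter than one segment is
merged into the previous segment to avoid a degenerate one-frame
calibration). On synthetic oscillating scenes the 10-frame segmented
correction leaves a background residual no larger than the whole-video
correction; motion-compensated calibration is deliberately out of scope.
Pixels whose calibration value is 0 (dead-dark) pass through uncorrected
with a logged warning. Output intensities are clipped to [0, 1] because
downstream Otsu thresholding assumes bounded intensities.

## Segmentation

Applied in order per video:

1. **Otsu binarization**, per frame, dark-on polarity: pixels strictly
   below the Otsu threshold become foreground. Per-frame scope is robust
   to inter-frame illumination drift; a single global threshold over the
   whole video is available behind a flag. A constant frame yields no
   foreground (warning logged).
2. **Frequency masking**: each pixel's frequency is the fraction of
   frames in which it is foreground; pixels whose frequency *strictly
   exceeds* `max_freq` (default 0.8) are switched off in every frame.
   This removes static artifacts — lens scratches, trapped bubbles —
   while organisms that move through the frame survive. The frequency
   is always computed over the full video, even when flat-fielding was
   segmented.
3. **Minimum area**: connected components *strictly smaller* than
   `min_area_px` (default 15; useful range roughly 15–50 depending on
   the particle sizes of interest) are removed. Both strict inequalities
   follow the worked-example semantics of the masking and area rules.
4. **Dilation** with the exact Euclidean disc
   `{(dy, dx): dy² + dx² ≤ r²}`, radius 5 by default. Translucent
   (gappy) organisms binarize into fragments; dilation rejoins fragments
   within `2r` of each other into one region. The exact disc (81 pixels
   at r = 5) is used rather than a decomposed approximation so results
   are identical across platforms.
5. **Optional second area filter** after dilation
   (`post_dilation_min_area_px`, off by default): the first filter is
   typically kept small so organism fragments survive until dilation
   rejoins them, after which a stricter filter can be applied.
6. **Region detection**: 8-connected components (configurable to 4) with
   tight half-open bounding boxes `(r0, c0, height, width)`, 0-based,
   ordered by box origin. Crops are cut from the *flat-fielded
   grayscale* at the bounding box — the classifier sees silhouette
   texture, not the binary mask — and the pre-resize crop dimensions are
   recorded as the classifier's size input.

ROIs are not tracked across frames: one organism visible in k frames
produces k detections. This inflates absolute counts (see Abundance) but
keeps the segmentation stage stateless and is flagged wherever counts
are reported.

## Augmentation and dataset preparation

Class balance is restored by per-class multiplicative factors (the
shipped defaults: Chaetognath ×14, Crustacean ×0.5, DetritusA ×14,
DetritusB ×14, Gelatinous ×2, Larvacean ×2; secondary gelatinous set:
Annelida ×8, Ctenophora ×5, Doliolida ×8, Medusozoa ×2, Radiolaria ×3,
Siphonophora ×7). An integer factor k yields each original plus k−1
augmented copies; the only fractional factor supported is 0.5, which
keeps the larger half of the class by original pixel area (ceil(n/2)
images, ties broken by filename) — larger specimens carry more
morphology. The read of "larger images prioritized" as *retention* is a
judgment call; a flag flips it to removal. Secondary datasets are always
built from original raw images — augmentation is never applied twice,
and the builder rejects inputs that already contain augmented images.

Each augmented copy applies, in order: Gaussian blur (σ = 1.0 px),
additive Gaussian noise (σ = 0.02 on [0, 1]), then one random draw of
scale ∈ [0.8, 1.2], rotation ∈ [0°, 360°) and horizontal/vertical
reflection (each with probability 0.5). Blur and noise magnitudes are
"slight" at ROI scales of tens of pixels; silhouettes have no canonical
orientation in the water column, so the full rotation circle is used.
The canvas is preserved; exposed background is filled with the median
border intensity so rotation corners do not mimic silhouettes. Rotations
at multiples of 90° use lossless array rotation (so a 180° rotation is
an exact involution); other angles use bilinear interpolation.

Images are standardized to a square network input (default
229 × 229) by anisotropic bilinear stretch with anti-aliasing on
downscale — no letterboxing, because the size input (below) carries the
scale information that any resize destroys. The original (height, width)
is recorded before any resize and never altered afterwards.

The stratified 70/15/15 train/validation/test split shuffles each class
with the seed and apportions the three split sizes by largest remainder
(ties favor train, then validation), so each split's count is within one
image of its exact quota and per-class proportions always lie within
1/n of the nominal fractions. Classes with fewer than 3 images are
rejected by name. Augmented copies of one source image are not
constrained to one split by default; a leakage-safe variant is to split
before augmenting, and both orders are supported through the library.

## Dual-input classification

All backbone architectures in common use end in fully-connected +
softmax; the size adaptation replaces that ending with a head that
concatenates the backbone's feature vector with the ROI's original
(height, width) in pixels, normalizes the concatenated vector (z-score
with training-set statistics; the raw feature variances differ by orders
of magnitude), applies a ReLU activation, and finishes with
fully-connected layers and softmax. The final layer outputs one
probability per class (default 6). Confidence is the maximum softmax
probability; argmax ties break toward the lowest class index.

The backbone is pluggable behind a `transform(images) → features`
protocol. The default is a bank of 8 fixed, seeded, He-initialized 5 × 5
convolution filters with ReLU and 4 × 4 average pooling (128 features) —
a deliberately small random-feature extractor that trains in seconds on
CPU; the trainable component is the head (one hidden layer of 32 units
by default). Named deep architectures can be dropped in wherever a
`transform` is available; their internals are not the subject here, the
head and routing are.

Training: minibatch Adam (default learning rate 1e-3, configurable) on
cross-entropy, batch size 128, validation accuracy evaluated once per
epoch; stops at `max_epochs` (default 15) or after `patience` (default
50) evaluations without improvement, whichever comes first, returning
the best-validation weights. "Iterations with no improvement" is
interpreted as validation evaluations; cadence is configurable. Training
is deterministic given the seed (pure numpy, no backend
nondeterminism). A class present in validation but absent from training
is an error.

The size-dimorphic synthetic pair (below) is the mechanism probe: two
classes with identical silhouette geometry drawn from disjoint length
distributions, N(30, 2) vs N(120, 8) px. After resizing to a common
square the image-only model has essentially no signal; the size-aware
model separates the classes through the stored original dimensions. The
shipped experiment (48 px inputs, 60 images per class, 5 seeds,
100-epoch head training at learning rate 1e-2) shows the size-aware arm
winning on every seed — a one-sided sign test at 5/5 gives p ≈ 0.031.
The two heads differ by exactly the size-pathway parameters (2 extra
inputs to the hidden layer).

Hierarchical routing: a class tree lists base classes and optional
subclass lists with attached niche models (default: Gelatinous →
Annelid, Ctenophora, Doliolid, Medusozoa, Radiolaria, Siphonophora). An
ROI is routed into a niche model only when its base class is subdivided
*and* its base confidence is at or above the acceptance threshold
(default 0.70); below-threshold ROIs are flagged unaccepted and left in
`_unsorted/`. Raising the threshold never increases the accepted count.

## OOD pre-filter

The gradient-spike score is the maximum mass fraction in one bin of the
gradient-magnitude histogram (central differences, 64 bins over
[0, max]); it is 1.0 exactly when all gradient magnitudes share a bin
(constant images score 1.0 by convention) and is invariant to intensity
shifts and transposition. Images scoring strictly above the threshold
(default 0.5) are flagged. The statistic and threshold are this
package's interpretation of "a distinct spike in the gradient
histogram" — no closed form exists to copy — so every score is exported
with the flag and the threshold is expected to be recalibrated per
instrument. The filter is imperfect by design; textured aberrations
pass it.

## Metrics

One-vs-rest accounting on the confusion matrix `cm[true, predicted]`:
recall `TP/(TP+FN)` (row-normalized diagonal), precision `TP/(TP+FP)`
(column-normalized diagonal), accuracy `trace/total`. Zero-support
recall and zero-prediction precision are reported as NaN with a warning,
never silently 0 — macro-averaging conventions differ and a fabricated
zero would bias them.

## Abundance

Counts per clip divide by the pumped volume, flow rate × duration
(instrument defaults 18 L/s × 30 s = 540 L); an alternative mode
normalizes by imaged frame volume × frames (0.74 L/frame ≈ 45 cubic
inches, conversion 0.016387064 L/in³). Instrument geometry utilities
give the resolvable size range: minimum representable pixel count ×
pixel pitch (10 px × 35 μm = 350 μm) up to the longer frame dimension
(2440 px → 85.4 mm).

Outlier trimming is a single pass at 3 standard deviations using the
mean and SD of the full series (ddof = 1); it is not re-iterated, so
re-applying it with recomputed statistics can remove further points —
the single-pass semantics is the documented contract. A zero SD removes
nothing. Confidence intervals are percentile bootstrap of the mean:
B = 1000 resamples with replacement, empirical (α/2, 1−α/2) quantiles,
deterministic given the seed. Percentile rather than BCa is the default
for simplicity and exact reproducibility; the small undercoverage of
percentile intervals at moderate n (measured ~93–95% at n = 60) is
accepted and verified by a coverage simulation in the tests.

## Synthetic scenes: what they emulate, and what they do not

`synthgen` renders: a bright background at a set level; multiplicative
illumination fields (flat, linear ramp, radial); static dark artifacts
(disks, scratches) identical in every frame; a smooth dark layer
drifting sinusoidally across columns (the oscillating-background
failure mode); moving silhouettes of five morphologies (vermiform,
copepod-like, gelatinous blob, chain, round blob) whose proportions all
scale with body length, with optional interior gaps emulating
translucency; and additive Gaussian sensor noise. Silhouette shapes are
evaluated analytically in a rotated object frame, so rotation introduces
no interpolation, and each object carries an exact per-frame mask,
tight bounding box and area. Rendering is deterministic given the seed,
with one RNG stream per (seed, video id) so batch generation is
order-independent. Labeled image sets render one silhouette per canvas
with padding proportional to body length, so the canvas framing itself
carries no size cue after resizing.

Not emulated: physically accurate schlieren optics, focal-plane blur,
occlusion between organisms, intensity texture inside silhouettes, and
real taxonomic shape variation. Consequently, passing tests demonstrate
that the *pipeline machinery* is correct — recovery of every
sufficiently dark, sufficiently large moving object, rejection of
static artifacts, the size-input mechanism — not that any particular
field accuracy would be achieved; field performance depends on a real
labeled dataset that is outside this package's scope.

## Problem sizes

The shipped experiments are desk-scale by design: synthetic videos of
128–192 px frames and 6–12 frames, labeled sets of 40–120 images at
32–48 px inputs, 5-seed ablations, 500-series coverage simulations with
B = 1000 bootstrap resamples. Every quantity they measure is defined
identically at instrument scale (2440 × 2048 frames, 600-frame clips),
and the operations are vectorized so scale is a matter of runtime, not
semantics.

## Known limitations

- Per-detection counting overinflates absolute abundance when organisms
  span multiple frames; cross-frame deduplication (tracking) is not
  implemented.
- The default per-pixel flat-field gain cannot remove a perfectly static
  illumination gradient (it is a temporal corrector); use
  `uniform_background=True` for that.
- The OOD spike statistic is a stand-in with a configurable threshold,
  not a learned detector.
- AVI/MP4 decoding requires an imageio codec plugin; the native format
  is the PNG-sequence directory.
- The default backbone is a fixed random-feature extractor: adequate for
  silhouette geometry at desk scale, not a substitute for a trained deep
  backbone on field data.
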