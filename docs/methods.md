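# Methods

## Physics-driven cine-to-tagged transformation

**Contrast conversion.** Tagged acquisitions are gradient-echo-like, cine
acquisitions bSSFP-like.  The conversion is deliberately gross: min-max
normalise the slice to [0, 1], then take the element-wise square root.  The
map is monotone, so tissue intensity ordering is preserved while the
mid-range is brightened toward a GRE look.  The intensity scale of the input
is not assumed; normalisation before the square root makes the transform
scale-free.  A constant image has no range to stretch and is clipped to
[0, 1] unchanged — this keeps a uniform test target usable for tag-geometry
measurements.

**SPAMM preparation.** The tag modulation is obtained by simulating the
preparation with the Bloch equations in the rotating frame, neglecting
relaxation during the (millisecond-scale) pulse train.  Starting from
M = (0, 0, 1), each RF sub-pulse is a rotation about the transverse x-axis
by w_i/Σw · α_total; between consecutive sub-pulses the tagging gradient
advances the local precession phase ψ, a rotation about z.  After the train
a crusher spoils the transverse components, leaving Mz(ψ) as the imprinted
modulation.  Defaults: weights (1, 3, 3, 1) — a binomial train whose
saturation band is smooth and whose profile for small total flips stays
non-negative — and α_total = 70°, which leaves Mz(0) = cos 70° ≈ 0.342, i.e.
somewhat faded rather than fully nulled tag lines.

Two checks pin the simulation down independently of its implementation:
at ψ = 0 all sub-rotations compose about a single axis, so
Mz(0) = cos α_total for *any* weight vector; and the two-pulse (1, 1) train
at 90° has the closed-form profile Mz(ψ) = (1 − cos ψ)/2, derivable by hand
from three rotation matrices.  The test suite also compares 100 random
(ψ, flip, weights) draws against explicit 3×3 rotation-matrix composition.

**Grid geometry.** Per-pixel phases are ψ_u = 2π·u/spacing along two
orthogonal axes (u, v) obtained by rotating the pixel axes by the grid
angle; the field is Mz(ψ_u)·Mz(ψ_v), i.e. two sequential 1D preparations
with spoiling in between.  Pixel (0, 0) sits at phase zero on both axes,
tying the pattern to a reproducible origin.  Defaults: 5 px spacing, 45°
rotation (the typical clinical grid-tag orientation; the rotation angle is a
free parameter of the acquisition and is exposed in `TagPrepConfig`).
Whether a clinical sequence uses one 2D or two 1D preparations is a
sequence-design detail; the separable two-preparation form was chosen
because it is exactly testable (at rotation 0 the field must equal the outer
product of the 1D profiles).

**Composition and mask transfer.** The tagged-appearing image is the
sqrt-contrast image multiplied by |Mz| — magnitude imaging renders saturated
magnetization dark — then min-max renormalised.  The segmentation mask is
copied bit-identically: the transform moves no anatomy, so the cine
annotation remains valid.  Tag lines are static across the frame index; they
do not deform with myocardial motion, a stated limitation of this class of
transformation.

**Fading (optional, off by default).** Tag contrast in vivo decays with T1
recovery over the cycle.  When enabled, each pixel follows
Mz(t) = 1 + (Mz(0) − 1)·e^(−t/T1) with t = frame_index · frame_interval;
defaults T1 = 850 ms (myocardium at 1.5 T) and 40 ms per frame (25 frames
over a ~1 s cycle).  Default-off is the conservative choice matching static
tag lines; the parameters are exposed because the real contrast dynamics
depend on sequence parameters this package does not model (TR, imaging flip,
readout).

**Tag-period measurement.** `measure_tag_period` samples the image along the
grid-normal direction, averaging over a ±20 px band of parallel lines;
averaging along the tag-line direction suppresses both the orthogonal grid
modulation and bilinear-interpolation lattice ripples (at 45° a single
sampling line runs exactly along a dark-line valley, where those ripples
would dominate).  Minima are accepted at ≥10 % prominence of the profile
range; the period is the mean spacing of consecutive minima.

## Boundary-aware shape loss

φ(m) is the signed Euclidean distance map, computed between pixel centres
(`scipy.ndimage.distance_transform_edt` twice): +distance to the nearest
background pixel on foreground, −distance to the nearest foreground pixel on
background, then divided by the image-wide maximum absolute value so the
range is [−1, 1].  Three conventions had to be fixed:

- **Sign:** positive inside.  Only this choice makes
  SI(m) = H(1 − φ(m))·[φ(m) ≥ 0] a boundary-peaked interior map — largest
  (≈ H(1) = 0.993 at k = 0.2) at foreground pixels adjacent to the
  boundary, decaying toward H(0) = 0.5 in the deep interior, exactly zero
  outside.
- **Normaliser:** the per-channel image-wide max of |raw distance|.  Any
  fixed positive normaliser preserves the qualitative shape; the per-image
  choice guarantees the stated [−1, 1] range on every input.
- **Pixel-centre distances:** a foreground pixel touching background has
  raw distance 1, not 0; sub-pixel boundary geometry is not modelled.

L_S averages over channels the foreground-normalised pixel sum of
|p − SI(g)|; integrals over the domain are pixel sums.  The combined loss
adds (1 − soft Dice) and cross entropy.  Soft Dice uses pixel sums with a
smoothing ε = 1e−6 so empty predictions are defined; cross entropy keeps
only the g·log p term (no (1−g)·log(1−p) complement), with p clamped below
at ε, and is a *sum* over pixels, not a mean — its magnitude therefore
scales with image size.  Degenerate (empty or full) ground-truth channels
raise rather than silently producing NaNs.

## Evaluation metrics

Contours are foreground pixels with at least one 4-neighbour outside the
mask, with the image border counting as outside; coordinates are scaled by
the (possibly anisotropic) pixel spacing to millimetres.  HD-95 is the
maximum of the two directed 95 %-quantiles of nearest-neighbour contour
distances, with the linear-interpolation quantile estimator
(`numpy.quantile` default).  Conventions for edge cases: both masks empty →
DSC 1; exactly one empty → DSC 0; HD-95 is undefined on empty masks and is
reported as missing (NaN) in batch reports, excluded from aggregates, never
coerced to 0.  Batch aggregation reports per-pair records plus mean and
sample standard deviation.

## Synthetic phantom

Concentric discs: blood pool (0.9), myocardial annulus (0.5), background
(0.1), radii 30/48 px at end-diastole on a 256 grid, contracting by up to
25 % of the radius at end-systole under the smooth law
r(f) = r_ED · (1 − c·sin²(πf/(N−1))), N = 25 frames.  Any smooth periodic
law would do; this one is ED→ES→ED symmetric and testable in closed form.
Masks are hard-thresholded at pixel centres (no partial volume) so mask
invariants are exactly checkable; additive zero-mean Gaussian noise
(σ = 0.02 by default) is clipped to [0, 1], with the stream seeded by
(seed, frame) so series are reproducible element-wise.

What the phantom does *not* emulate — realistic torso anatomy, papillary
muscles, coil shading, k-space noise, through-plane motion — bounds what
passing tests show: they validate the transformation, loss and metric
*implementations*, not clinical image realism.

## Augmentation and preprocessing

Preprocessing resizes bilinearly to 256×256 (skipped when already at size,
so native-resolution inputs are not resampled) and standardises with
mean 0.456 / std 0.224.  Augmentations fire independently in the fixed order
flip → noise → blur → affine → elastic; geometric transforms use bilinear
interpolation for images and nearest-neighbour for masks (masks stay
binary), intensity transforms touch only the image.  The random stream is
`default_rng([seed, draw_index])`, so any draw can be replayed bit-exactly
and different draw indices are statistically independent.  Magnitude
defaults (±15° rotation, 0.9–1.1 scale, ±10 px translation, σ = 0.05 noise,
0.5–1.5 px blur, 32 px elastic grid with 3 px displacement SD, probability
0.5 each) are moderate values typical for cardiac segmentation pipelines and
are all configurable.  Out-of-bounds regions fill with 0.

## Problem sizes in tests

The test suite and the acceptance script run on 256² uniform images for tag
geometry, ≤16² random masks for the all-pairs distance oracle, ≤12² pairs
for the metric oracles, and a 2-subject × 25-frame 64² phantom dataset for
the pipeline — sizes at which the brute-force references are exact and fast
while exercising every code path.

## Known limitations

- Tag lines do not deform with the myocardium; pseudo-tagged data carries no
  true motion-encoding signal.
- The contrast conversion is a monotone approximation, not a signal model;
  blood/air contrast remains cine-like.
- No k-space/readout simulation, no through-plane motion, 2D only.
- The shape loss is implemented for evaluation, not optimisation: no
  gradients are provided.
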