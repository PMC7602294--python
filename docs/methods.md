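# Methods

`chestcad` implements a complete computer-aided detection (CAD) chain for
lung nodules in chest radiographs whose central component is a learned
rib/clavicle suppressor: a *massive-training* pixel-regression filter that
predicts a bone-only image from a single radiograph, so that a weighted
subtraction yields a soft-tissue image in which nodules obscured by ribs
become detectable.  Every stage is exercisable on synthetic chest phantoms
with exact ground truth; no external image set is required.

## Image model and phantoms

Phantoms use a strictly additive formation model,

    xray = soft_truth + bone + N(0, noise_sd),

which makes the bone teaching image and the soft-tissue target exact — the
role that dual-energy bone images play for real radiographs.  We chose the
additive model (rather than exponential attenuation) because the suppression
step itself is a subtraction; with additive formation the ground truth of
every intermediate image is available exactly, which turns suppression
quality into a measurable quantity rather than a visual impression.

Phantom content, per 512 px / 0.7 mm reference geometry (a 2048 px film at
0.175 mm, subsampled 4x; `default_config(n)` rescales everything
consistently):

- **Lung fields**: two elliptical lobes (semi-axes 0.34/0.155 of the image
  side, adjustable for shape-model experiments), rendered as smooth bright
  regions (base 100, amplitude 60, arbitrary linear units — the source
  gray-level calibration of digitized films is not modeled) plus a gentle
  planar trend so background correction has work to do.
- **Bone**: per lobe, `rib_count` = 6 oblique raised-cosine bands (width
  14 px, period 40 px, ±35°, contrast 30) plus one near-horizontal clavicle
  band at the apex (contrast 25).  Raised-cosine profiles reproduce the
  failure mode the suppressor targets: quasi-periodic bright bands crossing
  nodules.
- **Nodules**: truncated Gaussian domes (σ = R/2, exactly zero at the rim),
  default diameter 17.8 mm, with five subtlety grades mapping to strictly
  increasing peak contrasts {4, 8, 12, 18, 25} against rib contrast 30 and
  noise SD 2 — grade 1 is deliberately near the noise floor ("tremendously
  subtle"), grade 5 clearly visible.  Nodules add to the soft-tissue layer
  only and can be forced to lie under rib-band crests.

What the phantoms do **not** emulate: attenuation physics, scatter,
heart/mediastinum opacity, pose and anatomy variation, film grain. Passing
tests therefore demonstrate that the algorithms recover planted structure
under controlled conditions — not clinical performance.

## Multi-resolution pyramid

Decomposition stores, per level, the difference between the image and its
2x2-block-mean downsampled, pixel-replicated upsampled version; the base is
the final low-resolution image.  Because upsampling is plain replication the
transform is exactly invertible (round-trip error is float round-off;
asserted at ≤ 1e-9 on random images).  Odd side lengths are rejected rather
than padded — padding would break exactness; callers pad explicitly with
`io.pad_to_multiple`.  The default of 3 levels spans rib widths at the
512 px scale (ribs ≈ 8–20 px).

## The suppressor

One three-layer regressor per pyramid level (difference levels plus base),
each 81 → 20 → 1: a 9x9 patch of the x-ray level in, the bone level's
central pixel out, sigmoid hidden units, linear output.  Splitting by
resolution lets each small network handle one rib frequency band.  Training
uses plain mini-batch gradient descent at a fixed learning rate (default
0.05, 60 epochs, batch 256, ≤ 20 000 pairs per level subsampled under the
run seed); patches are standardized per level to zero mean / unit variance
and teaching values scaled to [−1, 1], constants stored in the model.
Training pixels come from the lung mask (block-mean downsampled and
thresholded at 0.5 per level) at least 4 px from the image border; inference
uses edge-replicated patches so the output covers every pixel.  Everything
is seeded and bit-reproducible.

Soft-tissue synthesis is the pixelwise identity

    soft = xray − w_c · f_b · mask,

with the rib-contrast weight `w_c ∈ [0, 1]`; `w_c = 0` and a zero mask are
exact identities (tested bit-exactly).

**Choosing w_c.**  Suppression involves a genuine trade-off that the
phantoms make measurable: at `w_c = 1` rib-band amplitude drops ~90% but
nodules overlapping ribs lose a large fraction of their contrast, because
where a dome overlaps a band the patch looks like "brighter rib" and part of
the dome is attributed to bone.  `sweep_rib_contrast` therefore scores each
grid value by a strict candidate-stage criterion: the fraction of nodules
for which one of the top-10 candidates falls *inside* the nodule (within its
annotated radius).  This criterion degrades both when ribs clutter the
candidate list (low w_c) and when over-subtraction erodes nodule prominence
(w_c near 1), and on phantom studies it selects an interior optimum —
typically 0.6–0.8 at the phantom's rib-to-nodule contrast ratios, varying
with the calibration-set realization because the statistic is a binary hit
over a small image set (the library default remains 0.4, the published
operating point for real radiographs, and is overridable everywhere).  The downstream FROC evaluation
uses the clinical 25 mm hit rule instead; the two criteria serve different
purposes (calibration vs. reporting) and are deliberately not unified.

## Lung fields and background trend

Segmentation is a segment-labelled point-distribution active shape model:
48 landmarks per lobe by arc-length resampling from a canonical top-most
start point, labelled apex / rib-cage / diaphragm / mediastinal by arc
fraction; shapes aligned by translation and scale; principal modes retained
to 95% variance.  Search moves each landmark to the strongest
gradient-magnitude response within ±8 px along the boundary normal
(Gaussian-gradient at σ = 2), then projects into the mode subspace with
±3σ clipping, iterating to a 0.5 px mean-shift tolerance.  A flat image
(no gradient evidence) returns the initial shape with a warning flag rather
than failing.  The full multi-segment transitional-node machinery of
clinical ASMs is not needed for two-lobe phantoms and is out of scope; real
radiographs can supply an external mask instead.

Background trend correction fits F(x, y) = ax² + by² + cxy + dx + ey + f by
least squares to the masked intensities and subtracts it inside the mask
only.  The fit runs on coordinates normalized to [−1, 1]² for conditioning,
but coefficients are converted back to pixel units before being reported, so
a planted gradient of (0.5, 0.3) per pixel is recovered as exactly that
(asserted to 1e-6).  Rank-deficient designs (collinear masks) raise; the
operation is idempotent to 1e-8.

## Candidate detection

Two-step nodule enhancement = opening-residue (top-hat) at two disk radii
(defaults 6 and 14 px at the 512 px scale, bracketing the ~13 px nodule
radius; 3 and 8 px at 256), clipped at zero and rescaled by the mask-interior
maximum into a likelihood in [0, 1].  Note that a narrow rib band is *also*
enhanced by a top-hat whose disk exceeds the band width — this is why
enhancement alone does not solve the rib problem and the suppressor earns
its keep; the no-suppression FROC arm quantifies exactly this.

The watershed of the negated likelihood (8-connected, one marker per
regional-maximum plateau, plateaus merged by connected-component labelling)
partitions the mask into catchment basins.  Clustering grows a candidate
from each seed basin by merging any adjacent basin whose saddle (highest
boundary crossing, measured as max over adjacent pixel pairs of the lower
likelihood) reaches `merge_fraction` (default 0.8) of the lower of the two
basins' peaks, iterated to a fixed point; identical merged regions are
deduplicated.  Auto-seeding uses all regional maxima of the step-2 map at or
above `likelihood_floor` (default 0.3); candidates are ranked by peak
likelihood and capped (default 30/image).

A candidate records both the merged-basin `region` (the watershed object)
and a compact `core_region` — the connected half-peak support around its
maximum — because basins partition the whole lung field and are anatomically
huge; features that measure the *opacity* (shape, texture, curvature) are
computed on the core, which approximates the bright blob itself.

## Features

31 named features per image domain, computed identically on the x-ray and
soft-tissue images at the same candidate region (62 total), so a nodule
whose rib-like traits the suppressor attenuated can still be recognized from
its x-ray block and vice versa.  Noteworthy numerical choices:

- **Circularity / perimeter**: R is the perimeter of the convex hull of the
  region's pixel squares.  This estimator is exact for convex axis-aligned
  shapes (4 for a single pixel, 4s for an s-px square, hence circularity
  π/4 for squares) and a close outer estimate for rasterized disks
  (within [0.95, 1.05] of 1); chain-code and crack-boundary counts cannot
  satisfy both properties simultaneously.
- **Gradient concentration**: eight angular sectors about the region
  centroid; per qualifying pixel (gradient magnitude within [t1, t2],
  defaulting to the 10th/98th percentile within the region) the cosine of
  the angle between the image gradient and the direction toward the
  centroid.  Grad_2 is the square root of the raw sum of squared sector
  deviations — no 1/8 — as the method's definition prints it; a normalized
  variant is available behind a flag.  Grad_3 = Grad_1/Grad_2 (0 when the
  spread vanishes).
- **Surface curvature**: full bivariate quartic least-squares fit over the
  region (needs ≥ 15 px), Hessian eigenvalues at the highest fitted point,
  ordered by absolute value with signs preserved; Surface_3 is their
  product, so Surface_3 = Surface_1 × Surface_2 holds identically.
- **Texture**: symmetric normalized co-occurrence matrix over 16 gray bins
  at offsets {(0,1),(1,0),(1,1),(1,−1)} within the region.  Texture_1 and
  Texture_2 square the matrix entries (an energy and a squared-weighted
  contrast, as the scheme defines them); Texture_3..6 are the conventional
  contrast, homogeneity, correlation and entropy of the same matrix.
- **Edge overlap (FalsePositive)**: fraction of the region's inner boundary
  lying on Canny edge chains dilated by 1 px — near 1 for candidates that
  merely trace an anatomical edge.
- **Surround**: dilation by max(3, 0.5·√(A/π)) px minus the region.
- Shape_4's reference point is the lung-field centroid.

The 14-feature baseline set (GLCM statistics, first-order gray statistics,
histogram entropy/uniformity/smoothness/skewness, circularity, area,
perimeter) reuses the same primitives.

## Classification and evaluation

A Gaussian-kernel SVM on standardized features, hyperparameters selected
over C ∈ {0.1, 1, 10, 100} × γ ∈ {0.01, 0.1, 1} by cross-validation
*grouped by image* — all candidates of one radiograph share a fold, so a
nodule's own image never appears in its training folds; out-of-fold decision
scores feed the FROC.  The baseline classifier is a single-hidden-layer
sigmoid network trained by the same fixed-rate gradient descent as the
suppressor's units (1000 hidden units as the conventional system specifies;
tests use far fewer).

FROC: a candidate is a true positive when its centroid lies within 25 mm
(converted via pixel spacing) of an unclaimed nodule center; matching is
greedy in descending score order with deterministic ties (image id, row,
col), so each truth nodule claims at most one candidate, and the
per-threshold curve equals the prefix of one global greedy pass.
`sensitivity_at_fp` interpolates linearly.

## Problem sizes

Phantom experiments run at 256 px (1.4 mm pixels; nodule radius 6 px,
enhancement radii 3/8 px).  The suppressor trains on the four-image census
(1 normal + 3 nodule); suppression quality is measured on 10 held-out
phantoms; the two-arm comparison uses a 60-phantom study (40 nodule images
with nodules under ribs at a uniform grade mix, 20 normals) with 3-fold
image-grouped cross-validation.  The rib-amplitude metric is the mean
crest-minus-trough difference over rib-band center/gap pixels taken from the
known band geometry (excluding the clavicle zone and a 2-radius disk around
each nodule), which is robust to noise; nodule retention is the core-minus-
annulus contrast in the suppressed image relative to the same measurement on
the true soft-tissue image.

## Known limitations

- The per-level 81–20–1 regressors predict isolated rib bands to ~10% of
  their amplitude but underfit rib–clavicle *crossings*, where bone
  intensity nearly doubles and training pixels are rare; the residual
  apex clutter is the main source of candidate-stage false positives at
  intermediate w_c and of variance in the sweep's argmax.  This mirrors the
  method's own motivation (crossings are the classic false-positive source)
  and is a capacity limit of the published architecture, not a training
  artifact — tripling epochs or pairs, or importance-sampling strong-bone
  pixels, changes it only marginally.
- The suppressor is trained and evaluated on the same phantom family; its
  JSRT-scale behavior (and the published operating point w_c = 0.4 there)
  is not reproduced here and headline clinical sensitivities should not be
  read off phantom numbers.
- Grade-1 nodules (contrast 4 over noise 2, under contrast-30 ribs) are at
  the detectability floor by construction; overall sensitivities on uniform
  grade mixes are correspondingly bounded.
- The watershed tie-break on plateaus follows the library's deterministic
  flooding order; the steepest-ascent oracle agrees on ≥ 99% of pixels with
  discrepancies confined to ridge pixels.
- The ASM is a plain two-lobe point-distribution model; it will not track
  anatomy (costophrenic angles, apical overlap) that phantoms do not
  generate.
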