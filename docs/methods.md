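# Methods

## The measurement model

A plate-halo assay image contains one dish, one or more dark colonies,
and around each colony a brighter cleared halo. Quantification works on
binary masks: the colony mask (class BAC) and the *total* halo mask
(class AS), defined as halo ∪ colony. The solubilization efficiency is

    Ef = (A + B) / A

with A the colony measure and B the total-region measure in the same
units, rounded half-up to two decimals. Two conventions circulate in the
field: A, B as diameters (manual calipers/rulers) and A, B as areas
(automated masks). Both are implemented as explicit modes (`diameter_cm`,
`area_px`, `area_cm2`) and neither is silently converted into the other:
the manual diameter readings and the automated area readings of the same
plate are treated as independent measurements, because a diameter pair
and a mask-area pair are not cross-derivable without a geometric model
the assay does not provide. With B the total region and halo ⊇ colony,
area-mode Ef = halo/colony + 1 ≥ 2; Ef is exactly invariant under any
common rescaling of A and B, which makes the px/cm² equivalence exact
rather than approximate.

Calibration truncates to an integer pixels-per-centimeter factor,
`floor(width_px / dish_cm)` (1746/11 → 158). Truncation, not rounding, is
the deliberate convention for this factor. Equivalent diameters are
`2·sqrt(area/π) / factor`.

Only the largest 8-connected component of each mask enters the
measurement: the assay reads one colony/halo pair per plate, and smaller
fragments are segmentation debris. An empty colony mask is a measurement
error, not a zero.

## Synthetic plates

The generator emulates standardized top-down plate photographs: a square
grayscale image (default 1746 px ≙ an 11 cm dish), background at 0.08,
agar disk at 0.55, halo disks at 0.85, colony disks at 0.25 (intensities
in [0, 1]). The ordering colony < agar < halo encodes that a halo is a
clearing in opaque medium and a colony is dense growth. Disk membership
uses the inclusive pixel-center rule (distance ≤ radius), the single
convention shared by synthesis, the test oracles, and quantification, so
a rasterized disk's pixel count is within 1% of πr² for r ≥ 20.

Ground truth is geometric and noiseless: colony masks, total halo masks
(always supersets of their colonies), the dish mask, and the true Ef of
each colony computed on the rasterized masks. A multiplicative linear
illumination ramp (total relative change ≤ 0.3 across the width) and
additive Gaussian pixel noise perturb the image only. Generation is a
pure function of the config including its seed; identical configs give
byte-identical images.

What the generator does not emulate: real colony texture and irregular
margins, condensation, reflections, diffuse halo edges, agar color
variation, multi-dish frames. Tests passing on these images therefore
demonstrate the correctness of the measurement and evaluation machinery
and the internal consistency of the pipeline — not segmentation
performance on laboratory photographs, which depends on a trained model
supplied externally.

Default synthetic study conditions: one colony per plate, colony radius
drawn uniformly from 45–85 px and halo radius 1.25–1.6× that (at 1746 px
scale; both scale linearly with image size), placed uniformly inside the
dish with no halo overlap. These give colony areas of order 10⁴ px and
Ef between ~2.5 and ~3.6, the regime of a clearly positive assay. The
intensity levels are plausible stand-ins chosen once; the source imagery
published no intensity statistics.

## Annotation formats and splitting

YOLO-seg lines are `class_id x1 y1 x2 y2 …` with coordinates normalized
by image width/height, class ids fixed at 0 = BAC, 1 = AS, written with
6-decimal formatting for stable diffs. Prediction files may carry an
optional confidence token after the class id; it is accepted on read and
emitted only when < 1, so label files stay in the plain dialect. COCO
polygon segmentations are normalized on read; RLE is rejected. All
readers reject coordinates outside [0, 1] after normalization.

The train/test split shuffles with a seeded RNG and assigns
`floor(n · fraction)` items to training (default 0.75). The floor rule is
a package decision — with the published 75/25 proportion and n divisible
by 4 it is exact, otherwise training gets the smaller remainder.

Mask → polygon conversion takes the longest 0.5-level contour
(sub-pixel, via marching squares) subsampled to ≤ 200 vertices;
re-rasterizing with the pixel-center-in-polygon rule recovers the source
mask at IoU ≥ 0.98 for disk-like regions. 200 vertices keeps label files
small while holding that roundtrip bound at full 1746 px resolution.

## Reference segmenter

A classical stand-in that makes the whole pipeline runnable and testable
without trained weights; it is not a reimplementation of any learned
model. Pipeline: (1) dish = largest bright connected region above the
global Otsu threshold, holes filled; rejected if below 5% of the image.
(2) Inside the dish, a three-class multi-level Otsu split yields a dark
threshold (colony) and a bright threshold (halo). (3) Morphological
opening + closing (disk radius 5 px at 1746 px scale, scaled linearly)
and small-object removal (400 px at 1746 px scale, scaled by area) clean
both masks. (4) The total AS region is the hole-filled union of bright
pixels with colonies; each connected colony is paired with the region
containing its centroid (falling back to the smallest overlapping
region), and the paired total region always contains its colony by
construction. Unpaired halo regions are logged and excluded. If only one
of the two pixel classes survives cleanup the result is empty: a genuine
plate shows both a dark colony and a bright clearing, and a lone class is
the forced three-way threshold slicing noise.

Confidences are fixed at 1.0 — thresholding has no probabilistic head —
so the confidence filter is only selective for imported predictions. The
filter keeps annotations with confidence ≥ threshold (inclusive boundary,
default 0.30), is idempotent and monotone.

On the synthetic conditions above the segmenter recovers colony area and
Ef within 5% on noiseless plates and per-class IoU ≥ 0.9 at noise
σ = 0.02 with a 5% illumination gradient (in practice ≥ 0.99); these are
the parameter-recovery bounds the test suite asserts.

## Evaluation protocol

Predictions and truths of one class are matched greedily one-to-one in
descending IoU; a pair at or above the threshold (default 0.5, the
standard instance-segmentation criterion) is a TP, leftover predictions
are FP and leftover truths FN. Object-level true negatives are not
derivable from masks — "background objects" have no natural count — so
the caller supplies `negative_units`, the number of evaluation units
containing no object of the class, and TN = max(0, negative_units − FP).

Reported metrics are truncated (floored) to two decimals, and F1 is the
harmonic mean of the *truncated* precision and recall, itself truncated.
Truncation and the truncated-input F1 are reporting conventions chosen to
match how such confusion-matrix reports are conventionally printed (e.g.
9/17 = 0.529 reported as 0.52); the raw ratios are a one-line computation
from the counts if needed. A tiny epsilon (1e-9) guards the floor against
float artifacts. The evaluation suite pins a small expected-discrepancy
list: published metric cells that are not arithmetically consistent with
their own published counts under any single convention are asserted to
*differ* from the count-derived values, so an accidental "fix" fails
loudly.

## Pipeline

`run_analysis` takes a YAML-configurable batch of plates — each an image
(segmented by the reference method or by imported predictions) or a
pre-computed mask pair — and produces a per-plate report with areas,
calibration, diameters, Ef, and, when a manual Ef is supplied, the
relative difference |auto − manual|/manual × 100. Per-plate failures are
recorded and the batch continues; an empty batch is an error. Reports are
deterministic for a fixed config (byte-identical CSV/JSON on re-run).
When multiple colonies are detected the per-class union is measured and
the largest-component rule selects the dominant pair; a warning notes the
multiplicity. `run_validation` tabulates automated vs manual pairs with
max/mean aggregates, excluding unpaired rows.

## Numerical choices and degenerate inputs

* Ef rounding: decimal half-up on the repr of the float ratio, avoiding
  both banker's rounding and binary-representation surprises.
* IoU of two empty masks is 0 with a warning (no overlap evidence).
* Metric denominators of zero raise an undefined-metric error rather
  than returning 0.
* Degenerate polygons (< 3 distinct vertices) and empty masks are
  skipped with warnings, never fatal.
* Zero-radius disks rasterize to exactly the center pixel (inclusive
  rule); negative radii are errors.

## Problem sizes

The test suite exercises plates at 512 px (geometry identical to full
scale up to the linear scaling of radii and morphology) plus a full
1746 px path in the CLI dataset round-trip; oracle comparisons
(per-pixel brute force, flood fill, repeated-argmax matching) run on
grids ≤ 100 px and scenes ≤ 4 objects per class, where exhaustive
computation is exact and fast. The whole suite runs in a few seconds.

## Known limitations

* The reference segmenter assumes one dish per image, roughly uniform
  illumination, and the colony < agar < halo intensity ordering; plates
  violating it (e.g. translucent colonies) need imported predictions.
* Overlapping halos from adjacent colonies are merged by the fill-based
  total-region construction; both colonies then pair with the same
  region, and area-based Ef for such pairs is not meaningful.
* Object-level TN, and hence accuracy, depends entirely on the
  caller-supplied negative-unit count; precision/recall/F1 do not.
* The synthetic generator's realism limits are listed above; no claim is
  made about performance on laboratory imagery.
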