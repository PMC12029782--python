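# igloo

Toolkit for quantifying phosphate solubilization on Petri-dish images:
segment bacterial colonies (class **BAC**) and their solubilization halos
(class **AS**, always the total halo ∪ colony region), measure mask areas,
calibrate pixels to centimeters, and compute the solubilization
efficiency. Written for microbiologists screening phosphate-solubilizing
bacteria with the plate-halo assay, and for anyone evaluating
instance-segmentation predictions of such plates.

## The quantity at the core

On opaque phosphate medium (e.g. NBRIP), a solubilizing colony clears a
halo around itself. The assay's headline number is the solubilization
efficiency (solubilization index)

```
Ef = (A + B) / A
```

where `A` is the colony measure and `B` the halo measure in the same
units — manual protocols use diameters in cm, automated segmentation uses
pixel areas of binary masks. `Ef` is dimensionless and exactly scale
invariant, so pixel areas and calibrated cm² areas give the identical
index. Pixel → cm calibration uses the integer factor
`floor(image width in px / dish diameter in cm)`; for a standardized
1746 px image of an 11 cm dish this is **158 px/cm**. Reported values are
rounded half-up to two decimals.

The package covers the full workflow:

* `igloo.plate_synth` — synthetic plate generator with exact geometric
  ground truth (disk colonies inside halo disks on an agar dish, optional
  illumination gradient and Gaussian noise).
* `igloo.annotations_io` — YOLO-seg polygon labels, COCO segmentation
  JSON, class-map YAML, seeded 75/25 dataset splits.
* `igloo.segmentation` — a classical reference segmenter (multi-level
  Otsu + morphology), import of external model predictions, the 30%
  confidence filter, polygon → mask rasterization.
* `igloo.quantify` — mask areas, calibration, equivalent diameters, `Ef`.
* `igloo.evaluate` — object-level IoU matching, confusion counts
  (TP/FP/FN/TN), precision/recall/F1/accuracy with two-decimal truncation
  reporting.
* `igloo.pipeline` + `igloo.cli` — the end-to-end `igloo` command.

## Worked example

Measure a colony/halo mask pair (any non-zero pixel counts as set):

```sh
igloo quantify --colony-mask colony.png --halo-mask halo.png \
    --width-px 1746 --dish-cm 11 --mode area_px
```

For masks whose areas are 13,329 px (colony) and 25,571 px (total halo
region) this prints:

```json
{
  "colony_area_px": 13329,
  "halo_area_px": 25571,
  "pixels_per_cm": 158,
  "colony_equiv_diameter_cm": 0.8245,
  "halo_equiv_diameter_cm": 1.142,
  "mode": "area_px",
  "Ef": 2.92
}
```

Ef = (13329 + 25571)/13329 = 2.9184…, reported as 2.92: the colony plus
its cleared zone occupy 2.92× the colony's own area — a strong
solubilizer. `pixels_per_cm` is the truncated 1746/11 calibration; the
equivalent diameters are those of circles with the same areas. Running
with `--mode area_cm2` produces the identical Ef, as scale invariance
demands.

Other verbs: `igloo synth` (generate labeled synthetic plates),
`igloo split` (seeded train/test split), `igloo segment` (reference
segmentation or prediction import), `igloo eval` (confusion-matrix
metrics against ground-truth labels), `igloo analyze` (YAML-configured
batch analysis), `igloo validate` (automated vs manual Ef comparison).

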