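# Methods

This note records the models, conventions and design choices behind
`octlayers`, in the order the pipeline runs them: phantom generation → crop
partitioning → segmentation backends → fusion and boundary extraction →
evaluation.

## Phantom model

The phantom generator emulates the *geometry* of annotated macular OCT
B-scans, not the optics of the instrument. Each phantom is built bottom-up
from per-region thickness profiles:

1. The deepest boundary (RPE or CSI) is a smooth curve: the stack's vertical
   centre plus a global curvature term (three random-phase cosine harmonics,
   amplitude `2 × boundary_waviness`).
2. Each region k has thickness `t_k(c) = mean_k + wobble_k(c) −
   depth · w_k · G(c)`, clipped at zero, where `G` is a Gaussian foveal pit
   profile (centre column, FWHM = `fovea_width`) and `w_k` distributes the
   pit depth over the inner regions. Boundaries are cumulative sums of
   thicknesses, so the top-to-bottom ordering holds by construction;
   clipping at zero lets inner layers *vanish* at the fovea (tangent
   boundaries), the layer drop-out that makes foveal columns genuinely
   undefined for per-layer boundary extraction.
3. Regions are filled with fixed mean reflectances (adjacent regions and the
   background differ by ≥ 0.1) and multiplied by gamma-distributed speckle
   with mean 1 and standard deviation `speckle_level`.

One `numpy` Generator seeded per phantom drives every draw; no global state,
and fixed seeds reproduce bit-identical images and traces on any platform.

Default study conditions (chosen once as plausible for macular B-scans in
which the retina fills roughly half of a 512-px frame; not calibrated to any
particular population):

| parameter | retinal7 | choroid3 |
|---|---|---|
| image size | 1534 × 512 px | 1534 × 512 px |
| mean layer thicknesses | 35, 55, 45, 50, 28, 38 px | 250, 120 px |
| foveal pit depth / FWHM | 120 / 180 px | 60 / 200 px |
| pit weights (inner regions) | 0.35, 0.30, 0.20, 0.15 | 1.0 |
| boundary waviness | 3 px | 3 px |
| speckle sd | 0.25 | 0.25 |

With these defaults the per-layer bounding-box ratio modes on 512-px crops
fall in the 4–16 band characteristic of real layer masks (checked by test).

What the phantom does **not** model: vessel shadows, pathology (drusen,
fluid), instrument artifacts, depth-dependent signal decay, realistic
speckle correlation. Tests passing on phantoms therefore validate the
*apparatus* — cropping, fusion, selection, extraction, metrics — not the
hard perception problem a trained network solves on real data.

## Rasterization and the half-pixel question

Boundary traces are real-valued row positions per column (row 0 = top).
Rasterizing region k assigns pixel row `r` the label k iff
`snap(t_k) ≤ r < snap(t_{k+1})`, where `snap` rounds to the nearest pixel row
(ties upward). Integer traces therefore rasterize exactly half-open
(`t_k ≤ r < t_{k+1}`; traces 10 and 20 give rows 10…19), and a real trace is
never more than half a pixel from the mask edge it produces — which is what
makes the round-trip guarantees below achievable at all. A ceil-style
assignment (`label k iff t_k ≤ r`) was rejected because its one-sided
rounding makes the best possible extraction error approach a full pixel.

Extraction reads traces back off column-contiguous masks:

* **edge-unbiased** (default): internal boundary `(last_upper + first_lower
  + 1)/2`; top trace = first labeled row; bottom trace = last labeled row
  + 1. Recovers integer ground truth exactly, real-valued ground truth
  within 0.5 px per column.
* **raw midpoint**: `(last_upper + first_lower)/2`, outer traces shifted by
  the same half pixel. On integer ground truth every boundary lands exactly
  0.5 px shallow (mean signed error −0.5 px) — the bias inherent in
  averaging pixel *indices* rather than pixel *edges*, and the scale of the
  ±0.5 px systematic offsets typical of direct mask-based boundary readers.

Both conventions are exposed because published mask-to-boundary procedures
rarely state which one they use; the defaults here are edge-unbiased.
Columns where a needed layer is absent (vanished foveal layers, dropped
detections) yield NaN traces; a linear-interpolation flag exists for
visualization only and is never used in evaluation.

## Crop partitioning and fusion

`specific_crop(W, C)` emits offsets `0, C/2, C, …` while `offset + C ≤ W`,
then one clamped offset `W − C` if the last multiple stops short — the rule
is the minimal generalization that reproduces the nominal
(1534, 512) → (0, 256, 512, 768, 1022) layout, including its final 49.6%
overlap, while staying valid for any `C ≤ W`. Roles alternate main /
auxiliary starting with main; with an odd window count (the nominal case)
the sequence also ends with main.

Fusion assigns every full-image column the column of the covering *main*
crop with the nearest centre (nearest covering crop of any role if no main
covers it, which can happen for even window counts). Then, for each column,
if the chosen base misses a layer class that an overlapping auxiliary crop
detected there — the incomplete-segmentation failure mode at crop borders —
the auxiliary's whole column replaces it (nearest auxiliary first). Where
both crops disagree with non-background labels, the main simply wins; the
auxiliary only repairs *absence*. The fused map is re-checked for per-column
contiguity and layer ordering, and each column records which crop supplied
it. Supplying the crop/label-map pairs in a different order cannot change
the result (windows are kept sorted by offset; ties in centre distance break
toward the lower offset).

## Segmentation backends and instance selection

The segmenter is a contract: `segment(crop_image, window) → InstanceSet`,
each instance carrying a roster class name, a score in [0, 1] and a
non-empty binary mask inside the crop; sets are truncated to 200 instances
by score, echoing the usual cap on regions of interest fed to a mask head.
The oracle backend returns the rasterized ground truth (score 1.0); the
perturbed oracle degrades it deterministically per (seed, crop offset):
vertical shift, square-element dilation, per-class drop-out, and duplicates
hoisted to the top of the crop to violate the anatomical order. Scores fall
with perturbation strength (duplicates at 0.6×), so score-based tie-breaks
stay meaningful.

When a class is detected more than once, selection walks the roster top to
bottom and keeps, per class, the candidate whose mean foreground row does
not lie above the previously selected class's mean row; ties break by score,
then area. The previously-selected anchor only advances when the chosen
candidate was itself consistent, so one bad class cannot poison the rest.
The rule is deliberately greedy — the idea it formalizes ("pick the instance
in the anatomically correct position") admits many algorithms, and the
greedy mean-row version is transparent, idempotent and sufficient to reject
every order-violating duplicate the perturbed oracle can produce.

## Rotation augmentation

Training-style augmentation rotates image and annotation about the image
centre, angles limited to ±10°. Annotations are rotated as rasterized label
maps (boundary traces are not closed under rotation near steep boundaries):
nearest-neighbour lookup by default, or per-class signed-distance-field
interpolation (`mask_method="distance"`) when sub-pixel edge fidelity
matters. Pixels rotating in from outside the frame are background; content
rotating *out* of the frame is lost by construction, so a +a/−a round trip
is only an identity away from the frame edges (per-layer Dice ≥ 99% on the
interior; measured ≥ 99.7% for both methods on default phantoms with a
55-px margin).

## Evaluation protocol

All metrics run over the central columns only: by default 100 px excluded
at the left edge (low-contrast region) and 300 px at the right (optic nerve
head), leaving exactly 1134 of 1534 columns. The margins are absolute
pixels tied to the nominal geometry; `EvalConfig.scaled(width)` shrinks them
proportionally for other widths.

* Dice is reported per layer and twice overall: union-of-layers vs
  union-of-layers, and the plain per-layer mean — an "overall" column admits
  either reading, so both are available. Two empty masks score 100:
  agreeing that a foveal layer vanished is a correct prediction.
* Boundary errors average predicted − true row over columns where both
  traces are defined (counts reported); positive = predicted deeper. A
  boundary with no evaluable column is NaN and excluded from across-boundary
  averages; only a report with *no* evaluable boundary at all is an error.
* Pixel metrics are one-vs-rest per class with macro (mean of per-class
  percentages, undefined excluded) and micro (pooled counts) averages, since
  single-number summaries are quoted both ways in the literature.
* Run aggregation uses the sample (n−1) standard deviation.

## Graph-search comparator

The comparator used by probability-map pipelines is plain dynamic
programming: one row per column, `|Δrow| ≤ smoothness`, minimum total cost,
ties broken toward the lowest row both at the final column and for
predecessors (candidates are scanned in ascending row order, so the first
minimum wins). It operates on caller-supplied cost maps; `gradient_cost`
builds one from the vertical intensity gradient as a convenience. The
implementation is verified against exhaustive path enumeration on random
maps up to 6×6.

## Problem sizes used in the shipped checks

The test suite exercises a miniature geometry (192×64 images, 64-px crops —
the same five-window main/aux structure as the nominal layout) for module
tests, and the full 1534×512 geometry for the acceptance suite: ten phantoms
for the end-to-end identity, five shift levels and three dilation levels for
perturbation recovery, and 500 random cost maps for the graph-search
equivalence. `scripts/acceptance.py` re-runs those same computations from a
user-supplied seed.

## Known limitations

* No neural backend is shipped; the contract accepts one, but training and
  inference of an actual region-proposal network are out of scope.
* The anchor-proposal heuristic (quantile-coverage doubling chain) is a
  documented default, not a claim about optimal anchor selection; the
  mapping from mask-ratio statistics to the anchor list of a multi-scale
  feature pyramid is architecture-dependent.
* Phantom realism is structural only (see above); absolute metric values on
  phantoms say nothing about performance on real scans.
* Fusion repairs missing classes per column; it cannot repair a class that
  is wrong in *both* the main and auxiliary crop, nor does it smooth the
  pixelated boundaries a real network produces near the foveal pit — no
  curve regularization is applied anywhere.
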