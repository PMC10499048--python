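# Methods

## Model and procedure

The package studies a data-side refinement mechanism for leaf instance
segmentation. Given an image `f` and a set of annotated instance masks,
each instance region is filtered in place with one of two spatial filters
and composited back strictly inside its mask:

* **Gaussian low-pass (GLPF).** Convolution with the sampled Gaussian
  `w(x, y) ∝ exp(−(x² + y²)/2σ²)` on the integer offset grid, normalized
  to unit sum (normalization subsumes the continuous `1/2πσ²` constant).
  Implemented separably (two 1-D passes), which equals dense 2-D
  convolution to ≤1e-6 before quantization.
* **High-boost (HBF).** `f_HB = (A − 1)·f + f_hp` with `A ≥ 1`. The
  high-pass component is taken as the unsharp mask `f_hp = f − GLPF(f)`
  with the *same* kernel size and σ as the HBF's stated kernel, so the
  single "kernel size" knob stays meaningful; algebraically
  `f_HB = A·f − GLPF(f)`.

Refinement procedure per instance: crop the mask's bounding box padded by
the kernel radius (clamped to image bounds), filter the crop, write
filtered values back at mask pixels only. The contract is defined by this
procedure; away from the image border it coincides with whole-image
filtering restricted to the mask. Instances are processed in ascending
annotation-id order, so overlapping regions are filtered repeatedly and
deterministically; disjoint instances commute. The stacked GLPF→HBF
configuration runs as two consecutive local passes on the same region
(composite between stages), so the HBF stage sees the blurred composite —
matching sequential application of the two filters to the same areas.

Scenario construction: `TRAIN_REPLACE` and `TEST_REFINE` swap every image
for its refined version and never touch annotation geometry (filtering
moves no pixels); `TRAIN_COMBINE` appends refined copies under fresh
image/annotation ids, exactly doubling both counts.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `kernel_size` | filter support, pixels (odd) | 3 | smallest non-trivial kernel; sweeps use 5/7/9/15 |
| `sigma` | Gaussian std dev, pixels | `0.3·((k−1)/2 − 1) + 0.8` | widely used size→σ convention; results depend on it, so it is explicit and overridable |
| `A` | high-boost amplification | 2 | the classic unsharp-masking midpoint of the high-boost family |
| boundary | crop/image-edge handling | mirror (edge pixel not repeated) | avoids dark halos at crop borders |
| arithmetic | internal precision | float64, round half-to-even, clip to [0, 255] | deterministic quantization; channels independent |

Evaluation uses the implicit COCO conventions: IoU thresholds
0.50:0.05:0.95, 101-recall-point interpolation, at most 100 detections
per image, single category (so mAP equals the leaf AP), APs on the 0–100
scale. Matching ties are broken by prediction order at equal scores and
lowest ground-truth index at equal IoU. The predicted-mask count uses a
0.5 score threshold by default. The count "change rate" is defined as
`(count_filtered − count_baseline)/count_baseline`, averaged arithmetically
over a kernel-size series; the definition is isolated in one function so
it can be swapped.

## Synthetic scenes

The generator emulates the structural properties of real greenhouse leaf
datasets — variation in leaf size and appearance, partial occlusion
between instances, locally defocused regions, cluttered backgrounds —
without photorealism. Leaves are lobed ellipses (radius modulated by a
low-order radial harmonic, 64-vertex polygons), layered so later leaves
occlude earlier ones; annotations store each leaf's *visible* region.
Segmentations are written as uncompressed column-major run-length masks,
making the ledger's per-leaf areas exact by construction (a polygonized
boundary would reintroduce up to half-pixel error on thin occluded
slivers); polygon segmentations remain first-class citizens of the I/O
and augmentation layers. Defaults, chosen once for desk scale: 160×160
scenes, 4–10 leaves with semi-major axis 7–18 px, occlusion probability
0.3, blur fraction 0.2, cluttered background. Blurred leaves receive a
local 5×5, σ=1.5 GLPF at generation time. All randomness flows through
one PCG64 generator per call, so outputs are byte-reproducible per seed
across platforms.

What the generator does **not** emulate: real leaf texture, venation and
color distributions, lighting and shadows, perspective, annotation noise,
and the correlations between them. Passing tests therefore demonstrate
the correctness and directional behavior of the mechanism and the
metrics, not field performance of any trained model.

The mock predictor perturbs ground truth with instance drops, mask
translation, erosion/dilation, spurious ellipse instances, and score
noise. In blur-aware mode it is deterministic in the image content: an
instance is emitted only if the mean gradient magnitude inside its mask
reaches the sharpness threshold (default 4.0, the lower-mid range of the
unblurred-leaf sharpness distribution, whose median is ≈5), and its mask
is eroded in proportion to the sharpness deficit. This gate makes the
predicted-mask count respond monotonically to test-data blurring and
sharpening — the qualitative behavior of a detector facing defocused
instances — without training a model.

## Numerical and design choices

* Pixel conventions, stated once and used everywhere: 0-based
  coordinates, origin top-left, boxes `[x, y, w, h]` half-open; a pixel
  belongs to a polygon iff its center is inside under the even-odd rule.
* Mask-shaped (not box-shaped) compositing, so background pixels are
  provably untouched; the locality suite checks bit-identity outside the
  mask union.
* Filtering under the mask uses the original pixels inside the padded
  crop, including occluded-neighbor pixels; no inpainting.
* IoU of two empty masks is an error, not 0; AP with zero ground truths
  is an error rather than a silent 0 or 100.
* Augmentation geometry: horizontal flip maps polygon x → W − x (pixel
  centers c → W−1−c); rotation keeps the canvas size, resamples images
  bilinearly with mirror fill and masks by nearest neighbor, and rotates
  polygon vertices about the image center; transformed-polygon vs
  transformed-raster agreement is held to a 1-pixel boundary band (≤5%
  of union area). "Pixel loss" and "pixel dropout" are the same
  operation (random pixels set to 0). Default magnitudes (brightness and
  contrast ±25%, dropout ≤2%, rotation ±15°) are package defaults, not
  literature values.
* The evaluator was cross-checked against an independent loop-based
  reference implementation of the COCO accumulation procedure
  (`tests/reference_ap.py`); the acceptance suite holds agreement to
  0.1 AP over 200 random scenes and exact agreement with brute-force
  precision–recall enumeration on ≤5-instance scenes.

## Problem sizes

Test-suite and acceptance-script workloads use 40–200 scenes of 80–160 px
per side with 2–10 instances each; these sizes were chosen as the
package's standard desk-scale study conditions and are stated in the
relevant configs.

## Known limitations

* The refinement contract is procedural (padded-crop filtering); near
  image borders it differs from whole-image filtering by the boundary
  reflection of the crop.
* `TRAIN_*` scenarios require in-memory pixel data; lazily streaming very
  large datasets is out of scope.
* The AP engine implements the single-category, all-areas, 100-detection
  COCO slice only (no small/medium/large breakdown, no crowd handling —
  crowd flags are treated as ordinary instances for this single-class
  problem).
* Rotation of run-length masks is nearest-neighbor and loses sub-pixel
  boundary detail; polygon annotations avoid this.
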