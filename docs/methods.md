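# Methods

## Synthetic brightfield scenes

The generator emulates transmitted-light imaging of spheroids in
microwell plates. Each scene starts from a bright background at 0.75 of
dynamic range, tilted by an illumination-gradient plane (fractional
change per image width/height, default up to ±10% in the `default`
profile). Objects are painted darker than the local background
(interior at 0.55× background), surrounded by a 3-px bright halo ring at
1.1× background — the characteristic rim of a dense aggregate slightly
above the focal plane. Defocus is modelled per object as a Gaussian blur
of the object's intensity delta; Gaussian sensor noise is added last,
after blur, from a single generator seeded per scene, so identical scene
specifications render bit-identical output.

Object boundaries follow a truncated Fourier radial model
`r(θ) = R·(1 + Σ a_k cos(kθ + φ_k))` with harmonic orders k ≥ 2,
amplitudes below 0.3 and summed amplitude below 0.5. This keeps every
contour smooth, simple and star-shaped around the centre while giving
direct control over circularity; zero amplitudes give exact digital
disks, used for parameter-recovery checks. Object masks are defined by
the pixel-centre-inside-curve rule, so ground truth is exact by
construction. Scenes reject overlapping objects: spheroids settle
individually in wells and the downstream matching assumes
non-overlapping instances.

Three artifact classes reproduce the classical-pipeline failure cases:

- **air bubble** — a dark refractive ring around a brighter lumen, with
  an angular gap in the rim (bubbles lit off-axis have broken dark rims;
  the gap also means hole-filling cannot convert the ring into a solid,
  high-solidity disk, preserving its ring-like signature),
- **plate border** — a dark arc band from a large circle centred outside
  the frame, the shadow of a curved well wall,
- **plastic defect** — a thin bent dark crack, two joined 2-px segments.

All three are deliberately non-convex, so a solidity filter separates
them from genuine spheroids. Artifacts perturb only the image, never the
label mask.

### Difficulty profiles

Scenes are 512×512 px at 2.0 µm/px, so the 200–250 µm spheroid diameter
range maps to radii of 50–62.5 px. The camera pixel size of the original
instrument class is not standardised, so 2 µm/px was chosen as a typical
stereomicroscope value; it is a parameter everywhere.

| profile | objects | irregularity | defocus σ | noise σ | artifacts |
|---|---|---|---|---|---|
| clean | 1–4 | none | 0 | 0 | none |
| default | 1–4 | ≤3 harmonics, a ≤ 0.08 | 0–2 px | 0.02 | 20% of scenes |
| artifact | 1–3 | ≤3 harmonics, a ≤ 0.08 | 0–2 px | 0.02 | every scene, 1–2 |

Per-image seeds are spawned from the set seed, so each image is
reproducible independently of how many images are requested.

The generator emulates geometry, intensity polarity, halos, defocus,
uneven illumination, noise and the artifact classes. It does **not**
emulate textured spheroid interiors, necrotic-core contrast, medium
meniscus vignetting, debris fields, or genuinely touching/overlapping
objects. Tests passing on these scenes therefore validate the pipeline
mechanics and the metric definitions, not performance on real
microscope data.

`sample_feature_population` additionally draws morphometric records
directly (area normal around 25 000 µm² with SD 4 000, circularity
normal around 0.84 with SD 0.03, matching the reported spread of picked
batches) for studying selection policies at population scale without
rendering images.

## Segmentation

Both classical pipelines take the darker side of a global Otsu threshold
computed after Gaussian pre-smoothing (σ = 2 px, configurable — it
stabilises the threshold under noise), fill holes, and label 8-connected
components. The watershed variant additionally seeds a watershed on the
negated distance transform from distance-map maxima separated by at
least 10 px, splitting objects that thresholding merges. Shape filters
(area bounds, minimum solidity, minimum circularity) remove debris and
artifacts; defaults are fully permissive and the filter step is
idempotent. Foreground polarity is fixed to dark-on-bright with an
`invert` flag.

The resize-to-1024 preprocessing scales the longer side to exactly
1024 px (bilinear, anti-aliased when downscaling), anchors content at
the top-left and zero-pads right/bottom; the transform records scale and
padding so predicted masks can be mapped back with nearest-neighbour
interpolation, preserving label identity. Top-left anchoring was chosen
for invertibility simplicity. The pixel size is rescaled by 1/scale.

Learned backends (e.g. a Mask R-CNN service) attach through a registry
keyed by name; outputs are validated for shape and label integrity.
Training such models is outside this package's scope.

## Morphometrics

Circularity is `4πA/P²` clamped at 1; the perimeter is the Crofton
estimator (4 directions). A boundary-pixel-count perimeter overestimates
P for smooth shapes and would push true circles to circularity ≈ 0.8,
destroying the meaning of thresholds like 0.815; with Crofton, digital
disks of radius ≥ 10 px score ≥ 0.97. Volume is reported as the
sphere-equivalent `(π/6)d_eq³` and flagged `sphere_equivalent` — exact
3D volume is not recoverable from a single projection. Areas are pixel
counts times the squared pixel size; the default pixel size is 1.0 µm/px
and must be stated explicitly in the CLI.

## Selection

Interval bounds are inclusive. Rejection reasons report the first failed
criterion in a fixed feature order (area, circularity, then the rest
alphabetically) so logs are reproducible. Preferred-value ranking sorts
by absolute distance with ties broken by ascending label; the default
order without a preferred value is input (scan) order. Batch summaries
use the sample standard deviation (n−1); a single-record set reports
SD 0. SD ratios are reported to three decimals.

## Evaluation

Matching is an optimal one-to-one assignment (Hungarian algorithm) on
the IoU matrix restricted to pairs with IoU ≥ τ, maximising total IoU;
an exhaustive-search oracle over all one-to-one assignments verifies it
on small layouts. Greedy matching can differ on crossed overlaps, which
is why the optimal assignment was chosen and verified. The default
threshold grid is 0.50–0.95 in steps of 0.05. Pooled (micro) aggregation
— summing counts across images per threshold before scoring — is the
default; per-image macro averages are also computed, with images lacking
ground-truth objects excluded from the sensitivity average and scored 1
by convention for detection quality when nothing was predicted.

## Instrument layer

Plate constants default to ANSI/SLAS geometry (96-well pitch 9 mm with
A1 at (14.38, 11.24) mm; 384-well pitch 4.5 mm; 24-well pitch 19.3 mm),
overridable per layout. Image-to-stage calibration stores the pixel
where the capillary tip appears, the µm/px scale and per-axis signs;
pixel columns map to stage x and rows to stage y. Scan plans tile each
well's bounding square with a serpentine grid stepped by fov·(1−overlap)
— serpentine order minimises stage travel.

Transfer plans follow a fixed per-spheroid sequence (stage centres the
object under the tip → pipette over the work position → descend to the
minimum safe height → aspirate → ascend → stage moves the target well in
→ descend → dispense → ascend), ending with a pipette retraction out of
the field of view. Aspiration volume defaults to 3.5 µl, the midpoint of
the 3–4 µl working band, and is validated against those bounds; the
syringe's 3 µl resolution is recorded as metadata, not enforced. Plan
validation asserts that the pipette is never commanded below the minimum
safe height and that every aspirate/dispense happens at a valid height
with aspirates and dispenses strictly alternating per spheroid.

G-code emission targets the Marlin dialect: pipette X/Z as `G1` moves,
the syringe as relative extruder moves with negative E = intake, and a
`G28`/`G90`/`M83` header. The microscope stage rides a separate
controller, so stage motions are emitted as structured `;STAGE` comments
rather than an invented serial protocol. Success rates round half up to
the nearest integer percent (25/28 → 89).

## Dataset bookkeeping

Splitting is per image — objects inherit their image's split — with a
seeded shuffle followed by contiguous assignment sized by
largest-remainder rounding of the 70/15/15 default fractions, so small
datasets still use every image (10 images → 7/2/1). The pipeline runner
validates its config schema before doing any work and writes a JSON-lines
run log with seeds and parameters.

## Problem sizes and numerical choices

The test suite and the acceptance script run entirely on synthetic data:
50 clean images for parameter recovery, 20 clean plus 15 artifact-laden
images for pipeline behaviour, 200 random ≤5-object layouts for matcher
validation, and a 400-record population (42-record comparison batches,
the size of the reported picking experiments) for the selection-policy
comparison — sizes at which the exhaustive oracles remain tractable and
the statistical properties are already stable across seeds. Determinism
relies on `numpy.random.Generator` seeded per scene and per stage;
floating-point comparisons in tests use relative tolerances of 1–2% for
discretisation-limited geometry and exact equality for counting
quantities.

## Known limitations

- Synthetic realism is deliberately limited (see above); absolute scores
  on these scenes overstate performance on real brightfield data.
- Classical pipelines here are baselines; no learned model ships with
  the package, only the plugin contract.
- Volume is a sphere-equivalent estimate from one projection.
- The expert-selection comparison uses a simulated acceptance window
  (±25% of the target area), not recorded human decisions, so the
  resulting SD ratio is directional rather than a reproduction of any
  particular measured batch.
- The virtual instrument emits commands but does not simulate mechanics,
  fluidics or failure probabilities; transfer logs are inputs.
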