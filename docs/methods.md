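# Methods

## Stain model

Brightfield stains mix multiplicatively in transmitted intensity, so all
color arithmetic happens in optical density, OD = −log₁₀((I+1)/(I₀+1)) per
channel with I₀ = 255; the +1 offset keeps OD finite at I = 0 (maximum
≈ 2.408). A `StainVectorSet` is a 3×3 matrix of unit-norm OD directions,
defaulting to the Ruifrok–Johnston triplets for hematoxylin, eosin and DAB
(the de-facto community convention); deconvolution projects pixel OD
through the matrix inverse and clips small negative unmixing noise at
zero. Remixing nonnegative concentrations and unmixing them again is exact
to numerical precision, which the tests assert at 1e-6.

## Synthetic slide pairs

The generator emulates two serial sections of the same tissue:

- **Placement.** `n_nuclei` centroids are dart-thrown inside the tumor
  polygons (the whole slide when none are given) and `n_background_nuclei`
  outside them, with a minimum separation of one maximum nucleus diameter
  plus 2 px so nuclei are well separated and countable. Annotated regions
  therefore carry a denser nuclear texture than background — the cue the
  patch classifier learns. Dart throwing saturates near the random
  sequential adsorption limit (~55% disk coverage); requests beyond it
  raise a placement error rather than degrade silently.
- **Rendering.** Nuclei are mildly rotated ellipses with radii drawn
  U[4, 7] px — enough size/eccentricity spread to exercise morphology
  features without claiming biological realism. On HE, every nucleus takes
  hematoxylin (concentration 0.8) over an eosin cytoplasmic halo (0.25,
  nucleus radius + 3 px); on IHC, Ki-67-positive nuclei take DAB (0.9) and
  negative nuclei hematoxylin counterstain only (0.35). Pixels are
  synthesized through the stain matrix with additive Gaussian OD noise
  (default sd 0.02, a free parameter chosen to visibly perturb OD-scale
  features while leaving nuclei clearly resolvable).
- **Geometry.** IHC nucleus positions are the HE positions mapped through
  a configurable true rigid transform plus independent Gaussian jitter
  (sd 0.5 px) emulating section-to-section tissue shift.
- **Labels.** Every nucleus draws its Ki-67 label Bernoulli(p)
  independently, so a fraction of 1 labels every nucleus positive
  regardless of the polygon layout, and the realized in-tumor fraction
  matches p within binomial error.
- **Determinism.** One seed spawns independent child generators for
  placement, labels, shapes, jitter and noise, so identical specs render
  bit-identical pairs.

What the generator does **not** emulate: tissue texture, chromatin
structure, overlapping/clustered nuclei beyond incidental jitter contact,
stain gradients, out-of-focus or scanner artifacts, and DCIS-vs-IDC
morphology. Passing recovery tests therefore demonstrates correctness of
the pipeline mechanics (geometry, unmixing, counting, pooling), not
performance on clinical slides.

## Tiling and the patch dataset

Patches are size×size squares on a stride grid (default stride = size,
i.e. non-overlapping; partial border patches are dropped rather than
padded to avoid fabricated pixels). A patch is tumor-positive when the
mask covers ≥ 50% of its footprint — a symmetric default since annotation
boundaries give no natural choice. Sampling caps each class **per slide**
(default 2000) before pooling, and splits are assigned per slide by
shuffled largest-remainder apportionment so no slide straddles splits.
Patches straddling an annotation boundary are intrinsically ambiguous;
the recovery tests align tumor rectangles to the patch grid so held-out
accuracy reflects the classifier, not label noise.

## Region classifier

The patch model is deliberately an interface (`score_patches` over feature
matrices); the reference implementation is a 100-tree random forest over a
documented 37-feature vector: 8-bin RGB histograms, stain-concentration
statistics in OD space, Sobel gradient-magnitude statistics of luminance,
and a nuclear-density proxy (count of smoothed nuclear-signal blobs above
0.15 OD concentration with ≥ 12 px area). Heatmap cells map 1:1 to tile
origins; `heatmap_to_mask` paints footprints with probability ≥ threshold
(default 0.5) and combines overlapping footprints by maximum, so raising
the threshold can never grow the mask. No morphological post-processing is
applied by default. Training touches only the train split; the test split
stays blind until evaluation.

## Registration

Similarity is ZNCC of luminance (0.2125 R + 0.7154 G + 0.0721 B):
stain colors differ across modalities but structure correlates in
luminance. The rigid transform is rotation about the image center plus
translation in (row, col); search runs an exhaustive coarse stage
(angle ±15° step 1°, integer shifts up to ±25 px, on 4× downsampled
images) followed by Nelder-Mead refinement of (angle, dr, dc) at full
resolution, with out-of-overlap pixels excluded from the correlation
support. Quality maps ZNCC to [0, 1] as max(ZNCC, 0): positively
correlated tissue keeps its numeric correlation value and anti-correlation
carries no registration merit. Low quality (< 0.2) is flagged, not raised
— dissimilar serial sections can still register their core areas. Images
resample bilinearly, masks nearest-neighbour. Deformable refinement is
deliberately out of scope: slight regional misalignment has little effect
on a count-pooled index, and rigid-only keeps the search testable.

## Cell scoring

The nuclear signal is hematoxylin + DAB concentration, smoothed with a
Gaussian (σ = 2 px). The foreground threshold is the **lowest cut of a
three-class multi-Otsu** (falling back to two-class Otsu when the
histogram cannot support three classes): the signal is typically trimodal
— background, weak counterstain, strong DAB — and a two-class Otsu on a
DAB-dominated slide would cut between the nucleus classes and silently
drop negatives, biasing the index upward. Touching nuclei split by a
distance-transform watershed seeded at distance maxima ≥ 8 px apart (one
seed per elongated nucleus, separate seeds for touching pairs); components
outside [30, 2000] px² are discarded. Features per nucleus: area,
perimeter, eccentricity, mean hematoxylin and DAB concentrations. The
classifier is a seeded 100-tree random forest thresholded at probability
0.5 — never a raw intensity cut, since staining intensity is irrelevant to
the index. ROIs are explicit masks or auto grid squares (256 px) holding
≥ 100 detected cells; per-ROI and slide counts are pooled by counts
(Σpos/Σtotal), never by averaging per-ROI percentages. All reported
percentages round half-up to 2 decimals; internal values are never
rounded. Whole-mask average scoring is the default; hot-spot scoring is a
caller decision via explicit ROI masks.

## Metric suite

All twelve indicators derive from (sensitivity, specificity) plus
prevalence-dependent terms from the confusion counts. Identities (Youden =
sens + spec − 1, etc.) hold exactly; PLR at specificity 1 yields an
infinity sentinel with a warning, undefined PPV/NPV yield NaN. Note that a
published PLR of 17.84 alongside sensitivity 0.8505 and specificity 0.9523
recomputes to 17.83 from those rounded rates; the suite reports values
computed from its actual inputs rather than matching such printed
roundings. AUC is the Mann–Whitney rank statistic (average ranks, ties
count half), identical to trapezoidal ROC area; tests verify it against
exhaustive pair counting on all small inputs and against an independent
library implementation.

## Pipeline and reproducibility

`run_pipeline` chains identify → register → migrate → score, accepting
either an explicit IDC annotation or a trained region model, and fails
validation before any computation when neither is supplied. One top-level
seed derives per-stage seeds via a seed sequence; every stage logs one
structured line with input hashes, and prediction never reads gold labels.
Reports are JSON with sorted keys, so identical config + seed reproduces
byte-identical files.

## Problem sizes

Tests and examples run at desk scale by choice: 320–1024 px slides,
100–2000 nuclei, 64-px patches on 384-px training slides. The end-to-end
recovery experiments use 2000 tumor nuclei per slide at fractions
0.1/0.3/0.7, and registration recovery uses 20 seeded pairs spanning
±10° and ±20 px. Real whole-slide images (gigapixel pyramids) are out of
scope; callers export tiles or pyramid levels to PNG/TIFF first and choose
the resolution.

## Known limitations

- The patch classifier keys on nuclear density and stain statistics; it
  will not transfer to real tissue without retraining on real patches.
- Detection assumes mostly separated, roughly elliptical nuclei; heavy
  clustering would need stronger splitting than a distance watershed.
- Registration assumes a single rigid offset; strong local deformation
  lowers quality but is not corrected.
- Binomial label sampling means the realized ground-truth index differs
  from the nominal fraction by sampling error; recovery tests compare
  against tolerances wide enough to absorb it.
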