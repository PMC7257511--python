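# ki67score

Automated quantification of the **Ki-67 proliferation index** in breast
invasive ductal carcinoma (IDC) from paired histology images: a
hematoxylin–eosin (HE) section for morphology and its serial-section
Ki-67 immunohistochemistry (IHC) slide, where proliferating nuclei stain
brown with the DAB chromogen.

The package is written for digital-pathology researchers who need a fully
testable, desk-scale version of the standard three-stage workflow:

1. **IDC region identification** — slides are tiled into fixed-size patches
   (default 128 px), each patch is scored with a tumor probability by a
   pluggable classifier (the reference model is a random forest over
   explicit intensity/stain/texture/nuclear-density features), and the
   per-patch **heatmap** is thresholded into a pixel-resolution region mask.
2. **Rigid registration** — the HE image is registered onto the IHC image
   by maximizing zero-mean normalized cross-correlation (ZNCC) over
   rotation + translation; the IDC annotation is then migrated into the
   IHC frame. Registration quality is reported as max(ZNCC, 0) ∈ [0, 1];
   SSD and normalized mutual information are available as alternatives.
3. **Cell scoring** — nuclei are detected in the migrated IDC region by
   Beer–Lambert color deconvolution (OD = −log₁₀((I+1)/256), Ruifrok–
   Johnston H-DAB stain vectors), Gaussian smoothing, thresholding and a
   distance-transform watershed; a random forest on morphology + stain
   features labels each nucleus, and the index is

   Ki-67 index = 100 · positive / (positive + negative)

   over IDC-region cells, with count-weighted pooling across ROIs/slides,
   half-up rounding to 2 decimals, and an integer "standard score"
   interval (⌊index⌋, ⌊index⌋+1). Reports warn below 1000 scored cells and
   error below the accepted absolute minimum of 500.

A **synthetic slide-pair generator** renders elliptical nuclei through the
same stain model with a known rigid offset, per-nucleus jitter, OD noise
and full ground truth (mask, centroids, labels, transform), so every stage
is testable without slide data. A diagnostic **metric suite** (sensitivity,
specificity, Youden index, likelihood ratios, predictive values, ROC/AUC
as the Mann–Whitney rank statistic, …) evaluates region classifiers, and
`index_agreement` applies the 1-percentage-point agreement rule.

## Worked example

`examples/04_score_ki67.py` trains a cell classifier on one synthetic
slide, then scores an unseen pair whose sections are offset by 2° and
(6, −4) px:

```
cell classifier trained on 600 gold-labelled nuclei
registration quality: 0.819
scored 700 cells: 205 positive, 495 negative
Ki-67 index: 29.29%  (standard score 29 or 30)
ground truth: 29.29%
warning: slide total 700 below the recommended 1000 cells
```

The pipeline recovers the generating index exactly here: registration
aligns the serial sections to sub-pixel accuracy, detection finds all 700
tumor nuclei, and the classifier separates DAB-stained from
hematoxylin-only nuclei. The other examples demonstrate the generator,
the region heatmap, registration/migration, and the metric suite, e.g.

```
true  angle -5.00 deg, shift (+12.0, +7.0) px
found angle -4.99 deg, shift (+12.06, +7.06) px
registration quality (NCC in [0,1]): 0.822
```

A thin CLI mirrors the library (`ki67score simulate | tile | train-region |
predict-region | register | score | evaluate | run`); exit codes are
0 success / 2 validation error / 3 computation error.

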