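"""Full pipeline: identify (annotation) -> register -> migrate -> score.

Nuclei are detected in the migrated IDC region of the IHC image by stain
deconvolution + watershed, classified positive/negative by a random forest
on morphology and stain features, and pooled into the Ki-67 index.
"""

import numpy as np
from scipy.spatial import cKDTree

import ki67score as k
from ki67score.stains import HED_STAINS, deconvolve, rgb_to_od


def make_pair(n_nuclei, positive_fraction, seed, angle_deg=0.0, shift=(0, 0)):
    height = width = 640
    polygon = [[40, 40], [40, 599], [599, 599], [599, 40]]
    tf = k.RigidTransform(np.deg2rad(angle_deg), shift,
                          ((height - 1) / 2, (width - 1) / 2))
    spec = k.SyntheticSlideSpec(height=height, width=width, n_nuclei=n_nuclei,
                                positive_fraction=positive_fraction,
                                tumor_polygons=(polygon,), true_transform=tf,
                                seed=seed)
    return k.generate_slide_pair(spec)


# Train the cell classifier on a balanced slide with gold nucleus labels.
train_pair = make_pair(600, 0.5, seed=1)
records = k.detect_nuclei(deconvolve(rgb_to_od(train_pair.ihc_image), HED_STAINS))
truth = np.array([n.ihc_centroid for n in train_pair.nuclei])
_, nearest = cKDTree(truth).query(np.array([r.centroid for r in records]))
gold = [train_pair.nuclei[j].ki67_positive for j in nearest]
cell_model = k.train_cell_classifier(records, gold, seed=0)
print(f"cell classifier trained on {len(records)} gold-labelled nuclei")

# Score an unseen slide pair with a 2 degree / (6, -4) px section offset.
test_pair = make_pair(700, 0.3, seed=2, angle_deg=2.0, shift=(6.0, -4.0))
result = k.run_pipeline(k.PipelineConfig(seed=0), test_pair.he_image,
                        test_pair.ihc_image, idc_annotation=test_pair.tumor_mask,
                        cell_model=cell_model, outdir="scratch/example_score")
report = result["report"]

print(f"registration quality: {result['registration'].quality:.3f}")
print(f"scored {report.total} cells: {report.positive} positive, "
      f"{report.negative} negative")
print(f"Ki-67 index: {report.index:.2f}%  "
      f"(standard score {report.standard_score[0]} or {report.standard_score[1]})")
print(f"ground truth: {k.ground_truth_index(test_pair):.2f}%")
for w in report.warnings:
    print("warning:", w)
# The index is the percentage of IDC-region cells staining Ki-67 positive;
# a slide under 1000 cells is flagged, under 500 it errors by default.
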