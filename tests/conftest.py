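"""Shared fixtures: synthetic slide pairs and trained models.

Everything is generated at test time from fixed seeds; no data files.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial import cKDTree

import ki67score as k
from ki67score.stains import HED_STAINS, deconvolve, rgb_to_od


def make_pair(height=512, width=512, n_nuclei=300, n_background=0,
              positive_fraction=0.3, angle_deg=0.0, shift=(0.0, 0.0),
              seed=0, margin=40, **kwargs):
    """One synthetic HE/IHC pair with a rectangular tumor polygon."""
    poly = [[margin, margin], [margin, width - 1 - margin],
            [height - 1 - margin, width - 1 - margin], [height - 1 - margin, margin]]
    tf = k.RigidTransform(np.deg2rad(angle_deg), tuple(shift),
                          ((height - 1) / 2.0, (width - 1) / 2.0))
    spec = k.SyntheticSlideSpec(
        height=height, width=width, n_nuclei=n_nuclei,
        n_background_nuclei=n_background, positive_fraction=positive_fraction,
        tumor_polygons=(poly,), true_transform=tf, seed=seed, **kwargs)
    return k.generate_slide_pair(spec)


def gold_label_detections(pair, records):
    """Assign each detection the label of its nearest ground-truth nucleus."""
    truth = np.array([n.ihc_centroid for n in pair.nuclei])
    _, idx = cKDTree(truth).query(np.array([r.centroid for r in records]))
    return [pair.nuclei[j].ki67_positive for j in idx]


@pytest.fixture(scope="session")
def balanced_pair():
    """512x512 pair, 400 nuclei at 50% positive — classifier training stock."""
    return make_pair(n_nuclei=400, positive_fraction=0.5, seed=1)


@pytest.fixture(scope="session")
def cell_model(balanced_pair):
    """Cell classifier trained on gold-labelled detections of balanced_pair."""
    conc = deconvolve(rgb_to_od(balanced_pair.ihc_image), HED_STAINS)
    records = k.detect_nuclei(conc)
    labels = gold_label_detections(balanced_pair, records)
    return k.train_cell_classifier(records, labels, seed=0)


@pytest.fixture(scope="session")
def region_setup():
    """Ten annotated HE slides (tumor square aligned to the 64-px patch
    grid), a per-slide split, and a trained patch model."""
    from ki67score.region import train_patch_classifier
    from ki67score.tiling import PatchDataset, label_slide_patches, sample_patches

    poly = [[64, 64], [64, 319], [319, 319], [319, 64]]
    slides, patches = {}, []
    for s in range(10):
        spec = k.SyntheticSlideSpec(
            height=384, width=384, n_nuclei=150, n_background_nuclei=30,
            positive_fraction=0.3, tumor_polygons=(poly,), seed=100 + s)
        pair = k.generate_slide_pair(spec)
        sid = f"s{s}"
        slides[sid] = pair.he_image
        patches += sample_patches(
            label_slide_patches(sid, pair.tumor_mask, size=64), 2000, seed=s)
    split = k.split_slides(list(slides), (0.6, 0.2, 0.2), seed=0)
    dataset = PatchDataset(patches=patches, split=split)
    model = train_patch_classifier(dataset, slides, seed=0)
    return {"slides": slides, "dataset": dataset, "model": model, "polygon": poly}
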