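"""Nucleus detection, cell classification and Ki-67 index computation."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

import ki67score as k
from ki67score.scoring import (InsufficientCellsError, NucleusRecord,
                               UndefinedIndexError, compute_ki67_index,
                               pooled_index, score_slide, standard_score_interval)
from ki67score.stains import HED_STAINS, deconvolve, rgb_to_od
from tests.conftest import gold_label_detections, make_pair

TABLE_COUNTS = [
    (29961, 299428), (50073, 270593), (31119, 73719), (20272, 109013),
    (9854, 79026), (11939, 122641), (9332, 100608), (232515, 86582),
    (30003, 270266), (85036, 69088),
]


class TestIndexArithmetic:
    @pytest.mark.parametrize("pos,neg,expected", [
        (29961, 299428, 9.10),
        (31119, 73719, 29.68),
        (232515, 86582, 72.87),
        (85036, 69088, 55.17),
        (1, 0, 100.00),
        (50, 50, 50.00),
    ])
    def test_index_values(self, pos, neg, expected):
        assert compute_ki67_index(pos, neg) == expected

    def test_half_up_rounding(self):
        # 0.125% rounds half-up to 0.13, not banker's 0.12.
        assert compute_ki67_index(1, 799) == 0.13

    def test_zero_total_undefined(self):
        with pytest.raises(UndefinedIndexError):
            compute_ki67_index(0, 0)

    @pytest.mark.parametrize("index,expected", [
        (9.10, (9, 10)), (29.68, (29, 30)), (72.87, (72, 73)),
        (55.17, (55, 56)), (42.00, (42, 42)), (0.0, (0, 0)),
    ])
    def test_standard_score_interval(self, index, expected):
        assert standard_score_interval(index) == expected

    def test_pooled_index_is_count_weighted(self):
        assert pooled_index(TABLE_COUNTS) == 25.62
        assert pooled_index([(10, 90), (10, 90)]) == 10.00
        assert pooled_index([(100, 0), (0, 100)]) == 50.00

    def test_pooled_equals_index_of_summed_counts(self):
        pos = sum(p for p, _ in TABLE_COUNTS)
        neg = sum(n for _, n in TABLE_COUNTS)
        assert pooled_index(TABLE_COUNTS) == compute_ki67_index(pos, neg)


class TestDetection:
    def test_blank_image_yields_no_detections(self):
        blank = np.zeros((128, 128, 3))
        assert k.detect_nuclei(blank) == []

    def test_well_separated_nuclei_counted_exactly(self):
        pair = make_pair(height=512, width=512, n_nuclei=100, seed=3, margin=30)
        conc = deconvolve(rgb_to_od(pair.ihc_image), HED_STAINS)
        records = k.detect_nuclei(conc)
        assert len(records) == 100
        truth = np.array([n.ihc_centroid for n in pair.nuclei])
        dist, _ = cKDTree(np.array([r.centroid for r in records])).query(truth)
        assert dist.max() <= 2.0

    def test_touching_nuclei_split_by_watershed(self):
        from skimage.draw import ellipse

        conc = np.zeros((96, 96, 3))
        rr, cc = ellipse(48, 36, 7, 6, shape=(96, 96))
        conc[rr, cc, 0] = 0.8
        rr, cc = ellipse(48, 52, 7, 6, shape=(96, 96))  # overlapping pair
        conc[rr, cc, 1] = 0.9
        records = k.detect_nuclei(conc)
        assert len(records) == 2

    def test_detection_features_measure_stain_means(self):
        pair = make_pair(height=256, width=256, n_nuclei=30, seed=5,
                         positive_fraction=1.0, margin=30)
        conc = deconvolve(rgb_to_od(pair.ihc_image), HED_STAINS)
        records = k.detect_nuclei(conc)
        # All positive nuclei: DAB signal dominates hematoxylin everywhere.
        assert all(r.mean_od_dab > r.mean_od_hematoxylin for r in records)
        assert all(r.area >= 30 for r in records)


class TestCellClassifier:
    def test_disjoint_dab_ranges_classify_perfectly(self):
        rng = np.random.default_rng(0)

        def rec(dab):
            return NucleusRecord(centroid=(0, 0), area=rng.uniform(60, 120),
                                 perimeter=30.0, eccentricity=0.5,
                                 mean_od_hematoxylin=rng.uniform(0.1, 0.3),
                                 mean_od_dab=dab)

        train = [rec(rng.uniform(0.6, 0.9)) for _ in range(50)] + \
                [rec(rng.uniform(0.0, 0.1)) for _ in range(50)]
        y = [1] * 50 + [0] * 50
        model = k.train_cell_classifier(train, y, seed=0)
        held = [rec(0.75), rec(0.05)]
        labels, proba = model.predict(held)
        assert labels == ["positive", "negative"]
        assert proba[0] > 0.5 > proba[1]

    def test_single_class_training_rejected(self):
        recs = [NucleusRecord((0, 0), 50, 25, 0.5, 0.2, 0.8)] * 10
        with pytest.raises(ValueError):
            k.train_cell_classifier(recs, [1] * 10, seed=0)

    def test_training_deterministic_from_seed(self, balanced_pair, cell_model):
        conc = deconvolve(rgb_to_od(balanced_pair.ihc_image), HED_STAINS)
        records = k.detect_nuclei(conc)
        labels = gold_label_detections(balanced_pair, records)
        again = k.train_cell_classifier(records, labels, seed=0)
        p1, _ = cell_model.predict(records)
        p2, _ = again.predict(records)
        assert p1 == p2

    def test_synthetic_recovery_heldout_accuracy(self, cell_model):
        """>= 0.95 held-out accuracy on an unseen slide with OD noise."""
        pair = make_pair(n_nuclei=400, positive_fraction=0.4, seed=77)
        conc = deconvolve(rgb_to_od(pair.ihc_image), HED_STAINS)
        records = k.detect_nuclei(conc)
        gold = gold_label_detections(pair, records)
        pred, _ = cell_model.predict(records)
        acc = np.mean([(p == "positive") == g for p, g in zip(pred, gold)])
        assert acc >= 0.95


class TestScoreSlide:
    def test_perfect_classifier_reproduces_ground_truth_index(self, cell_model):
        pair = make_pair(height=600, width=600, n_nuclei=600,
                         positive_fraction=0.3, seed=8, margin=20)
        report, records = score_slide(pair.ihc_image, pair.tumor_mask, cell_model)
        # Identity transform: tumor mask is valid in the IHC frame.
        assert report.total == len(records)
        assert report.positive + report.negative == report.total
        assert abs(report.index - k.ground_truth_index(pair)) <= 1.5

    def test_roi_under_100_cells_warns(self, cell_model):
        pair = make_pair(height=600, width=600, n_nuclei=600, seed=8, margin=20)
        roi = np.zeros_like(pair.tumor_mask)
        roi[40:160, 40:160] = True  # a small ROI holding few nuclei
        report, _ = score_slide(pair.ihc_image, pair.tumor_mask, cell_model,
                                rois=[roi])
        assert any("< 100" in w or "(< 100)" in w for w in report.warnings)

    def test_slide_under_500_cells_is_error_and_overridable(self, cell_model):
        pair = make_pair(height=512, width=512, n_nuclei=450, seed=9, margin=10)
        with pytest.raises(InsufficientCellsError):
            score_slide(pair.ihc_image, pair.tumor_mask, cell_model)
        report, _ = score_slide(pair.ihc_image, pair.tumor_mask, cell_model,
                                allow_insufficient=True)
        assert any("below the recommended 1000" in w for w in report.warnings)

    def test_empty_mask_is_error(self, cell_model):
        pair = make_pair(height=256, width=256, n_nuclei=50, seed=10)
        with pytest.raises(ValueError):
            score_slide(pair.ihc_image, np.zeros((256, 256), dtype=bool), cell_model)

    def test_roi_counts_sum_to_slide_counts_when_rois_partition(self, cell_model):
        pair = make_pair(height=600, width=600, n_nuclei=600, seed=12, margin=20)
        h, w = pair.tumor_mask.shape
        quadrants = []
        for r0, c0 in [(0, 0), (0, w // 2), (h // 2, 0), (h // 2, w // 2)]:
            q = np.zeros_like(pair.tumor_mask)
            q[r0:r0 + h // 2, c0:c0 + w // 2] = True
            quadrants.append(q & pair.tumor_mask)
        report, _ = score_slide(pair.ihc_image, pair.tumor_mask, cell_model,
                                rois=quadrants)
        assert sum(r.positive for r in report.rois) == report.positive
        assert sum(r.negative for r in report.rois) == report.negative

    def test_index_invariant_under_joint_rotation(self, cell_model):
        from ki67score.registration import RigidTransform, warp_image

        pair = make_pair(height=600, width=600, n_nuclei=600,
                         positive_fraction=0.3, seed=13, margin=60)
        base, _ = score_slide(pair.ihc_image, pair.tumor_mask, cell_model)
        tf = RigidTransform(angle=np.deg2rad(7.0), translation=(4.0, -6.0),
                            center=(299.5, 299.5))
        ihc_rot = warp_image(pair.ihc_image.astype(float), tf, cval=255.0)
        ihc_rot = np.clip(ihc_rot, 0, 255).astype(np.uint8)
        mask_rot = warp_image(pair.tumor_mask.astype(float), tf, order=0,
                              cval=0.0) > 0.5
        rotated, _ = score_slide(ihc_rot, mask_rot, cell_model)
        assert abs(rotated.index - base.index) <= 0.5


def test_report_json_structure(cell_model):
    pair = make_pair(height=600, width=600, n_nuclei=600, seed=14, margin=20)
    report, _ = score_slide(pair.ihc_image, pair.tumor_mask, cell_model)
    d = report.to_dict()
    assert d["slide"]["total"] == d["slide"]["positive"] + d["slide"]["negative"]
    assert d["slide"]["standard_score"] == list(standard_score_interval(report.index))
    for roi in d["rois"]:
        assert roi["total"] == roi["positive"] + roi["negative"]
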