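"""Patch features, region classifier, heatmap assembly and mask thresholding."""

import numpy as np
import pytest

import ki67score as k
from ki67score.metrics import ConfusionCounts, metric_suite
from ki67score.region import (Heatmap, extract_patch_features, extract_patch_pixels,
                              heatmap_to_mask, predict_heatmap, train_patch_classifier)
from ki67score.tiling import PatchDataset, tile_grid
from tests.conftest import make_pair


class TestFeatures:
    def test_white_patch_has_zero_od_and_zero_blobs(self):
        white = np.full((64, 64, 3), 255, dtype=np.uint8)
        f = dict(zip(k.region.FEATURE_NAMES, extract_patch_features(white)))
        assert f["od_h_mean"] == pytest.approx(0.0, abs=1e-9)
        assert f["od_s2_mean"] == pytest.approx(0.0, abs=1e-9)
        assert f["blob_count"] == 0

    def test_features_are_pure_functions_of_pixels(self):
        pair = make_pair(height=256, width=256, n_nuclei=60, seed=31, margin=20)
        patch = extract_patch_pixels(pair.he_image, (32, 32), 64)
        assert np.array_equal(extract_patch_features(patch.copy()),
                              extract_patch_features(patch.copy()))

    def test_blob_count_matches_rendered_nucleus_count(self):
        spec = k.SyntheticSlideSpec(height=96, width=96, n_nuclei=5,
                                    radius_range=(3.0, 5.0), noise_sd=0.0, seed=40)
        pair = k.generate_slide_pair(spec)
        f = dict(zip(k.region.FEATURE_NAMES,
                     extract_patch_features(pair.he_image)))
        assert f["blob_count"] == 5

    def test_wrong_patch_size_rejected(self):
        with pytest.raises(ValueError):
            extract_patch_features(np.zeros((32, 32, 3)), size=64)


class TestTrainAndPredict:
    def test_heldout_accuracy_on_synthetic_slides(self, region_setup):
        """Feature-based model separates tumor from background texture with
        >= 0.95 held-out patch accuracy."""
        slides, ds, model = (region_setup["slides"], region_setup["dataset"],
                             region_setup["model"])
        test = ds.subset("test")
        feats = np.array([
            extract_patch_features(extract_patch_pixels(slides[p.slide_id],
                                                        p.origin, p.size), p.size)
            for p in test])
        pred = model.score_patches(feats) >= 0.5
        truth = np.array([p.label == "positive" for p in test])
        assert len(test) >= 50
        assert (pred == truth).mean() >= 0.95

    def test_training_deterministic(self, region_setup):
        slides, ds = region_setup["slides"], region_setup["dataset"]
        m1 = train_patch_classifier(ds, slides, seed=0)
        m2 = train_patch_classifier(ds, slides, seed=0)
        probe = extract_patch_pixels(slides["s0"], (64, 64), 64)
        assert m1.score(probe) == m2.score(probe)

    def test_single_class_training_rejected(self, region_setup):
        slides = region_setup["slides"]
        ds = region_setup["dataset"]
        only_pos = PatchDataset(
            patches=[p for p in ds.patches if p.label == "positive"],
            split=ds.split)
        with pytest.raises(ValueError):
            train_patch_classifier(only_pos, slides, seed=0)

    def test_heatmap_separates_tumor_from_background(self, region_setup):
        slides, model, poly = (region_setup["slides"], region_setup["model"],
                               region_setup["polygon"])
        hm = predict_heatmap(slides["s9"], model, size=64)
        mask = k.polygons_to_mask([poly], slides["s9"].shape[:2])
        tumor_scores, bg_scores = [], []
        for i in range(hm.grid.shape[0]):
            for j in range(hm.grid.shape[1]):
                r, c = hm.cell_origin(i, j)
                frac = mask[r:r + 64, c:c + 64].mean()
                (tumor_scores if frac >= 0.5 else bg_scores).append(hm.grid[i, j])
        assert np.mean(tumor_scores) > np.mean(bg_scores)

    def test_model_save_load_round_trip(self, region_setup, tmp_path):
        model = region_setup["model"]
        path = tmp_path / "region_model.joblib"
        model.save(path)
        back = k.PatchModel.load(path)
        probe = extract_patch_pixels(region_setup["slides"]["s1"], (0, 0), 64)
        assert back.score(probe) == model.score(probe)


class TestHeatmapGeometry:
    def test_grid_dims_match_tile_grid(self, region_setup):
        slide = region_setup["slides"]["s0"]
        hm = predict_heatmap(slide, region_setup["model"], size=64)
        assert hm.grid.size == len(tile_grid(*slide.shape[:2], 64, 64))

    def test_slide_smaller_than_patch_gives_empty_heatmap(self, region_setup):
        tiny = np.full((32, 32, 3), 255, dtype=np.uint8)
        hm = predict_heatmap(tiny, region_setup["model"], size=64)
        assert hm.grid.size == 0
        assert heatmap_to_mask(hm, 0.5).sum() == 0

    def test_constant_model_scores_fill_grid(self):
        class AlwaysOne:
            size = 64

            def score_patches(self, feats):
                return np.ones(len(np.atleast_2d(feats)))

        slide = np.full((256, 256, 3), 255, dtype=np.uint8)
        hm = predict_heatmap(slide, AlwaysOne(), size=64)
        assert hm.grid.shape == (4, 4)
        assert np.all(hm.grid == 1.0)

    def test_values_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            Heatmap(np.array([[1.5]]), 64, 64, (64, 64))


class TestHeatmapToMask:
    def _hm(self, grid, size=128, stride=128):
        g = np.asarray(grid, dtype=float)
        shape = (g.shape[0] * stride + (size - stride),
                 g.shape[1] * stride + (size - stride))
        return Heatmap(g, size, stride, shape)

    def test_threshold_zero_covers_every_footprint(self):
        hm = self._hm(np.zeros((4, 4)))
        assert heatmap_to_mask(hm, 0.0).all()

    def test_threshold_one_with_all_ones_grid_full_coverage(self):
        hm = self._hm(np.ones((4, 4)))
        assert heatmap_to_mask(hm, 1.0).all()
        with pytest.raises(ValueError):
            heatmap_to_mask(hm, 1.5)

    def test_single_hot_cell_paints_one_square(self):
        grid = np.full((4, 4), 0.1)
        grid[1, 2] = 0.9
        mask = heatmap_to_mask(self._hm(grid), 0.5)
        assert mask.sum() == 128 * 128
        assert mask[128:256, 256:384].all()

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        hm = self._hm(rng.random((5, 5)))
        lower = heatmap_to_mask(hm, 0.3)
        higher = heatmap_to_mask(hm, 0.7)
        assert not (higher & ~lower).any()  # raising threshold never grows mask

    def test_overlapping_strides_combine_by_maximum(self):
        grid = np.zeros((2, 2))
        grid[0, 0] = 1.0
        hm = Heatmap(grid, size=128, stride=64, slide_shape=(192, 192))
        mask = heatmap_to_mask(hm, 0.5)
        assert mask[:128, :128].all()
        assert not mask[128:, :].any()


def test_patch_confusion_counts_agree_with_metric_suite(region_setup):
    """Confusion counts from thresholded heatmap scores vs gold patch labels
    reproduce the metric-suite rates exactly (oracle cross-check)."""
    slides, ds, model = (region_setup["slides"], region_setup["dataset"],
                         region_setup["model"])
    test = ds.subset("test")
    feats = np.array([
        extract_patch_features(extract_patch_pixels(slides[p.slide_id],
                                                    p.origin, p.size), p.size)
        for p in test])
    pred = model.score_patches(feats) >= 0.5
    truth = np.array([p.label == "positive" for p in test])
    tp = int((pred & truth).sum())
    fp = int((pred & ~truth).sum())
    tn = int((~pred & ~truth).sum())
    fn = int((~pred & truth).sum())
    suite = metric_suite(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
    assert suite.sensitivity == pytest.approx(tp / (tp + fn))
    assert suite.accuracy == pytest.approx((pred == truth).mean())
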