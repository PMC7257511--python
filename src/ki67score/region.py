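"""Tumor-region (IDC) patch classification, heatmaps and region masks.

A pluggable patch model scores each fixed-size patch with a tumor
probability; scores arranged on the tiling grid form a heatmap that is
thresholded into a pixel-resolution region mask. The reference model is a
random-forest ensemble over explicit hand-crafted features (intensity
histograms, optical-density stain statistics, gradient texture, and a
nuclear-density blob count); any object with a compatible ``score_patches``
can stand in, so the heatmap/mask/metric contracts are architecture
independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import joblib
import numpy as np
from scipy import ndimage
from sklearn.ensemble import RandomForestClassifier

from .stains import HED_STAINS, StainVectorSet, deconvolve, rgb_to_od
from .tiling import Patch, PatchDataset, tile_grid

__all__ = [
    "Heatmap",
    "PatchModel",
    "FEATURE_NAMES",
    "extract_patch_features",
    "train_patch_classifier",
    "predict_heatmap",
    "heatmap_to_mask",
    "extract_patch_pixels",
]

_HIST_BINS = 8
# Nuclear blobs: smoothed nuclear OD above a fixed concentration threshold.
_BLOB_SIGMA = 1.0
_BLOB_THRESHOLD = 0.15
_BLOB_MIN_AREA = 12

FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"hist_{ch}_{b}" for ch in "rgb" for b in range(_HIST_BINS)]
    + ["od_h_mean", "od_h_std", "od_s2_mean", "od_s2_std", "od_total_mean"]
    + ["grad_mean", "grad_std", "grad_p90"]
    + ["blob_count"]
)


@dataclass(frozen=True)
class Heatmap:
    """Patch-grid tumor probabilities plus the geometry to map cells back to
    pixel footprints."""

    grid: np.ndarray  # 2-D, values in [0, 1]
    size: int
    stride: int
    slide_shape: tuple[int, int]

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        if g.size and (g.min() < 0.0 or g.max() > 1.0):
            raise ValueError("heatmap values must lie in [0, 1]")
        object.__setattr__(self, "grid", g)

    def cell_origin(self, i: int, j: int) -> tuple[int, int]:
        return (i * self.stride, j * self.stride)


def extract_patch_pixels(slide: np.ndarray, origin: tuple[int, int],
                         size: int) -> np.ndarray:
    r, c = origin
    return slide[r:r + size, c:c + size]


def extract_patch_features(patch_pixels: np.ndarray, size: int | None = None,
                           stains: StainVectorSet = HED_STAINS) -> np.ndarray:
    """Fixed-length feature vector for one RGB patch.

    Order (see FEATURE_NAMES): 8-bin intensity histograms per RGB channel
    (density-normalized), OD-space stain statistics (hematoxylin and
    second-stain concentration mean/std plus total OD mean), gradient-
    magnitude statistics of luminance, and a dark-blob count proxy for
    nuclear density. A pure white patch maps to zero OD means and zero blobs.
    """
    px = np.asarray(patch_pixels)
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError("patch must be an RGB array")
    if size is not None and px.shape[:2] != (size, size):
        raise ValueError(f"patch must be {size}x{size}, got {px.shape[:2]}")
    px = px.astype(float)

    feats: list[float] = []
    for ch in range(3):
        hist, _ = np.histogram(px[..., ch], bins=_HIST_BINS, range=(0, 255))
        feats.extend(hist / px[..., ch].size)

    od = rgb_to_od(px)
    conc = deconvolve(od, stains)
    feats.extend([conc[..., 0].mean(), conc[..., 0].std(),
                  conc[..., 1].mean(), conc[..., 1].std(),
                  od.sum(axis=-1).mean()])

    lum = px[..., 0] * 0.2125 + px[..., 1] * 0.7154 + px[..., 2] * 0.0721
    gr = np.hypot(ndimage.sobel(lum, axis=0), ndimage.sobel(lum, axis=1))
    feats.extend([gr.mean(), gr.std(), float(np.percentile(gr, 90))])

    nuclear = ndimage.gaussian_filter(conc[..., 0] + conc[..., 1], _BLOB_SIGMA)
    labeled, n_blobs = ndimage.label(nuclear > _BLOB_THRESHOLD)
    if n_blobs:
        areas = ndimage.sum_labels(np.ones_like(labeled), labeled,
                                   index=np.arange(1, n_blobs + 1))
        n_blobs = int(np.sum(areas >= _BLOB_MIN_AREA))
    feats.append(float(n_blobs))
    return np.array(feats)


@dataclass
class PatchModel:
    """Trained patch scorer: feature recipe id + fitted ensemble."""

    estimator: RandomForestClassifier
    size: int
    feature_recipe: str = "ki67score-patch-features-v1"

    def score_patches(self, feature_matrix: np.ndarray) -> np.ndarray:
        proba = self.estimator.predict_proba(np.atleast_2d(feature_matrix))
        pos_col = list(self.estimator.classes_).index(1)
        return proba[:, pos_col]

    def score(self, patch_pixels: np.ndarray) -> float:
        return float(self.score_patches(
            extract_patch_features(patch_pixels, self.size)[None, :])[0])

    def save(self, path) -> None:
        joblib.dump({"format_version": 1, "feature_recipe": self.feature_recipe,
                     "size": self.size, "estimator": self.estimator}, path)

    @classmethod
    def load(cls, path) -> "PatchModel":
        d = joblib.load(path)
        if d.get("feature_recipe") != "ki67score-patch-features-v1":
            raise ValueError(f"unknown feature recipe {d.get('feature_recipe')!r}")
        return cls(estimator=d["estimator"], size=d["size"],
                   feature_recipe=d["feature_recipe"])


def _dataset_features(slides: dict[str, np.ndarray], patches: list[Patch]) -> np.ndarray:
    return np.array([
        extract_patch_features(
            extract_patch_pixels(slides[p.slide_id], p.origin, p.size), p.size)
        for p in patches
    ])


def train_patch_classifier(dataset: PatchDataset, slides: dict[str, np.ndarray],
                           seed: int = 0, n_estimators: int = 100) -> PatchModel:
    """Fit the reference patch model on the dataset's train split only.

    The validation split is available to the caller for hyperparameter
    tuning; the test split is never touched here (single-blind contract).
    """
    train = dataset.subset("train")
    labels = np.array([1 if p.label == "positive" else 0 for p in train])
    if len(set(labels.tolist())) < 2:
        raise ValueError("training split must contain both classes")
    feats = _dataset_features(slides, train)
    est = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    est.fit(feats, labels)
    return PatchModel(estimator=est, size=train[0].size)


def predict_heatmap(slide: np.ndarray, model: PatchModel,
                    size: int | None = None, stride: int | None = None) -> Heatmap:
    """Score every grid patch of a slide; grid cells map 1:1 to tile
    origins. A slide smaller than one patch yields an empty heatmap."""
    size = size or model.size
    stride = stride or size
    h, w = slide.shape[:2]
    origins = tile_grid(h, w, size, stride)
    n_rows = len(range(0, h - size + 1, stride)) if h >= size else 0
    n_cols = len(range(0, w - size + 1, stride)) if w >= size else 0
    if not origins:
        return Heatmap(np.zeros((0, 0)), size, stride, (h, w))
    feats = np.array([
        extract_patch_features(extract_patch_pixels(slide, o, size), size)
        for o in origins
    ])
    scores = model.score_patches(feats)
    return Heatmap(scores.reshape(n_rows, n_cols), size, stride, (h, w))


def heatmap_to_mask(heatmap: Heatmap, threshold: float = 0.5) -> np.ndarray:
    """Pixel-resolution binary mask: each patch footprint with grid value
    >= threshold is painted 1; overlapping footprints combine by maximum."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    mask = np.zeros(heatmap.slide_shape, dtype=bool)
    hot = np.argwhere(heatmap.grid >= threshold)
    for i, j in hot:
        r, c = heatmap.cell_origin(int(i), int(j))
        mask[r:r + heatmap.size, c:c + heatmap.size] = True
    return mask
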