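"""Nucleus detection, positive/negative classification and the Ki-67 index.

Nuclei are detected on the stain-deconvolved IHC image: the nuclear signal
(hematoxylin + DAB concentration) is smoothed, thresholded (Otsu), split by
a distance-transform watershed, and filtered by area. Each retained nucleus
yields morphology (area, perimeter, eccentricity) and mean per-stain OD
features, on which a random-forest classifier assigns the Ki-67 label —
classification thresholds the ensemble probability at 0.5, never a raw
intensity cut, since staining intensity is not relevant to the index.

The Ki-67 index is 100 x positive / (positive + negative) over tumor-region
nuclei, reported with half-up rounding to 2 decimals, together with a
standard-score integer interval (floor, floor+1). Reports warn when an ROI
holds fewer than 100 cells or the slide fewer than 1000, and scoring fewer
than 500 cells is an error by default (the accepted absolute minimum).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_multiotsu, threshold_otsu
from skimage.feature import peak_local_max
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .stains import HED_STAINS, StainVectorSet, deconvolve, rgb_to_od

__all__ = [
    "NucleusRecord",
    "DetectionParams",
    "CellModel",
    "Ki67Report",
    "ROIResult",
    "detect_nuclei",
    "train_cell_classifier",
    "compute_ki67_index",
    "standard_score_interval",
    "score_slide",
    "pooled_index",
    "nucleus_feature_matrix",
    "render_overlay",
    "write_nucleus_csv",
    "UndefinedIndexError",
    "InsufficientCellsError",
    "MIN_CELLS_ABSOLUTE",
    "MIN_CELLS_RECOMMENDED",
    "MIN_CELLS_PER_ROI",
]

MIN_CELLS_PER_ROI = 100
MIN_CELLS_RECOMMENDED = 1000
MIN_CELLS_ABSOLUTE = 500


class UndefinedIndexError(ValueError):
    """Ki-67 index undefined for zero scored cells."""


class InsufficientCellsError(ValueError):
    """Fewer cells than the accepted absolute minimum for a reliable index."""


@dataclass(frozen=True)
class NucleusRecord:
    centroid: tuple[float, float]
    area: float
    perimeter: float
    eccentricity: float
    mean_od_hematoxylin: float
    mean_od_dab: float
    label: str | None = None  # "positive" | "negative" | None before classification
    roi_id: str | None = None


@dataclass(frozen=True)
class DetectionParams:
    """Detection operator chain parameters (desk-scale defaults)."""

    sigma: float = 2.0  # px, Gaussian smoothing of the nuclear signal
    min_area: float = 30.0  # px^2
    max_area: float = 2000.0
    signal_floor: float = 0.08  # OD conc below which a slide is called blank
    min_peak_distance: int = 8  # px, watershed seed separation


FEATURES = ("area", "perimeter", "eccentricity",
            "mean_od_hematoxylin", "mean_od_dab")


def nucleus_feature_matrix(records: list[NucleusRecord]) -> np.ndarray:
    return np.array([[getattr(r, f) for f in FEATURES] for r in records])


def detect_nuclei(concentration_maps: np.ndarray,
                  params: DetectionParams | None = None,
                  mask: np.ndarray | None = None) -> list[NucleusRecord]:
    """Detect nuclei on stain concentration maps (..., 3).

    Nuclear signal = hematoxylin + DAB concentration; smooth, Otsu
    threshold, distance-transform watershed to split touching nuclei, then
    filter components to the configured area range. Returns unlabelled
    records; an empty list for blank imagery.
    """
    params = params or DetectionParams()
    maps = np.asarray(concentration_maps, dtype=float)
    if maps.ndim != 3 or maps.shape[2] != 3:
        raise ValueError("expected (H, W, 3) concentration maps")
    nuclear = ndimage.gaussian_filter(maps[..., 0] + maps[..., 1], params.sigma)
    if mask is not None:
        nuclear = np.where(mask, nuclear, 0.0)
    if nuclear.max() < params.signal_floor:
        return []
    # Nuclear signal is often trimodal (background, weak counterstain,
    # strong DAB); the lowest multi-Otsu cut separates tissue background
    # from nuclei of either intensity. Fall back to two-class Otsu when the
    # histogram cannot support three classes.
    try:
        thresh = float(threshold_multiotsu(nuclear, classes=3)[0])
    except ValueError:
        thresh = float(threshold_otsu(nuclear))
    binary = nuclear > max(thresh, params.signal_floor)
    if mask is not None:
        binary &= mask.astype(bool)

    distance = ndimage.distance_transform_edt(binary)
    # Watershed seeds: distance-map maxima at least min_peak_distance apart,
    # so a single elongated nucleus keeps one seed while touching nuclei
    # (centers farther apart) are split.
    coords = peak_local_max(distance, min_distance=params.min_peak_distance,
                            labels=binary)
    seeds = np.zeros_like(binary)
    seeds[tuple(coords.T)] = True
    markers, _ = ndimage.label(seeds)
    markers = watershed(-distance, markers, mask=binary)

    records: list[NucleusRecord] = []
    for prop in regionprops(markers):
        if not params.min_area <= prop.area <= params.max_area:
            continue
        rows, cols = prop.coords[:, 0], prop.coords[:, 1]
        records.append(NucleusRecord(
            centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
            area=float(prop.area),
            perimeter=float(prop.perimeter),
            eccentricity=float(prop.eccentricity),
            mean_od_hematoxylin=float(maps[rows, cols, 0].mean()),
            mean_od_dab=float(maps[rows, cols, 1].mean()),
        ))
    return records


@dataclass
class CellModel:
    """Random-forest Ki-67 positive/negative cell classifier."""

    estimator: object
    feature_names: tuple[str, ...] = FEATURES

    def predict(self, records: list[NucleusRecord]) -> tuple[list[str], np.ndarray]:
        """Labels and positive-class probabilities; the decision is
        probability >= 0.5, never an intensity threshold."""
        if not records:
            return [], np.empty(0)
        proba = self.estimator.predict_proba(nucleus_feature_matrix(records))
        pos_col = list(self.estimator.classes_).index(1)
        p = proba[:, pos_col]
        return ["positive" if v >= 0.5 else "negative" for v in p], p

    def save(self, path) -> None:
        joblib.dump({"format_version": 1, "feature_names": self.feature_names,
                     "estimator": self.estimator}, path)

    @classmethod
    def load(cls, path) -> "CellModel":
        d = joblib.load(path)
        return cls(estimator=d["estimator"],
                   feature_names=tuple(d["feature_names"]))


def train_cell_classifier(records: list[NucleusRecord], labels,
                          seed: int = 0, n_estimators: int = 100) -> CellModel:
    """Fit the cell classifier on gold-labelled nucleus records.

    ``labels`` may be "positive"/"negative" strings or 0/1 integers; both
    classes must be present. Deterministic from seed.
    """
    from sklearn.ensemble import RandomForestClassifier

    y = np.array([1 if (lab in ("positive", 1, True)) else 0 for lab in labels])
    if len(set(y.tolist())) < 2:
        raise ValueError("need both positive and negative training cells")
    est = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    est.fit(nucleus_feature_matrix(records), y)
    return CellModel(estimator=est)


def _round_half_up(x: float, ndigits: int = 2) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(f"1e-{ndigits}"),
                                           rounding=ROUND_HALF_UP))


def compute_ki67_index(positive: int, negative: int) -> float:
    """Ki-67 index (%): 100 x positive / (positive + negative), half-up
    rounded to 2 decimals. Staining intensity plays no role."""
    if positive < 0 or negative < 0:
        raise ValueError("counts must be nonnegative")
    total = positive + negative
    if total == 0:
        raise UndefinedIndexError("no cells scored: index undefined")
    return _round_half_up(100.0 * positive / total)


def standard_score_interval(index: float) -> tuple[int, int]:
    """Integer standard-score interval for an index %: (floor, floor+1) for
    a fractional index, (n, n) for an exact integer."""
    if not 0.0 <= index <= 100.0:
        raise ValueError("index must lie in [0, 100]")
    low = math.floor(index)
    if math.isclose(index, low, abs_tol=1e-9):
        return (low, low)
    return (low, low + 1)


def pooled_index(counts: list[tuple[int, int]]) -> float:
    """Count-weighted pooled index over (positive, negative) pairs:
    100 x sum(positive) / sum(total) — not the mean of per-item indices."""
    pos = sum(p for p, _ in counts)
    neg = sum(n for _, n in counts)
    return compute_ki67_index(pos, neg)


@dataclass(frozen=True)
class ROIResult:
    roi_id: str
    positive: int
    negative: int

    @property
    def total(self) -> int:
        return self.positive + self.negative

    @property
    def index(self) -> float:
        return compute_ki67_index(self.positive, self.negative)


@dataclass
class Ki67Report:
    rois: list[ROIResult]
    positive: int
    negative: int
    warnings: list[str] = field(default_factory=list)

    @property
    def total(self) -> int:
        return self.positive + self.negative

    @property
    def index(self) -> float:
        return compute_ki67_index(self.positive, self.negative)

    @property
    def standard_score(self) -> tuple[int, int]:
        return standard_score_interval(self.index)

    def to_dict(self) -> dict:
        return {
            "slide": {"positive": self.positive, "negative": self.negative,
                      "total": self.total, "ki67_index_percent": self.index,
                      "standard_score": list(self.standard_score)},
            "rois": [{"roi_id": r.roi_id, "positive": r.positive,
                      "negative": r.negative, "total": r.total,
                      "ki67_index_percent": r.index} for r in self.rois],
            "warnings": list(self.warnings),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"


def _auto_rois(records: list[NucleusRecord], roi_grid: int) -> list[str | None]:
    """Grid-partition ROI assignment; cells in grid squares holding fewer
    than MIN_CELLS_PER_ROI detections stay unassigned."""
    cell_of = []
    counts: dict[str, int] = {}
    for rec in records:
        gid = f"roi_{int(rec.centroid[0] // roi_grid)}_{int(rec.centroid[1] // roi_grid)}"
        cell_of.append(gid)
        counts[gid] = counts.get(gid, 0) + 1
    return [gid if counts[gid] >= MIN_CELLS_PER_ROI else None for gid in cell_of]


def score_slide(ihc_image: np.ndarray, idc_mask: np.ndarray, cell_model: CellModel,
                rois: list[np.ndarray] | None = None,
                params: DetectionParams | None = None,
                stains: StainVectorSet = HED_STAINS,
                roi_grid: int = 256,
                allow_insufficient: bool = False) -> tuple[Ki67Report, list[NucleusRecord]]:
    """Detect, classify and count nuclei inside the migrated IDC mask.

    ``rois`` may be explicit binary masks (IHC frame); otherwise ROIs are
    grid squares of ``roi_grid`` px containing at least 100 detected cells.
    Raises InsufficientCellsError below 500 scored cells unless
    ``allow_insufficient``; warns per ROI under 100 cells and for slides
    under 1000.
    """
    idc_mask = np.asarray(idc_mask).astype(bool)
    if not idc_mask.any():
        raise ValueError("empty IDC mask: nothing to score")
    conc = deconvolve(rgb_to_od(ihc_image), stains)
    detected = detect_nuclei(conc, params=params, mask=idc_mask)

    if rois is not None:
        roi_ids: list[str | None] = []
        for rec in detected:
            r, c = int(round(rec.centroid[0])), int(round(rec.centroid[1]))
            gid = None
            for k, roi_mask in enumerate(rois):
                if roi_mask[r, c]:
                    gid = f"roi_{k}"
                    break
            roi_ids.append(gid)
    else:
        roi_ids = _auto_rois(detected, roi_grid)

    labels, _ = cell_model.predict(detected)
    records = [
        NucleusRecord(**{**rec.__dict__, "label": lab, "roi_id": gid})
        for rec, lab, gid in zip(detected, labels, roi_ids)
    ]

    positive = sum(r.label == "positive" for r in records)
    negative = len(records) - positive
    total = len(records)
    warnings_list: list[str] = []
    if total == 0:
        raise UndefinedIndexError("no nuclei detected inside the IDC mask")
    if total < MIN_CELLS_ABSOLUTE and not allow_insufficient:
        raise InsufficientCellsError(
            f"{total} cells scored; below the accepted absolute minimum of "
            f"{MIN_CELLS_ABSOLUTE}")
    if total < MIN_CELLS_RECOMMENDED:
        warnings_list.append(
            f"slide total {total} below the recommended {MIN_CELLS_RECOMMENDED} cells")

    roi_results = []
    for gid in sorted({r.roi_id for r in records if r.roi_id is not None}):
        members = [r for r in records if r.roi_id == gid]
        pos = sum(r.label == "positive" for r in members)
        roi_results.append(ROIResult(gid, pos, len(members) - pos))
        if len(members) < MIN_CELLS_PER_ROI:
            warnings_list.append(
                f"ROI {gid} holds {len(members)} cells (< {MIN_CELLS_PER_ROI})")

    report = Ki67Report(rois=roi_results, positive=positive, negative=negative,
                        warnings=warnings_list)
    return report, records


def render_overlay(ihc_image: np.ndarray, records: list[NucleusRecord],
                   positive_color=(255, 0, 0), negative_color=(0, 0, 255),
                   radius: int = 4) -> np.ndarray:
    """Paint classified nuclei onto the IHC image (red positive, blue
    negative by default)."""
    from skimage.draw import disk

    out = np.asarray(ihc_image).copy()
    for rec in records:
        color = positive_color if rec.label == "positive" else negative_color
        rr, cc = disk(rec.centroid, radius, shape=out.shape[:2])
        out[rr, cc] = color
    return out


def write_nucleus_csv(path: str | Path, records: list[NucleusRecord]) -> None:
    rows = [{
        "row": r.centroid[0], "col": r.centroid[1], "area": r.area,
        "perimeter": r.perimeter, "eccentricity": r.eccentricity,
        "od_h": r.mean_od_hematoxylin, "od_dab": r.mean_od_dab,
        "label": r.label or "", "roi_id": r.roi_id or "",
    } for r in records]
    pd.DataFrame(rows, columns=["row", "col", "area", "perimeter", "eccentricity",
                                "od_h", "od_dab", "label", "roi_id"]
                 ).to_csv(path, index=False)
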