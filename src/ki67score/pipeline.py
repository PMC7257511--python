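"""End-to-end orchestration: identify -> register -> migrate -> score.

The pipeline takes an HE image, its serial-section Ki-67 IHC image, and
either an explicit IDC annotation (polygons or mask in the HE frame) or a
trained region model. It registers HE onto IHC, migrates the IDC region
into the IHC frame, scores nuclei there, and writes the heatmap, transform,
overlay and JSON report. One top-level seed drives every stage through
deterministically derived child seeds; each stage logs one structured line
with parameter values and input hashes so that a prediction run is
auditably blind to gold labels.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .region import Heatmap, PatchModel, heatmap_to_mask, predict_heatmap
from .registration import RegistrationResult, RegistrationSearch, register_rigid, migrate_annotation
from .scoring import CellModel, DetectionParams, Ki67Report, score_slide
from .synthetic import polygons_to_mask

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "stage_seeds"]

logger = logging.getLogger("ki67score")


class PipelineError(RuntimeError):
    """A stage failed; the message carries the stage name."""


@dataclass
class PipelineConfig:
    """Declarative pipeline configuration; CLI flags override file values."""

    schema_version: int = 1
    patch_size: int = 128
    patch_stride: int | None = None
    patch_cap_per_class: int = 2000
    split_ratios: tuple[float, float, float] = (0.7, 0.15, 0.15)
    positive_threshold: float = 0.5
    mask_threshold: float = 0.5
    registration: RegistrationSearch = field(default_factory=RegistrationSearch)
    detection: DetectionParams = field(default_factory=DetectionParams)
    roi_grid: int = 256
    allow_insufficient_cells: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.patch_size < 1:
            raise ValueError("patch_size must be >= 1")
        if self.patch_stride is not None and self.patch_stride < 1:
            raise ValueError("patch_stride must be >= 1")
        if self.patch_cap_per_class < 1:
            raise ValueError("patch_cap_per_class must be >= 1")
        if abs(sum(self.split_ratios) - 1.0) > 1e-9:
            raise ValueError("split_ratios must sum to 1")
        for name in ("positive_threshold", "mask_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        reg = RegistrationSearch(**raw.pop("registration", {}))
        det = DetectionParams(**raw.pop("detection", {}))
        if "split_ratios" in raw:
            raw["split_ratios"] = tuple(raw["split_ratios"])
        cfg = cls(registration=reg, detection=det, **raw)
        cfg.validate()
        return cfg


def stage_seeds(seed: int) -> dict[str, int]:
    """Per-stage seeds derived deterministically from one top-level seed."""
    ss = np.random.SeedSequence(seed)
    names = ("simulate", "tiling", "region", "registration", "cells")
    return {name: int(child.generate_state(1)[0] % (2**31))
            for name, child in zip(names, ss.spawn(len(names)))}


def _hash(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:12]


def _log(stage: str, **params) -> None:
    logger.info("stage=%s %s", stage,
                " ".join(f"{k}={v}" for k, v in sorted(params.items())))


def run_pipeline(config: PipelineConfig, he_image: np.ndarray, ihc_image: np.ndarray,
                 idc_annotation=None, region_model: PatchModel | None = None,
                 cell_model: CellModel | None = None,
                 outdir: str | Path | None = None):
    """Run identify -> register -> migrate -> score.

    ``idc_annotation`` is either a binary HE-frame mask or a list of
    (n, 2) polygons; when absent, ``region_model`` must be supplied and the
    IDC mask comes from thresholding its heatmap. Returns a dict with the
    report, registration result, masks and (optional) heatmap; artifacts are
    written under ``outdir`` when given.
    """
    config.validate()
    if cell_model is None:
        raise PipelineError("validation: a trained cell model is required")
    if idc_annotation is None and region_model is None:
        raise PipelineError(
            "validation: either an IDC annotation or a trained region model is required")

    he_image = np.asarray(he_image)
    ihc_image = np.asarray(ihc_image)
    _log("inputs", he=_hash(he_image), ihc=_hash(ihc_image), seed=config.seed)

    heatmap: Heatmap | None = None
    try:
        if idc_annotation is not None:
            if isinstance(idc_annotation, np.ndarray) and idc_annotation.ndim == 2:
                he_mask = idc_annotation.astype(bool)
            else:
                he_mask = polygons_to_mask(idc_annotation, he_image.shape[:2])
            _log("identify", source="annotation", mask_px=int(he_mask.sum()))
        else:
            heatmap = predict_heatmap(he_image, region_model,
                                      size=config.patch_size, stride=config.patch_stride)
            he_mask = heatmap_to_mask(heatmap, config.mask_threshold)
            _log("identify", source="model", mask_px=int(he_mask.sum()),
                 threshold=config.mask_threshold)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"identify: {exc}") from exc

    try:
        reg: RegistrationResult = register_rigid(ihc_image, he_image,
                                                 config.registration)
        _log("register", angle_rad=f"{reg.transform.angle:.6f}",
             dr=f"{reg.transform.translation[0]:.3f}",
             dc=f"{reg.transform.translation[1]:.3f}",
             quality=f"{reg.quality:.4f}", flags=",".join(reg.flags) or "-")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"register: {exc}") from exc

    try:
        ihc_mask = migrate_annotation(he_mask, reg.transform,
                                      output_shape=ihc_image.shape[:2])
        _log("migrate", mask_px=int(ihc_mask.sum()))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"migrate: {exc}") from exc

    try:
        report, records = score_slide(
            ihc_image, ihc_mask, cell_model, params=config.detection,
            roi_grid=config.roi_grid,
            allow_insufficient=config.allow_insufficient_cells)
        _log("score", positive=report.positive, negative=report.negative,
             index=report.index)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"score: {exc}") from exc

    result = {"report": report, "registration": reg, "he_mask": he_mask,
              "ihc_mask": ihc_mask, "heatmap": heatmap, "nuclei": records}
    if outdir is not None:
        result["paths"] = _write_artifacts(Path(outdir), ihc_image, result)
    return result


def _write_artifacts(outdir: Path, ihc_image: np.ndarray, result: dict) -> dict:
    import tifffile

    from .scoring import render_overlay, write_nucleus_csv

    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    report: Ki67Report = result["report"]
    paths["report"] = outdir / "report.json"
    paths["report"].write_text(report.to_json())
    paths["transform"] = outdir / "transform.json"
    result["registration"].transform.save(paths["transform"])
    paths["ihc_mask"] = outdir / "idc_mask_ihc.png"
    iio.imwrite(paths["ihc_mask"], result["ihc_mask"].astype(np.uint8) * 255)
    if result["heatmap"] is not None:
        paths["heatmap"] = outdir / "heatmap.tiff"
        tifffile.imwrite(paths["heatmap"], result["heatmap"].grid.astype(np.float32))
        hm = result["heatmap"]
        (outdir / "heatmap_geometry.json").write_text(
            json.dumps({"size": hm.size, "stride": hm.stride,
                        "slide_shape": list(hm.slide_shape)}) + "\n")
    paths["overlay"] = outdir / "overlay.png"
    iio.imwrite(paths["overlay"], render_overlay(ihc_image, result["nuclei"]))
    paths["nuclei"] = outdir / "nuclei.csv"
    write_nucleus_csv(paths["nuclei"], result["nuclei"])
    return {k: str(v) for k, v in paths.items()}
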