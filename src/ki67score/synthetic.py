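"""Synthetic paired HE / Ki-67 IHC slide generator with full ground truth.

Emulates serial sectioning: the same nucleus layout appears in an HE-stained
image and in a Ki-67 IHC image related by an unknown rigid transform plus
small per-nucleus jitter. Nuclei are mildly rotated ellipses; on HE every
nucleus takes up hematoxylin and its cytoplasmic halo eosin, on IHC
Ki-67-positive nuclei take up DAB while negative nuclei show hematoxylin
counterstain only. Pixels are synthesized in optical-density space through
a stain-vector matrix (Beer-Lambert mixing) with additive Gaussian OD noise,
so downstream color deconvolution recovers the generating concentrations.

Everything is reproducible from the seed in SyntheticSlideSpec, and the
generator records
the ground truth (tumor mask, nucleus centroids and labels, the true rigid
transform) that every downstream stage is tested against.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from shapely.geometry import Polygon
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import polygon as draw_polygon

from .annotations import write_annotation
from .registration import RigidTransform
from .stains import HE_STAINS, HED_STAINS, StainVectorSet, od_to_rgb, reconstruct_od

__all__ = [
    "SyntheticSlideSpec",
    "Nucleus",
    "SlidePair",
    "generate_slide_pair",
    "ground_truth_index",
    "polygons_to_mask",
    "PlacementError",
    "UndefinedIndexError",
    "write_slide_pair",
]


class PlacementError(RuntimeError):
    """Nuclei could not be placed without overlap within the retry budget."""


class UndefinedIndexError(ValueError):
    """Ki-67 index undefined: no nuclei in the scored region."""


@dataclass(frozen=True)
class SyntheticSlideSpec:
    """Parameters of one synthetic HE/IHC slide pair.

    ``n_nuclei`` tumor nuclei are placed inside the tumor polygons (over the
    whole slide when no polygons are given, in which case the whole slide is
    the tumor region) and ``n_background_nuclei`` sparse nuclei outside
    them, so annotated regions carry a denser nuclear texture.
    positive_fraction is the Bernoulli probability that any nucleus is
    Ki-67 positive; noise_sd is additive Gaussian noise in OD units.
    """

    height: int = 512
    width: int = 512
    n_nuclei: int = 300
    n_background_nuclei: int = 0
    positive_fraction: float = 0.3
    tumor_polygons: tuple = ()
    true_transform: RigidTransform | None = None
    noise_sd: float = 0.02
    seed: int = 0
    radius_range: tuple[float, float] = (4.0, 7.0)
    jitter_sd: float = 0.5
    hematoxylin_conc: float = 0.8
    dab_conc: float = 0.9
    eosin_conc: float = 0.25
    counterstain_conc: float = 0.35

    def __post_init__(self) -> None:
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ValueError("positive_fraction must lie in [0, 1]")
        if self.n_nuclei < 0 or self.n_background_nuclei < 0:
            raise ValueError("nucleus counts must be nonnegative")
        if self.height < 1 or self.width < 1:
            raise ValueError("image dimensions must be positive")
        for poly in self.tumor_polygons:
            arr = np.asarray(poly, dtype=float)
            if arr.ndim != 2 or arr.shape[0] < 3:
                raise ValueError("tumor polygon needs at least 3 vertices")
            if Polygon(arr).area <= 0:
                raise ValueError("zero-area tumor polygon")
            if arr.min() < 0 or arr[:, 0].max() > self.height - 1 or arr[:, 1].max() > self.width - 1:
                raise ValueError("tumor polygon outside image bounds")


@dataclass(frozen=True)
class Nucleus:
    centroid: tuple[float, float]  # (row, col) in the HE frame
    in_tumor: bool
    ki67_positive: bool
    radii: tuple[float, float] = (5.0, 5.0)
    orientation: float = 0.0
    ihc_centroid: tuple[float, float] = (0.0, 0.0)  # after transform + jitter


@dataclass
class SlidePair:
    """An HE image and its serial-section IHC image with ground truth."""

    he_image: np.ndarray
    ihc_image: np.ndarray
    tumor_mask: np.ndarray  # binary, HE frame
    nuclei: list[Nucleus] = field(default_factory=list)
    true_transform: RigidTransform | None = None
    spec: SyntheticSlideSpec | None = None


def polygons_to_mask(polygons, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize (row, col) vertex polygons into a binary mask."""
    mask = np.zeros(shape, dtype=bool)
    for poly in polygons:
        arr = np.asarray(poly, dtype=float)
        rr, cc = draw_polygon(arr[:, 0], arr[:, 1], shape=shape)
        mask[rr, cc] = True
    return mask


class _DartBoard:
    """Dart-throwing placement with a spatial hash; centroids never closer
    than the largest nucleus diameter plus a margin."""

    def __init__(self, rng: np.random.Generator, spec: SyntheticSlideSpec,
                 margin: float = 2.0) -> None:
        self.rng = rng
        self.spec = spec
        r_max = spec.radius_range[1]
        self.min_dist = 2 * r_max + margin
        self.cell = self.min_dist / math.sqrt(2.0)
        self.border = r_max + 1.0
        if spec.height - 2 * self.border <= 0 or spec.width - 2 * self.border <= 0:
            raise PlacementError("image too small for the configured nucleus size")
        self.grid: dict[tuple[int, int], list[np.ndarray]] = {}

    def place(self, n: int, accept) -> np.ndarray:
        """Place n non-overlapping centroids satisfying accept(r, c)."""
        placed = np.empty((n, 2))
        max_attempts = 400 * max(n, 1)
        count = attempts = 0
        while count < n:
            if attempts >= max_attempts:
                raise PlacementError(
                    f"placed only {count}/{n} nuclei after {max_attempts} attempts")
            attempts += 1
            r = self.rng.uniform(self.border, self.spec.height - 1 - self.border)
            c = self.rng.uniform(self.border, self.spec.width - 1 - self.border)
            if not accept(r, c):
                continue
            key = (int(r / self.cell), int(c / self.cell))
            if any(np.hypot(*(p - (r, c))) < self.min_dist
                   for dk in range(-2, 3) for dj in range(-2, 3)
                   for p in self.grid.get((key[0] + dk, key[1] + dj), ())):
                continue
            placed[count] = (r, c)
            self.grid.setdefault(key, []).append(placed[count])
            count += 1
        return placed


def _render_nucleus(conc: np.ndarray, centroid, radii, orientation,
                    stain_index: int, amount: float) -> None:
    rr, cc = draw_ellipse(centroid[0], centroid[1], radii[0], radii[1],
                          shape=conc.shape[:2], rotation=orientation)
    conc[rr, cc, stain_index] = np.maximum(conc[rr, cc, stain_index], amount)


def _render_image(conc: np.ndarray, stains: StainVectorSet,
                  noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    od = reconstruct_od(conc, stains)
    if noise_sd > 0:
        od = od + rng.normal(0.0, noise_sd, size=od.shape)
    return od_to_rgb(np.clip(od, 0.0, None))


def generate_slide_pair(spec: SyntheticSlideSpec,
                        he_stains: StainVectorSet = HE_STAINS,
                        ihc_stains: StainVectorSet = HED_STAINS) -> SlidePair:
    """Generate one HE/IHC pair with complete ground truth.

    Bit-identical for identical spec (the seed drives placement, labels,
    shapes, jitter and noise through independent child generators).
    """
    root = np.random.SeedSequence(spec.seed)
    rng_place, rng_label, rng_shape, rng_jitter, rng_noise_he, rng_noise_ihc = (
        np.random.default_rng(s) for s in root.spawn(6))

    shape = (spec.height, spec.width)
    if spec.tumor_polygons:
        tumor_mask = polygons_to_mask(spec.tumor_polygons, shape)
    else:
        # No annotation: the whole slide is the scored (tumor) region.
        tumor_mask = np.ones(shape, dtype=bool)

    board = _DartBoard(rng_place, spec)
    inside = (lambda r, c: bool(tumor_mask[int(round(r)), int(round(c))]))
    tumor_centroids = board.place(spec.n_nuclei, inside)
    bg_centroids = board.place(spec.n_background_nuclei,
                               lambda r, c: not inside(r, c))
    centroids = np.vstack([tumor_centroids, bg_centroids])
    n_total = spec.n_nuclei + spec.n_background_nuclei
    labels = rng_label.random(n_total) < spec.positive_fraction
    radii = rng_shape.uniform(*spec.radius_range, size=(n_total, 2))
    orientations = rng_shape.uniform(-math.pi / 2, math.pi / 2, size=n_total)

    tf = spec.true_transform or RigidTransform(
        center=((spec.height - 1) / 2.0, (spec.width - 1) / 2.0))
    ihc_centroids = tf.apply(centroids) if n_total else centroids.copy()
    if n_total and spec.jitter_sd > 0:
        ihc_centroids = ihc_centroids + rng_jitter.normal(
            0.0, spec.jitter_sd, size=ihc_centroids.shape)

    he_conc = np.zeros(shape + (3,))
    ihc_conc = np.zeros(shape + (3,))
    nuclei: list[Nucleus] = []
    for i in range(n_total):
        ctr = (float(centroids[i, 0]), float(centroids[i, 1]))
        ictr = (float(ihc_centroids[i, 0]), float(ihc_centroids[i, 1]))
        rad = (float(radii[i, 0]), float(radii[i, 1]))
        halo = (rad[0] + 3.0, rad[1] + 3.0)
        # HE: eosin cytoplasmic halo under a hematoxylin nucleus.
        _render_nucleus(he_conc, ctr, halo, orientations[i], 1, spec.eosin_conc)
        _render_nucleus(he_conc, ctr, rad, orientations[i], 0, spec.hematoxylin_conc)
        # IHC: DAB for positive nuclei, hematoxylin counterstain for negative.
        if labels[i]:
            _render_nucleus(ihc_conc, ictr, rad, orientations[i], 1, spec.dab_conc)
        else:
            _render_nucleus(ihc_conc, ictr, rad, orientations[i], 0,
                            spec.counterstain_conc)
        in_tumor = bool(tumor_mask[int(round(ctr[0])), int(round(ctr[1]))])
        nuclei.append(Nucleus(centroid=ctr, in_tumor=in_tumor,
                              ki67_positive=bool(labels[i]), radii=rad,
                              orientation=float(orientations[i]),
                              ihc_centroid=ictr))

    he_image = _render_image(he_conc, he_stains, spec.noise_sd, rng_noise_he)
    ihc_image = _render_image(ihc_conc, ihc_stains, spec.noise_sd, rng_noise_ihc)
    return SlidePair(he_image=he_image, ihc_image=ihc_image, tumor_mask=tumor_mask,
                     nuclei=nuclei, true_transform=tf, spec=spec)


def ground_truth_index(pair: SlidePair) -> float:
    """Ki-67 index (%) over the ground-truth nuclei inside the tumor mask:
    100 x positives / (positives + negatives)."""
    in_tumor = [n for n in pair.nuclei if n.in_tumor]
    if not in_tumor:
        raise UndefinedIndexError("no nuclei inside the tumor region")
    positives = sum(n.ki67_positive for n in in_tumor)
    return 100.0 * positives / len(in_tumor)


def write_slide_pair(pair: SlidePair, outdir: str | Path, stem: str = "slide") -> dict:
    """Write the pair to disk: PNG images, PNG mask, GeoJSON-like polygon
    annotation, ground-truth nuclei CSV, and the true transform JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "he": outdir / f"{stem}_he.png",
        "ihc": outdir / f"{stem}_ihc.png",
        "mask": outdir / f"{stem}_tumor_mask.png",
        "polygons": outdir / f"{stem}_tumor.json",
        "nuclei": outdir / f"{stem}_nuclei.csv",
        "transform": outdir / f"{stem}_transform.json",
    }
    iio.imwrite(paths["he"], pair.he_image)
    iio.imwrite(paths["ihc"], pair.ihc_image)
    iio.imwrite(paths["mask"], (pair.tumor_mask.astype(np.uint8) * 255))
    if pair.spec is not None:
        write_annotation(paths["polygons"], list(pair.spec.tumor_polygons))
    with open(paths["nuclei"], "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["row", "col", "in_tumor", "label"])
        for n in pair.nuclei:
            writer.writerow([f"{n.centroid[0]:.3f}", f"{n.centroid[1]:.3f}",
                             int(n.in_tumor),
                             "positive" if n.ki67_positive else "negative"])
    if pair.true_transform is not None:
        pair.true_transform.save(paths["transform"])
    return {k: str(v) for k, v in paths.items()}
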