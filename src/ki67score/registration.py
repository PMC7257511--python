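"""Rigid registration of HE sections onto serial-section Ki-67 IHC images.

Serial sections are nearly identical in morphology and related by an
approximately rigid transform (rotation about the image center plus a
translation). Registration maximizes zero-mean normalized cross-correlation
(ZNCC) of the luminance images over a coarse angle/shift grid followed by
local refinement; quality is reported on [0, 1] as max(ZNCC, 0). SSD and
normalized mutual information are provided as alternative similarity
metrics. A recovered transform migrates polygon or mask annotations from
the HE frame into the IHC frame.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize

__all__ = [
    "RigidTransform",
    "RegistrationResult",
    "RegistrationSearch",
    "zncc",
    "registration_quality",
    "alt_similarity",
    "register_rigid",
    "migrate_annotation",
    "warp_image",
    "DegenerateImageError",
]


class DegenerateImageError(ValueError):
    """Raised when similarity is undefined (constant or empty imagery)."""


@dataclass(frozen=True)
class RigidTransform:
    """Rotation by ``angle`` (radians) about ``center`` plus a translation.

    Maps a point p in the moving (HE) frame into the fixed (IHC) frame:
    ``p' = R(angle) @ (p - center) + center + (dr, dc)`` with points in
    0-based (row, col) coordinates, pixel centers at integers.
    """

    angle: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)
    center: tuple[float, float] = (0.0, 0.0)

    def matrix(self) -> np.ndarray:
        c, s = math.cos(self.angle), math.sin(self.angle)
        return np.array([[c, -s], [s, c]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (n, 2) array of (row, col) points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        ctr = np.asarray(self.center, dtype=float)
        out = (pts - ctr) @ self.matrix().T + ctr + np.asarray(self.translation)
        return out if np.asarray(points).ndim == 2 else out[0]

    def inverse(self) -> "RigidTransform":
        rot_t = self.matrix().T
        t = np.asarray(self.translation, dtype=float)
        # p = R^T(p' - c - t) + c = R^T(p' - c) + c - R^T t
        new_t = -rot_t @ t
        return RigidTransform(-self.angle, (float(new_t[0]), float(new_t[1])), self.center)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform applying ``other`` first, then ``self`` (same center required)."""
        if not np.allclose(self.center, other.center):
            raise ValueError("composition requires a shared center")
        rot = self.matrix()
        t = rot @ np.asarray(other.translation) + np.asarray(self.translation)
        return RigidTransform(self.angle + other.angle, (float(t[0]), float(t[1])), self.center)

    def to_dict(self) -> dict:
        return {
            "angle_rad": self.angle,
            "dr": self.translation[0],
            "dc": self.translation[1],
            "center": [self.center[0], self.center[1]],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(
            angle=float(d["angle_rad"]),
            translation=(float(d["dr"]), float(d["dc"])),
            center=(float(d["center"][0]), float(d["center"][1])),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "RigidTransform":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class RegistrationResult:
    transform: RigidTransform
    quality: float
    metric_name: str = "NCC"
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class RegistrationSearch:
    """Search configuration for :func:`register_rigid`.

    Angle bounds/steps in degrees; the coarse stage runs on imagery
    downsampled by ``downsample`` and scans angle x integer shift, the
    refinement stage polishes (angle, dr, dc) at full resolution.
    """

    angle_bound_deg: float = 15.0
    angle_step_deg: float = 1.0
    shift_bound: float = 25.0
    downsample: int = 4
    quality_floor: float = 0.2


def _as_gray(image: np.ndarray) -> np.ndarray:
    """Luminance of RGB; stain colors differ across modalities but tissue
    structure correlates in luminance."""
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img[..., 0] * 0.2125 + img[..., 1] * 0.7154 + img[..., 2] * 0.0721
    return img


def zncc(image_a: np.ndarray, image_b: np.ndarray) -> float:
    """Zero-mean normalized cross-correlation of two equal-shape images.

    Inputs are converted to luminance if RGB. Invariant to affine intensity
    rescaling of either input; returns a value in [-1, 1].
    """
    a = _as_gray(image_a).ravel()
    b = _as_gray(image_b).ravel()
    if a.shape != b.shape:
        raise ValueError("images must have equal dimensions")
    if a.size < 2:
        raise DegenerateImageError("need at least 2 pixels")
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise DegenerateImageError("constant image: correlation undefined")
    return float(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))


def registration_quality(zncc_value: float) -> float:
    """Map ZNCC in [-1, 1] onto the [0, 1] quality scale as max(zncc, 0).

    Positively correlated tissue keeps its numeric correlation value;
    anti-correlation carries no registration merit and clamps to 0.
    """
    if not -1.0 - 1e-12 <= zncc_value <= 1.0 + 1e-12:
        raise ValueError("zncc value outside [-1, 1]")
    return float(max(min(zncc_value, 1.0), 0.0))


def alt_similarity(image_a: np.ndarray, image_b: np.ndarray, metric: str = "SSD",
                   bins: int = 64) -> float:
    """SSD (mean squared luminance difference, lower better) or NMI
    ((H(A)+H(B))/H(A,B) on a joint histogram, higher better, 2.0 at identity).
    """
    a = _as_gray(image_a)
    b = _as_gray(image_b)
    if a.shape != b.shape:
        raise ValueError("images must have equal dimensions")
    metric = metric.upper()
    if metric == "SSD":
        return float(np.mean((a - b) ** 2))
    if metric == "NMI":
        joint, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=bins)
        pab = joint / joint.sum()
        pa = pab.sum(axis=1)
        pb = pab.sum(axis=0)

        def entropy(p: np.ndarray) -> float:
            p = p[p > 0]
            return float(-np.sum(p * np.log2(p)))

        h_ab = entropy(pab.ravel())
        if h_ab == 0.0:
            raise DegenerateImageError("constant images: NMI undefined")
        return (entropy(pa) + entropy(pb)) / h_ab
    raise ValueError(f"unknown metric {metric!r}")


def warp_image(image: np.ndarray, transform: RigidTransform,
               output_shape: tuple[int, int] | None = None,
               order: int = 1, cval: float = np.nan) -> np.ndarray:
    """Resample ``image`` (grayscale or RGB) through ``transform`` so the
    output lives in the fixed frame. Bilinear by default; use order=0 for
    masks. Out-of-support pixels are ``cval``."""
    img = np.asarray(image, dtype=float)
    inv = transform.inverse()
    rot = inv.matrix()
    ctr = np.asarray(inv.center)
    offset = ctr + np.asarray(inv.translation) - rot @ ctr
    shape = output_shape or img.shape[:2]
    if img.ndim == 3:
        out = np.stack(
            [ndimage.affine_transform(img[..., k], rot, offset=offset,
                                      output_shape=shape, order=order, cval=cval)
             for k in range(img.shape[2])], axis=-1)
    else:
        out = ndimage.affine_transform(img, rot, offset=offset,
                                       output_shape=shape, order=order, cval=cval)
    return out


def _masked_zncc(fixed: np.ndarray, warped: np.ndarray) -> float:
    """ZNCC over the warp support only (NaNs excluded)."""
    valid = ~np.isnan(warped)
    n = int(valid.sum())
    if n < 16:
        return -1.0
    a = fixed[valid]
    b = warped[valid]
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return -1.0
    return float(np.dot(a, b) / (na * nb))


def _score(fixed: np.ndarray, moving: np.ndarray, angle: float, dr: float, dc: float,
           center: tuple[float, float]) -> float:
    tf = RigidTransform(angle, (dr, dc), center)
    warped = warp_image(moving, tf, output_shape=fixed.shape)
    return _masked_zncc(fixed, warped)


def register_rigid(fixed: np.ndarray, moving: np.ndarray,
                   search: RegistrationSearch | None = None) -> RegistrationResult:
    """Find the rigid transform mapping ``moving`` (HE) onto ``fixed`` (IHC)
    by maximizing ZNCC.

    Coarse stage: exhaustive angle grid x integer-shift grid on imagery
    downsampled by ``search.downsample``. Refinement: Nelder-Mead polish of
    (angle, dr, dc) on the full-resolution luminance. Deterministic for a
    fixed configuration. A quality below ``search.quality_floor`` is flagged
    (serial sections with large differences may still register core areas),
    never raised.
    """
    search = search or RegistrationSearch()
    fg = _as_gray(fixed)
    mg = _as_gray(moving)
    if fg.std() == 0.0 or mg.std() == 0.0:
        raise DegenerateImageError("constant image cannot be registered")
    center = ((fg.shape[0] - 1) / 2.0, (fg.shape[1] - 1) / 2.0)

    ds = max(1, int(search.downsample))
    f_small = fg[::ds, ::ds]
    m_small = mg[::ds, ::ds]
    c_small = ((f_small.shape[0] - 1) / 2.0, (f_small.shape[1] - 1) / 2.0)
    shift_max = int(math.ceil(search.shift_bound / ds))

    best = (-2.0, 0.0, 0.0, 0.0)  # (score, angle, dr, dc) at coarse scale
    angles = np.deg2rad(np.arange(-search.angle_bound_deg,
                                  search.angle_bound_deg + 1e-9,
                                  search.angle_step_deg))
    shifts = range(-shift_max, shift_max + 1)
    for ang in angles:
        rotated = warp_image(m_small, RigidTransform(float(ang), (0, 0), c_small))
        for dr in shifts:
            for dc in shifts:
                shifted = np.full_like(rotated, np.nan)
                src = rotated[max(0, -dr):rotated.shape[0] - max(0, dr),
                              max(0, -dc):rotated.shape[1] - max(0, dc)]
                shifted[max(0, dr):max(0, dr) + src.shape[0],
                        max(0, dc):max(0, dc) + src.shape[1]] = src
                s = _masked_zncc(f_small, shifted)
                if s > best[0]:
                    best = (s, float(ang), float(dr * ds), float(dc * ds))

    x0 = np.array(best[1:])
    res = minimize(
        lambda x: -_score(fg, mg, x[0], x[1], x[2], center),
        x0, method="Nelder-Mead",
        options={"xatol": 1e-3, "fatol": 1e-7, "maxiter": 300},
    )
    x = res.x if -res.fun >= best[0] else x0
    final = _score(fg, mg, x[0], x[1], x[2], center)
    quality = registration_quality(max(min(final, 1.0), -1.0))
    flags = ("low_quality",) if quality < search.quality_floor else ()
    tf = RigidTransform(float(x[0]), (float(x[1]), float(x[2])), center)
    return RegistrationResult(transform=tf, quality=quality, metric_name="NCC", flags=flags)


def migrate_annotation(annotation, transform: RigidTransform,
                       output_shape: tuple[int, int] | None = None):
    """Carry an HE-frame annotation into the IHC frame.

    Polygons (a list of (n, 2) vertex arrays) are mapped pointwise; a 2-D
    binary mask is resampled with nearest-neighbour interpolation.
    """
    if isinstance(annotation, np.ndarray) and annotation.ndim == 2:
        warped = warp_image(annotation.astype(float), transform,
                            output_shape=output_shape, order=0, cval=0.0)
        return warped > 0.5
    return [transform.apply(np.asarray(poly, dtype=float)) for poly in annotation]
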