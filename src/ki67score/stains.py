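"""Beer-Lambert optical density and color (stain) deconvolution.

Brightfield histology mixes stains multiplicatively in transmitted light;
working in optical density (OD) makes the mixing linear:

    OD_c = -log10((I_c + 1) / (I0 + 1)),   I0 = 255

The ``+1`` offset keeps OD finite at I = 0 (max OD = log10(256) ~ 2.408).
A :class:`StainVectorSet` holds one unit-norm OD direction per stain;
deconvolution projects each pixel's OD vector through the matrix inverse
to recover per-stain concentrations (Ruifrok-Johnston color deconvolution).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StainVectorSet",
    "HED_STAINS",
    "HE_STAINS",
    "rgb_to_od",
    "od_to_rgb",
    "deconvolve",
    "reconstruct_od",
]

_I0 = 255.0
_MAX_OD = float(np.log10(_I0 + 1.0))


def _unit_columns(matrix: np.ndarray) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    norms = np.linalg.norm(m, axis=0)
    if np.any(norms <= 0):
        raise ValueError("stain vector with zero norm")
    return m / norms


@dataclass(frozen=True)
class StainVectorSet:
    """3x3 matrix of unit-norm OD stain vectors, one column per stain.

    Column order is (hematoxylin, second stain, residual) where the second
    stain is eosin for HE imagery or DAB for Ki-67 IHC.
    """

    matrix: np.ndarray
    names: tuple[str, str, str] = ("hematoxylin", "stain2", "residual")
    _inverse: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        m = _unit_columns(self.matrix)
        if m.shape != (3, 3):
            raise ValueError("stain matrix must be 3x3")
        cond = np.linalg.cond(m)
        if not np.isfinite(cond) or cond > 1e8:
            raise ValueError("stain matrix is singular or near-singular")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "_inverse", np.linalg.inv(m))

    @property
    def inverse(self) -> np.ndarray:
        return self._inverse


def _residual_column(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    r = np.cross(a, b)
    return r / np.linalg.norm(r)


# Ruifrok & Johnston OD triplets, the de-facto community convention.
_H = np.array([0.650, 0.704, 0.286])
_E = np.array([0.072, 0.990, 0.105])
_DAB = np.array([0.268, 0.570, 0.776])

HE_STAINS = StainVectorSet(
    np.column_stack([_H, _E, _residual_column(_H, _E)]),
    names=("hematoxylin", "eosin", "residual"),
)
HED_STAINS = StainVectorSet(
    np.column_stack([_H, _DAB, _residual_column(_H, _DAB)]),
    names=("hematoxylin", "dab", "residual"),
)


def rgb_to_od(image: np.ndarray) -> np.ndarray:
    """Convert an RGB image (uint8 or float in [0, 255]) to optical density.

    OD = -log10((I+1)/256) per channel: 0 for pure white, ~2.408 for black,
    monotone decreasing in intensity.
    """
    img = np.asarray(image, dtype=float)
    if np.any(img < 0) or np.any(img > 255):
        raise ValueError("RGB intensities must lie in [0, 255]")
    return -np.log10((img + 1.0) / (_I0 + 1.0))


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    """Invert :func:`rgb_to_od`, returning a uint8 image."""
    od = np.asarray(od, dtype=float)
    intensity = (_I0 + 1.0) * np.power(10.0, -od) - 1.0
    return np.clip(np.rint(intensity), 0, 255).astype(np.uint8)


def deconvolve(od: np.ndarray, stains: StainVectorSet) -> np.ndarray:
    """Unmix an OD image (..., 3) into per-stain concentration maps (..., 3).

    Concentrations are the OD vector projected through the stain-matrix
    inverse, clipped at zero (negative values are unmixing noise).
    """
    od = np.asarray(od, dtype=float)
    if od.shape[-1] != 3:
        raise ValueError("OD image must have 3 channels in the last axis")
    conc = od @ stains.inverse.T
    return np.clip(conc, 0.0, None)


def reconstruct_od(concentrations: np.ndarray, stains: StainVectorSet) -> np.ndarray:
    """Remix per-stain concentrations (..., 3) back into an OD image."""
    conc = np.asarray(concentrations, dtype=float)
    return conc @ stains.matrix.T
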