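"""Patch tiling, patch labelling and balanced dataset assembly.

Slides are tiled into fixed-size square patches (default 128 px) on a
regular grid; partial border patches are dropped. A patch is labelled
tumor-positive when the annotated tumor mask covers at least
``positive_threshold`` of its footprint. Per slide, at most ``cap`` patches
per class enter the dataset (redundant patches are discarded), and the
train/validation/test split is assigned per slide — no slide ever straddles
splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Patch",
    "PatchDataset",
    "tile_grid",
    "label_patch",
    "label_slide_patches",
    "sample_patches",
    "split_slides",
    "write_manifest",
    "read_manifest",
]

DEFAULT_PATCH_SIZE = 128


@dataclass(frozen=True)
class Patch:
    slide_id: str
    origin: tuple[int, int]  # 0-based (row, col) of the top-left pixel
    size: int = DEFAULT_PATCH_SIZE
    label: str = "excluded"  # {"positive", "negative", "excluded"}


@dataclass
class PatchDataset:
    patches: list[Patch] = field(default_factory=list)
    split: dict[str, str] = field(default_factory=dict)  # slide_id -> split name

    def subset(self, split_name: str) -> list[Patch]:
        return [p for p in self.patches if self.split.get(p.slide_id) == split_name]


def tile_grid(height: int, width: int, size: int = DEFAULT_PATCH_SIZE,
              stride: int | None = None) -> list[tuple[int, int]]:
    """Row-major origins (r, c) at multiples of ``stride`` with the full
    size x size footprint inside the slide; border partials are dropped.
    A slide smaller than one patch yields an empty list."""
    if size < 1 or (stride is not None and stride < 1):
        raise ValueError("size and stride must be >= 1")
    stride = stride or size
    rows = range(0, max(height - size + 1, 0), stride) if height >= size else []
    cols = range(0, max(width - size + 1, 0), stride) if width >= size else []
    return [(r, c) for r in rows for c in cols]


def label_patch(origin: tuple[int, int], size: int, tumor_mask: np.ndarray,
                positive_threshold: float = 0.5) -> str:
    """positive iff the tumor-mask fraction over the patch footprint is at
    least ``positive_threshold``; else negative."""
    r, c = origin
    if r < 0 or c < 0 or r + size > tumor_mask.shape[0] or c + size > tumor_mask.shape[1]:
        raise ValueError("patch footprint outside the mask")
    frac = float(tumor_mask[r:r + size, c:c + size].mean())
    return "positive" if frac >= positive_threshold else "negative"


def label_slide_patches(slide_id: str, tumor_mask: np.ndarray,
                        size: int = DEFAULT_PATCH_SIZE, stride: int | None = None,
                        positive_threshold: float = 0.5) -> list[Patch]:
    """Tile a slide and label every patch from its tumor mask."""
    h, w = tumor_mask.shape
    return [
        Patch(slide_id, origin, size,
              label_patch(origin, size, tumor_mask, positive_threshold))
        for origin in tile_grid(h, w, size, stride)
    ]


def sample_patches(labeled_patches: list[Patch], cap_per_class: int,
                   seed: int) -> list[Patch]:
    """Per slide and per class, keep min(cap, available) patches drawn
    without replacement; reproducible from seed."""
    if cap_per_class < 1:
        raise ValueError("cap_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    by_group: dict[tuple[str, str], list[Patch]] = {}
    for p in labeled_patches:
        if p.label in ("positive", "negative"):
            by_group.setdefault((p.slide_id, p.label), []).append(p)
    kept: list[Patch] = []
    for key in sorted(by_group):
        group = by_group[key]
        if len(group) <= cap_per_class:
            kept.extend(group)
        else:
            idx = rng.choice(len(group), size=cap_per_class, replace=False)
            kept.extend(group[i] for i in sorted(idx))
    return kept


def split_slides(slide_ids, ratios: tuple[float, float, float],
                 seed: int) -> dict[str, str]:
    """Shuffle slides by seed, then partition into train/validation/test by
    cumulative ratio with largest-remainder rounding."""
    names = ("train", "validation", "test")
    ratios = tuple(float(r) for r in ratios)
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("split ratios must sum to 1")
    if any(r < 0 for r in ratios):
        raise ValueError("split ratios must be nonnegative")
    slide_ids = list(slide_ids)
    n = len(slide_ids)
    nonzero = sum(r > 0 for r in ratios)
    if n < nonzero:
        raise ValueError(f"{n} slides cannot fill {nonzero} nonempty splits")
    # Largest-remainder apportionment of n among the three groups.
    exact = [r * n for r in ratios]
    sizes = [int(np.floor(x)) for x in exact]
    remainders = sorted(range(3), key=lambda i: (-(exact[i] - sizes[i]), i))
    for i in remainders[: n - sum(sizes)]:
        sizes[i] += 1
    order = list(np.random.default_rng(seed).permutation(n))
    split: dict[str, str] = {}
    pos = 0
    for name, k in zip(names, sizes):
        for i in order[pos:pos + k]:
            split[slide_ids[i]] = name
        pos += k
    return split


def write_manifest(path: str | Path, dataset: PatchDataset) -> None:
    """Dataset manifest CSV: slide_id, origin_row, origin_col, size, label, split."""
    rows = [
        {"slide_id": p.slide_id, "origin_row": p.origin[0], "origin_col": p.origin[1],
         "size": p.size, "label": p.label,
         "split": dataset.split.get(p.slide_id, "")}
        for p in dataset.patches
    ]
    pd.DataFrame(rows, columns=["slide_id", "origin_row", "origin_col",
                                "size", "label", "split"]).to_csv(path, index=False)


def read_manifest(path: str | Path) -> PatchDataset:
    df = pd.read_csv(path, dtype={"slide_id": str})
    patches = [
        Patch(r.slide_id, (int(r.origin_row), int(r.origin_col)), int(r.size), r.label)
        for r in df.itertuples()
    ]
    split = {r.slide_id: r.split for r in df.itertuples() if isinstance(r.split, str)}
    return PatchDataset(patches=patches, split=split)
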