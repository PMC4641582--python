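"""Multi-level chromatin segmentation of the FCM-labelled image.

The centroid-valued segmented image is thresholded at five sensitivity
levels: t_k is the k-th lowest distinct intensity present in the
segmented image, and the level-k mask keeps every pixel with intensity
<= t_k, so the masks form nested level sets (level 1 strictest, level 5
loosest).

When a level-k connected component overlaps regions already accepted at
lower levels, those lower-level regions are preserved unchanged and the
larger component is discarded; components touching nothing previously
detected enter as new regions with ``birth_level = k``.  Final region
sets are therefore nested across levels and pairwise pixel-disjoint
within a level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .features import eccentricity_from_pixels

__all__ = [
    "ChromatinRegion",
    "LevelSegmentation",
    "compute_thresholds",
    "binarize_at",
    "extract_components",
    "resolve_levels",
]


@dataclass
class ChromatinRegion:
    """One connected chromatin blob."""

    id: int
    pixels: np.ndarray = field(repr=False)  # (N, 2) row/col coordinates
    area_px: int
    centroid: tuple[float, float]
    eccentricity: float
    birth_level: int

    @classmethod
    def from_pixels(
        cls, pixels: np.ndarray, region_id: int, birth_level: int
    ) -> "ChromatinRegion":
        pixels = np.asarray(pixels, dtype=np.int64)
        if pixels.size == 0:
            raise ValueError("a region needs at least one pixel")
        centroid = (
            float(pixels[:, 0].mean()),
            float(pixels[:, 1].mean()),
        )
        return cls(
            id=region_id,
            pixels=pixels,
            area_px=int(pixels.shape[0]),
            centroid=centroid,
            eccentricity=eccentricity_from_pixels(pixels),
            birth_level=birth_level,
        )


@dataclass
class LevelSegmentation:
    """Final region set at one sensitivity level."""

    level: int
    regions: list[ChromatinRegion]

    @property
    def n(self) -> int:
        return len(self.regions)

    def total_area_px(self) -> int:
        return int(sum(r.area_px for r in self.regions))


def compute_thresholds(
    segmented: np.ndarray, n_levels: int = 5
) -> np.ndarray:
    """Sensitivity thresholds: the ``n_levels`` lowest distinct
    intensities of the segmented image, sorted ascending."""
    distinct = np.unique(np.asarray(segmented))
    if distinct.size < n_levels:
        raise ValueError(
            f"segmented image has only {distinct.size} distinct "
            f"intensities but {n_levels} sensitivity thresholds are "
            "required; increase the cluster count"
        )
    return distinct[:n_levels].astype(np.int64)


def binarize_at(segmented: np.ndarray, t_k: int) -> np.ndarray:
    """Cumulative level-set mask: True where intensity <= t_k."""
    if not 0 <= t_k <= 255:
        raise ValueError("threshold must lie in [0, 255]")
    return np.asarray(segmented) <= t_k


def extract_components(
    mask: np.ndarray,
    min_area_px: int = 1,
    connectivity: int = 2,
    birth_level: int = 1,
    start_id: int = 0,
) -> list[ChromatinRegion]:
    """Connected components of a binary mask as chromatin regions.

    8-connectivity by default (``connectivity=2`` in scikit-image
    terms); components with fewer than ``min_area_px`` pixels dropped.
    """
    labels = measure.label(
        np.asarray(mask, dtype=bool), connectivity=connectivity
    )
    regions: list[ChromatinRegion] = []
    next_id = start_id
    for props in measure.regionprops(labels):
        if props.area < min_area_px:
            continue
        regions.append(
            ChromatinRegion.from_pixels(props.coords, next_id, birth_level)
        )
        next_id += 1
    return regions


def resolve_levels(
    segmented: np.ndarray,
    thresholds: np.ndarray,
    min_area_px: int = 1,
    connectivity: int = 2,
    keep_residual: bool = False,
) -> list[LevelSegmentation]:
    """Final region sets at every sensitivity level.

    Level 1 takes the components of the strictest mask.  At level k >= 2
    a component overlapping any previously accepted region (one or more
    shared pixels) is dropped in favour of those regions; components
    overlapping nothing are added with ``birth_level = k``.  With
    ``keep_residual=True`` the non-overlapping pixels of a dropped
    component are re-labelled and kept as additional new regions instead
    of being discarded with it.
    """
    segmented = np.asarray(segmented)
    thresholds = np.asarray(thresholds)
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly increasing")

    claimed = np.zeros(segmented.shape, dtype=bool)
    accepted: list[ChromatinRegion] = []
    out: list[LevelSegmentation] = []
    next_id = 0

    for idx, t_k in enumerate(thresholds):
        level = idx + 1
        mask = binarize_at(segmented, int(t_k))
        labels = measure.label(mask, connectivity=connectivity)
        for props in measure.regionprops(labels):
            coords = props.coords
            overlaps = bool(claimed[coords[:, 0], coords[:, 1]].any())
            if overlaps:
                if not keep_residual:
                    continue
                free = coords[~claimed[coords[:, 0], coords[:, 1]]]
                if free.shape[0] == 0:
                    continue
                sub = np.zeros(segmented.shape, dtype=bool)
                sub[free[:, 0], free[:, 1]] = True
                for part in measure.regionprops(
                    measure.label(sub, connectivity=connectivity)
                ):
                    if part.area < min_area_px:
                        continue
                    region = ChromatinRegion.from_pixels(
                        part.coords, next_id, level
                    )
                    next_id += 1
                    accepted.append(region)
                    claimed[part.coords[:, 0], part.coords[:, 1]] = True
                continue
            if props.area < min_area_px:
                continue
            region = ChromatinRegion.from_pixels(coords, next_id, level)
            next_id += 1
            accepted.append(region)
            claimed[coords[:, 0], coords[:, 1]] = True
        out.append(LevelSegmentation(level=level, regions=list(accepted)))
    return out
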