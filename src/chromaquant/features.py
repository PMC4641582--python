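"""Chromatin region features at region, image and cohort scope.

Three feature families are computed for the chromatin regions detected
at each sensitivity level:

* area — pixel count per region, total A_jk and mean per image, and the
  pooled cohort mean  sum_j A_jk / sum_j n_jk  (ratio of totals, not a
  mean of per-image means);
* nearest-pair distance — per region, the Euclidean distance between
  its centroid and the closest other region's centroid; averaged per
  image, then averaged over the images where it is defined (n >= 2);
* eccentricity — of the ellipse sharing the region's second central
  moments, 0 for a circle and approaching 1 for a line.  Pixels are
  treated as unit squares (1/12 added to the axial second moments), so
  degenerate one-pixel-wide regions stay strictly below 1.

Undefined statistics (no regions, or fewer than two regions for the
distance) are carried as NaN and excluded from cohort aggregation,
never silently replaced by zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

if TYPE_CHECKING:  # pragma: no cover
    from .segmentation import ChromatinRegion

__all__ = [
    "ImageFeatureSummary",
    "CohortSummary",
    "eccentricity_from_pixels",
    "axis_ratio_from_pixels",
    "total_area",
    "mean_area",
    "distance_matrix",
    "mean_nearest_distance",
    "summarize_image",
    "summarize_cohort",
    "px_to_um",
    "summaries_to_frame",
    "level_trends",
]


@dataclass
class ImageFeatureSummary:
    """Per-image statistics at one sensitivity level."""

    image_id: str
    level: int
    n: int
    total_area_px: float
    mean_area_px: float
    mean_nn_dist_px: float
    mean_eccentricity: float
    total_eccentricity: float


@dataclass
class CohortSummary:
    """Cohort statistics at one sensitivity level.

    ``overall_mean_area_px`` is the pooled ratio of total area to total
    region count across the cohort; the distance and eccentricity means
    average the per-image averages over images where they are defined.
    Dispersion fields are sample standard deviations of the per-image
    averages.
    """

    level: int
    n_images: int
    total_regions: int
    total_area_px: float
    overall_mean_area_px: float
    overall_mean_nn_dist_px: float
    overall_mean_eccentricity: float
    sd_mean_area_px: float
    sd_mean_nn_dist_px: float
    sd_mean_eccentricity: float
    n_images_with_nn: int


def _second_moments(pixels: np.ndarray) -> tuple[float, float, float]:
    """Central second moments (mu_rr, mu_cc, mu_rc) of a pixel set,
    with the unit-square pixel correction of 1/12 on the axial terms."""
    pts = np.asarray(pixels, dtype=np.float64)
    r = pts[:, 0]
    c = pts[:, 1]
    mu_rr = float(np.var(r)) + 1.0 / 12.0
    mu_cc = float(np.var(c)) + 1.0 / 12.0
    mu_rc = float(np.mean((r - r.mean()) * (c - c.mean())))
    return mu_rr, mu_cc, mu_rc


def _moment_axes(pixels: np.ndarray) -> tuple[float, float]:
    """Eigenvalues (major, minor) of the second-moment tensor."""
    mu_rr, mu_cc, mu_rc = _second_moments(pixels)
    half_tr = 0.5 * (mu_rr + mu_cc)
    disc = math.sqrt((0.5 * (mu_rr - mu_cc)) ** 2 + mu_rc**2)
    return half_tr + disc, half_tr - disc


def eccentricity_from_pixels(pixels: np.ndarray) -> float:
    """Moment-based ellipse eccentricity of a pixel set, in [0, 1).

    sqrt(1 - lambda_minor / lambda_major) for the eigenvalues of the
    second-moment tensor; 0 for a single pixel or any fourfold-symmetric
    region.
    """
    lam1, lam2 = _moment_axes(pixels)
    if lam1 <= 0:
        return 0.0
    ratio = max(lam2, 0.0) / lam1
    return math.sqrt(max(1.0 - ratio, 0.0))


def axis_ratio_from_pixels(pixels: np.ndarray) -> float:
    """Major/minor axis-length ratio of the moment ellipse (>= 1).

    Alternative shape metric; the eccentricity above is the primary one.
    """
    lam1, lam2 = _moment_axes(pixels)
    if lam2 <= 0:
        return math.inf
    return math.sqrt(lam1 / lam2)


def total_area(regions: Sequence["ChromatinRegion"]) -> float:
    """Total area A_jk = sum of region pixel counts (0 if empty)."""
    return float(sum(r.area_px for r in regions))


def mean_area(regions: Sequence["ChromatinRegion"]) -> float:
    """Mean region area; NaN for an empty region list."""
    if len(regions) == 0:
        return math.nan
    return total_area(regions) / len(regions)


def distance_matrix(regions: Sequence["ChromatinRegion"]) -> np.ndarray:
    """Symmetric matrix of Euclidean centroid distances."""
    if len(regions) == 0:
        return np.zeros((0, 0))
    pts = np.array([r.centroid for r in regions], dtype=np.float64)
    return cdist(pts, pts)


def mean_nearest_distance(matrix: np.ndarray) -> float:
    """Mean over regions of the distance to the nearest other region.

    NaN when fewer than two regions exist (self-distances excluded).
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    n = matrix.shape[0]
    if n < 2:
        return math.nan
    masked = matrix + np.where(np.eye(n, dtype=bool), np.inf, 0.0)
    return float(masked.min(axis=1).mean())


def summarize_image(
    regions: Sequence["ChromatinRegion"], level: int, image_id: str = ""
) -> ImageFeatureSummary:
    """All per-image statistics for one level's final region set."""
    n = len(regions)
    a_tot = total_area(regions)
    eccs = [r.eccentricity for r in regions]
    e_tot = float(sum(eccs)) if n else math.nan
    return ImageFeatureSummary(
        image_id=image_id,
        level=level,
        n=n,
        total_area_px=a_tot,
        mean_area_px=a_tot / n if n else math.nan,
        mean_nn_dist_px=mean_nearest_distance(distance_matrix(regions)),
        mean_eccentricity=e_tot / n if n else math.nan,
        total_eccentricity=e_tot,
    )


def summarize_cohort(
    summaries: Sequence[ImageFeatureSummary], level: int
) -> CohortSummary:
    """Aggregate per-image summaries at one level into cohort statistics."""
    rows = [s for s in summaries if s.level == level]
    if not rows:
        raise ValueError(f"no image summaries at level {level}")
    total_regions = int(sum(s.n for s in rows))
    total_area_px = float(sum(s.total_area_px for s in rows))
    mean_areas = np.array(
        [s.mean_area_px for s in rows if s.n >= 1], dtype=np.float64
    )
    nn = np.array(
        [s.mean_nn_dist_px for s in rows if not math.isnan(s.mean_nn_dist_px)],
        dtype=np.float64,
    )
    eccs = np.array(
        [
            s.mean_eccentricity
            for s in rows
            if not math.isnan(s.mean_eccentricity)
        ],
        dtype=np.float64,
    )

    def _sd(x: np.ndarray) -> float:
        return float(np.std(x, ddof=1)) if x.size >= 2 else math.nan

    return CohortSummary(
        level=level,
        n_images=len(rows),
        total_regions=total_regions,
        total_area_px=total_area_px,
        overall_mean_area_px=(
            total_area_px / total_regions if total_regions else math.nan
        ),
        overall_mean_nn_dist_px=float(nn.mean()) if nn.size else math.nan,
        overall_mean_eccentricity=(
            float(eccs.mean()) if eccs.size else math.nan
        ),
        sd_mean_area_px=_sd(mean_areas),
        sd_mean_nn_dist_px=_sd(nn),
        sd_mean_eccentricity=_sd(eccs),
        n_images_with_nn=int(nn.size),
    )


def px_to_um(
    value_px: float, pixel_size_um: float, kind: str = "length"
) -> float:
    """Convert a pixel length or area to micrometres.

    kind="length": value * pixel_size; kind="area": value * pixel_size^2.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    if kind == "length":
        return value_px * pixel_size_um
    if kind == "area":
        return value_px * pixel_size_um**2
    raise ValueError(f"unknown kind {kind!r}")


def summaries_to_frame(
    summaries: Sequence[ImageFeatureSummary],
) -> pd.DataFrame:
    """Per-image summaries as a tidy DataFrame (one row per image-level)."""
    return pd.DataFrame(
        {
            "image_id": [s.image_id for s in summaries],
            "level": [s.level for s in summaries],
            "n_regions": [s.n for s in summaries],
            "total_area_px": [s.total_area_px for s in summaries],
            "mean_area_px": [s.mean_area_px for s in summaries],
            "mean_nn_dist_px": [s.mean_nn_dist_px for s in summaries],
            "mean_eccentricity": [s.mean_eccentricity for s in summaries],
            "total_eccentricity": [s.total_eccentricity for s in summaries],
        }
    )


def level_trends(summaries: Sequence[ImageFeatureSummary]) -> pd.DataFrame:
    """Level-wise trend table: mean and SD of each per-image statistic.

    One row per level, tabulating what the cohort trend plots show.
    """
    levels = sorted({s.level for s in summaries})
    rows = []
    for k in levels:
        c = summarize_cohort(summaries, k)
        rows.append(
            {
                "level": k,
                "n_images": c.n_images,
                "total_regions": c.total_regions,
                "total_area_px": c.total_area_px,
                "mean_regions_per_image": c.total_regions / c.n_images,
                "overall_mean_area_px": c.overall_mean_area_px,
                "sd_mean_area_px": c.sd_mean_area_px,
                "overall_mean_nn_dist_px": c.overall_mean_nn_dist_px,
                "sd_mean_nn_dist_px": c.sd_mean_nn_dist_px,
                "overall_mean_eccentricity": c.overall_mean_eccentricity,
                "sd_mean_eccentricity": c.sd_mean_eccentricity,
            }
        )
    return pd.DataFrame(rows)
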