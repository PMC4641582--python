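"""End-to-end pipeline: preprocess -> FCM -> segmentation -> features.

``process_image`` runs one nucleus crop through the whole chain;
``run_pipeline`` maps it over an image set, aggregates cohort summaries
per sensitivity level, runs the cross-level statistics, and (optionally)
writes the tabular outputs plus a run manifest sufficient to replay the
run.  The cluster count is chosen per image from its own histogram.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .fcm import FCMConfig, fcm_fit, histogram, label_image, select_cluster_count
from .features import (
    CohortSummary,
    ImageFeatureSummary,
    level_trends,
    summaries_to_frame,
    summarize_image,
)
from .preprocess import preprocess_image, read_image
from .segmentation import LevelSegmentation, compute_thresholds, resolve_levels
from .stats import FriedmanResult, PosthocResult, friedman, pairwise_posthoc

logger = logging.getLogger("chromaquant")

__all__ = ["PipelineConfig", "ImageResult", "PipelineResult",
           "process_image", "run_pipeline"]

#: the two per-image statistics compared across levels
_STAT_COLUMNS = ("mean_area_px", "mean_nn_dist_px")


@dataclass
class PipelineConfig:
    """All pipeline settings with the default study parameters."""

    m: float = 2.0
    max_iter: int = 100
    tol: float = 1e-5
    cluster_strategy: str = "histogram-peak"  # or "fixed"
    cluster_count: int | None = None
    c_min: int = 6
    c_max: int = 255
    levels: int = 5
    connectivity: int = 2
    min_area_px: int = 1
    keep_residual: bool = False
    pixel_size_um: float = 0.032
    alpha: float = 0.05
    crop_size: int | None = None
    stretch: bool = True
    low_percentile: float = 0.0
    high_percentile: float = 100.0

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.cluster_strategy not in ("histogram-peak", "fixed"):
            raise ValueError(
                f"unknown cluster strategy {self.cluster_strategy!r}"
            )
        if self.cluster_strategy == "fixed" and self.cluster_count is None:
            raise ValueError("fixed strategy requires cluster_count")

    def fcm_config(self) -> FCMConfig:
        return FCMConfig(
            m=self.m,
            max_iter=self.max_iter,
            tol=self.tol,
            c_min=self.c_min,
            c_max=self.c_max,
        )


@dataclass
class ImageResult:
    """Per-image pipeline outcome."""

    image_id: str
    c_requested: int
    c_effective: int
    thresholds: np.ndarray
    level_segmentations: list[LevelSegmentation]
    summaries: list[ImageFeatureSummary]


@dataclass
class PipelineResult:
    """Cohort-level pipeline outcome."""

    config: PipelineConfig
    image_results: list[ImageResult]
    image_summaries: list[ImageFeatureSummary]
    cohorts: dict[int, CohortSummary]
    trends: pd.DataFrame
    friedman_results: dict[str, FriedmanResult] = field(default_factory=dict)
    posthoc_results: dict[str, PosthocResult] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)

    def block_table(self, statistic: str) -> np.ndarray:
        """N-image x K-level table of a per-image statistic."""
        frame = summaries_to_frame(self.image_summaries)
        wide = frame.pivot(index="image_id", columns="level",
                           values=statistic)
        return wide.to_numpy(dtype=np.float64)


def process_image(
    image: np.ndarray, config: PipelineConfig | None = None,
    image_id: str = "",
) -> ImageResult:
    """Run one image through preprocess, FCM and level segmentation."""
    if config is None:
        config = PipelineConfig()
    gray = preprocess_image(
        image,
        crop_size=config.crop_size,
        stretch=config.stretch,
        low_percentile=config.low_percentile,
        high_percentile=config.high_percentile,
    )
    hist = histogram(gray)
    if config.cluster_strategy == "fixed":
        c = int(config.cluster_count)  # type: ignore[arg-type]
    else:
        c = select_cluster_count(hist, config.c_min, config.c_max)
    result = fcm_fit(hist, c, config.fcm_config())
    segmented = label_image(gray, result)
    thresholds = compute_thresholds(segmented, n_levels=config.levels)
    levels = resolve_levels(
        segmented,
        thresholds,
        min_area_px=config.min_area_px,
        connectivity=config.connectivity,
        keep_residual=config.keep_residual,
    )
    summaries = [
        summarize_image(ls.regions, ls.level, image_id) for ls in levels
    ]
    return ImageResult(
        image_id=image_id,
        c_requested=result.c_requested,
        c_effective=result.c_effective,
        thresholds=thresholds,
        level_segmentations=levels,
        summaries=summaries,
    )


def _load(item) -> np.ndarray | None:
    if isinstance(item, np.ndarray):
        return item
    try:
        return read_image(item)
    except Exception as exc:  # unreadable input: skip, do not abort
        logger.warning("skipping %s: %s", item, exc)
        return None


def run_pipeline(
    images,
    config: PipelineConfig | None = None,
    image_ids: list[str] | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full pipeline over paths and/or in-memory arrays.

    Unreadable files are skipped with a warning; at least one image must
    survive.  With ``out_dir`` set, the per-region, per-image and cohort
    tables, the statistics report and a JSON run manifest are written.
    """
    if config is None:
        config = PipelineConfig()
    items = list(images)
    if image_ids is None:
        image_ids = [
            Path(it).stem if not isinstance(it, np.ndarray) else f"image_{i:04d}"
            for i, it in enumerate(items)
        ]
    if len(image_ids) != len(items):
        raise ValueError("image_ids length mismatch")

    image_results: list[ImageResult] = []
    skipped: list[str] = []
    for item, image_id in zip(items, image_ids):
        arr = _load(item)
        if arr is None:
            skipped.append(str(item))
            continue
        image_results.append(process_image(arr, config, image_id=image_id))
    if not image_results:
        raise ValueError("no readable input image")

    summaries = [s for r in image_results for s in r.summaries]
    levels = sorted({s.level for s in summaries})
    from .features import summarize_cohort

    cohorts = {k: summarize_cohort(summaries, k) for k in levels}
    trends = level_trends(summaries)

    result = PipelineResult(
        config=config,
        image_results=image_results,
        image_summaries=summaries,
        cohorts=cohorts,
        trends=trends,
        skipped=skipped,
    )

    if len(image_results) >= 2 and len(levels) >= 2:
        for stat in _STAT_COLUMNS:
            table = result.block_table(stat)
            usable = table[~np.isnan(table).any(axis=1)]
            if usable.shape[0] < 2:
                logger.warning(
                    "too few complete images for %s statistics", stat
                )
                continue
            result.friedman_results[stat] = friedman(table)
            result.posthoc_results[stat] = pairwise_posthoc(
                table, alpha=config.alpha, levels=levels,
                statistic_name=stat,
            )

    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _regions_frame(image_results: list[ImageResult]) -> pd.DataFrame:
    rows = []
    for res in image_results:
        for ls in res.level_segmentations:
            for reg in ls.regions:
                rows.append(
                    {
                        "image_id": res.image_id,
                        "level": ls.level,
                        "region_id": reg.id,
                        "area_px": reg.area_px,
                        "centroid_row": reg.centroid[0],
                        "centroid_col": reg.centroid[1],
                        "eccentricity": reg.eccentricity,
                        "birth_level": reg.birth_level,
                    }
                )
    return pd.DataFrame(rows)


def _posthoc_frame(res: PosthocResult) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "level_i": [p.level_i for p in res.pairs],
            "level_j": [p.level_j for p in res.pairs],
            "z": [p.z for p in res.pairs],
            "p_raw": [p.p_raw for p in res.pairs],
            "p_holm": [p.p_holm for p in res.pairs],
            "p_shaffer": [p.p_shaffer for p in res.pairs],
            "significant_holm": [p.significant_holm for p in res.pairs],
            "significant_shaffer": [p.significant_shaffer for p in res.pairs],
        }
    )


def stats_report(result: PipelineResult) -> str:
    """Human-readable statistics block for the run."""
    lines = []
    for stat, fr in result.friedman_results.items():
        lines.append(
            f"Friedman test on {stat}: chi2 = {fr.statistic:.4f}, "
            f"p = {fr.p_value:.3e} (N = {fr.n_used}, K = {fr.k}, "
            f"{fr.n_dropped} image(s) dropped)"
        )
        ph = result.posthoc_results.get(stat)
        if ph is None:
            continue
        lines.append(
            "  pairwise mean-rank comparisons "
            f"(alpha = {ph.alpha}, Holm / Shaffer step-down):"
        )
        for p in ph.pairs:
            flag = "ns" if not p.significant_shaffer else "*"
            lines.append(
                f"    [{p.level_i}] vs [{p.level_j}]: z = {p.z:+.3f}, "
                f"p = {p.p_raw:.3e}, Holm = {p.p_holm:.3e}, "
                f"Shaffer = {p.p_shaffer:.3e} {flag}"
            )
    return "\n".join(lines) + ("\n" if lines else "")


def _write_outputs(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    _regions_frame(result.image_results).to_csv(
        out_dir / "regions.csv", index=False
    )
    summaries_to_frame(result.image_summaries).to_csv(
        out_dir / "image_summaries.csv", index=False
    )
    result.trends.to_csv(out_dir / "cohort_summary.csv", index=False)
    for stat, ph in result.posthoc_results.items():
        _posthoc_frame(ph).to_csv(
            out_dir / f"posthoc_{stat}.csv", index=False
        )
    (out_dir / "stats.txt").write_text(stats_report(result))
    manifest = {
        "package": "chromaquant",
        "version": __version__,
        "config": dataclasses.asdict(result.config),
        "n_images": len(result.image_results),
        "skipped": result.skipped,
        "images": [
            {
                "image_id": r.image_id,
                "c_requested": r.c_requested,
                "c_effective": r.c_effective,
                "thresholds": [int(t) for t in r.thresholds],
                "regions_per_level": {
                    str(ls.level): ls.n for ls in r.level_segmentations
                },
            }
            for r in result.image_results
        ],
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
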