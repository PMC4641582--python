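"""Quantitative chromatin model and its rendered realisation.

``build_model`` condenses a cohort summary at one sensitivity level into
the handful of numbers that characterise "evenly distributed, finely
granular chromatin": average region count per nucleus, total and mean
region area, mean nearest-pair distance and mean eccentricity, in both
pixels and micrometres.  ``render_model`` draws a simulated nucleus
realising those numbers: elliptical spots of the mean area and
eccentricity on a jittered hexagonal layout whose spacing is the mean
nearest-neighbour distance.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

from .features import CohortSummary, px_to_um
from .synthesis import SpotTruth, SynthesisParams, generate

__all__ = ["ChromatinModel", "build_model", "render_model"]


@dataclass
class ChromatinModel:
    """Quantitative chromatin-pattern model at one sensitivity level."""

    level: int
    n_chromatin: int
    total_area_px: float
    mean_area_px: float
    mean_nn_dist_px: float
    mean_eccentricity: float
    pixel_size_um: float
    total_area_um2: float
    mean_area_um2: float
    mean_nn_dist_um: float
    n_images: int

    def to_json(self, path=None) -> str:
        payload = json.dumps(dataclasses.asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload


def build_model(
    cohort: CohortSummary,
    pixel_size_um: float = 0.032,
    area_pixel_size_um: float | None = None,
) -> ChromatinModel:
    """Model parameters from a cohort summary.

    The region count is the cohort average per image, rounded to the
    nearest integer; the total area is the average per-image total.
    Lengths convert to micrometres via ``pixel_size_um``; areas use
    ``area_pixel_size_um`` if given (the published length and area
    calibrations are mutually inconsistent, so both are exposed),
    otherwise the same pixel size.
    """
    if cohort.total_regions == 0:
        raise ValueError("cohort contains no chromatin regions")
    if np.isnan(cohort.overall_mean_nn_dist_px):
        raise ValueError(
            "nearest-pair distance undefined for every image in the cohort"
        )
    ap = area_pixel_size_um if area_pixel_size_um is not None else (
        pixel_size_um
    )
    n_chromatin = int(round(cohort.total_regions / cohort.n_images))
    total_area_px = cohort.total_area_px / cohort.n_images
    return ChromatinModel(
        level=cohort.level,
        n_chromatin=n_chromatin,
        total_area_px=total_area_px,
        mean_area_px=cohort.overall_mean_area_px,
        mean_nn_dist_px=cohort.overall_mean_nn_dist_px,
        mean_eccentricity=cohort.overall_mean_eccentricity,
        pixel_size_um=pixel_size_um,
        total_area_um2=px_to_um(total_area_px, ap, "area"),
        mean_area_um2=px_to_um(cohort.overall_mean_area_px, ap, "area"),
        mean_nn_dist_um=px_to_um(
            cohort.overall_mean_nn_dist_px, pixel_size_um, "length"
        ),
        n_images=cohort.n_images,
    )


def render_model(
    model: ChromatinModel,
    canvas: int = 500,
    seed: int = 0,
    spot_intensity: int = 60,
    background_intensity: int = 200,
    noise_sd: float = 0.0,
    jitter_frac: float = 0.10,
) -> tuple[np.ndarray, list[SpotTruth]]:
    """Render the model as a simulated nucleus image.

    ``model.n_chromatin`` two-tone elliptical spots (dark on bright) of
    the model's mean area and eccentricity, randomly oriented, on a
    jittered hexagonal layout with spacing equal to the model's mean
    nearest-neighbour distance.  Deterministic given ``seed``; raises if
    the spots cannot be packed on the canvas.  Returns the image and the
    ground-truth spot list.
    """
    params = SynthesisParams(
        canvas=canvas,
        tier_intensities=(spot_intensity,),
        tier_counts=(model.n_chromatin,),
        mean_spot_area_px=model.mean_area_px,
        spot_area_sd=0.05 * model.mean_area_px,
        target_eccentricity=model.mean_eccentricity,
        eccentricity_sd=0.02,
        target_nn_dist_px=model.mean_nn_dist_px,
        background_intensity=background_intensity,
        noise_sd=noise_sd,
        jitter_frac=jitter_frac,
        seed=seed,
    )
    return generate(params)
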