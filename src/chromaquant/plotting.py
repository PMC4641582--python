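"""Cohort trend plots (plumbing around the feature tables)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_level_trends"]

_PANELS = [
    ("overall_mean_area_px", "sd_mean_area_px", "mean area (px)"),
    ("overall_mean_nn_dist_px", "sd_mean_nn_dist_px",
     "mean NN distance (px)"),
    ("overall_mean_eccentricity", "sd_mean_eccentricity",
     "mean eccentricity"),
]


def plot_level_trends(trends: pd.DataFrame, out_path: str | Path) -> Path:
    """Mean +- SD of each per-image statistic against sensitivity level."""
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    for ax, (col, sd_col, label) in zip(axes, _PANELS):
        ax.errorbar(
            trends["level"], trends[col], yerr=trends[sd_col],
            marker="o", capsize=3,
        )
        ax.set_xlabel("sensitivity level")
        ax.set_ylabel(label)
        ax.set_xticks(trends["level"])
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
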