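"""Minimal rendering of the emitted plot data (ROC and calibration).

The pipeline's primary products are the plot *data* (ROC point sets and
decile tables); these helpers turn them into plain matplotlib figures.
Styling is deliberately minimal.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

__all__ = ["render_roc", "render_calibration"]


def render_roc(roc_points: Mapping[str, np.ndarray], path: str | Path) -> None:
    """One ROC curve per score plus the chance diagonal."""
    fig, ax = plt.subplots(figsize=(5, 5))
    for name, pts in roc_points.items():
        ax.plot(pts[:, 0], pts[:, 1], label=name, lw=1.2)
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(fontsize=7)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def render_calibration(deciles: Mapping[str, pd.DataFrame],
                       path: str | Path) -> None:
    """Observed vs mean predicted mortality by risk decile, per score."""
    fig, ax = plt.subplots(figsize=(5, 5))
    for name, tab in deciles.items():
        ax.plot(tab["mean_predicted"], tab["observed_mortality"],
                marker="o", ms=3, lw=0.8, label=name)
    lim = ax.get_xlim()[1]
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlim(0, max(lim, 1.0))
    ax.set_ylim(0, 1)
    ax.set_xlabel("predicted mortality")
    ax.set_ylabel("observed mortality")
    ax.legend(fontsize=7)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
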