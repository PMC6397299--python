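"""Simple diagnostic plots: dose-response envelope and slope distribution."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .dose_response import DoseCurve, MonteCarloDoseFit

__all__ = ["plot_dose_curve", "plot_slope_distribution"]


def plot_dose_curve(
    curve: DoseCurve, path: Union[str, Path], title: Optional[str] = None
) -> None:
    """Median dose-response curve (solid) with the min/max envelope (dotted)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.n_grid, curve.p_median, "k-", label="median")
    ax.plot(curve.n_grid, curve.p_min, "k:", label="extremes")
    ax.plot(curve.n_grid, curve.p_max, "k:")
    ax.set_xlabel("ingested debris items")
    ax.set_ylabel("P(death due to debris ingestion)")
    ax.set_ylim(0, 1)
    ax.legend()
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_slope_distribution(
    mcfit: MonteCarloDoseFit, path: Union[str, Path], bins: int = 30
) -> None:
    """Histogram of per-replicate slope estimates and their p-values."""
    conv = mcfit.converged_fits
    b1 = np.array([f.b1 for f in conv])
    pv = np.array([f.slope_p_value for f in conv])
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(6, 6))
    ax1.hist(b1, bins=bins, color="grey")
    ax1.set_xlabel("slope per ingested item")
    ax1.set_ylabel("replicates")
    ax2.hist(pv, bins=bins, color="grey")
    ax2.axvline(0.05, color="k", linestyle=":")
    ax2.set_xlabel("slope p-value")
    ax2.set_ylabel("replicates")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
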