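"""Diagnostic figures: per-ROI distribution panels and score heatmaps.

Matplotlib is an optional dependency; core scoring and audits never import
this module. Figures use the Agg backend so they render headlessly.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from .config import HeatmapBinning
from .exceptions import DegenerateDistributionError, ValidationError
from .scoring import log_transform_table, pscore_table, zscore_table
from .tables import NormativeTable, ScoreTable

logger = logging.getLogger(__name__)

__all__ = ["plot_roi_panels", "plot_concatenated_distributions", "plot_heatmap"]

PANELS = ("raw", "log", "zscore", "pscore")


def _mpl():
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    return plt


def _panel(plt, values: np.ndarray, title: str, out_path: Path, color: str):
    from scipy import stats as sps
    fig, ax = plt.subplots(figsize=(4.2, 3.2))
    ax.hist(values, bins=40, density=True, color=color, edgecolor="white", lw=0.3)
    mean, med, sd = values.mean(), np.median(values), values.std(ddof=1)
    ax.axvline(mean, color="green", ls="--", lw=1.2, label="mean")
    ax.axvline(med, color="red", ls="--", lw=1.2, label="median")
    if sd > 0:
        grid = np.linspace(values.min(), values.max(), 200)
        ax.plot(grid, sps.norm.pdf(grid, mean, sd), color="purple", ls="--",
                lw=1.2, label="normal fit")
    ax.set_title(title, fontsize=9)
    ax.legend(fontsize=7, frameon=False)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def plot_roi_panels(table: NormativeTable, roi: str, out_dir) -> list[Path]:
    """Write the four distribution panels (raw, log, Z, P) for one ROI.

    Each panel is its own image: histogram with mean/median lines and a
    fitted normal density, so skew shows up as mean-median misalignment
    and a poor normal fit. Degenerate columns skip the affected score
    panels with a logged reason.
    """
    if roi not in table.data.columns:
        raise ValidationError(f"unknown ROI {roi!r}")
    plt = _mpl()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    colors = {"raw": "lightgray", "log": "dimgray", "zscore": "lightcoral",
              "pscore": "lightskyblue"}
    written = []
    for panel in PANELS:
        try:
            if panel == "raw":
                vals = table.data[roi].to_numpy()
            elif panel == "log":
                vals = log_transform_table(table).data[roi].to_numpy()
            elif panel == "zscore":
                vals = zscore_table(table).data[roi].to_numpy()
            else:
                vals = pscore_table(table).data[roi].to_numpy()
        except (DegenerateDistributionError, ValidationError) as err:
            logger.warning("skipping %s panel for ROI %s: %s", panel, roi, err)
            continue
        path = out_dir / f"{table.metric_name}_{roi}_{panel}.png"
        _panel(plt, vals, f"{table.metric_name} {roi} — {panel}", path, colors[panel])
        written.append(path)
    return written


def plot_concatenated_distributions(zscores: ScoreTable, pscores: ScoreTable,
                                    out_path) -> Path:
    """Paired histograms of all concatenated Z and P scores for one metric."""
    plt = _mpl()
    fig, axes = plt.subplots(2, 1, figsize=(5.5, 5.0), sharex=True)
    for ax, st, color in zip(axes, (zscores, pscores), ("lightcoral", "lightskyblue")):
        v = st.values.ravel(order="F")
        ax.hist(v, bins=80, density=True, color=color)
        pos = 100 * np.count_nonzero(v > 0) / v.size
        ax.axvline(0, color="black", lw=0.8)
        ax.set_title(f"{st.method}: {100 - pos:.0f}% | {pos:.0f}% about 0", fontsize=9)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return Path(out_path)


def plot_heatmap(zscores: ScoreTable, pscores: ScoreTable,
                 binning: HeatmapBinning | None = None, out_path="heatmap.png") -> Path:
    """Stacked participant × ROI heatmap: Z scores above, P scores below.

    Columns are participants, rows ROIs; tiles take a discrete diverging
    palette (blues negative, reds positive) per the binning. A systematic
    tail imbalance shows as one color dominating a whole half.
    """
    if zscores.shape != pscores.shape or \
            list(zscores.data.columns) != list(pscores.data.columns):
        raise ValidationError("Z and P score tables must share shape and labels")
    binning = binning or HeatmapBinning()
    plt = _mpl()
    from matplotlib.colors import ListedColormap

    k = len(binning.positive_edges)
    blues = plt.get_cmap("Blues")(np.linspace(0.95, 0.35, k + 1))
    reds = plt.get_cmap("Reds")(np.linspace(0.35, 0.95, k + 1))
    cmap = ListedColormap(np.vstack([blues, reds]))

    z = binning.bin_index(zscores.values.T)  # rows = ROIs, cols = participants
    p = binning.bin_index(pscores.values.T)
    stacked = np.vstack([z, p])

    fig, ax = plt.subplots(figsize=(10, 6))
    im = ax.imshow(stacked, cmap=cmap, vmin=0, vmax=2 * k + 1, aspect="auto",
                   interpolation="nearest")
    ax.axhline(z.shape[0] - 0.5, color="black", lw=2)
    ax.set_xlabel("participants")
    ax.set_ylabel("ROIs  (top: Zscore, bottom: Pscore)")
    cbar = fig.colorbar(im, ax=ax, ticks=np.arange(2 * k + 2))
    cbar.ax.set_yticklabels(binning.labels(), fontsize=7)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return Path(out_path)
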