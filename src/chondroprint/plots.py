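"""Figure renderers: correlogram, clustered image map, loading bars."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .fingerprint import CIMResult, PLSDAModel
from .stats import CorrelogramResult, PercentChangeResult

__all__ = ["plot_correlogram", "plot_cim", "plot_loadings",
           "plot_percent_change"]


def plot_correlogram(result: CorrelogramResult, path) -> None:
    """Circle-style correlogram; non-significant pairs are left blank."""
    r = result.r
    k = len(r)
    fig, ax = plt.subplots(figsize=(0.5 * k + 2, 0.5 * k + 2))
    for i in range(k):
        for j in range(k):
            val = r.iloc[i, j]
            if not np.isfinite(val) or not result.significant.iloc[i, j]:
                continue
            ax.scatter(j, k - 1 - i, s=400 * abs(val),
                       c=[val], cmap="RdBu_r", vmin=-1, vmax=1,
                       edgecolors="k", linewidths=0.3)
    ax.set_xticks(range(k), r.columns, rotation=90)
    ax.set_yticks(range(k), r.index[::-1])
    ax.set_xlim(-0.5, k - 0.5)
    ax.set_ylim(-0.5, k - 0.5)
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_cim(result: CIMResult, path) -> None:
    """Heatmap of the reordered z-scored matrix (color key in SD units)."""
    m = result.reordered()
    fig, ax = plt.subplots(figsize=(0.5 * m.shape[1] + 2,
                                    0.3 * m.shape[0] + 2))
    vmax = float(np.nanmax(np.abs(m.values))) or 1.0
    im = ax.imshow(m.values, cmap="RdBu_r", vmin=-vmax, vmax=vmax,
                   aspect="auto")
    ax.set_xticks(range(m.shape[1]), m.columns, rotation=90)
    ax.set_yticks(range(m.shape[0]), m.index)
    fig.colorbar(im, ax=ax, label="SD from feature mean")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_loadings(model: PLSDAModel, path) -> None:
    """Component-1 loading bars; bar length = feature importance, color =
    the class the feature marks."""
    load = model.importance.sort_values()
    colors = ["tab:blue" if v < 0 else "tab:red" for v in load.values]
    fig, ax = plt.subplots(figsize=(6, 0.35 * len(load) + 1.5))
    ax.barh(range(len(load)), load.values, color=colors)
    ax.set_yticks(range(len(load)), load.index)
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel("component-1 loading (− control / + treated)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_percent_change(result: PercentChangeResult, path) -> None:
    """Percent-change table: green = significant, red = not."""
    pct = result.percent
    fig, ax = plt.subplots(figsize=(1.2 * pct.shape[1] + 3,
                                    0.4 * pct.shape[0] + 1.5))
    ax.axis("off")
    tab = ax.table(
        cellText=[[f"{v:+.1f}%" for v in row] for row in pct.values],
        rowLabels=pct.index, colLabels=pct.columns, loc="center")
    for (i, j), cell in tab.get_celld().items():
        if i > 0 and j >= 0:
            ok = bool(result.significant.iloc[i - 1, j])
            cell.set_facecolor("#c6efce" if ok else "#ffc7ce")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
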