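"""QC plot rendering: every figure is a derived artifact of a metrics
table, never the only record of a number."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def _density_colors(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-point 2-D Gaussian kernel density, for density-colored scatters."""
    from scipy.stats import gaussian_kde

    pts = np.vstack([x, y])
    if pts.shape[1] < 3 or np.linalg.matrix_rank(np.cov(pts)) < 2:
        return np.ones(pts.shape[1])
    return gaussian_kde(pts)(pts)


def plot_barnyard(counts: pd.DataFrame, ax=None, log: bool = True):
    """Two-species scatter of per-barcode counts, colored by local density."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    a, b = counts.columns[:2]
    x = counts[a].to_numpy(float)
    y = counts[b].to_numpy(float)
    if log:
        x, y = np.log10(x + 1), np.log10(y + 1)
    c = _density_colors(x, y) if len(x) else None
    ax.scatter(x, y, c=c, s=6, cmap="viridis")
    ax.set_xlabel(f"{a} counts" + (" (log10)" if log else ""))
    ax.set_ylabel(f"{b} counts" + (" (log10)" if log else ""))
    return ax


def plot_tss_profile(profile: pd.Series, ax=None):
    """Aggregate insertion profile around the TSS."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.plot(profile.index, profile.to_numpy())
    ax.set_xlabel("distance from TSS (bp)")
    ax.set_ylabel("insertions")
    return ax


def plot_qc_scatter(
    qc: pd.DataFrame,
    x: str = "unique_fragments",
    y: str = "tss_enrichment",
    thresholds: tuple[float, float] | None = None,
    ax=None,
):
    """Per-barcode QC scatter (density-colored) with explicit threshold
    lines, log-x."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    sub = qc[[x, y]].dropna()
    xs = np.log10(sub[x].to_numpy(float) + 1)
    ys = sub[y].to_numpy(float)
    c = _density_colors(xs, ys) if len(xs) else None
    ax.scatter(xs, ys, c=c, s=5, cmap="viridis")
    if thresholds is not None:
        ax.axvline(np.log10(thresholds[0] + 1), color="red", lw=1)
        ax.axhline(thresholds[1], color="red", lw=1)
    ax.set_xlabel(f"{x} (log10)")
    ax.set_ylabel(y)
    return ax


def plot_violin(qc: pd.DataFrame, columns: list[str], ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(1.5 * len(columns) + 1, 4))
    data = [qc[c].dropna().to_numpy(float) for c in columns]
    ax.violinplot(data, showmedians=True)
    ax.set_xticks(range(1, len(columns) + 1), columns, rotation=30)
    return ax


def plot_bead_overlay(
    brightfield: np.ndarray,
    fluorescence_mask: np.ndarray,
    detections=None,
    ax=None,
):
    """Brightfield with the fluorescence mask overlaid at 50% transparency,
    optionally circling detections."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(brightfield, cmap="gray")
    overlay = np.zeros((*fluorescence_mask.shape, 4))
    overlay[fluorescence_mask.astype(bool)] = (0.0, 1.0, 0.0, 0.5)
    ax.imshow(overlay)
    if detections:
        for d in detections:
            ax.add_patch(
                plt.Circle((d.center[1], d.center[0]), d.radius, fill=False, color="red", lw=0.5)
            )
    ax.set_axis_off()
    return ax


def save(ax, path) -> None:
    ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(ax.figure)
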