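"""Figure helpers for binned condition differences and model predictions."""

from __future__ import annotations

import numpy as np

from .analysis_stats import EccBinSeries, ExpFitResult

__all__ = ["plot_binned_differences", "plot_difference_grid"]


def plot_binned_differences(
    series: EccBinSeries,
    fit: ExpFitResult | None = None,
    ax=None,
    focused_extent: float = 0.3,
    distributed_extent: float = 5.0,
    ylabel: str = "distributed − focused",
):
    """Across-participant bin means with SEM bars, task extents, and an
    optional exponential fit with its bootstrap band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    mean = series.participant_mean()
    sem = series.values.std(axis=0, ddof=1).to_numpy() / np.sqrt(
        series.values.notna().sum(axis=0).to_numpy().clip(min=1)
    )
    ok = np.isfinite(mean)
    ax.errorbar(series.bin_centers[ok], mean[ok], yerr=sem[ok], fmt="o", ms=4, color="k", zorder=3)
    if fit is not None:
        ax.plot(fit.eval_grid, fit.curve(fit.eval_grid), color="purple", lw=2)
        ax.fill_between(fit.eval_grid, fit.ci_low, fit.ci_high, color="purple", alpha=0.25, lw=0)
    ax.axhline(0, color="gray", lw=0.5)
    ax.axvline(focused_extent, color="gray", ls="--", lw=0.8)
    top = ax.get_ylim()[1]
    ax.plot([0, focused_extent], [top, top], color="orange", lw=3, solid_capstyle="butt")
    ax.plot([focused_extent, distributed_extent], [top, top], color="teal", lw=3, solid_capstyle="butt")
    ax.set_xlabel("independent eccentricity (deg)")
    ax.set_ylabel(ylabel)
    ax.set_title(series.roi_label)
    return ax


def plot_difference_grid(series_by_roi: dict, fits: dict | None = None, path: str | None = None):
    """One panel per visual area, optionally saved to ``path``."""
    import matplotlib.pyplot as plt

    rois = list(series_by_roi)
    n = len(rois)
    ncol = min(3, n)
    nrow = int(np.ceil(n / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3 * nrow), squeeze=False)
    for i, roi in enumerate(rois):
        ax = axes[i // ncol][i % ncol]
        plot_binned_differences(series_by_roi[roi], (fits or {}).get(roi), ax=ax)
    for j in range(n, nrow * ncol):
        axes[j // ncol][j % ncol].axis("off")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
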