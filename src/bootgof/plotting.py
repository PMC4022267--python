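"""Optional figure exports: cloud + density contours, ROC, calibration.

Plots are outputs only; no figure-derived numbers enter any computation.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_cloud", "plot_roc", "plot_calibration"]


def plot_cloud(cloud, observed=None, grid=None, ax=None, path=None):
    """Scatter a 2-column cloud, optionally with density contours and the
    observed statistic pair (drawn as a red square)."""
    pts = cloud.stat_matrix if hasattr(cloud, "stat_matrix") else np.asarray(cloud)
    names = getattr(cloud, "statistic_names", ("statistic 1", "statistic 2"))
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.plot(pts[:, 0], pts[:, 1], ".", ms=3, color="seagreen", alpha=0.5,
            label=f"cloud (B={len(pts)})")
    if grid is not None and grid.grid_y is not None:
        ax.contour(grid.grid_x, grid.grid_y, grid.density.T, levels=8,
                   colors="gray", linewidths=0.7)
    if observed is not None:
        ax.plot([observed[0]], [observed[1]], "s", color="crimson", ms=7,
                label="observed")
    ax.set_xlabel(names[0])
    ax.set_ylabel(names[1])
    ax.legend(loc="best", fontsize=8)
    if path:
        ax.figure.savefig(path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_roc(rocs: dict, fpr_limit: float = 0.1, ax=None, path=None):
    """Overlay ROC curves ({test_name: roc dict from roc_curve})."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for name, roc in rocs.items():
        ax.plot(roc["fpr"], roc["tpr"], label=f"{name} (pAUC={roc['pauc']:.2f})")
    ax.plot([0, fpr_limit], [0, fpr_limit], "k:", lw=0.8)
    ax.set_xlim(0, fpr_limit)
    ax.set_ylim(0, 1)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right", fontsize=8)
    if path:
        ax.figure.savefig(path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_calibration(calibrations: dict, ax=None, path=None):
    """Observed vs nominal FPR curves ({test_name: dict from type1_calibration})."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for name, cal in calibrations.items():
        t = cal["table"]
        ax.plot(t["alpha"], t["observed_fpr"], "o-", ms=3,
                label=f"{name} ({cal['verdict']})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("nominal FPR (alpha)")
    ax.set_ylabel("observed FPR")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.legend(loc="upper left", fontsize=7)
    if path:
        ax.figure.savefig(path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
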