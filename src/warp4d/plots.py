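"""Static plots: DVH comparison curves and dose-difference slices."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .dvh import DVHCurve
from .grid import ScalarVolume, StructureMask

__all__ = ["plot_dvh_comparison", "plot_difference_slice"]


def plot_dvh_comparison(curves: dict[str, DVHCurve], path: str,
                        title: str = "Dose-volume histograms"):
    """Overlay cumulative DVHs (one label per calculation arm or structure)."""
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for label, dvh in curves.items():
        ax.plot(dvh.bin_edges, 100.0 * dvh.cumulative_fraction, label=label)
    ax.set_xlabel("Dose (Gy)")
    ax.set_ylabel("Volume (%)")
    ax.set_ylim(0, 102)
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_difference_slice(diff: ScalarVolume, path: str, axis: str = "AP",
                          roi: StructureMask | None = None,
                          title: str = "Dose difference (Gy)"):
    """Mid-volume coronal/sagittal/axial slice of a difference map.

    ``axis`` names the viewing direction: AP gives the coronal plane
    (LR x SI), LR the sagittal, SI the axial.
    """
    ax_idx = {"LR": 0, "AP": 1, "SI": 2}[axis]
    mid = diff.grid.shape[ax_idx] // 2
    sl = np.take(diff.values, mid, axis=ax_idx).T
    vmax = max(abs(float(sl.min())), abs(float(sl.max())), 1e-6)
    fig, ax = plt.subplots(figsize=(5.5, 5))
    im = ax.imshow(sl, origin="lower", cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    if roi is not None:
        ax.contour(np.take(roi.member, mid, axis=ax_idx).T.astype(float),
                   levels=[0.5], colors="k", linewidths=0.8)
    fig.colorbar(im, ax=ax, shrink=0.8, label=title)
    ax.set_title(f"{title}, mid-{axis} slice")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
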