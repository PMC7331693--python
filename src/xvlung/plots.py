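"""Figure export: histogram + fit curves, volume/time curves, map slices."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .expansion import ExpansionMap
from .global_function import VolumeTimeCurve
from .quantify import DoubleGaussianResults, ExpansionHistogram


def plot_histogram_fit(
    hist: ExpansionHistogram,
    fit: DoubleGaussianResults | None = None,
    hd: float | None = None,
    cd: float | None = None,
    path: str | Path | None = None,
):
    """Grey data line, dashed black fit, HD/CD/R^2 annotations."""
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    ax.plot(hist.bin_centers, hist.density, color="0.5", lw=1.5, label="data")
    notes = []
    if fit is not None:
        xs = np.linspace(hist.bin_edges[0], hist.bin_edges[-1], 400)
        ax.plot(xs, fit.predict(xs), "k--", lw=1.2, label="double-Gaussian fit")
        notes.append(f"$R^2$ = {fit.r_squared:.3f}")
    if hd is not None:
        notes.append(f"HD = {hd:.2f}")
    if cd is not None and np.isfinite(cd):
        notes.append(f"CD = {cd:.2f}")
    if notes:
        ax.text(0.97, 0.95, "\n".join(notes), ha="right", va="top", transform=ax.transAxes)
    ax.set_xlabel("fractional expansion")
    ax.set_ylabel("normalised density")
    ax.legend(frameon=False, loc="upper left", fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_volume_curve(curve: VolumeTimeCurve, path: str | Path | None = None):
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    ax.plot(curve.times, curve.fractional_volume, "o-", ms=3)
    if curve.tau is not None:
        ax.axvline(curve.times[curve.peak_phase] + curve.tau, ls=":", color="r")
        ax.text(
            curve.times[curve.peak_phase] + curve.tau,
            0.9 * curve.tidal_fraction,
            rf"  $\tau$ = {curve.tau * 1e3:.0f} ms",
            color="r",
        )
    ax.set_xlabel("time (s)")
    ax.set_ylabel("fractional volume")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_expansion_slice(emap: ExpansionMap, y_index: int | None = None, path=None):
    """Coronal (fixed-y) slice of the expansion map."""
    vals = np.where(emap.effective_mask, emap.values, np.nan)
    if y_index is None:
        y_index = vals.shape[1] // 2
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(vals[:, y_index, :], cmap="viridis")
    fig.colorbar(im, ax=ax, label="fractional expansion")
    ax.set_xlabel("x")
    ax.set_ylabel("z")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
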