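"""Standard figures: series overview, lag-response curves, RR surface."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_series", "plot_curves", "plot_surface", "save_standard_plots"]


def plot_series(series, ax=None):
    """Daily counts and pollen concentration on twin axes."""
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3.2))
    t = series.frame["date"]
    ax.bar(t, series.counts, color="0.55", width=1.0, label="visits")
    ax.set_ylabel("daily visits")
    ax2 = ax.twinx()
    ax2.plot(t, series.exposure, color="tab:green", lw=0.9, label="pollen")
    ax2.set_ylabel("pollen (grains/1000 mm$^2$)")
    ax.set_xlabel("date")
    return ax


def plot_curves(curves, tag: str, ax=None):
    """RR vs lag with 95% CI band, one panel line per percentile."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for p, entry in curves.items():
        curve = entry[tag]
        ax.plot(curve.lags, curve.rr, label=f"P{p} ({entry['exposure']:.0f})")
        ax.fill_between(curve.lags, curve.ci_low, curve.ci_high, alpha=0.15)
    ax.axhline(1.0, color="k", lw=0.8, ls="--")
    ax.set_xlabel("lag (days)")
    ax.set_ylabel("RR")
    ax.set_title(f"{tag} lag effect")
    ax.legend(fontsize=8)
    return ax


def plot_surface(surface, fig=None):
    """Heatmap plus 3-D view of the lag-specific RR surface."""
    if fig is None:
        fig = plt.figure(figsize=(10, 4))
    ax1 = fig.add_subplot(1, 2, 1)
    pc = ax1.pcolormesh(surface.lags, surface.exposures, surface.rr, shading="auto", cmap="viridis")
    fig.colorbar(pc, ax=ax1, label="RR")
    ax1.set_xlabel("lag (days)")
    ax1.set_ylabel("pollen (grains/1000 mm$^2$)")
    ax2 = fig.add_subplot(1, 2, 2, projection="3d")
    Lg, Xg = np.meshgrid(surface.lags, surface.exposures)
    ax2.plot_surface(Xg, Lg, surface.rr, cmap="viridis", linewidth=0)
    ax2.set_xlabel("pollen")
    ax2.set_ylabel("lag")
    ax2.set_zlabel("RR")
    return fig


def save_standard_plots(out_dir, series, surface, curves) -> list[Path]:
    out = Path(out_dir)
    written = []
    ax = plot_series(series)
    ax.figure.tight_layout()
    ax.figure.savefig(out / "fig_series.png", dpi=120)
    plt.close(ax.figure)
    written.append(out / "fig_series.png")
    for tag in ("specific", "cumulative"):
        ax = plot_curves(curves, tag)
        ax.figure.tight_layout()
        ax.figure.savefig(out / f"fig_{tag}_curves.png", dpi=120)
        plt.close(ax.figure)
        written.append(out / f"fig_{tag}_curves.png")
    fig = plot_surface(surface)
    fig.tight_layout()
    fig.savefig(out / "fig_surface.png", dpi=120)
    plt.close(fig)
    written.append(out / "fig_surface.png")
    return written
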