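"""Box-whisker-vs-size charts for protocol health review.

One glyph per exam at its AP+LAT size: a thick bar spanning the 10th-90th
mA percentiles, thin whiskers to the non-outlier extremes, a horizontal tick
at the median, and crosses for outliers.  Optional overlays show the fitted
exponential percentile curves and the protocol's configured mA range, which
makes rail-hugging exams obvious at a glance.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

__all__ = ["plot_ma_vs_size"]


def plot_ma_vs_size(points, fit=None, limits=None, path=None, *,
                    title: str = "AEC tube current vs patient size",
                    log_y: bool = True):
    """Plot per-exam mA summaries against patient size.

    Parameters
    ----------
    points : sequence of (size_cm, ExamStats)
    fit : SizeFitModel, optional
        Fitted percentile curves to overlay.
    limits : (ma_min, ma_max), optional
        Protocol mA range drawn as horizontal lines.
    path : path-like, optional
        Where to save the figure; when omitted the figure is returned
        unsaved.
    """
    fig, ax = plt.subplots(figsize=(8, 5))
    for s, st in points:
        ax.plot([s, s], [st.whisker_low, st.whisker_high],
                color="0.6", lw=0.8, zorder=1)
        ax.plot([s, s], [st.p10_ma, st.p90_ma], color="C0", lw=2.5, zorder=2)
        ax.plot([s - 0.4, s + 0.4], [st.median_ma, st.median_ma],
                color="k", lw=1.2, zorder=3)
        if st.outliers:
            ax.plot([s] * len(st.outliers), st.outliers, "x",
                    color="C3", ms=4, zorder=2)
    if fit is not None:
        grid = np.linspace(fit.s_min, fit.s_max, 200)
        for stat, style in (("p10", ":"), ("median", "-"), ("p90", "--")):
            if stat in fit.fits:
                ax.plot(grid, [fit.evaluate(stat, s) for s in grid],
                        style, color="C1", lw=1.2, label=f"{stat} fit")
    if limits is not None:
        ma_min, ma_max = limits
        ax.axhline(ma_max, color="C3", lw=1.0, ls="-", label=f"ma_max = {ma_max:g}")
        ax.axhline(ma_min, color="C2", lw=1.0, ls="-", label=f"ma_min = {ma_min:g}")
    if log_y:
        ax.set_yscale("log")
    ax.set_xlabel("AP + LAT patient size (cm)")
    ax.set_ylabel("tube current (mA)")
    ax.set_title(title)
    if fit is not None or limits is not None:
        ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(Path(path), dpi=110)
        plt.close(fig)
        return Path(path)
    return fig
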