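"""Correlation-plot rendering: CI rectangles, band lines, finite-bound box."""

from __future__ import annotations

import math

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .correlation import CorrelationBand, PotencyInterval, finite_bound_box

__all__ = ["plot_correlation"]


def plot_correlation(pairs, band: CorrelationBand, path, x_label="in vitro BMD05 (ug/ml)",
                     y_label="BMD (mg/kg/day)", title=None) -> None:
    """Double-log scatter of BMD CI rectangles with unity-slope band lines.

    Infinite bounds are drawn to the plot edge; the dashed box marks the
    lowest BMDL and the largest finite BMDU on each axis, so intervals with
    infinite bounds are the ones crossing outside it.
    """
    xs = [p[0] for p in pairs]
    ys = [p[1] for p in pairs]
    finite_vals = [math.log10(v.bmdl) for v in xs + ys]
    finite_vals += [math.log10(v.bmdu) for v in xs + ys if math.isfinite(v.bmdu)]
    lo_ax, hi_ax = min(finite_vals) - 1.0, max(finite_vals) + 1.0

    fig, ax = plt.subplots(figsize=(6, 6))
    for x, y in pairs:
        xl, xu = math.log10(x.bmdl), math.log10(x.bmdu) if x.finite else hi_ax
        yl, yu = math.log10(y.bmdl), math.log10(y.bmdu) if y.finite else hi_ax
        ax.plot([xl, xu], [(yl + yu) / 2] * 2, color="steelblue", lw=1)
        ax.plot([(xl + xu) / 2] * 2, [yl, yu], color="steelblue", lw=1)
        ax.annotate(x.compound, ((xl + xu) / 2, yu), fontsize=6, ha="center")

    grid = [lo_ax, hi_ax]
    ax.plot(grid, [g + band.intercept_lo for g in grid], "k--", lw=1)
    ax.plot(grid, [g + band.intercept_hi for g in grid], "k--", lw=1)

    try:
        bx = finite_bound_box(xs)
        by = finite_bound_box(ys)
        ax.add_patch(
            plt.Rectangle(
                (math.log10(bx[0]), math.log10(by[0])),
                math.log10(bx[1]) - math.log10(bx[0]),
                math.log10(by[1]) - math.log10(by[0]),
                fill=False,
                linestyle=":",
                edgecolor="gray",
            )
        )
    except ValueError:
        pass  # no finite uppers at all: omit the box

    ax.set_xlim(lo_ax, hi_ax)
    ax.set_ylim(lo_ax, hi_ax)
    ax.set_xlabel(f"log10 {x_label}")
    ax.set_ylabel(f"log10 {y_label}")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
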