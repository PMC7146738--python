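"""Figures: interaction contour map and ratio-vs-mixing-ratio scatter."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .interaction import InteractionSurface, RatioScatter

__all__ = ["plot_interaction_surface", "plot_ratio_scatter"]


def plot_interaction_surface(surface: InteractionSurface, path) -> None:
    """Contour map of OI reduction over the lnOAV plane.

    Measured samples are overlaid in red, model-predicted grid points in
    black, matching the usual presentation of such maps.  Masked cells
    (OI_sum below the cut-off) are left blank.
    """
    la, lb = surface.grid()
    reduction = np.ma.masked_where(surface.mask, surface.oi_reduction)
    fig, ax = plt.subplots(figsize=(6, 5))
    cf = ax.contourf(la, lb, reduction, levels=14, cmap="RdYlBu_r")
    fig.colorbar(cf, ax=ax, label="OI reduction (OIRS units)")
    pred = surface.anchors[surface.anchors["source"] == "predicted"]
    meas = surface.anchors[surface.anchors["source"] == "measured"]
    ax.plot(pred["lnoav_a"], pred["lnoav_b"], ".", color="black", ms=1.5,
            alpha=0.4, label="predicted")
    ax.plot(meas["lnoav_a"], meas["lnoav_b"], "o", color="red", ms=4,
            label="measured")
    a, b = surface.pair
    ax.set_xlabel(f"lnOAV ({a})")
    ax.set_ylabel(f"lnOAV ({b})")
    ax.set_title(f"Odor interaction: {a} + {b}")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_ratio_scatter(scatter: RatioScatter, path) -> None:
    """OI reduction ratio vs mixing ratio, colored by mixture intensity."""
    table = scatter.table
    fig, ax = plt.subplots(figsize=(6, 4.5))
    pred = table[table["source"] == "predicted"]
    meas = table[table["source"] == "measured"]
    sc = ax.scatter(pred["x_a"], pred["oi_reduction_ratio"], c=pred["oi_mix"],
                    s=8, cmap="viridis", alpha=0.7, label="predicted")
    ax.scatter(meas["x_a"], meas["oi_reduction_ratio"], c=meas["oi_mix"],
               s=40, cmap="viridis", edgecolors="red", linewidths=0.8,
               label="measured")
    fig.colorbar(sc, ax=ax, label="OI$_{mix}$ (OIRS units)")
    a, b = scatter.pair
    ax.set_xlabel(f"mixing ratio $x_a$ = lnOAV$_{{{a}}}$ / (lnOAV$_{{{a}}}$ + lnOAV$_{{{b}}}$)")
    ax.set_ylabel("OI reduction ratio")
    ax.axhline(0.0, color="grey", lw=0.8, ls="--")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
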