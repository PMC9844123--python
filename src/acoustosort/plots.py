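"""Scatter and density plots in the layout cytometrists expect.

Deformation (or brightness) against projected area with gate overlays
and marginal kernel-density curves; purely presentational, nothing here
feeds back into the analysis.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .gating import Gate, kde_density

__all__ = ["scatter_with_gate", "density_plot"]


def _draw_gate(ax, gate: Gate, y_axis: str) -> None:
    if gate.polygon is not None and y_axis == "deformation":
        poly = np.asarray(gate.polygon + (gate.polygon[0],))
        ax.plot(poly[:, 0], poly[:, 1], color="crimson", lw=1.2, label=gate.label)
        return
    x_lo, x_hi = gate.area_range if gate.area_range else (None, None)
    if y_axis == "deformation":
        y_lo, y_hi = 0.0, gate.deformation_max
    else:
        y_lo, y_hi = gate.brightness_range if gate.brightness_range else (None, None)
    if None in (x_lo, x_hi) or y_hi is None:
        return
    ax.add_patch(plt.Rectangle((x_lo, y_lo or 0.0), x_hi - x_lo,
                               (y_hi - (y_lo or 0.0)),
                               fill=False, edgecolor="crimson", lw=1.2,
                               label=gate.label))


def scatter_with_gate(events: pd.DataFrame, gate: Gate | None = None,
                      y_axis: str = "deformation", path=None,
                      title: str | None = None):
    """Event scatter (area on x) with an optional gate overlay.

    ``y_axis`` is 'deformation' or 'brightness_au'.  Saves to ``path``
    when given, otherwise returns the figure.
    """
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(events["area_um2"], events[y_axis], s=4, alpha=0.3,
               linewidths=0, color="#20639b")
    if gate is not None:
        _draw_gate(ax, gate, y_axis)
    ax.set_xlabel("cell size, area (µm²)")
    ax.set_ylabel("deformation" if y_axis == "deformation" else "brightness (a.u.)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig


def density_plot(values, bandwidth: float, path=None, xlabel: str = ""):
    """Histogram with Gaussian-kernel density overlay."""
    values = np.asarray(values, dtype=float)
    grid, density = kde_density(values, bandwidth)
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.hist(values, bins=60, density=True, color="#c9d7e4")
    ax.plot(grid, density, color="#173f5f", lw=1.5)
    ax.set_xlabel(xlabel)
    ax.set_ylabel("density")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
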