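"""Map rendering: WQI prediction surfaces as blue-low / red-high rasters
with sample overlays.  Cosmetic output only — nothing numeric depends on
these figures."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .errors import WqimapError
from .geostat import KrigingGrid, SpatialSample


def render_map(
    grid: KrigingGrid,
    samples: Sequence[SpatialSample] = (),
    path: str | Path = "wqi_map.png",
    title: str = "Predicted WQI",
) -> Path:
    """Heat map of a kriged WQI surface (blue = small WQI, red = high),
    with the monitoring points overlaid."""
    if grid.predicted.size == 0:
        raise WqimapError("cannot render an empty grid")
    spec = grid.spec
    fig, ax = plt.subplots(figsize=(7, 5.5))
    zmin, zmax = float(grid.predicted.min()), float(grid.predicted.max())
    if zmin == zmax:  # constant surface: give the colorbar a tiny span
        zmin, zmax = zmin - 0.5, zmax + 0.5
    im = ax.imshow(
        grid.predicted,
        origin="lower",
        extent=(spec.x_min, spec.x_max, spec.y_min, spec.y_max),
        cmap="RdYlBu_r",
        vmin=zmin,
        vmax=zmax,
        aspect="auto",
    )
    if samples:
        ax.scatter(
            [s.x for s in samples],
            [s.y for s in samples],
            s=12, c="black", marker="o", linewidths=0, alpha=0.7,
            label="monitoring points",
        )
        ax.legend(loc="upper right", fontsize=8)
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="WQI")
    path = Path(path)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path


def render_yearly_panels(
    grids: dict[int, KrigingGrid],
    samples: Sequence[SpatialSample] = (),
    path: str | Path = "wqi_panels.png",
) -> Path:
    """One panel per year, shared color scale (temporal comparison)."""
    if not grids:
        raise WqimapError("no grids to render")
    years = sorted(grids)
    zmin = min(float(g.predicted.min()) for g in grids.values())
    zmax = max(float(g.predicted.max()) for g in grids.values())
    if zmin == zmax:
        zmin, zmax = zmin - 0.5, zmax + 0.5
    n = len(years)
    ncols = min(3, n)
    nrows = -(-n // ncols)
    fig, axes = plt.subplots(nrows, ncols, figsize=(4.5 * ncols, 3.6 * nrows),
                             squeeze=False)
    im = None
    for ax, year in zip(axes.ravel(), years):
        g = grids[year]
        im = ax.imshow(
            g.predicted, origin="lower",
            extent=(g.spec.x_min, g.spec.x_max, g.spec.y_min, g.spec.y_max),
            cmap="RdYlBu_r", vmin=zmin, vmax=zmax, aspect="auto",
        )
        if samples:
            ax.scatter([s.x for s in samples], [s.y for s in samples],
                       s=6, c="black", linewidths=0, alpha=0.6)
        ax.set_title(str(year), fontsize=10)
    for ax in axes.ravel()[n:]:
        ax.set_visible(False)
    fig.supxlabel("longitude")
    fig.supylabel("latitude")
    fig.colorbar(im, ax=axes, label="WQI", shrink=0.8)
    path = Path(path)
    fig.savefig(path, dpi=110, bbox_inches="tight")
    plt.close(fig)
    return path
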