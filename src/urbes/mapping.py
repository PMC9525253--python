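"""Rasterization of per-compartment scores and the averaged trade-off map.

Each indicator's scores are painted onto a regular metric grid (1 m x 1 m
cells by default): a cell takes the score of the compartment whose polygon
contains the cell center, and is nodata outside all compartments.  The
per-indicator rasters are then averaged cellwise into the trade-off map,
which — because unassessed scores are zeros, not holes — equals the raster
of the averaged ES-ED scores exactly.

Rasters are written as ESRI ASCII grids (a plain-text format readable by
any GIS raster calculator) with nodata -9999 on disk and NaN in memory.
Coordinates must be in a projected/metric CRS: square-metre cells are
meaningless in degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from shapely import contains_xy
from shapely.geometry.base import BaseGeometry

from .surveys import Compartment, ValidationError

__all__ = [
    "ScoreRaster",
    "rasterize_scores",
    "average_rasters",
    "read_ascii_grid",
    "write_ascii_grid",
    "write_quicklook",
]

NODATA_ON_DISK = -9999.0
_OVERLAP_TOL_M2 = 1e-6

_GEOGRAPHIC_HINTS = ("4326", "wgs84", "geographic", "longlat", "epsg:4269")


@dataclass
class ScoreRaster:
    """A single-band score grid on a metric coordinate system.

    ``grid`` is a 2-D float array with row 0 at the top (north); nodata is
    NaN.  ``x_min``/``y_max`` locate the outer corner of the top-left cell;
    ``cell_size`` is the square cell edge in metres.
    """

    grid: np.ndarray
    x_min: float
    y_max: float
    cell_size: float
    indicator_id: str = ""
    crs: str = "local-metric"

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def same_grid(self, other: "ScoreRaster") -> bool:
        return (
            self.grid.shape == other.grid.shape
            and math.isclose(self.x_min, other.x_min)
            and math.isclose(self.y_max, other.y_max)
            and math.isclose(self.cell_size, other.cell_size)
            and self.crs == other.crs
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid of cell-center coordinates (xs, ys), shaped like grid."""
        nrows, ncols = self.grid.shape
        xs = self.x_min + (np.arange(ncols) + 0.5) * self.cell_size
        ys = self.y_max - (np.arange(nrows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)


def _check_metric(crs: str) -> None:
    low = crs.lower()
    if any(h in low for h in _GEOGRAPHIC_HINTS):
        raise ValidationError(
            f"CRS {crs!r} looks geographic; scores must be rasterized on a "
            "projected metric CRS (1 m cells are undefined in degrees)"
        )


def _check_no_overlap(compartments: Sequence[Compartment]) -> None:
    for i, a in enumerate(compartments):
        for b in compartments[i + 1 :]:
            inter = a.geometry.intersection(b.geometry)
            if inter.area > _OVERLAP_TOL_M2:
                raise ValidationError(
                    f"compartment polygons overlap: {a.id!r} and {b.id!r} "
                    f"({inter.area:.1f} m2)"
                )


def rasterize_scores(
    compartments: Iterable[Compartment],
    scores: Mapping[str, float],
    cell_size: float = 1.0,
    indicator_id: str = "",
    crs: str = "local-metric",
) -> ScoreRaster:
    """Paint one indicator's per-compartment scores onto a score grid.

    Every cell whose center falls inside a compartment polygon carries that
    compartment's score (cell-center containment, not all-touched: an
    unbiased area estimate).  The grid origin is snapped outward to integer
    multiples of ``cell_size``, covering the union of all geometries.
    ``scores`` must provide a value for every compartment that has
    geometry; polygons must be valid, non-empty and pairwise disjoint.
    """
    _check_metric(crs)
    comps = sorted(
        (c for c in compartments if c.geometry is not None), key=lambda c: c.id
    )
    if not comps:
        raise ValidationError("no compartment has geometry")
    for c in comps:
        geom: BaseGeometry = c.geometry
        if geom.is_empty or not geom.is_valid:
            raise ValidationError(f"compartment {c.id!r}: invalid or empty geometry")
        if c.id not in scores:
            raise ValidationError(f"no score for compartment {c.id!r}")
    _check_no_overlap(comps)

    xs0 = min(c.geometry.bounds[0] for c in comps)
    ys0 = min(c.geometry.bounds[1] for c in comps)
    xs1 = max(c.geometry.bounds[2] for c in comps)
    ys1 = max(c.geometry.bounds[3] for c in comps)
    x_min = math.floor(xs0 / cell_size) * cell_size
    y_min = math.floor(ys0 / cell_size) * cell_size
    x_max = math.ceil(xs1 / cell_size) * cell_size
    y_max = math.ceil(ys1 / cell_size) * cell_size
    ncols = max(1, round((x_max - x_min) / cell_size))
    nrows = max(1, round((y_max - y_min) / cell_size))

    grid = np.full((nrows, ncols), np.nan)
    xs = x_min + (np.arange(ncols) + 0.5) * cell_size
    ys = y_max - (np.arange(nrows) + 0.5) * cell_size
    for c in comps:
        bx0, by0, bx1, by1 = c.geometry.bounds
        j = np.flatnonzero((xs > bx0 - cell_size) & (xs < bx1 + cell_size))
        i = np.flatnonzero((ys > by0 - cell_size) & (ys < by1 + cell_size))
        if not len(i) or not len(j):
            continue
        xx, yy = np.meshgrid(xs[j], ys[i])
        inside = contains_xy(c.geometry, xx.ravel(), yy.ravel()).reshape(xx.shape)
        sub = grid[np.ix_(i, j)]
        sub[inside] = float(scores[c.id])
        grid[np.ix_(i, j)] = sub

    return ScoreRaster(grid, x_min, y_max, cell_size, indicator_id, crs)


def average_rasters(
    rasters: Sequence[ScoreRaster], indicator_id: str = "averaged_es_ed"
) -> ScoreRaster:
    """Cellwise arithmetic mean over co-registered score rasters.

    All inputs must share grid shape, origin, cell size and CRS.  A cell is
    nodata in the output iff it is nodata in any layer (inside the mapped
    compartments every layer is defined, because unassessed indicators
    score 0 rather than nodata).
    """
    rasters = list(rasters)
    if not rasters:
        raise ValidationError("no rasters to average")
    first = rasters[0]
    for r in rasters[1:]:
        if not first.same_grid(r):
            raise ValidationError(
                f"raster grid mismatch between {first.indicator_id!r} and {r.indicator_id!r}"
            )
    stack = np.stack([r.grid for r in rasters])
    return ScoreRaster(
        stack.mean(axis=0), first.x_min, first.y_max, first.cell_size, indicator_id, first.crs
    )


def write_ascii_grid(raster: ScoreRaster, path: str | Path) -> None:
    """Write an ESRI ASCII grid (.asc); NaN becomes -9999."""
    nrows, ncols = raster.grid.shape
    y_min = raster.y_max - nrows * raster.cell_size
    grid = np.where(np.isnan(raster.grid), NODATA_ON_DISK, raster.grid)
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {raster.x_min:.6f}\n"
        f"yllcorner {y_min:.6f}\n"
        f"cellsize {raster.cell_size:.6f}\n"
        f"NODATA_value {NODATA_ON_DISK:g}\n"
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header)
        np.savetxt(fh, grid, fmt="%.10g")


def read_ascii_grid(path: str | Path, indicator_id: str = "") -> ScoreRaster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    meta: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            meta[key.lower()] = float(val)
        grid = np.loadtxt(fh, ndmin=2)
    nodata = meta.get("nodata_value", NODATA_ON_DISK)
    grid[grid == nodata] = np.nan
    cell = meta["cellsize"]
    y_max = meta["yllcorner"] + meta["nrows"] * cell
    return ScoreRaster(grid, meta["xllcorner"], y_max, cell, indicator_id)


def write_quicklook(raster: ScoreRaster, path: str | Path, title: str | None = None) -> None:
    """Save a diverging-colormap PNG preview of a score raster."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 6))
    im = ax.imshow(raster.grid, cmap="RdBu_r", vmin=-1, vmax=1)
    fig.colorbar(im, ax=ax, label="score")
    ax.set_title(title or raster.indicator_id)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
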