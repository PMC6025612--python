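"""Inverse distance weighted (IDW) interpolation of point concentrations.

IDW estimates the value at a grid cell centre as a weighted average of
sample values with weights w_i = d_i^-p, where d_i is the distance to
sample i and p the power parameter.  The estimate is therefore always a
convex combination of the sample values (bounded by their min/max) and is
exact at sample locations (a cell centre within the snap tolerance of a
sample takes the sample's value, which also avoids the d=0 singularity).

Grids are regular, cell-centre registered, and masked to a site boundary
polygon; cells outside the boundary are NODATA.  Threshold-exceedance
summaries and leave-one-out cross-validation (for choosing p) operate on
the same machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry

__all__ = [
    "IDWConfig",
    "RasterGrid",
    "NODATA",
    "idw_interpolate",
    "idw_at_points",
    "exceedance_summary",
    "cross_validate_idw",
]

#: NODATA sentinel used on disk (ESRI ASCII convention); in memory the mask
#: is carried as NaN.
NODATA = -9999.0


@dataclass(frozen=True)
class IDWConfig:
    """IDW parameters.

    power
        Distance-decay exponent p > 0 (2 is the common convention).
    neighborhood
        ``"all"`` uses every sample; ``"k_nearest"`` the k closest;
        ``"radius"`` all samples within ``radius`` metres.
    cell_size
        Grid resolution in metres.
    snap_tolerance
        Cell centres within this distance of a sample take its value.
    """

    power: float = 2.0
    neighborhood: Literal["all", "k_nearest", "radius"] = "all"
    k: int = 12
    radius: float = 100.0
    cell_size: float = 5.0
    snap_tolerance: float = 1e-6

    def __post_init__(self) -> None:
        if not self.power > 0:
            raise ValueError(f"power must be > 0, got {self.power!r}")
        if not self.cell_size > 0:
            raise ValueError(f"cell size must be > 0, got {self.cell_size!r}")
        if self.neighborhood == "k_nearest" and self.k < 1:
            raise ValueError("k must be >= 1")
        if self.neighborhood == "radius" and not self.radius > 0:
            raise ValueError("radius must be > 0")
        if self.neighborhood not in ("all", "k_nearest", "radius"):
            raise ValueError(f"unknown neighborhood rule {self.neighborhood!r}")


@dataclass
class RasterGrid:
    """Regular cell-centre-registered grid of concentrations (mg/kg).

    ``values`` has shape (nrows, ncols) with row 0 at the TOP (north), the
    ESRI ASCII layout; NODATA cells are NaN.  (xllcorner, yllcorner) is the
    lower-left corner of the lower-left cell.
    """

    xllcorner: float
    yllcorner: float
    cell_size: float
    values: np.ndarray

    nrows: int = field(init=False)
    ncols: int = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("grid values must be 2-D")
        self.nrows, self.ncols = self.values.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) coordinate arrays of every cell centre, shaped like values."""
        xs = self.xllcorner + (np.arange(self.ncols) + 0.5) * self.cell_size
        ys = self.yllcorner + (np.arange(self.nrows)[::-1] + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    @property
    def mask(self) -> np.ndarray:
        """True where the cell holds data."""
        return ~np.isnan(self.values)

    def translated(self, dx: float, dy: float) -> "RasterGrid":
        return RasterGrid(self.xllcorner + dx, self.yllcorner + dy,
                          self.cell_size, self.values.copy())


def _neighbor_weights(d: np.ndarray, config: IDWConfig) -> np.ndarray:
    """Raw (unnormalised) IDW weights for one evaluation point.

    d: distances to all samples.  Samples outside the neighborhood get
    weight 0.  Distances are floored at the snap tolerance by the caller.
    """
    w = d ** (-config.power)
    if config.neighborhood == "k_nearest" and config.k < d.size:
        cutoff = np.partition(d, config.k - 1)[config.k - 1]
        w = np.where(d <= cutoff, w, 0.0)
    elif config.neighborhood == "radius":
        w = np.where(d <= config.radius, w, 0.0)
    return w


def idw_at_points(
    sample_xy: np.ndarray,
    sample_values: np.ndarray,
    query_xy: np.ndarray,
    config: IDWConfig = IDWConfig(),
) -> np.ndarray:
    """Evaluate the IDW surface at arbitrary points.

    Vectorised over query points; snapping to coincident samples applies.
    Raises if two distinct samples share coordinates (duplicates must be
    reconciled/averaged first so that exactness is well defined).
    """
    xy = np.asarray(sample_xy, dtype=float)
    v = np.asarray(sample_values, dtype=float)
    q = np.asarray(query_xy, dtype=float)
    if xy.shape[0] == 0:
        raise ValueError("IDW needs at least one sample")
    if xy.shape[0] > 1:
        d_ss = np.hypot(xy[:, None, 0] - xy[None, :, 0], xy[:, None, 1] - xy[None, :, 1])
        close = (d_ss < config.snap_tolerance) & ~np.eye(xy.shape[0], dtype=bool)
        if close.any():
            i, j = np.argwhere(close)[0]
            raise ValueError(
                f"samples {i} and {j} share coordinates (within snap tolerance); "
                "average duplicates before interpolating"
            )
    d = np.hypot(q[:, None, 0] - xy[None, :, 0], q[:, None, 1] - xy[None, :, 1])
    snapped = d < config.snap_tolerance          # (nq, ns)
    d_safe = np.maximum(d, config.snap_tolerance)
    out = np.empty(q.shape[0])
    for row in range(q.shape[0]):
        hit = np.flatnonzero(snapped[row])
        if hit.size:
            out[row] = v[hit[0]]
            continue
        w = _neighbor_weights(d_safe[row], config)
        total = w.sum()
        if total == 0:  # radius rule with no neighbours
            out[row] = np.nan
        else:
            out[row] = float(w @ v) / total
    return out


def idw_interpolate(
    sample_xy: np.ndarray,
    sample_values: np.ndarray,
    config: IDWConfig,
    boundary: BaseGeometry,
) -> RasterGrid:
    """Interpolate samples onto a regular grid clipped to a boundary polygon.

    The grid spans the boundary's bounding box at ``config.cell_size``;
    cells whose centre falls outside the boundary are NODATA (NaN).
    """
    if boundary.is_empty or boundary.area == 0:
        raise ValueError("boundary polygon is empty")
    minx, miny, maxx, maxy = boundary.bounds
    cs = config.cell_size
    ncols = max(1, int(np.ceil((maxx - minx) / cs)))
    nrows = max(1, int(np.ceil((maxy - miny) / cs)))
    grid = RasterGrid(minx, miny, cs, np.full((nrows, ncols), np.nan))
    gx, gy = grid.cell_centers()
    inside = shapely.contains_xy(boundary, gx.ravel(), gy.ravel())
    if inside.any():
        q = np.column_stack([gx.ravel()[inside], gy.ravel()[inside]])
        vals = idw_at_points(sample_xy, sample_values, q, config)
        flat = grid.values.ravel()
        flat[inside] = vals
        grid.values = flat.reshape(nrows, ncols)
    return grid


def exceedance_summary(grid: RasterGrid, threshold: float) -> dict:
    """Fraction and area of the mapped site above a concentration threshold.

    Returns ``fraction`` (of non-NODATA cells strictly above the threshold),
    ``area_m2`` (that cell count times cell_size^2), plus the counts.
    """
    data = grid.values[grid.mask]
    if data.size == 0:
        raise ValueError("grid contains no data cells")
    above = int((data > threshold).sum())
    return {
        "threshold": float(threshold),
        "n_cells": int(data.size),
        "n_above": above,
        "fraction": above / data.size,
        "area_m2": above * grid.cell_size ** 2,
    }


def cross_validate_idw(
    sample_xy: np.ndarray,
    sample_values: np.ndarray,
    config: IDWConfig = IDWConfig(),
) -> dict:
    """Leave-one-out cross-validation of the IDW surface.

    Each sample is predicted from all the others; returns the per-sample
    residuals (predicted - observed) and their RMSE.  Useful for choosing
    the power parameter, which survey reports rarely state.
    """
    xy = np.asarray(sample_xy, dtype=float)
    v = np.asarray(sample_values, dtype=float)
    n = xy.shape[0]
    if n < 3:
        raise ValueError(f"leave-one-out CV needs at least 3 samples, got {n}")
    residuals = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        pred = idw_at_points(xy[keep], v[keep], xy[i:i + 1], config)[0]
        residuals[i] = pred - v[i]
    return {"residuals": residuals, "rmse": float(np.sqrt(np.mean(residuals ** 2)))}
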