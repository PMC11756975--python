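"""The three volumetric estimators for quadrat vegetation.

* canopy height model (CHM): 0.01 m max-height raster with IDW gap fill;
  plot mean height times the 0.2 m^2 frame area is a volume,
* convex hull: volume of the smallest convex solid around the nonground
  points,
* voxel occupancy: count of occupied cubic cells times the cell volume,
  swept over edge lengths from 2 to 100 mm.

All volumes are carried in m^3 internally; reports convert to cm^3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .frames import QuadratFrame

#: voxel edge lengths (m) used in the size sweep: 2 mm to 100 mm
DEFAULT_EDGE_LENGTHS = (0.002, 0.005, 0.010, 0.020, 0.040, 0.050, 0.100)


@dataclass(frozen=True)
class ChmParams:
    """cell_size in m; fill_neighborhood is the odd window width (7 => 7x7)."""

    cell_size: float = 0.01
    fill_neighborhood: int = 7
    idw_power: float = 2.0

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.fill_neighborhood < 3 or self.fill_neighborhood % 2 == 0:
            raise ValueError("fill_neighborhood must be odd and >= 3")


@dataclass(frozen=True)
class VoxelParams:
    edge_lengths: tuple[float, ...] = DEFAULT_EDGE_LENGTHS

    def __post_init__(self) -> None:
        edges = tuple(self.edge_lengths)
        if not edges or any(e <= 0 for e in edges):
            raise ValueError("edge lengths must be positive")
        if list(edges) != sorted(edges):
            raise ValueError("edge lengths must be sorted ascending")
        object.__setattr__(self, "edge_lengths", edges)


@dataclass
class PlotVolumes:
    """Per-plot record of every volumetric estimate (m^3)."""

    plot_id: str
    chm_mean_height: float = 0.0
    chm_volume: float = 0.0
    hull_volume: float = 0.0
    voxel_volume: dict[float, float] = field(default_factory=dict)
    occupied_count: dict[float, int] = field(default_factory=dict)


class ChmResult(NamedTuple):
    grid: np.ndarray  # (nx, ny) heights, NaN where empty after filling
    mean_height: float
    volume: float
    empty: bool


class HullResult(NamedTuple):
    volume: float
    degenerate: bool


def compute_chm(
    xy: np.ndarray,
    heights: np.ndarray,
    frame: QuadratFrame,
    params: ChmParams = ChmParams(),
) -> ChmResult:
    """Rasterize max height-above-ground per cell and gap-fill by IDW.

    Empty cells take the inverse-distance-weighted (power ``idw_power``,
    cell-centre distances) mean of the non-empty cells inside the
    ``fill_neighborhood`` window; cells with no populated neighbour stay
    empty and are excluded from the plot mean.  volume = mean * frame area.
    """
    cs = params.cell_size
    nx = int(round(frame.width_x / cs))
    ny = int(round(frame.width_y / cs))
    grid = np.full((nx, ny), np.nan)

    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    heights = np.asarray(heights, dtype=float).reshape(-1)
    if len(xy) == 0:
        return ChmResult(grid, 0.0, 0.0, True)
    if (heights < 0).any():
        raise ValueError("heights above ground must be non-negative")

    ix = np.floor((xy[:, 0] - frame.x0) / cs).astype(int)
    iy = np.floor((xy[:, 1] - frame.y0) / cs).astype(int)
    inside = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
    ix, iy, h = ix[inside], iy[inside], heights[inside]
    if len(h) == 0:
        return ChmResult(grid, 0.0, 0.0, True)
    acc = np.full((nx, ny), -np.inf)
    np.maximum.at(acc, (ix, iy), h)
    populated = np.isfinite(acc)
    grid[populated] = acc[populated]

    filled = _idw_fill(grid, cs, params.fill_neighborhood, params.idw_power)
    valid = np.isfinite(filled)
    mean_height = float(filled[valid].mean()) if valid.any() else 0.0
    return ChmResult(filled, mean_height, mean_height * frame.area, not valid.any())


def _idw_fill(grid: np.ndarray, cell_size: float, window: int, power: float) -> np.ndarray:
    """Fill NaN cells from populated cells in a window x window neighbourhood."""
    half = window // 2
    nx, ny = grid.shape
    out = grid.copy()
    empty = ~np.isfinite(grid)
    if not empty.any():
        return out
    num = np.zeros_like(grid)
    den = np.zeros_like(grid)
    src = np.where(np.isfinite(grid), grid, 0.0)
    has = np.isfinite(grid).astype(float)
    for dx in range(-half, half + 1):
        for dy in range(-half, half + 1):
            if dx == 0 and dy == 0:
                continue
            w = 1.0 / (cell_size * np.hypot(dx, dy)) ** power
            # shifted source contributing to each target cell
            tx0, tx1 = max(0, -dx), min(nx, nx - dx)
            ty0, ty1 = max(0, -dy), min(ny, ny - dy)
            sx0, sx1 = tx0 + dx, tx1 + dx
            sy0, sy1 = ty0 + dy, ty1 + dy
            num[tx0:tx1, ty0:ty1] += w * src[sx0:sx1, sy0:sy1] * has[sx0:sx1, sy0:sy1]
            den[tx0:tx1, ty0:ty1] += w * has[sx0:sx1, sy0:sy1]
    fixable = empty & (den > 0)
    out[fixable] = num[fixable] / den[fixable]
    return out


def convex_hull_volume(points: np.ndarray) -> HullResult:
    """3-D convex hull volume (m^3); degenerate inputs yield volume 0, flagged."""
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(points) < 4:
        return HullResult(0.0, True)
    try:
        hull = ConvexHull(points)
    except QhullError:
        return HullResult(0.0, True)
    return HullResult(float(hull.volume), False)


def voxel_volume(
    points: np.ndarray, edge: float, origin: np.ndarray | tuple[float, float, float]
) -> tuple[int, float]:
    """Occupancy voxelization: floor((p - origin)/edge), half-open cells.

    Returns (number of occupied voxels, occupied count * edge^3 in m^3).
    """
    if edge <= 0:
        raise ValueError("voxel edge must be positive")
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(points) == 0:
        return 0, 0.0
    idx = np.floor((points - np.asarray(origin, dtype=float)) / edge).astype(np.int64)
    count = len(np.unique(idx, axis=0))
    return count, count * edge**3


def voxel_size_sweep(
    points: np.ndarray,
    params: VoxelParams,
    origin: np.ndarray | tuple[float, float, float],
) -> tuple[dict[float, int], dict[float, float]]:
    """voxel_volume at every edge length with a shared origin."""
    counts: dict[float, int] = {}
    vols: dict[float, float] = {}
    for edge in params.edge_lengths:
        counts[edge], vols[edge] = voxel_volume(points, edge, origin)
    return counts, vols
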