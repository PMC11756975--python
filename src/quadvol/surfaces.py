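"""Ground-surface fitting and reconstructed-vs-reference comparisons.

The terrain model is a regular 0.01 m grid of elevations fitted from
ground-classified points: linear interpolation over a Delaunay
triangulation (exact on planes), with nearest-ground-point extrapolation
outside the triangulation's hull, so the grid has no empty cells.
Vegetation points strictly above the terrain elevation of their cell are
the "above-surface" subset used by the stricter volume variants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import QhullError, cKDTree

from .allometry import lins_ccc, tls_fit
from .frames import QuadratFrame
from .io import LABEL_VEGETATION, PointCloud


@dataclass
class TerrainGrid:
    """Ground elevations (m) on a regular grid over the quadrat frame.

    z has shape (nx, ny); cell (i, j) covers the half-open square
    [x0 + i*cs, x0 + (i+1)*cs) x [y0 + j*cs, y0 + (j+1)*cs).
    """

    x0: float
    y0: float
    cell_size: float
    z: np.ndarray

    @property
    def nx(self) -> int:
        return self.z.shape[0]

    @property
    def ny(self) -> int:
        return self.z.shape[1]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        cx = self.x0 + (np.arange(self.nx) + 0.5) * self.cell_size
        cy = self.y0 + (np.arange(self.ny) + 0.5) * self.cell_size
        return cx, cy

    def elevation_at(self, xy: np.ndarray) -> np.ndarray:
        """Terrain elevation of the containing cell; NaN outside the grid."""
        xy = np.asarray(xy, dtype=float).reshape(-1, 2)
        ix = np.floor((xy[:, 0] - self.x0) / self.cell_size).astype(int)
        iy = np.floor((xy[:, 1] - self.y0) / self.cell_size).astype(int)
        inside = (ix >= 0) & (ix < self.nx) & (iy >= 0) & (iy < self.ny)
        out = np.full(len(xy), np.nan)
        out[inside] = self.z[ix[inside], iy[inside]]
        return out

    def to_esri_ascii(self, path) -> None:
        """ESRI ASCII grid (rows north to south)."""
        header = (
            f"ncols {self.nx}\nnrows {self.ny}\n"
            f"xllcorner {self.x0}\nyllcorner {self.y0}\n"
            f"cellsize {self.cell_size}\nNODATA_value -9999\n"
        )
        rows = self.z.T[::-1]  # row 0 = northernmost
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, rows, fmt="%.6f")


def read_esri_ascii(path) -> TerrainGrid:
    with open(path) as fh:
        meta = {}
        for _ in range(6):
            key, value = fh.readline().split()
            meta[key.lower()] = float(value)
        rows = np.loadtxt(fh)
    z = rows[::-1].T
    grid = TerrainGrid(meta["xllcorner"], meta["yllcorner"], meta["cellsize"], z)
    nodata = meta.get("nodata_value")
    if nodata is not None:
        grid.z = np.where(grid.z == nodata, np.nan, grid.z)
    return grid


def fit_ground_surface(
    ground_points: np.ndarray,
    frame: QuadratFrame,
    cell_size: float = 0.01,
) -> TerrainGrid:
    """Fit the terrain grid from ground-classified points.

    Per-cell elevation is the Delaunay linear interpolation evaluated at
    the cell centre; cells outside the convex hull of the ground points
    take the elevation of the nearest ground point, so no cell is empty.
    Fewer than 3 points, or collinear points, are an error.
    """
    pts = np.asarray(ground_points, dtype=float).reshape(-1, 3)
    if len(pts) < 3:
        raise ValueError("need at least 3 ground points to fit a surface")
    nx = int(round(frame.width_x / cell_size))
    ny = int(round(frame.width_y / cell_size))
    cx = frame.x0 + (np.arange(nx) + 0.5) * cell_size
    cy = frame.y0 + (np.arange(ny) + 0.5) * cell_size
    gx, gy = np.meshgrid(cx, cy, indexing="ij")
    try:
        interp = LinearNDInterpolator(pts[:, :2], pts[:, 2])
    except QhullError as exc:
        raise ValueError(f"ground points are degenerate (collinear?): {exc}") from exc
    z = interp(gx, gy)
    missing = np.isnan(z)
    if missing.any():
        tree = cKDTree(pts[:, :2])
        _, nearest = tree.query(np.column_stack([gx[missing], gy[missing]]))
        z[missing] = pts[nearest, 2]
    return TerrainGrid(frame.x0, frame.y0, cell_size, z)


def points_above_surface(
    cloud: PointCloud,
    labels: np.ndarray,
    terrain: TerrainGrid,
) -> tuple[PointCloud, np.ndarray, int]:
    """Vegetation-labeled points strictly above the terrain surface.

    Returns (subset cloud, per-point height above ground, count of
    vegetation points that fell outside the terrain grid and were
    excluded).  Heights use the elevation of the containing cell.
    """
    labels = np.asarray(labels).reshape(-1)
    if len(labels) != len(cloud):
        raise ValueError("labels length does not match cloud")
    if np.isnan(terrain.z).any():
        raise ValueError("terrain grid has empty cells")
    veg = labels == LABEL_VEGETATION
    elev = terrain.elevation_at(cloud.coords[:, :2])
    outside = veg & np.isnan(elev)
    keep = veg & ~np.isnan(elev) & (cloud.z > elev)
    heights = (cloud.z - elev)[keep]
    return cloud.select(keep), heights, int(outside.sum())


@dataclass(frozen=True)
class AgreementReport:
    """Agreement between reconstructed- and reference-surface volumes."""

    mean_abs_rel_diff: float
    r_squared: float
    tls_slope: float
    tls_intercept: float
    ccc: float
    n: int


def surface_agreement(
    recon_volumes: np.ndarray, reference_volumes: np.ndarray
) -> AgreementReport:
    """Compare per-plot volumes computed above the two ground surfaces.

    Reports the mean absolute relative difference (relative to the
    reference), ordinary-regression R^2, the total-least-squares line,
    and Lin's concordance correlation coefficient.
    """
    recon = np.asarray(recon_volumes, dtype=float)
    ref = np.asarray(reference_volumes, dtype=float)
    if len(recon) != len(ref) or len(recon) < 3:
        raise ValueError("need paired volume vectors of length >= 3")
    if np.ptp(recon) == 0 or np.ptp(ref) == 0:
        raise ValueError("zero variance in volumes")
    if (ref <= 0).any():
        raise ValueError("reference volumes must be positive")
    rel = np.abs(recon - ref) / ref
    r = np.corrcoef(recon, ref)[0, 1]
    line = tls_fit(ref, recon)
    return AgreementReport(
        mean_abs_rel_diff=float(rel.mean()),
        r_squared=float(r**2),
        tls_slope=line.slope,
        tls_intercept=line.intercept,
        ccc=lins_ccc(ref, recon),
        n=len(recon),
    )
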