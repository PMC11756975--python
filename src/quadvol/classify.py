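"""Ground / vegetation classification for litter-covered quadrats.

Two stages, mirroring the workflow the package is built around:

1. **SMRF** (simple morphological filter): rasterize the minimum
   elevation, progressively open the raster with growing windows to strip
   off above-ground objects, and label points within an elevation
   threshold of the resulting provisional ground surface as ground.
   With the default 11 cm threshold this is deliberately permissive — a
   litter mat a few centimetres thick and the bases of grass stems all
   land in the ground class.

2. **Iterative Gaussian-mixture refinement**: on the current ground
   class, compute a per-point roughness feature (surface variation, a
   bounded curvature proxy, by default; raw elevation optionally), split
   it with a two-component 1-D Gaussian mixture, and move the
   high-component (rough, vegetation-like) points into the vegetation
   class.  The merge is additive — points only ever move ground ->
   vegetation.  A merge is kept only while it grows the vegetation voxel
   volume by more than the improvement fraction (default 5%); the first
   merge that fails this test is reverted and iteration stops.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from sklearn.mixture import GaussianMixture

from .frames import QuadratFrame
from .io import LABEL_GROUND, LABEL_VEGETATION, PointCloud
from .volumes import voxel_volume


@dataclass(frozen=True)
class SmrfParams:
    """Morphological ground-filter parameters.

    elevation_threshold (m): max distance from the provisional ground
    surface for a point to be called ground.  slope_threshold
    (dimensionless) and elevation_scale scale the per-window object cut:
    a raster cell is flagged non-ground at window radius r when it rises
    more than elevation_scale * slope_threshold * r * cell_size above the
    opened surface.
    """

    cell_size: float = 0.01
    elevation_threshold: float = 0.11
    slope_threshold: float = 0.1
    elevation_scale: float = 0.9
    max_window_radius: int = 10

    def __post_init__(self) -> None:
        if min(self.cell_size, self.elevation_threshold, self.slope_threshold,
               self.elevation_scale) <= 0:
            raise ValueError("all SMRF parameters must be positive")
        if self.max_window_radius < 1:
            raise ValueError("max_window_radius must be >= 1")


@dataclass(frozen=True)
class RefineParams:
    """Gaussian-mixture refinement: neighbourhood sizes for the curvature
    passes (50 then 200 neighbours; the 200-neighbour pass runs on the
    ground output of the 50-neighbour pass), stopping fraction for the
    vegetation-volume improvement, and the voxel edge used to measure it."""

    neighbor_counts: tuple[int, ...] = (50, 200)
    improvement_fraction: float = 0.05
    volume_voxel_edge: float = 0.005
    feature: str = "curvature"
    max_iterations: int = 10

    def __post_init__(self) -> None:
        if not self.neighbor_counts or any(k < 1 for k in self.neighbor_counts):
            raise ValueError("neighbor_counts must be positive")
        if not 0 < self.improvement_fraction < 1:
            raise ValueError("improvement_fraction must be in (0, 1)")
        if self.feature not in ("curvature", "elevation"):
            raise ValueError("feature must be 'curvature' or 'elevation'")


@dataclass
class ClassificationResult:
    labels: np.ndarray  # per-point, {1 = ground, 2 = vegetation}
    iterations_run: int
    vegetation_volume_trace: list[float] = field(default_factory=list)


class DegenerateMixtureError(ValueError):
    """All feature values identical: a two-component split is meaningless."""


def _disk_footprint(radius: int) -> np.ndarray:
    r = np.arange(-radius, radius + 1)
    xx, yy = np.meshgrid(r, r, indexing="ij")
    return (xx**2 + yy**2) <= radius**2


def _nearest_fill(grid: np.ndarray, invalid: np.ndarray) -> np.ndarray:
    """Replace invalid cells with the value of the nearest valid cell."""
    if not invalid.any():
        return grid
    if invalid.all():
        raise ValueError("no valid cells to fill from")
    idx = ndimage.distance_transform_edt(invalid, return_distances=False, return_indices=True)
    return grid[tuple(idx)]


def smrf_classify(
    cloud: PointCloud,
    params: SmrfParams = SmrfParams(),
    frame: QuadratFrame | None = None,
) -> np.ndarray:
    """SMRF ground filter; returns per-point labels {1=ground, 2=vegetation}.

    Steps: (1) minimum-z raster at ``cell_size`` over the frame (or the
    cloud's bounding box); (2) empty cells inpainted from their nearest
    populated neighbour; (3) progressive morphological opening with disk
    windows of radius 1..max_window_radius, flagging cells that exceed
    the opened surface by the slope-scaled threshold; (4) points within
    ``elevation_threshold`` of the interpolated provisional ground
    surface are ground, the rest vegetation.
    """
    if len(cloud) == 0:
        raise ValueError("cannot classify an empty cloud")
    cs = params.cell_size
    if frame is not None:
        x0, y0 = frame.x0, frame.y0
        nx = int(round(frame.width_x / cs))
        ny = int(round(frame.width_y / cs))
    else:
        x0, y0 = cloud.x.min(), cloud.y.min()
        nx = int(np.ceil((cloud.x.max() - x0) / cs)) or 1
        ny = int(np.ceil((cloud.y.max() - y0) / cs)) or 1
    if nx < 2 or ny < 2:
        raise ValueError(f"cloud extent spans {nx} x {ny} cells; need >= 2 per axis")

    ix = np.clip(np.floor((cloud.x - x0) / cs).astype(int), 0, nx - 1)
    iy = np.clip(np.floor((cloud.y - y0) / cs).astype(int), 0, ny - 1)

    minz = np.full((nx, ny), np.inf)
    np.minimum.at(minz, (ix, iy), cloud.z)
    empty = ~np.isfinite(minz)
    minz = _nearest_fill(np.where(empty, 0.0, minz), empty)

    surface = minz.copy()
    object_cells = np.zeros((nx, ny), dtype=bool)
    for radius in range(1, params.max_window_radius + 1):
        opened = ndimage.grey_opening(surface, footprint=_disk_footprint(radius))
        cut = params.elevation_scale * params.slope_threshold * radius * cs
        object_cells |= (surface - opened) > cut
        surface = opened

    ground_raster = _nearest_fill(minz, object_cells | empty)
    dz = cloud.z - ground_raster[ix, iy]
    labels = np.where(np.abs(dz) <= params.elevation_threshold,
                      LABEL_GROUND, LABEL_VEGETATION)
    return labels.astype(np.int64)


def estimate_curvature(cloud: PointCloud, k: int, chunk: int = 20_000) -> np.ndarray:
    """Surface variation lam3/(lam1+lam2+lam3) of each point's k-neighbourhood.

    Eigenvalues of the covariance of the point plus its k nearest
    neighbours; 0 for a perfect plane, up to 1/3 for isotropic scatter.
    """
    n = len(cloud)
    if k < 3:
        raise ValueError("k must be >= 3")
    if n <= k:
        raise ValueError(f"cloud has {n} points; need more than k={k}")
    tree = cKDTree(cloud.coords)
    out = np.empty(n)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        _, idx = tree.query(cloud.coords[start:stop], k=k + 1)
        nbrs = cloud.coords[idx]  # (m, k+1, 3)
        nbrs = nbrs - nbrs.mean(axis=1, keepdims=True)
        cov = np.einsum("mki,mkj->mij", nbrs, nbrs) / (k + 1)
        eig = np.linalg.eigvalsh(cov)  # ascending
        total = eig.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(total > 0, eig[:, 0] / total, 0.0)
        out[start:stop] = np.clip(ratio, 0.0, 1.0 / 3.0)
    return out


def gmm_two_component_split(values: np.ndarray, seed: int = 0) -> np.ndarray:
    """Fit a two-component 1-D Gaussian mixture by EM; True = high-mean component.

    Initialisation is deterministic (components started at the 10th and
    90th percentiles with the sample variance), EM capped at 100
    iterations, tolerance 1e-6.  Ties in posterior go to the low (ground-
    like) component.
    """
    values = np.asarray(values, dtype=float).reshape(-1, 1)
    if len(values) < 2 or np.ptp(values) == 0:
        raise DegenerateMixtureError("feature values are constant; cannot split")
    q10, q90 = np.quantile(values, [0.10, 0.90])
    if q10 == q90:
        q10, q90 = values.min(), values.max()
    var = max(values.var(), 1e-30)
    gmm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        means_init=np.array([[q10], [q90]]),
        weights_init=np.array([0.5, 0.5]),
        precisions_init=np.array([[[1.0 / var]], [[1.0 / var]]]),
        max_iter=100,
        tol=1e-6,
        reg_covar=1e-12,
        random_state=seed,
    )
    with warnings.catch_warnings():
        # EM occasionally stops at max_iter without reaching tol; the
        # assignment boundary is stable well before that
        warnings.simplefilter("ignore")
        gmm.fit(values)
    means = gmm.means_.ravel()
    hi = int(np.argmax(means))
    post = gmm.predict_proba(values)
    return post[:, hi] > post[:, 1 - hi]


def iterative_refine(
    cloud: PointCloud,
    smrf_labels: np.ndarray,
    refine: RefineParams = RefineParams(),
    seed: int = 0,
    voxel_origin: np.ndarray | tuple[float, float, float] | None = None,
) -> ClassificationResult:
    """Iteratively move rough ground-class points into the vegetation class.

    Each pass: feature on the current ground class (neighbor_counts[0]
    neighbours on the first pass, neighbor_counts[-1] on later passes,
    each pass consuming the previous pass's ground output), two-component
    Gaussian-mixture split, candidate merge of the high component into
    vegetation.  The candidate is kept only if the vegetation voxel
    volume (at ``volume_voxel_edge``) improves by more than
    ``improvement_fraction``; otherwise it is reverted and the loop
    stops.  An initially empty vegetation class terminates immediately
    (there is no volume to measure improvement against).
    """
    labels = np.asarray(smrf_labels, dtype=np.int64).copy()
    if len(labels) != len(cloud):
        raise ValueError("labels length does not match cloud")
    if voxel_origin is None:
        voxel_origin = cloud.coords.min(axis=0)
    edge = refine.volume_voxel_edge

    def veg_volume(lab: np.ndarray) -> float:
        return voxel_volume(cloud.coords[lab == LABEL_VEGETATION], edge, voxel_origin)[1]

    volume = veg_volume(labels)
    trace = [volume]
    iterations = 0
    for it in range(refine.max_iterations):
        if volume == 0.0:
            break
        ground_idx = np.flatnonzero(labels == LABEL_GROUND)
        k = refine.neighbor_counts[0] if it == 0 else refine.neighbor_counts[-1]
        if len(ground_idx) <= max(k, 3):
            break
        sub = cloud.select(ground_idx)
        if refine.feature == "curvature":
            feat = estimate_curvature(sub, k)
        else:
            feat = sub.z
        try:
            high = gmm_two_component_split(feat, seed=seed + it)
        except DegenerateMixtureError:
            break
        if not high.any():
            break
        candidate = labels.copy()
        candidate[ground_idx[high]] = LABEL_VEGETATION
        cand_volume = veg_volume(candidate)
        iterations += 1
        if (cand_volume - volume) / volume > refine.improvement_fraction:
            labels, volume = candidate, cand_volume
            trace.append(volume)
        else:
            break
    return ClassificationResult(labels=labels, iterations_run=iterations,
                                vegetation_volume_trace=trace)


def classify_cloud(
    cloud: PointCloud,
    smrf: SmrfParams = SmrfParams(),
    refine: RefineParams = RefineParams(),
    frame: QuadratFrame | None = None,
    seed: int = 0,
) -> ClassificationResult:
    """SMRF followed by iterative Gaussian-mixture refinement."""
    smrf_labels = smrf_classify(cloud, smrf, frame=frame)
    return iterative_refine(cloud, smrf_labels, refine, seed=seed)
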