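"""Synthetic photo-quadrat scenes with exact ground truth.

Emulates what close-range SfM sees on an annual-grass rangeland plot:
smooth mineral-soil microtopography, a rough litter mat covering a known
fraction of the frame, and fine curved grass stems — sampled as surface
point clouds at a realistic density with a hard minimum point spacing,
and with ground points under litter removed stochastically (SfM cannot
see through the mat).  Every sampled point carries an exact class label
(ground / litter / stem), the analytic terrain is available on the
reference grid, and reference vegetation volumes can be voxelized from
the analytic geometry, so every pipeline stage is testable without field
data.

Label conventions: ``true_labels`` are 3-class (1 ground, 2 stem, 3
litter); ``binary_labels`` collapses them to the classifier's 2-class
convention where nonground = litter + stems.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .frames import QuadratFrame
from .io import LABEL_GROUND, LABEL_VEGETATION, BiomassRecord, PointCloud
from .surfaces import TerrainGrid
from .volumes import voxel_volume

TRUE_GROUND = 1
TRUE_STEM = 2
TRUE_LITTER = 3

#: mask resolution (m) used to draw and measure litter cover
_MASK_CELL = 0.002


@dataclass(frozen=True)
class SceneParams:
    """Study-condition knobs for one synthetic quadrat.

    Defaults mirror the field setting the package targets: ~2 cm soil
    microrelief, a litter mat over 60% of the frame ~3 cm thick, 300
    fine stems 5-60 cm tall, 0.5 million points/m^2 with a 1 mm minimum
    spacing, and strong (70%) occlusion of the soil beneath litter.
    """

    seed: int = 0
    terrain_relief_m: float = 0.02
    litter_cover_fraction: float = 0.6
    litter_thickness_m: float = 0.03
    stem_count: int = 300
    stem_height_range_m: tuple[float, float] = (0.05, 0.6)
    stem_radius_range_m: tuple[float, float] = (0.001, 0.003)
    point_density_per_m2: float = 5e5
    min_spacing_m: float = 0.001
    occlusion_strength: float = 0.7
    soil_noise_m: float = 0.0003
    litter_roughness_m: float = 0.004
    stem_capture_fraction: float = 0.25
    litter_affinity: float = 0.8

    def __post_init__(self) -> None:
        if not 0 <= self.litter_cover_fraction <= 1:
            raise ValueError("litter_cover_fraction must be in [0, 1]")
        if not 0 <= self.occlusion_strength <= 1:
            raise ValueError("occlusion_strength must be in [0, 1]")
        for name in ("terrain_relief_m", "litter_thickness_m",
                     "point_density_per_m2", "min_spacing_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.stem_count < 0:
            raise ValueError("stem_count must be >= 0")


@dataclass(frozen=True)
class AllometryModel:
    """Power-law volume -> biomass generator with multiplicative noise.

    total_g = coefficient_g * (V / reference_volume_m3)^exponent *
    exp(N(0, noise_sd_log^2)); the total splits into litter
    (litter_fraction_of_total) and vegetation, the latter divided
    annual:perennial:forb = 0.8:0.15:0.05.  The coefficient and reference
    volume put a typical plot near the ~900 g cohort mean the package's
    study system exhibits.
    """

    coefficient_g: float = 800.0
    exponent: float = 1.0
    noise_sd_log: float = 0.5
    litter_fraction_of_total: float = 0.6
    #: typical true 5 mm voxel volume of a default scene; normalising by it
    #: puts the cohort mean near the ~900 g the study system exhibits
    reference_volume_m3: float = 7e-3
    component_split: tuple[float, float, float] = (0.8, 0.15, 0.05)

    def __post_init__(self) -> None:
        if self.coefficient_g <= 0 or self.reference_volume_m3 <= 0:
            raise ValueError("coefficient and reference volume must be positive")
        if self.noise_sd_log < 0:
            raise ValueError("noise_sd_log must be >= 0")
        if not 0 <= self.litter_fraction_of_total <= 1:
            raise ValueError("litter_fraction_of_total must be in [0, 1]")


@dataclass
class SyntheticScene:
    """Parametric scene: analytic terrain, litter mask, stem geometry."""

    params: SceneParams
    frame: QuadratFrame
    # terrain = relief-scaled sum of low-frequency sinusoids
    _amps: np.ndarray = field(repr=False, default=None)
    _waves: np.ndarray = field(repr=False, default=None)  # (k, 2) wave vectors, rad/m
    _phases: np.ndarray = field(repr=False, default=None)
    litter_mask: np.ndarray = field(repr=False, default=None)  # bool, _MASK_CELL grid
    stem_base: np.ndarray = field(repr=False, default=None)  # (S, 2)
    stem_height: np.ndarray = field(repr=False, default=None)
    stem_radius: np.ndarray = field(repr=False, default=None)
    stem_lean: np.ndarray = field(repr=False, default=None)  # (S, 2) tip offset
    stem_bow: np.ndarray = field(repr=False, default=None)  # (S, 2) mid-bow offset
    stem_facing: np.ndarray = field(repr=False, default=None)  # visible-side azimuth

    def terrain_z(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Exact analytic soil elevation (m)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        z = np.zeros(np.broadcast(x, y).shape)
        for a, (kx, ky), ph in zip(self._amps, self._waves, self._phases):
            z = z + a * np.sin(kx * x + ky * y + ph)
        return z

    def litter_at(self, xy: np.ndarray) -> np.ndarray:
        """Boolean litter-cover lookup on the drawing mask."""
        xy = np.asarray(xy, dtype=float).reshape(-1, 2)
        ix = np.floor((xy[:, 0] - self.frame.x0) / _MASK_CELL).astype(int)
        iy = np.floor((xy[:, 1] - self.frame.y0) / _MASK_CELL).astype(int)
        ix = np.clip(ix, 0, self.litter_mask.shape[0] - 1)
        iy = np.clip(iy, 0, self.litter_mask.shape[1] - 1)
        return self.litter_mask[ix, iy]

    @property
    def litter_cover_measured(self) -> float:
        return float(self.litter_mask.mean())

    def reference_ground(self, cell_size: float = 0.01) -> TerrainGrid:
        """Analytic terrain on the standard grid — the oracle ground surface."""
        nx = int(round(self.frame.width_x / cell_size))
        ny = int(round(self.frame.width_y / cell_size))
        cx = self.frame.x0 + (np.arange(nx) + 0.5) * cell_size
        cy = self.frame.y0 + (np.arange(ny) + 0.5) * cell_size
        gx, gy = np.meshgrid(cx, cy, indexing="ij")
        return TerrainGrid(self.frame.x0, self.frame.y0, cell_size, self.terrain_z(gx, gy))

    def stem_axis(self, s: int, t: np.ndarray) -> np.ndarray:
        """Centre-line of stem s at parameter t in [0, 1] -> (len(t), 3)."""
        t = np.asarray(t, dtype=float)
        base = self.stem_base[s]
        xy = (
            base
            + np.outer(t, self.stem_lean[s])
            + np.outer(np.sin(np.pi * t), self.stem_bow[s])
        )
        z0 = float(self.terrain_z(base[0], base[1]))
        z = z0 + t * self.stem_height[s]
        return np.column_stack([xy, z])


def generate_scene(params: SceneParams, frame: QuadratFrame | None = None) -> SyntheticScene:
    """Build a deterministic scene from the seed.

    The litter mat is drawn as overlapping random discs added until the
    measured covered area (on a 2 mm mask) is within ~+/-1.5% of the
    requested fraction; stems root on the terrain with random lean and
    bow.
    """
    frame = frame or QuadratFrame()
    rng = np.random.default_rng(params.seed)

    k = 3
    amps = params.terrain_relief_m * np.array([0.5, 0.3, 0.2])
    wavelengths = rng.uniform(0.25, 0.6, size=k)
    theta = rng.uniform(0, 2 * np.pi, size=k)
    waves = (2 * np.pi / wavelengths)[:, None] * np.column_stack([np.cos(theta), np.sin(theta)])
    phases = rng.uniform(0, 2 * np.pi, size=k)

    nx = int(round(frame.width_x / _MASK_CELL))
    ny = int(round(frame.width_y / _MASK_CELL))
    mask = np.zeros((nx, ny), dtype=bool)
    target = params.litter_cover_fraction
    if target > 0:
        cx = (np.arange(nx) + 0.5) * _MASK_CELL
        cy = (np.arange(ny) + 0.5) * _MASK_CELL
        gx, gy = np.meshgrid(cx, cy, indexing="ij")
        max_radius = 0.05
        rejects = 0
        while mask.mean() < target - 0.005:
            r = rng.uniform(0.015, max_radius)
            px = rng.uniform(0, frame.width_x)
            py = rng.uniform(0, frame.width_y)
            disc = (gx - px) ** 2 + (gy - py) ** 2 <= r**2
            candidate = mask | disc
            if candidate.mean() > target + 0.015:
                rejects += 1
                if rejects >= 25:
                    max_radius = max(0.015, max_radius * 0.6)
                    rejects = 0
                continue
            mask = candidate

    s = params.stem_count
    # annual grasses grow up through their own prior-year litter, so stems
    # root preferentially inside mat patches (litter_affinity) when any exist
    base = np.column_stack(
        [
            frame.x0 + rng.uniform(0, frame.width_x, size=s),
            frame.y0 + rng.uniform(0, frame.width_y, size=s),
        ]
    )
    if mask.any() and s:
        in_litter = rng.random(s) < params.litter_affinity
        litter_cells = np.argwhere(mask)
        pick = rng.integers(0, len(litter_cells), size=int(in_litter.sum()))
        cells = litter_cells[pick]
        jitter = rng.uniform(0, _MASK_CELL, size=(len(cells), 2))
        base[in_litter] = (
            np.array([frame.x0, frame.y0]) + cells * _MASK_CELL + jitter
        )
    height = rng.uniform(*params.stem_height_range_m, size=s)
    radius = rng.uniform(*params.stem_radius_range_m, size=s)
    lean_mag = rng.uniform(0.0, 0.3, size=s) * height
    lean_dir = rng.uniform(0, 2 * np.pi, size=s)
    lean = lean_mag[:, None] * np.column_stack([np.cos(lean_dir), np.sin(lean_dir)])
    bow_mag = rng.uniform(0.0, 0.1, size=s) * height
    bow_dir = rng.uniform(0, 2 * np.pi, size=s)
    bow = bow_mag[:, None] * np.column_stack([np.cos(bow_dir), np.sin(bow_dir)])
    facing = rng.uniform(0, 2 * np.pi, size=s)

    return SyntheticScene(
        params=params,
        frame=frame,
        _amps=amps,
        _waves=waves,
        _phases=phases,
        litter_mask=mask,
        stem_base=base,
        stem_height=height,
        stem_radius=radius,
        stem_lean=lean,
        stem_bow=bow,
        stem_facing=facing,
    )


def _jittered_lattice(
    frame: QuadratFrame, density: float, min_spacing: float, rng: np.random.Generator,
    offset: float = 0.0,
) -> np.ndarray:
    """Near-uniform (x, y) samples at the requested areal density.

    A square lattice at spacing 1/sqrt(density) with per-axis jitter
    bounded so that within-lattice spacing never drops below
    min_spacing.  SfM clouds filtered to a minimum point spacing are
    similarly quasi-uniform.
    """
    a = 1.0 / np.sqrt(density)
    if a < min_spacing:
        raise ValueError("requested density incompatible with min spacing")
    nx = int(round(frame.width_x / a))
    ny = int(round(frame.width_y / a))
    gx, gy = np.meshgrid(
        frame.x0 + (np.arange(nx) + 0.5 + offset) * a,
        frame.y0 + (np.arange(ny) + 0.5 + offset) * a,
        indexing="ij",
    )
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    j = 0.45 * (a - min_spacing)
    pts += rng.uniform(-j, j, size=pts.shape)
    return pts


class SampledCloud:
    """A sampled scene: the point cloud plus exact 3-class truth."""

    def __init__(self, cloud: PointCloud, true_labels: np.ndarray):
        self.cloud = cloud
        self.true_labels = np.asarray(true_labels, dtype=np.int64)

    @property
    def binary_labels(self) -> np.ndarray:
        """Classifier truth: nonground (litter + stems) vs ground."""
        return np.where(self.true_labels == TRUE_GROUND, LABEL_GROUND, LABEL_VEGETATION)


def sample_cloud(scene: SyntheticScene) -> SampledCloud:
    """Surface-sample the scene into a labeled point cloud.

    Soil and litter tops are sampled on jittered lattices at the scene
    density; stems as rings of points along each curved axis, captured
    with a top-weighted probability (seed heads and awns dominate what
    SfM reconstructs of a fine grass stem).  Ground points beneath
    litter are dropped with probability ``occlusion_strength``.  A final
    close-pair sweep enforces the global minimum point spacing.
    """
    p = scene.params
    frame = scene.frame
    if p.point_density_per_m2 * frame.area < 100:
        raise ValueError("scene too sparse: density * area < 100 points")
    rng = np.random.default_rng(p.seed + 1)

    # soil
    gxy = _jittered_lattice(frame, p.point_density_per_m2, p.min_spacing_m, rng)
    gz = scene.terrain_z(gxy[:, 0], gxy[:, 1]) + rng.normal(0, p.soil_noise_m, len(gxy))
    under = scene.litter_at(gxy)
    occluded = under & (rng.random(len(gxy)) < p.occlusion_strength)
    gxy, gz = gxy[~occluded], gz[~occluded]

    # litter mat top surface
    lxy = _jittered_lattice(frame, p.point_density_per_m2, p.min_spacing_m, rng, offset=0.31)
    on_litter = scene.litter_at(lxy)
    lxy = lxy[on_litter]
    lz = (
        scene.terrain_z(lxy[:, 0], lxy[:, 1])
        + p.litter_thickness_m
        + rng.normal(0, p.litter_roughness_m, len(lxy))
    )

    # stems
    stem_pts = []
    ring_step = 1.3 * p.min_spacing_m
    for s in range(p.stem_count):
        h, r = scene.stem_height[s], scene.stem_radius[s]
        n_rings = max(2, int(np.ceil(h / ring_step)))
        t = (np.arange(n_rings) + 0.5) / n_rings
        axis = scene.stem_axis(s, t)
        m = max(1, int(np.floor(np.pi * r / ring_step)))
        theta = scene.stem_facing[s] + np.pi * (np.arange(m) + 0.5) / m
        offsets = r * np.column_stack([np.cos(theta), np.sin(theta), np.zeros(m)])
        pts = (axis[:, None, :] + offsets[None, :, :]).reshape(-1, 3)
        t_all = np.repeat(t, m)
        keep_prob = np.clip(p.stem_capture_fraction * (0.3 + 1.4 * t_all), 0.0, 1.0)
        keep = rng.random(len(pts)) < keep_prob
        stem_pts.append(pts[keep])
    sxyz = np.concatenate(stem_pts) if stem_pts else np.empty((0, 3))
    if len(sxyz):
        inside = frame.contains(sxyz[:, :2])
        sxyz = sxyz[inside]
    if len(sxyz):
        # the mat occludes stem bottoms: no SfM point forms on a stem segment
        # buried inside or below the litter layer
        buried = scene.litter_at(sxyz[:, :2]) & (
            sxyz[:, 2] < scene.terrain_z(sxyz[:, 0], sxyz[:, 1]) + p.litter_thickness_m
        )
        sxyz = sxyz[~buried]

    coords = np.concatenate(
        [np.column_stack([gxy, gz]), np.column_stack([lxy, lz]), sxyz]
    )
    labels = np.concatenate(
        [
            np.full(len(gxy), TRUE_GROUND),
            np.full(len(lxy), TRUE_LITTER),
            np.full(len(sxyz), TRUE_STEM),
        ]
    )

    # global minimum-spacing sweep: later points (stems) yield to earlier ones
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=p.min_spacing_m * (1 - 1e-12), output_type="ndarray")
    alive = np.ones(len(coords), dtype=bool)
    if len(pairs):
        order = np.argsort(pairs.max(axis=1))
        for i, j in pairs[order]:
            if alive[i] and alive[j]:
                alive[max(i, j)] = False
    return SampledCloud(PointCloud(coords=coords[alive]), labels[alive])


def true_vegetation_volume(scene: SyntheticScene, edge: float) -> float:
    """Reference voxel volume (m^3) of the analytic litter + stem geometry.

    Densely samples the analytic surfaces at edge/5 resolution (no
    randomness, independent of the sampled cloud) and voxelizes at the
    same origin convention the pipeline uses (frame corner at the
    terrain minimum).
    """
    if edge <= 0:
        raise ValueError("edge must be positive")
    frame = scene.frame
    step = edge / 5.0
    pts = []
    if scene.litter_mask is not None and scene.litter_mask.any():
        xs = np.arange(frame.x0 + step / 2, frame.x0 + frame.width_x, step)
        ys = np.arange(frame.y0 + step / 2, frame.y0 + frame.width_y, step)
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        xy = np.column_stack([gx.ravel(), gy.ravel()])
        covered = scene.litter_at(xy)
        xy = xy[covered]
        z = scene.terrain_z(xy[:, 0], xy[:, 1]) + scene.params.litter_thickness_m
        pts.append(np.column_stack([xy, z]))
    for s in range(scene.params.stem_count):
        h, r = scene.stem_height[s], scene.stem_radius[s]
        n_rings = max(2, int(np.ceil(h / step)))
        t = (np.arange(n_rings) + 0.5) / n_rings
        axis = scene.stem_axis(s, t)
        m = max(4, int(np.ceil(2 * np.pi * r / step)))
        theta = 2 * np.pi * (np.arange(m) + 0.5) / m
        offsets = r * np.column_stack([np.cos(theta), np.sin(theta), np.zeros(m)])
        stem = (axis[:, None, :] + offsets[None, :, :]).reshape(-1, 3)
        stem = stem[frame.contains(stem[:, :2])]
        if len(stem):
            buried = scene.litter_at(stem[:, :2]) & (
                stem[:, 2]
                < scene.terrain_z(stem[:, 0], stem[:, 1]) + scene.params.litter_thickness_m
            )
            stem = stem[~buried]
        pts.append(stem)
    if not pts:
        return 0.0
    allpts = np.concatenate(pts)
    if len(allpts) == 0:
        return 0.0
    ref = scene.reference_ground()
    origin = (frame.x0, frame.y0, float(ref.z.min()))
    return voxel_volume(allpts, edge, origin)[1]


def draw_biomass(
    scene_volume: float,
    model: AllometryModel,
    seed: int,
    plot_id: str = "synthetic",
) -> BiomassRecord:
    """Draw one plot's biomass from the power-law model with lognormal noise."""
    if scene_volume <= 0:
        raise ValueError("scene volume must be positive")
    rng = np.random.default_rng(seed)
    noise = np.exp(rng.normal(0.0, model.noise_sd_log)) if model.noise_sd_log > 0 else 1.0
    total = (
        model.coefficient_g
        * (scene_volume / model.reference_volume_m3) ** model.exponent
        * noise
    )
    litter = model.litter_fraction_of_total * total
    veg = total - litter
    wa, wp, wf = model.component_split
    wsum = wa + wp + wf
    return BiomassRecord(
        plot_id=plot_id,
        annual_g=veg * wa / wsum,
        perennial_g=veg * wp / wsum,
        forb_g=veg * wf / wsum,
        litter_g=litter,
    )
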