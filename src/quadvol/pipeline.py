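"""Per-plot and cohort orchestration.

``run_plot`` executes the full workflow on one quadrat cloud:
clip -> denoise -> SMRF -> iterative GMM refinement -> ground-surface
fit -> above-surface selection -> CHM + convex hull + voxel sweep.
``run_cohort`` joins per-plot volumes with the biomass table and fits
every estimator x biomass-component x {linear, log} combination with
f^2 power screening, plus the voxel-size Wilcoxon table and (when
reference surfaces exist) the reconstructed-vs-reference agreement
report.  Plot failures are isolated: a failing plot is recorded in the
manifest with its stage and reason and the run continues.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .allometry import (RegressionResult, compare_voxel_distributions,
                        fit_linear, fit_log, power_screen)
from .classify import (ClassificationResult, RefineParams, SmrfParams,
                       iterative_refine, smrf_classify)
from .denoise import DenoiseParams, statistical_outlier_filter
from .frames import QuadratFrame
from .io import (LABEL_GROUND, LABEL_VEGETATION, BiomassRecord, PointCloud,
                 clip_to_frame, read_point_cloud)
from .surfaces import (AgreementReport, TerrainGrid, fit_ground_surface,
                       points_above_surface, surface_agreement)
from .volumes import (ChmParams, PlotVolumes, VoxelParams, compute_chm,
                      convex_hull_volume, voxel_size_sweep, voxel_volume)

log = logging.getLogger("quadvol")

M3_TO_CM3 = 1e6


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the per-plot workflow in one auditable place."""

    frame: QuadratFrame = QuadratFrame()
    denoise: DenoiseParams = DenoiseParams()
    smrf: SmrfParams = SmrfParams()
    refine: RefineParams = RefineParams()
    chm: ChmParams = ChmParams()
    voxel: VoxelParams = VoxelParams()
    alpha: float = 0.05
    min_power: float = 0.90
    #: margin (m) above the reference soil surface beyond which a point
    #: counts as nonground in the reference-surface volume variant
    reference_margin_m: float = 0.002
    seed: int = 0

    def to_dict(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            out[f.name] = dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        kwargs = {}
        section_types = {
            "frame": QuadratFrame, "denoise": DenoiseParams, "smrf": SmrfParams,
            "refine": RefineParams, "chm": ChmParams, "voxel": VoxelParams,
        }
        for key, value in data.items():
            if key in section_types:
                if isinstance(value, dict):
                    value = {
                        k: tuple(v) if isinstance(v, list) else v for k, v in value.items()
                    }
                    kwargs[key] = section_types[key](**value)
                else:
                    kwargs[key] = value
            else:
                kwargs[key] = value
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)


@dataclass
class PlotResult:
    plot_id: str
    volumes: PlotVolumes
    classification: ClassificationResult
    terrain: TerrainGrid
    labeled_cloud: PointCloud
    n_input: int
    n_clipped: int
    n_denoised: int
    n_ground: int
    n_vegetation: int
    n_above_surface: int
    n_outside_grid: int
    hull_degenerate: bool
    hull_above_volume: float  # m^3
    voxel_above_5mm: float  # m^3, above-surface points at the 5 mm edge
    reference_voxel_5mm: float | None = None  # m^3, above the reference surface


def run_plot(
    cloud: PointCloud | str | Path,
    config: PipelineConfig = PipelineConfig(),
    plot_id: str = "plot",
    reference_ground: TerrainGrid | None = None,
) -> PlotResult:
    """Full classification + volumetrics workflow for one quadrat cloud."""
    if not isinstance(cloud, PointCloud):
        cloud = read_point_cloud(cloud)
    n_input = len(cloud)

    clipped = clip_to_frame(cloud, config.frame)
    log.info("%s: clip %d -> %d points", plot_id, n_input, len(clipped))
    if len(clipped) <= config.denoise.k_neighbors:
        raise ValueError(
            f"{plot_id}: only {len(clipped)} points inside frame; "
            f"need more than k={config.denoise.k_neighbors}"
        )
    denoised, n_removed = statistical_outlier_filter(clipped, config.denoise)
    log.info("%s: denoise removed %d points", plot_id, n_removed)

    smrf_labels = smrf_classify(denoised, config.smrf, frame=config.frame)
    result = iterative_refine(denoised, smrf_labels, config.refine, seed=config.seed)
    labels = result.labels
    n_ground = int((labels == LABEL_GROUND).sum())
    n_veg = int((labels == LABEL_VEGETATION).sum())
    log.info("%s: classified %d ground / %d vegetation (%d refinement passes)",
             plot_id, n_ground, n_veg, result.iterations_run)

    terrain = fit_ground_surface(
        denoised.coords[labels == LABEL_GROUND], config.frame, config.chm.cell_size
    )
    above, heights, n_outside = points_above_surface(denoised, labels, terrain)

    chm = compute_chm(above.coords[:, :2], heights, config.frame, config.chm)
    veg_points = denoised.coords[labels == LABEL_VEGETATION]
    hull = convex_hull_volume(veg_points)
    hull_above = convex_hull_volume(above.coords)
    origin = (config.frame.x0, config.frame.y0, float(terrain.z.min()))
    counts, vols = voxel_size_sweep(veg_points, config.voxel, origin)
    voxel_above = voxel_volume(above.coords, 0.005, origin)[1]

    reference_5mm = None
    if reference_ground is not None:
        ref_elev = reference_ground.elevation_at(denoised.coords[:, :2])
        nonground = denoised.coords[denoised.z > ref_elev + config.reference_margin_m]
        ref_origin = (config.frame.x0, config.frame.y0, float(reference_ground.z.min()))
        reference_5mm = voxel_volume(nonground, 0.005, ref_origin)[1]

    volumes = PlotVolumes(
        plot_id=plot_id,
        chm_mean_height=chm.mean_height,
        chm_volume=chm.volume,
        hull_volume=hull.volume,
        voxel_volume=vols,
        occupied_count=counts,
    )
    return PlotResult(
        plot_id=plot_id,
        volumes=volumes,
        classification=result,
        terrain=terrain,
        labeled_cloud=denoised.with_labels(labels),
        n_input=n_input,
        n_clipped=len(clipped),
        n_denoised=len(denoised),
        n_ground=n_ground,
        n_vegetation=n_veg,
        n_above_surface=len(above),
        n_outside_grid=n_outside,
        hull_degenerate=hull.degenerate,
        hull_above_volume=hull_above.volume,
        voxel_above_5mm=voxel_above,
        reference_voxel_5mm=reference_5mm,
    )


def _edge_label(edge_m: float) -> str:
    return f"{edge_m * 1000:g}mm"


def volumes_row(result: PlotResult) -> dict:
    """One volumes.csv row, volumes in cm^3."""
    row = {
        "plot_id": result.plot_id,
        "n_points": result.n_denoised,
        "n_ground": result.n_ground,
        "n_vegetation": result.n_vegetation,
        "chm_mean_height_m": result.volumes.chm_mean_height,
        "chm_volume_cm3": result.volumes.chm_volume * M3_TO_CM3,
        "hull_volume_cm3": result.volumes.hull_volume * M3_TO_CM3,
        "hull_above_cm3": result.hull_above_volume * M3_TO_CM3,
    }
    for edge, vol in result.volumes.voxel_volume.items():
        row[f"voxel_{_edge_label(edge)}_cm3"] = vol * M3_TO_CM3
    row["voxel_above_5mm_cm3"] = result.voxel_above_5mm * M3_TO_CM3
    if result.reference_voxel_5mm is not None:
        row["voxel_ref_5mm_cm3"] = result.reference_voxel_5mm * M3_TO_CM3
    return row


#: biomass component -> record attribute(s)
_COMPONENTS = {
    "vegetation": lambda r: r.vegetation_total,
    "total": lambda r: r.total,
    "grass": lambda r: r.annual_g + r.perennial_g,
}


@dataclass
class CohortReport:
    regressions: pd.DataFrame
    wilcoxon: pd.DataFrame | None = None
    agreement: AgreementReport | None = None
    unmatched_plots: list[str] = dc_field(default_factory=list)


def run_cohort(
    volumes: pd.DataFrame,
    biomass: list[BiomassRecord],
    config: PipelineConfig = PipelineConfig(),
    forms: tuple[str, ...] = ("linear", "log"),
) -> CohortReport:
    """Fit every estimator x component x form combination with power screening."""
    bio = pd.DataFrame(
        {
            "plot_id": [r.plot_id for r in biomass],
            **{
                name: [fn(r) for r in biomass]
                for name, fn in _COMPONENTS.items()
            },
        }
    )
    merged = volumes.merge(bio, on="plot_id", how="inner")
    unmatched = sorted(set(volumes["plot_id"]) - set(bio["plot_id"]))
    if unmatched:
        log.warning("plots without biomass rows (excluded): %s", unmatched)
    if len(merged) < 3:
        raise ValueError("need >= 3 plots with matching biomass rows")

    estimator_cols = [
        c for c in volumes.columns
        if c.endswith("_cm3") or c == "chm_mean_height_m"
    ]
    rows = []
    for est in estimator_cols:
        x = merged[est].to_numpy(dtype=float)
        for comp in _COMPONENTS:
            y = merged[comp].to_numpy(dtype=float)
            for form in forms:
                try:
                    if form == "linear":
                        fit = fit_linear(x, y)
                    elif form == "log":
                        fit = fit_log(x, y)
                    elif form == "semilog":
                        fit = fit_log(x, y, semilog=True)
                    else:
                        raise ValueError(f"unknown model form {form!r}")
                except ValueError as exc:
                    log.warning("skipping %s/%s/%s: %s", est, comp, form, exc)
                    continue
                fit = power_screen(fit, alpha=config.alpha, min_power=config.min_power)
                rows.append({"estimator": est, "component": comp, **dataclasses.asdict(fit)})
    regressions = pd.DataFrame(rows)

    voxel_cols = [
        c for c in volumes.columns
        if c.startswith("voxel_") and c.endswith("_cm3") and "above" not in c and "ref" not in c
    ]
    wilcoxon = None
    if len(voxel_cols) >= 2 and len(merged) >= 6:
        wilcoxon = compare_voxel_distributions(merged[voxel_cols], alpha=config.alpha)

    agreement = None
    if {"voxel_above_5mm_cm3", "voxel_ref_5mm_cm3"} <= set(merged.columns):
        sub = merged.dropna(subset=["voxel_above_5mm_cm3", "voxel_ref_5mm_cm3"])
        if len(sub) >= 3:
            agreement = surface_agreement(
                sub["voxel_above_5mm_cm3"].to_numpy(),
                sub["voxel_ref_5mm_cm3"].to_numpy(),
            )
    return CohortReport(regressions=regressions, wilcoxon=wilcoxon,
                        agreement=agreement, unmatched_plots=unmatched)
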